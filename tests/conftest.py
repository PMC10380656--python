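import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_transcript  # noqa: E402

from svaexo.synthetic_cohort import SimulationConfig, simulate  # noqa: E402


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """One default-condition synthetic cohort shared across the session:
    (config, truth, output directory)."""
    config = SimulationConfig(seed=11)
    outdir = tmp_path_factory.mktemp("cohort")
    truth = simulate(config, outdir)
    return config, truth, outdir


@pytest.fixture
def toy_transcript_plus():
    return make_transcript()


@pytest.fixture
def toy_transcript_minus():
    return make_transcript(strand="-")
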