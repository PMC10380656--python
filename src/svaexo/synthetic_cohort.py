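"""Synthetic cohort generator.

Emits a fully specified toy study — genome, transcript annotation, SVA
coordinates, per-sample splice junctions, SV deletion genotypes, phenotypes
and a normalised count matrix — together with a machine-readable truth
table, so every pipeline stage can be tested end to end without
access-controlled data.

Planted structure
-----------------
* exonised SVAs inside transcript exons with a configurable placement mix
  (5'UTR / CDS / 3'UTR / non-coding exon) and same-orientation fraction;
* intronic SVAs, a subset within 100 bp of an exon, one of which mimics the
  genotype-conditional alternative-acceptor case: its alternative junction
  is emitted only for samples carrying at least one absent allele;
* novel SVA-to-exon junctions with per-sample Bernoulli dropout;
* presence/absence genotypes under Hardy-Weinberg at configurable MAFs,
  disease labels from a logistic model with a planted per-allele odds
  ratio, onset ages with a planted slope, exponential survival with a
  planted hazard ratio, all with age/sex/platform covariates;
* negative-binomial counts with log-linear diagnosis, tissue and genotype
  effects.

Determinism: one global seed; each stage derives its own generator from
``default_rng([seed, stage_index])`` so stages can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core_io import (
    CountMatrix,
    GenomicInterval,
    RipGenotypeMatrix,
    SpliceJunction,
    SvaElement,
    SvDeletionCall,
    TranscriptModel,
    ValidationError,
    write_count_matrix,
    write_fasta,
    write_gtf,
    write_junction_table,
    write_sva_bed,
    write_sv_vcf,
)

log = logging.getLogger("svaexo")

_STAGE = {"genome": 1, "genotypes": 2, "junctions": 3, "counts": 4}

PLACEMENTS = ("five_prime_utr", "cds", "three_prime_utr", "noncoding_exon")

#: dose of the absent allele -> presence/absence genotype
DOSE_TO_GENOTYPE = {0: "PP", 1: "PA", 2: "AA"}


@dataclass
class SimulationConfig:
    """Study conditions for the toy cohort (desk scale by default;
    ``full_scale`` switches the association cohort to 322 controls and
    2663 cases)."""

    seed: int = 0
    # genome / annotation
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_transcripts: int = 60
    # SVAs
    n_sva_total: int = 40
    n_sva_exonised: int = 10
    placement_mix: dict = field(
        default_factory=lambda: {
            "five_prime_utr": 0.2,
            "cds": 0.2,
            "three_prime_utr": 0.4,
            "noncoding_exon": 0.2,
        }
    )
    same_orientation_fraction: float = 0.82
    intronic_same_orientation_fraction: float = 0.29
    n_sva_proximal: int = 4
    proximal_window: int = 100
    # RIP genotypes and phenotypes
    n_sva_rip: int = 20
    rip_mafs: list = field(
        default_factory=lambda: [
            0.29, 0.15, 0.33, 0.25, 0.10, 0.20, 0.35, 0.40, 0.12, 0.18,
            0.22, 0.27, 0.30, 0.08, 0.45, 0.02, 0.03, 0.04, 0.01, 0.045,
        ]
    )
    n_cases: int = 500
    n_controls: int = 100
    full_scale: bool = False
    planted_or: float = 0.78
    onset_slope: float = -1.15     # years per present-allele copy
    onset_baseline: float = 59.6   # mean onset age at genotype AA
    planted_hr: float = 1.5        # per absent-allele copy
    # junction evidence
    n_novel_junctions: int = 8
    junction_dropout: float = 0.0
    n_junction_samples: int = 10
    casp8_gap: int = 30            # intron gap 5' of the downstream exon
    casp8_expressed_extension: int = 191
    # counts
    de_effects: dict = field(
        default_factory=lambda: {
            "diagnosis": {"n": 3, "log2fc": 1.0},
            "tissue": {"n": 3, "log2fc": 1.0},
            "genotype": {"n": 2, "log2fc": -0.5},
        }
    )
    nb_dispersion: float = 0.2

    def __post_init__(self) -> None:
        if abs(sum(self.placement_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("placement_mix proportions must sum to 1")
        if any(not (0 < m <= 0.5) for m in self.rip_mafs):
            raise ValidationError("rip_mafs must be in (0, 0.5]")
        for name in ("n_transcripts", "n_sva_total", "n_sva_exonised",
                     "n_sva_rip", "n_cases", "n_controls", "n_novel_junctions"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.junction_dropout <= 1:
            raise ValidationError("junction_dropout must be in [0, 1]")
        if self.n_sva_exonised > self.n_sva_total:
            raise ValidationError("n_sva_exonised cannot exceed n_sva_total")

    @property
    def cohort_sizes(self) -> tuple:
        if self.full_scale:
            return 2663, 322
        return self.n_cases, self.n_controls


@dataclass
class SyntheticTruth:
    """Everything planted, traceable through the emitted files."""

    config: SimulationConfig
    genome: dict
    transcripts: list
    svas: list
    exonised: list          # {sva_id, transcript_id, placement, same_orientation}
    intronic_orientation: dict  # sva_id -> same_orientation (vs host)
    novel_junctions: list   # {sva_id, chrom, intron_start, intron_end, ...}
    casp8: dict | None
    rips: list              # {sva_id, maf, causal}
    sample_ids: list = field(default_factory=list)
    genotype_dose: pd.DataFrame | None = None   # rip sva_id x sample, #A alleles
    phenotypes: pd.DataFrame | None = None
    junction_presence: dict = field(default_factory=dict)  # key -> {sample: bool}
    de_truth: list = field(default_factory=list)

    @property
    def causal_rip(self) -> str | None:
        for r in self.rips:
            if r["causal"]:
                return r["sva_id"]
        return None

    def to_json_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "config": cfg,
            "exonised": self.exonised,
            "intronic_orientation": self.intronic_orientation,
            "novel_junctions": self.novel_junctions,
            "casp8": self.casp8,
            "rips": self.rips,
            "sample_ids": self.sample_ids,
            "junction_presence": {
                "|".join(map(str, k)) if isinstance(k, tuple) else k: v
                for k, v in self.junction_presence.items()
            },
            "de_truth": self.de_truth,
        }


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


def _apportion(n: int, proportions: Mapping[str, float]) -> dict:
    """Deterministic largest-remainder apportionment of n among categories."""
    keys = list(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    rest = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:rest]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# genome + annotation + SVAs
# ---------------------------------------------------------------------------

_BASE_TABLE = bytes.maketrans(bytes(range(4)), b"ACGT")


def _random_sequence(rng, length: int) -> str:
    return bytes(rng.integers(0, 4, size=length, dtype=np.uint8)).translate(
        _BASE_TABLE
    ).decode("ascii")


def _build_transcript(tid, gene_idx, chrom, cursor, strand, biotype, role, rng):
    """One transcript starting at ``cursor``; returns (model, planted SVA
    interval or None, next cursor)."""
    n_exons = int(rng.integers(3, 6))
    exon_lens = [int(rng.integers(150, 351)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(2500, 5001)) for _ in range(n_exons - 1)]
    head_gidx = 0 if strand == "+" else n_exons - 1   # first exon, tx orientation
    tail_gidx = n_exons - 1 if strand == "+" else 0

    sva_len = int(rng.integers(250, 401))
    if role == "five_prime_utr":
        exon_lens[head_gidx] = 1200
    elif role == "three_prime_utr":
        exon_lens[tail_gidx] = 1200
    elif role == "cds":
        exon_lens[n_exons // 2] = 600
    elif role == "noncoding_exon":
        exon_lens[1] = 800

    starts, pos = [], cursor
    for i, L in enumerate(exon_lens):
        starts.append(pos)
        pos += L
        if i < n_exons - 1:
            pos += intron_lens[i]
    exons = [
        GenomicInterval(chrom, s, s + L, strand) for s, L in zip(starts, exon_lens)
    ]

    coding = biotype in ("protein_coding", "nonsense_mediated_decay")
    cds_span = None
    if coding:
        a = 800 if role == "five_prime_utr" else 80   # 5' UTR length in head exon
        b = 300 if role == "three_prime_utr" else 80  # coding length in tail exon
        head, tail = exons[head_gidx], exons[tail_gidx]
        if strand == "+":
            cds_lo, cds_hi = head.start + a, tail.start + b
        else:
            cds_lo, cds_hi = tail.end - b, head.end - a
        cds_span = GenomicInterval(chrom, cds_lo, cds_hi, strand)

    sva_iv = None
    if role == "five_prime_utr":
        e = exons[head_gidx]
        if strand == "+":
            sva_iv = (e.start + 100, e.start + 100 + sva_len)
        else:
            sva_iv = (e.end - 100 - sva_len, e.end - 100)
    elif role == "three_prime_utr":
        e = exons[tail_gidx]
        if strand == "+":
            sva_iv = (e.start + 400, e.start + 400 + sva_len)
        else:
            sva_iv = (e.end - 400 - sva_len, e.end - 400)
    elif role == "cds":
        e = exons[n_exons // 2]
        sva_iv = (e.start + 100, e.start + 100 + sva_len)
    elif role == "noncoding_exon":
        e = exons[1]
        sva_iv = (e.start + 100, e.start + 100 + sva_len)

    model = TranscriptModel(
        transcript_id=tid,
        gene_id=f"GENE{gene_idx:04d}",
        gene_name=f"gene{gene_idx}",
        strand=strand,
        exons=tuple(exons),
        cds_span=cds_span,
        biotype=biotype,
    )
    return model, sva_iv, pos + int(rng.integers(4000, 8001))


def make_genome_and_annotation(config: SimulationConfig) -> SyntheticTruth:
    """Random genome, transcript models, planted SVAs and the truth table."""
    rng = _rng(config, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # roles for exonised SVA hosts
    placement_counts = _apportion(config.n_sva_exonised, config.placement_mix)
    roles = []
    for placement in PLACEMENTS:
        roles.extend([placement] * placement_counts.get(placement, 0))
    if len(roles) > config.n_transcripts:
        raise ValidationError("more exonised SVAs than transcripts to host them")

    biotype_pool = ["protein_coding", "lncRNA", "nonsense_mediated_decay",
                    "processed_transcript"]
    biotype_probs = [0.5, 0.25, 0.1, 0.15]

    transcripts, exonised, svas = [], [], []
    cursors = {c: 10_000 for c in chroms}
    sva_counter = 0
    for i in range(config.n_transcripts):
        chrom = chroms[i % len(chroms)]
        role = roles[i] if i < len(roles) else None
        strand = "+" if rng.random() < 0.5 else "-"
        if role == "noncoding_exon":
            biotype = "lncRNA"
        elif role is not None:
            biotype = "protein_coding"
        else:
            biotype = str(rng.choice(biotype_pool, p=biotype_probs))
        model, sva_iv, nxt = _build_transcript(
            f"TX{i:04d}", i, chrom, cursors[chrom], strand, biotype, role, rng
        )
        cursors[chrom] = nxt
        transcripts.append(model)
        if sva_iv is not None:
            sva_counter += 1
            same = bool(rng.random() < config.same_orientation_fraction)
            sva_strand = strand if same else ("-" if strand == "+" else "+")
            sva = SvaElement(
                f"SVA_{sva_counter}",
                GenomicInterval(chrom, sva_iv[0], sva_iv[1], sva_strand),
                subtype=str(rng.choice(["D", "E", "F"])),
            )
            svas.append(sva)
            exonised.append(
                {
                    "sva_id": sva.sva_id,
                    "transcript_id": model.transcript_id,
                    "placement": role,
                    "same_orientation": same,
                }
            )
    for chrom in chroms:
        if cursors[chrom] > config.chrom_length:
            raise ValidationError(
                f"infeasible packing: {chrom} needs {cursors[chrom]} bp "
                f"> chrom_length {config.chrom_length}"
            )

    # ---- intronic SVAs -----------------------------------------------------
    n_intronic = config.n_sva_total - config.n_sva_exonised
    has_casp8 = n_intronic >= 1 and config.n_sva_rip >= 1
    n_proximal = min(config.n_sva_proximal, max(0, n_intronic - int(has_casp8)))
    n_novel = min(
        config.n_novel_junctions, max(0, n_intronic - int(has_casp8) - n_proximal)
    )

    plus_hosts = [t for t in transcripts if t.strand == "+" and len(t.exons) >= 3]
    all_hosts = [t for t in transcripts if len(t.exons) >= 3]
    host_cycle = list(rng.permutation(len(all_hosts)))

    intronic_orientation: dict[str, bool] = {}
    novel_junctions, casp8 = [], None
    used_introns: set = set()

    def place_in_intron(host, margin_left, margin_right, sva_len, rng):
        for idx, intron in enumerate(host.introns):
            key = (host.transcript_id, idx)
            if key in used_introns:
                continue
            if intron.length >= margin_left + sva_len + margin_right + 10:
                used_introns.add(key)
                start = intron.start + margin_left
                return idx, intron, start, start + sva_len
        return None

    def new_intronic_sva(host, margin_left, margin_right, sva_len):
        nonlocal sva_counter
        spot = place_in_intron(host, margin_left, margin_right, sva_len, rng)
        if spot is None:
            return None
        idx, intron, lo, hi = spot
        sva_counter += 1
        same = bool(rng.random() < config.intronic_same_orientation_fraction)
        strand = host.strand if same else ("-" if host.strand == "+" else "+")
        sva = SvaElement(
            f"SVA_{sva_counter}",
            GenomicInterval(host.chrom, lo, hi, strand),
            subtype=str(rng.choice(["D", "E", "F"])),
        )
        svas.append(sva)
        intronic_orientation[sva.sva_id] = same
        return sva, idx, intron

    made = 0
    # CASP8-like element: just 5' of the downstream exon (+-strand host)
    if has_casp8 and plus_hosts:
        host = plus_hosts[int(rng.integers(0, len(plus_hosts)))]
        sva_len = 800
        flank5 = config.casp8_expressed_extension - config.casp8_gap
        spot = place_in_intron(host, flank5 + 150, config.casp8_gap, sva_len, rng)
        if spot is not None:
            idx, intron, _, _ = spot
            hi = intron.end - config.casp8_gap
            lo = hi - sva_len
            sva_counter += 1
            same = bool(rng.random() < config.intronic_same_orientation_fraction)
            strand = host.strand if same else "-"
            sva = SvaElement(
                f"SVA_{sva_counter}",
                GenomicInterval(host.chrom, lo, hi, strand),
                subtype="E",
            )
            svas.append(sva)
            intronic_orientation[sva.sva_id] = same
            alt_end = lo - flank5
            casp8 = {
                "sva_id": sva.sva_id,
                "transcript_id": host.transcript_id,
                "chrom": host.chrom,
                "annotated_intron": [intron.start, intron.end],
                "alt_intron": [intron.start, alt_end],
                "expressed_extension_bp": (lo - alt_end) + config.casp8_gap,
                "reference_extension_bp": intron.end - alt_end,
                "gap_bp": config.casp8_gap,
            }
            made += 1

    # proximal intronic SVAs (within the 100-bp window of an exon)
    for _ in range(n_proximal):
        host = all_hosts[host_cycle[made % len(host_cycle)]]
        made += 1
        gap = int(rng.integers(5, config.proximal_window - 19))
        sva_len = int(rng.integers(800, 1401))
        spot = place_in_intron(host, 150, gap, sva_len, rng)
        if spot is None:
            continue
        idx, intron, _, _ = spot
        hi = intron.end - gap
        lo = hi - sva_len
        sva_counter += 1
        same = bool(rng.random() < config.intronic_same_orientation_fraction)
        strand = host.strand if same else ("-" if host.strand == "+" else "+")
        sva = SvaElement(
            f"SVA_{sva_counter}",
            GenomicInterval(host.chrom, lo, hi, strand),
            subtype=str(rng.choice(["D", "E", "F"])),
        )
        svas.append(sva)
        intronic_orientation[sva.sva_id] = same

    # novel-junction SVAs: splice from inside the SVA to an adjacent exon
    for _ in range(n_novel):
        host = all_hosts[host_cycle[made % len(host_cycle)]]
        made += 1
        sva_len = int(rng.integers(800, 1401))
        out = new_intronic_sva(host, 150, 150, sva_len)
        if out is None:
            continue
        sva, idx, intron = out
        mid = (sva.interval.start + sva.interval.end) // 2
        if rng.random() < 0.5:
            j_start, j_end = mid, intron.end          # SVA donor side (genomic)
        else:
            j_start, j_end = intron.start, mid        # SVA acceptor side
        novel_junctions.append(
            {
                "sva_id": sva.sva_id,
                "transcript_id": host.transcript_id,
                "chrom": host.chrom,
                "intron_start": int(j_start),
                "intron_end": int(j_end),
                "strand": host.strand,
                "same_orientation": sva.interval.strand == host.strand,
            }
        )

    # plain intronic background
    while len(svas) < config.n_sva_total:
        host = all_hosts[host_cycle[made % len(host_cycle)]]
        made += 1
        if new_intronic_sva(host, 150, 150, int(rng.integers(800, 1401))) is None:
            if made > config.n_sva_total * 10:
                raise ValidationError("infeasible packing: not enough intron space")

    # ---- RIP designation ---------------------------------------------------
    intronic_ids = [s for s in intronic_orientation]
    rip_ids = []
    if casp8 is not None:
        rip_ids.append(casp8["sva_id"])
    for sid in intronic_ids:
        if len(rip_ids) >= config.n_sva_rip:
            break
        if sid not in rip_ids:
            rip_ids.append(sid)
    mafs = [config.rip_mafs[i % len(config.rip_mafs)] for i in range(len(rip_ids))]
    # the causal element gets the first configured MAF; CASP8-like is listed
    # first so reorder: the causal RIP is the first non-CASP8 entry
    rips = []
    causal_assigned = False
    for sid, maf in zip(rip_ids, mafs):
        causal = False
        if not causal_assigned and (casp8 is None or sid != casp8["sva_id"]):
            causal = True
            causal_assigned = True
        rips.append({"sva_id": sid, "maf": float(maf), "causal": causal})

    genome = {c: _random_sequence(rng, config.chrom_length) for c in chroms}
    svas.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return SyntheticTruth(
        config=config,
        genome=genome,
        transcripts=transcripts,
        svas=svas,
        exonised=exonised,
        intronic_orientation=intronic_orientation,
        novel_junctions=novel_junctions,
        casp8=casp8,
        rips=rips,
    )


# ---------------------------------------------------------------------------
# SV genotypes + phenotypes
# ---------------------------------------------------------------------------

def draw_hwe_doses(maf: float, n: int, rng) -> np.ndarray:
    """Hardy-Weinberg absent-allele doses (0/1/2) at allele frequency maf."""
    q = maf
    return rng.choice(3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def draw_covariates(n: int, rng) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(58, 10, size=n), 18, 90).round(1),
            "sex": np.where(rng.random(n) < 0.58, "M", "F"),
            "platform": np.where(rng.random(n) < 0.5, "HiSeq", "NovaSeq"),
            "onset_site": np.where(rng.random(n) < 0.3, "bulbar", "limb"),
        }
    )


def draw_case_labels(
    dose: np.ndarray, covars: pd.DataFrame, planted_or: float, case_fraction: float, rng
) -> np.ndarray:
    """Bernoulli case labels from a logistic model with the planted
    per-allele odds ratio and mild covariate effects; the intercept is
    calibrated so the expected case fraction matches the design."""
    lp = (
        np.log(planted_or) * dose
        + 0.45 * (covars["sex"] == "M").to_numpy(float)
        + 0.01 * (covars["age"].to_numpy(float) - 58.0)
        + 0.10 * (covars["platform"] == "NovaSeq").to_numpy(float)
    )
    b0 = brentq(lambda b: expit(lp + b).mean() - case_fraction, -30, 30)
    return (rng.random(len(lp)) < expit(lp + b0)).astype(int)


def make_sv_genotypes(truth: SyntheticTruth, config: SimulationConfig) -> tuple:
    """Deletion calls (coextensive with each RIP) and the phenotype table;
    fills truth.sample_ids, truth.genotype_dose and truth.phenotypes."""
    rng = _rng(config, "genotypes")
    n_cases, n_controls = config.cohort_sizes
    n = n_cases + n_controls
    samples = [f"SAMP{i:04d}" for i in range(n)]
    sva_by_id = {s.sva_id: s for s in truth.svas}

    dose = pd.DataFrame(
        {
            r["sva_id"]: draw_hwe_doses(r["maf"], n, rng)
            for r in truth.rips
        },
        index=samples,
    ).T

    covars = draw_covariates(n, rng)
    covars.index = samples
    causal = truth.causal_rip
    g = dose.loc[causal].to_numpy() if causal else np.zeros(n, dtype=int)
    case = draw_case_labels(g, covars, config.planted_or, n_cases / n, rng)

    diagnosis = np.where(
        case == 1, np.where(rng.random(n) < 0.9, "ALS", "ALSND"), "NNC"
    )
    g_present = 2 - g
    onset = (
        config.onset_baseline
        + config.onset_slope * g_present
        - 0.5 * (covars["sex"] == "M").to_numpy(float)
        + rng.normal(0, 8, size=n)
    ).round(1)
    hazard = (1 / 30.0) * np.exp(
        np.log(config.planted_hr) * g + 0.2 * (covars["sex"] == "M").to_numpy(float)
    )
    t_event = rng.exponential(1 / hazard)
    t_censor = rng.uniform(6, 72, size=n)
    survival = np.minimum(t_event, t_censor).round(2)
    event = (t_event <= t_censor).astype(int)

    pheno = covars.copy()
    pheno["diagnosis"] = diagnosis
    pheno["onset_age"] = np.where(case == 1, onset, np.nan)
    pheno["survival_months"] = np.where(case == 1, survival, np.nan)
    pheno["event"] = np.where(case == 1, event, np.nan)

    calls = []
    for r in truth.rips:
        sva = sva_by_id[r["sva_id"]]
        d = dose.loc[r["sva_id"]]
        gts = {s: ("0/0", "0/1", "1/1")[int(d[s])] for s in samples}
        gqs = {s: 99 for s in samples}
        calls.append(
            SvDeletionCall(
                interval=GenomicInterval(
                    sva.interval.chrom, sva.interval.start, sva.interval.end, "."
                ),
                sample_genotypes=gts,
                filter_status="PASS",
                genotype_qualities=gqs,
                variant_id=f"DEL_{r['sva_id']}",
            )
        )

    truth.sample_ids = samples
    truth.genotype_dose = dose
    truth.phenotypes = pheno
    return calls, pheno


def truth_rip_matrix(truth: SyntheticTruth) -> RipGenotypeMatrix:
    """The planted genotypes as a presence/absence matrix (oracle view)."""
    geno = truth.genotype_dose.apply(
        lambda row: row.map(lambda d: DOSE_TO_GENOTYPE[int(d)]), axis=1
    )
    return RipGenotypeMatrix(geno)


# ---------------------------------------------------------------------------
# junction tables
# ---------------------------------------------------------------------------

def make_junctions(truth: SyntheticTruth, config: SimulationConfig) -> dict:
    """Per-sample junction lists: every annotated intron plus planted novel
    junctions with Bernoulli(1 - dropout) presence, plus the CASP8-like
    alternative junction for absent-allele carriers only."""
    rng = _rng(config, "junctions")
    if not truth.sample_ids:
        make_sv_genotypes(truth, config)
    samples = truth.sample_ids[: config.n_junction_samples]
    out: dict[str, list] = {s: [] for s in samples}
    presence: dict[tuple, dict] = {}

    for s in samples:
        for t in truth.transcripts:
            for intron in t.introns:
                out[s].append(
                    SpliceJunction(
                        chrom=t.chrom,
                        intron_start=intron.start,
                        intron_end=intron.end,
                        strand=t.strand,
                        unique_reads=int(rng.poisson(30) + 1),
                        sample_id=s,
                    )
                )

    for nj in truth.novel_junctions:
        key = (nj["chrom"], nj["intron_start"], nj["intron_end"])
        presence[key] = {}
        for s in samples:
            present = bool(rng.random() >= config.junction_dropout)
            presence[key][s] = present
            if present:
                out[s].append(
                    SpliceJunction(
                        chrom=nj["chrom"],
                        intron_start=nj["intron_start"],
                        intron_end=nj["intron_end"],
                        strand=nj["strand"],
                        unique_reads=int(rng.poisson(15) + 1),
                        sample_id=s,
                    )
                )

    if truth.casp8 is not None and truth.genotype_dose is not None:
        c = truth.casp8
        key = (c["chrom"], c["alt_intron"][0], c["alt_intron"][1])
        presence[key] = {}
        dose = truth.genotype_dose.loc[c["sva_id"]]
        for s in samples:
            carrier = int(dose[s]) >= 1  # >= 1 absent allele
            presence[key][s] = carrier
            if carrier:
                out[s].append(
                    SpliceJunction(
                        chrom=c["chrom"],
                        intron_start=c["alt_intron"][0],
                        intron_end=c["alt_intron"][1],
                        strand="+",
                        unique_reads=int(rng.poisson(12) + 1),
                        sample_id=s,
                    )
                )
    truth.junction_presence = presence
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def make_counts(truth: SyntheticTruth, config: SimulationConfig) -> CountMatrix:
    """Negative-binomial counts with log-linear diagnosis / tissue /
    genotype effects; metadata mirrors the phenotype table plus a tissue."""
    rng = _rng(config, "counts")
    if truth.phenotypes is None:
        make_sv_genotypes(truth, config)
    samples = truth.sample_ids
    pheno = truth.phenotypes
    tissues = rng.choice(
        ["MCX", "FCX", "SC", "CER"], size=len(samples), p=[0.3, 0.2, 0.3, 0.2]
    )
    tids = [t.transcript_id for t in truth.transcripts]
    base_log2 = rng.uniform(4, 9, size=len(tids))

    eff = config.de_effects
    pool = list(tids)
    de_truth = []
    log2fc = np.zeros((len(tids), len(samples)))
    is_case = pheno["diagnosis"].isin(["ALS", "ALSND"]).to_numpy(float)
    causal = truth.causal_rip
    g_present = (
        (2 - truth.genotype_dose.loc[causal].to_numpy(float))
        if causal is not None
        else np.zeros(len(samples))
    )
    cursor = 0
    for factor in ("diagnosis", "tissue", "genotype"):
        spec_ = eff.get(factor, {})
        n_aff, fc = int(spec_.get("n", 0)), float(spec_.get("log2fc", 0.0))
        chosen = pool[cursor : cursor + n_aff]
        cursor += n_aff
        for tid in chosen:
            i = tids.index(tid)
            if factor == "diagnosis":
                log2fc[i] += fc * is_case
                detail = "ALS/ALSND vs NNC"
            elif factor == "tissue":
                log2fc[i] += fc * (tissues == "SC").astype(float)
                detail = "SC vs rest"
            else:
                log2fc[i] += fc * g_present
                detail = f"per present allele of {causal}"
            de_truth.append(
                {"transcript_id": tid, "factor": factor, "log2fc": fc, "detail": detail}
            )

    mu = 2.0 ** (base_log2[:, None] + log2fc)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    frame = pd.DataFrame(counts, index=tids, columns=samples)
    meta = pheno.copy()
    meta.insert(0, "tissue", tissues)
    truth.de_truth = de_truth
    return CountMatrix(counts=frame.astype(float), metadata=meta)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, outdir: str | Path) -> SyntheticTruth:
    """Run every stage and write the full cohort to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_genome_and_annotation(config)
    calls, pheno = make_sv_genotypes(truth, config)
    junctions = make_junctions(truth, config)
    countmat = make_counts(truth, config)

    write_fasta(truth.genome, outdir / "genome.fa")
    write_gtf(truth.transcripts, outdir / "annot.gtf")
    write_sva_bed(truth.svas, outdir / "svas.bed")
    jdir = outdir / "junctions"
    jdir.mkdir(exist_ok=True)
    for sample, js in junctions.items():
        write_junction_table(js, jdir / f"{sample}.tsv")
    write_sv_vcf(
        calls,
        outdir / "dels.vcf",
        contigs={c: config.chrom_length for c in sorted(truth.genome)},
    )
    p = pheno.copy()
    p.index.name = "sample_id"
    p.to_csv(outdir / "pheno.tsv", sep="\t")
    write_count_matrix(countmat, outdir / "counts.tsv", outdir / "meta.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# lightweight association-replicate helper (no genome needed)
# ---------------------------------------------------------------------------

def simulate_association_cohort(
    n_cases: int,
    n_controls: int,
    maf: float,
    planted_or: float,
    rng,
    onset_slope: float = -1.15,
    onset_baseline: float = 59.6,
    planted_hr: float = 1.5,
) -> tuple:
    """One association replicate: (RipGenotypeMatrix with a single locus,
    phenotype frame). Used for repeated-recovery experiments where the
    genome and junction machinery are irrelevant."""
    n = n_cases + n_controls
    samples = [f"SAMP{i:04d}" for i in range(n)]
    dose = draw_hwe_doses(maf, n, rng)
    covars = draw_covariates(n, rng)
    covars.index = samples
    case = draw_case_labels(dose, covars, planted_or, n_cases / n, rng)
    pheno = covars.copy()
    pheno["diagnosis"] = np.where(case == 1, "ALS", "NNC")
    g_present = 2 - dose
    pheno["onset_age"] = np.where(
        case == 1,
        (onset_baseline + onset_slope * g_present + rng.normal(0, 8, n)).round(1),
        np.nan,
    )
    hazard = (1 / 30.0) * np.exp(np.log(planted_hr) * dose)
    t_event = rng.exponential(1 / hazard)
    t_censor = rng.uniform(6, 72, size=n)
    pheno["survival_months"] = np.where(
        case == 1, np.minimum(t_event, t_censor).round(2), np.nan
    )
    pheno["event"] = np.where(case == 1, (t_event <= t_censor).astype(int), np.nan)
    geno = pd.DataFrame(
        [[DOSE_TO_GENOTYPE[int(d)] for d in dose]], index=["SVA_sim"], columns=samples
    )
    return RipGenotypeMatrix(geno), pheno
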