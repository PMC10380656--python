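"""Annotation-based exonisation screen.

Intersects reference SVA elements with the exons of annotated transcripts,
classifies where each element sits in the transcript structure (UTR / CDS /
non-coding exon, first or last coding exon) and summarises the orientation
bias of exonised versus intronic elements, tested with a two-sided Fisher
exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .core_io import (
    ContractError,
    GenomicInterval,
    SvaElement,
    TranscriptModel,
    ValidationError,
    fetch_seq,
    spliced_sequence,
)

log = logging.getLogger("svaexo")

PLACEMENTS = ("five_prime_utr", "cds", "three_prime_utr", "cds_and_utr", "noncoding_exon")
CODING_POSITIONS = ("first_coding", "last_coding", "internal", "not_applicable")

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: closed biotype -> category mapping; unknown biotypes fall back on the
#: presence of a CDS (other_coding) or not (other_noncoding).
BIOTYPE_CATEGORIES = {
    "protein_coding": "protein_coding",
    "nonsense_mediated_decay": "nmd",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "processed_transcript": "processed_transcript",
    "non_stop_decay": "other_coding",
    "protein_coding_LoF": "other_coding",
    "IG_C_gene": "other_coding",
    "TR_C_gene": "other_coding",
    "retained_intron": "other_noncoding",
    "processed_pseudogene": "other_noncoding",
    "unprocessed_pseudogene": "other_noncoding",
    "misc_RNA": "other_noncoding",
    "miRNA": "other_noncoding",
    "snoRNA": "other_noncoding",
    "snRNA": "other_noncoding",
}


@dataclass(frozen=True)
class ExonisationRecord:
    """One (SVA, transcript, exon) overlap with its classification."""

    sva_id: str
    transcript_id: str
    gene_name: str
    exon_index: int
    overlap_bp: int
    overlap_start: int  # genomic coordinates of the overlapped segment
    overlap_end: int
    same_orientation: bool
    placement: str = "noncoding_exon"
    coding_exon_position: str = "not_applicable"
    transcript_category: str = "other_noncoding"


@dataclass(frozen=True)
class OrientationTable:
    """2x2 counts: rows (exonised, intronic) x columns (same, opposite)."""

    exonised_same: int
    exonised_opposite: int
    intronic_same: int
    intronic_opposite: int
    n_ambiguous_excluded: int = 0

    @property
    def table(self) -> list:
        return [
            [self.exonised_same, self.exonised_opposite],
            [self.intronic_same, self.intronic_opposite],
        ]

    @property
    def exonised_same_fraction(self) -> float:
        n = self.exonised_same + self.exonised_opposite
        return self.exonised_same / n if n else float("nan")

    @property
    def intronic_same_fraction(self) -> float:
        n = self.intronic_same + self.intronic_opposite
        return self.intronic_same / n if n else float("nan")


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

def _exon_trees(transcripts: Sequence[TranscriptModel]) -> dict:
    trees: dict[str, IntervalTree] = {}
    for ti, t in enumerate(transcripts):
        for ei, e in enumerate(t.exons):
            trees.setdefault(t.chrom, IntervalTree()).addi(e.start, e.end, (ti, ei))
    return trees


def intersect_sva_exons(
    svas: Sequence[SvaElement],
    transcripts: Sequence[TranscriptModel],
    min_overlap: int = 1,
) -> list:
    """All (SVA, transcript, exon) triples with >= ``min_overlap`` shared bp,
    classified by placement and transcript category, in deterministic
    (sva_id, transcript_id, exon_index) order."""
    if min_overlap < 1:
        raise ContractError("min_overlap must be >= 1")
    trees = _exon_trees(transcripts)
    records = []
    for sva in svas:
        iv = sva.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            ti, ei = hit.data
            t = transcripts[ti]
            exon = t.exons[ei]
            ov = iv.overlap_bp(exon)
            if ov < min_overlap:
                continue
            rec = ExonisationRecord(
                sva_id=sva.sva_id,
                transcript_id=t.transcript_id,
                gene_name=t.gene_name,
                exon_index=ei,
                overlap_bp=ov,
                overlap_start=max(iv.start, exon.start),
                overlap_end=min(iv.end, exon.end),
                same_orientation=(iv.strand == t.strand),
                transcript_category=classify_transcript(t),
            )
            placement, coding_pos = classify_placement(rec, t)
            records.append(
                replace(rec, placement=placement, coding_exon_position=coding_pos)
            )
    records.sort(key=lambda r: (r.sva_id, r.transcript_id, r.exon_index))
    return records


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_placement(record: ExonisationRecord, transcript: TranscriptModel) -> tuple:
    """(placement, coding_exon_position) of an overlap within a transcript.

    Orientation-aware: for a '-' transcript the 5' UTR is genomically
    downstream of the CDS. The coding-exon position marks whether the
    overlapped exon is the first or last CDS-containing exon in transcript
    orientation (ties for a single coding exon resolve to first_coding).
    """
    if not (0 <= record.exon_index < len(transcript.exons)):
        raise ContractError(
            f"record exon_index {record.exon_index} outside transcript "
            f"{transcript.transcript_id}"
        )
    exon = transcript.exons[record.exon_index]
    if not (exon.start <= record.overlap_start < record.overlap_end <= exon.end):
        raise ContractError("record overlap does not lie within the named exon")

    cds = transcript.cds_span
    if cds is None:
        return "noncoding_exon", "not_applicable"

    os_, oe = record.overlap_start, record.overlap_end
    if oe <= cds.start:
        placement = "five_prime_utr" if transcript.strand == "+" else "three_prime_utr"
    elif os_ >= cds.end:
        placement = "three_prime_utr" if transcript.strand == "+" else "five_prime_utr"
    elif cds.start <= os_ and oe <= cds.end:
        placement = "cds"
    else:
        placement = "cds_and_utr"

    coding_idx = [
        i for i, e in enumerate(transcript.exons)
        if max(e.start, cds.start) < min(e.end, cds.end)
    ]
    first, last = coding_idx[0], coding_idx[-1]
    if transcript.strand == "-":
        first, last = last, first
    if record.exon_index == first:
        coding_pos = "first_coding"
    elif record.exon_index == last:
        coding_pos = "last_coding"
    else:
        coding_pos = "internal"
    return placement, coding_pos


def classify_transcript(transcript: TranscriptModel) -> str:
    """Biotype -> category via a closed mapping; unknown biotypes fall back
    to other_coding / other_noncoding on CDS presence."""
    cat = BIOTYPE_CATEGORIES.get(transcript.biotype)
    if cat is not None:
        return cat
    return "other_coding" if transcript.cds_span is not None else "other_noncoding"


# ---------------------------------------------------------------------------
# premature-termination / NMD 50-nt rule
# ---------------------------------------------------------------------------

def _spliced_positions(transcript: TranscriptModel) -> tuple:
    """Cumulative exon lengths: spliced offset of each exon (genomic order)."""
    offsets, total = [], 0
    for e in transcript.exons:
        offsets.append(total)
        total += e.length
    return offsets, total


def _genomic_to_spliced(transcript: TranscriptModel, pos: int) -> int:
    """Map a genomic position (within an exon, or an exon boundary) to the
    spliced coordinate in *transcript orientation*."""
    offsets, total = _spliced_positions(transcript)
    for off, e in zip(offsets, transcript.exons):
        if e.start <= pos <= e.end:
            plus = off + (pos - e.start)
            return plus if transcript.strand == "+" else total - plus
    raise ContractError(f"position {pos} not exonic in {transcript.transcript_id}")


def ptc_nmd_rule(transcript: TranscriptModel, genome) -> bool:
    """50-nt rule: True iff the (first in-frame) stop codon ends more than
    50 nt upstream of the final exon-exon junction in spliced coordinates.

    Fallback predictor used only when the biotype does not already carry an
    NMD annotation. A CDS whose spliced length is not a multiple of 3
    triggers a warning and returns False.
    """
    if transcript.cds_span is None or len(transcript.exons) < 2:
        raise ContractError("ptc_nmd_rule requires a CDS and >= 2 exons")

    cds = transcript.cds_span
    blocks = []
    for e in transcript.exons:
        lo, hi = max(e.start, cds.start), min(e.end, cds.end)
        if lo < hi:
            blocks.append((lo, hi))
    seq = "".join(fetch_seq(genome, transcript.chrom, lo, hi) for lo, hi in blocks)
    from .core_io import revcomp

    if transcript.strand == "-":
        seq = revcomp(seq)
    if len(seq) % 3 != 0:
        warnings.warn(
            f"{transcript.transcript_id}: spliced CDS length {len(seq)} "
            "not a multiple of 3; NMD rule returns False"
        )
        return False

    stop_end_spliced = None
    cds_start_spliced = _genomic_to_spliced(
        transcript, cds.start if transcript.strand == "+" else cds.end
    )
    for i in range(0, len(seq), 3):
        if seq[i : i + 3] in STOP_CODONS:
            stop_end_spliced = cds_start_spliced + i + 3
            break
    if stop_end_spliced is None:
        return False

    # final exon-exon junction = start of the last exon in transcript orientation
    last_exon = transcript.exons[-1] if transcript.strand == "+" else transcript.exons[0]
    junction_pos = last_exon.start if transcript.strand == "+" else last_exon.end
    junction_spliced = _genomic_to_spliced(transcript, junction_pos)
    return (junction_spliced - stop_end_spliced) > 50


# ---------------------------------------------------------------------------
# SVA context assignment and orientation summary
# ---------------------------------------------------------------------------

def assign_sva_context(
    svas: Sequence[SvaElement],
    transcripts: Sequence[TranscriptModel],
    records: Sequence[ExonisationRecord] | None = None,
) -> dict:
    """Per-SVA context: category 'exonised' | 'intronic' | 'other', the
    orientation call and, for intronic elements, the host transcripts.

    Exonisation takes precedence over intronic residence. Intronic hosts
    are transcripts in which the SVA lies entirely within one intron; the
    orientation is judged against the host gene with the longest overlap,
    and gene-level ties spanning both strands are flagged ambiguous.
    """
    if records is None:
        records = intersect_sva_exons(svas, transcripts)
    rec_by_sva: dict[str, list] = {}
    for r in records:
        rec_by_sva.setdefault(r.sva_id, []).append(r)
    t_by_id = {t.transcript_id: t for t in transcripts}

    out = {}
    for sva in svas:
        iv = sva.interval
        if sva.sva_id in rec_by_sva:
            recs = rec_by_sva[sva.sva_id]
            best = max(recs, key=lambda r: (r.overlap_bp, r.transcript_id))
            out[sva.sva_id] = {
                "category": "exonised",
                "same_orientation": best.same_orientation,
                "hosts": sorted({r.transcript_id for r in recs}),
                "ambiguous": False,
            }
            continue
        hosts = []
        for t in transcripts:
            if t.chrom != iv.chrom:
                continue
            if any(intron.contains(iv) for intron in t.introns):
                hosts.append(t)
        if not hosts:
            out[sva.sva_id] = {
                "category": "other",
                "same_orientation": None,
                "hosts": [],
                "ambiguous": False,
            }
            continue
        # longest gene-span overlap; the SVA is fully intronic so overlaps tie
        # at its own length whenever it is contained — break ties by strand
        by_gene: dict[str, tuple] = {}
        for t in hosts:
            ov = iv.overlap_bp(t.span)
            prev = by_gene.get(t.gene_id)
            if prev is None or ov > prev[0]:
                by_gene[t.gene_id] = (ov, t.strand, t.transcript_id)
        best_ov = max(v[0] for v in by_gene.values())
        top = [v for v in by_gene.values() if v[0] == best_ov]
        strands = {v[1] for v in top}
        ambiguous = len(strands) > 1
        out[sva.sva_id] = {
            "category": "intronic",
            "same_orientation": None if ambiguous else (iv.strand == top[0][1]),
            "hosts": sorted(t.transcript_id for t in hosts),
            "ambiguous": ambiguous,
        }
    return out


def orientation_summary(
    svas: Sequence[SvaElement],
    transcripts: Sequence[TranscriptModel],
    records: Sequence[ExonisationRecord] | None = None,
) -> OrientationTable:
    """Count SVAs (not records) by category x orientation."""
    ctx = assign_sva_context(svas, transcripts, records)
    cells = {"exonised": [0, 0], "intronic": [0, 0]}
    n_ambiguous = 0
    for info in ctx.values():
        cat = info["category"]
        if cat not in cells:
            continue
        if info["ambiguous"]:
            n_ambiguous += 1
            continue
        cells[cat][0 if info["same_orientation"] else 1] += 1
    return OrientationTable(
        exonised_same=cells["exonised"][0],
        exonised_opposite=cells["exonised"][1],
        intronic_same=cells["intronic"][0],
        intronic_opposite=cells["intronic"][1],
        n_ambiguous_excluded=n_ambiguous,
    )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums, in log space, the hypergeometric probabilities of all tables with
    the observed margins whose probability is <= that of the observed table
    (relative tie tolerance 1e-7).
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ContractError("Fisher table cells must be >= 0")
    n = a + b + c + d
    if n == 0:
        raise ContractError("Fisher table is all zero")
    r1, c1 = a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        return 1.0
    kmin = max(0, c1 - (n - r1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    logp = hypergeom.logpmf(ks, n, r1, c1)
    obs = hypergeom.logpmf(a, n, r1, c1)
    mask = logp <= obs + 1e-7
    # log-sum-exp over the selected tables
    m = logp[mask].max()
    p = float(np.exp(m) * np.exp(logp[mask] - m).sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# result table
# ---------------------------------------------------------------------------

RECORD_COLUMNS = (
    "sva_id",
    "transcript_id",
    "gene_name",
    "exon_index",
    "overlap_bp",
    "same_orientation",
    "placement",
    "coding_exon_position",
    "transcript_category",
)


def records_to_frame(records: Sequence[ExonisationRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
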