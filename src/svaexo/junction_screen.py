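"""Junction-evidence screens.

Calls novel exonisation events from per-sample splice-junction tables
(one splice site inside a reference SVA, the other exactly on an annotated
exon boundary, and the intron itself unannotated), screens for intronic
SVAs close to exons, tests genotype-conditional junction usage, measures
alternative-acceptor exon extensions and scans included intronic sequence
for in-frame stop codons.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .core_io import (
    ContractError,
    GenomicInterval,
    RipGenotypeMatrix,
    SpliceJunction,
    SvaElement,
    TranscriptModel,
    fetch_seq,
    revcomp,
)
from .exon_screen import STOP_CODONS, assign_sva_context, fisher_exact_2x2

log = logging.getLogger("svaexo")


@dataclass(frozen=True)
class NovelExonisationCall:
    """A recurrent SVA-to-exon junction merged across samples."""

    sva_id: str
    junction: SpliceJunction  # canonical, sample-agnostic (sample_id='merged')
    partner_transcript_id: str
    partner_exon_index: int
    sva_end: str  # which splice site falls in the SVA: 'donor' | 'acceptor'
    same_orientation: bool
    samples_detected: frozenset
    total_detections: int


@dataclass(frozen=True)
class GenotypeJunctionAssociation:
    """Junction presence split by RIP genotype with a Fisher exact test on
    presence x (carries >= 1 absent allele)."""

    sva_id: str
    junction: SpliceJunction
    presence_by_genotype: dict  # genotype -> (n_with_junction, n_without)
    p_value: float
    consistent_with_absence_model: bool


# ---------------------------------------------------------------------------
# novel exonisation caller
# ---------------------------------------------------------------------------

def _sva_tree(svas: Sequence[SvaElement]) -> dict:
    trees: dict[str, IntervalTree] = {}
    for s in svas:
        iv = s.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, s)
    return trees


def _boundary_index(transcripts: Sequence[TranscriptModel]) -> tuple:
    """Exact lookup of annotated exon boundaries and annotated introns."""
    starts: dict[tuple, list] = {}
    ends: dict[tuple, list] = {}
    introns: set[tuple] = set()
    for ti, t in enumerate(transcripts):
        for ei, e in enumerate(t.exons):
            starts.setdefault((t.chrom, e.start), []).append((ti, ei))
            ends.setdefault((t.chrom, e.end), []).append((ti, ei))
        for iv in t.introns:
            introns.add((t.chrom, iv.start, iv.end))
    return starts, ends, introns


def call_novel_exonisation(
    junctions_by_sample: Mapping[str, Sequence[SpliceJunction]],
    svas: Sequence[SvaElement],
    transcripts: Sequence[TranscriptModel],
    min_reads: int = 1,
    boundary_tolerance: int = 0,
) -> list:
    """Novel exonisation calls merged across samples.

    A junction qualifies iff (a) exactly one of its splice sites lies within
    an SVA, (b) the other site coincides with an annotated exon start/end
    (within ``boundary_tolerance`` bp, default exact), (c) its intron is not
    an annotated intron, and (d) it has >= ``min_reads`` unique reads in
    that sample. The terminal intronic bases (``intron_start`` and
    ``intron_end - 1``) are the points tested for SVA membership.
    """
    trees = _sva_tree(svas)
    starts, ends, introns = _boundary_index(transcripts)

    def boundary_hits(index, chrom, pos):
        if boundary_tolerance == 0:
            return index.get((chrom, pos), [])
        hits = []
        for delta in range(-boundary_tolerance, boundary_tolerance + 1):
            hits.extend(index.get((chrom, pos + delta), []))
        return hits

    merged: dict[tuple, dict] = {}
    for sample_id, junctions in junctions_by_sample.items():
        for j in junctions:
            if j.unique_reads < min_reads:
                continue
            if (j.chrom, j.intron_start, j.intron_end) in introns:
                continue  # (c)
            tree = trees.get(j.chrom)
            if tree is None:
                continue
            left_svas = {iv.data for iv in tree.at(j.intron_start)}
            right_svas = {iv.data for iv in tree.at(j.intron_end - 1)}
            left_in = bool(left_svas)
            right_in = bool(right_svas)
            if left_in == right_in:
                continue  # (a): exactly one site in an SVA
            if left_in:
                partner = boundary_hits(starts, j.chrom, j.intron_end)
                sva = min(left_svas, key=lambda s: s.sva_id)
            else:
                partner = boundary_hits(ends, j.chrom, j.intron_start)
                sva = min(right_svas, key=lambda s: s.sva_id)
            if not partner:
                continue  # (b)
            key = (j.chrom, j.intron_start, j.intron_end)
            entry = merged.setdefault(
                key,
                {"samples": set(), "reads": 0, "sva": sva, "partner": partner,
                 "sva_side": "left" if left_in else "right"},
            )
            entry["samples"].add(sample_id)
            entry["reads"] += j.unique_reads

    calls = []
    for (chrom, i_start, i_end), entry in sorted(merged.items()):
        ti, ei = min(entry["partner"], key=lambda h: transcripts[h[0]].transcript_id)
        t = transcripts[ti]
        sva = entry["sva"]
        # donor = transcript-5' side of the intron
        if entry["sva_side"] == "left":
            sva_end = "donor" if t.strand == "+" else "acceptor"
        else:
            sva_end = "acceptor" if t.strand == "+" else "donor"
        calls.append(
            NovelExonisationCall(
                sva_id=sva.sva_id,
                junction=SpliceJunction(
                    chrom=chrom,
                    intron_start=i_start,
                    intron_end=i_end,
                    strand=".",
                    unique_reads=entry["reads"],
                    sample_id="merged",
                ),
                partner_transcript_id=t.transcript_id,
                partner_exon_index=ei,
                sva_end=sva_end,
                same_orientation=(sva.interval.strand == t.strand),
                samples_detected=frozenset(entry["samples"]),
                total_detections=len(entry["samples"]),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecurrenceSummary:
    n_calls: int
    total_detections: int
    mean_detections: float | None
    histogram: dict  # per-call sample count -> number of calls


def recurrence_summary(calls: Sequence[NovelExonisationCall]) -> RecurrenceSummary:
    """Mean per-call sample count and its histogram; empty input -> mean absent."""
    if not calls:
        return RecurrenceSummary(0, 0, None, {})
    counts = [c.total_detections for c in calls]
    return RecurrenceSummary(
        n_calls=len(calls),
        total_detections=sum(counts),
        mean_detections=sum(counts) / len(counts),
        histogram=dict(sorted(Counter(counts).items())),
    )


# ---------------------------------------------------------------------------
# proximity screen
# ---------------------------------------------------------------------------

def proximal_sva_screen(
    svas: Sequence[SvaElement],
    transcripts: Sequence[TranscriptModel],
    window: int = 100,
) -> list:
    """Intronic SVAs whose nearest boundary is within ``window`` bp
    (inclusive) of an exon boundary of a host transcript. Exonised SVAs are
    excluded; distance 0 means the SVA abuts the exon."""
    if window < 0:
        raise ContractError("window must be >= 0")
    ctx = assign_sva_context(svas, transcripts)
    t_by_id = {t.transcript_id: t for t in transcripts}
    out = []
    for sva in svas:
        info = ctx[sva.sva_id]
        if info["category"] != "intronic":
            continue
        iv = sva.interval
        for tid in info["hosts"]:
            t = t_by_id[tid]
            for i, intron in enumerate(t.introns):
                if not intron.contains(iv):
                    continue
                left_gap = iv.start - intron.start   # to upstream exon (genomic)
                right_gap = intron.end - iv.end      # to downstream exon
                if left_gap <= right_gap:
                    distance, exon_index = left_gap, i
                else:
                    distance, exon_index = right_gap, i + 1
                if distance <= window:
                    out.append((sva.sva_id, tid, exon_index, distance))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# genotype-conditional junction usage
# ---------------------------------------------------------------------------

def genotype_conditional_junctions(
    junctions_by_sample: Mapping[str, Sequence[SpliceJunction]],
    genotypes: RipGenotypeMatrix,
    sva_id: str,
    candidate_junction: SpliceJunction,
) -> GenotypeJunctionAssociation:
    """Test whether a candidate junction is restricted to carriers of the
    SVA-absent allele (AA or PA genotypes).

    Builds the presence x carrier 2x2 table over genotyped samples (missing
    genotypes excluded) and computes a two-sided Fisher exact p. The model
    flag is True iff at least one sample shows the junction and every such
    sample carries >= 1 absent allele.
    """
    if sva_id not in genotypes.sva_ids:
        raise ContractError(f"{sva_id} not in genotype matrix")
    key = candidate_junction.coords
    table = {"AA": [0, 0], "PA": [0, 0], "PP": [0, 0]}
    n_genotyped = 0
    positives_all_carriers = True
    any_positive = False
    for sample_id in junctions_by_sample:
        if sample_id not in genotypes.sample_ids:
            continue
        gt = genotypes.genotype(sva_id, sample_id)
        if gt == "missing":
            continue
        n_genotyped += 1
        present = any(
            j.coords == key and j.unique_reads > 0
            for j in junctions_by_sample[sample_id]
        )
        table[gt][0 if present else 1] += 1
        if present:
            any_positive = True
            if gt == "PP":
                positives_all_carriers = False
    if n_genotyped == 0:
        raise ContractError("no genotyped samples among the junction samples")

    carrier_with = table["AA"][0] + table["PA"][0]
    carrier_without = table["AA"][1] + table["PA"][1]
    p = fisher_exact_2x2(
        [[carrier_with, carrier_without], [table["PP"][0], table["PP"][1]]]
    )
    return GenotypeJunctionAssociation(
        sva_id=sva_id,
        junction=candidate_junction,
        presence_by_genotype={g: tuple(v) for g, v in table.items()},
        p_value=p,
        consistent_with_absence_model=any_positive and positives_all_carriers,
    )


# ---------------------------------------------------------------------------
# alternative acceptor extension
# ---------------------------------------------------------------------------

def alt_acceptor_extension(
    candidate_junction: SpliceJunction,
    annotated_junction: SpliceJunction,
    transcript: TranscriptModel,
) -> tuple:
    """(extension_bp, side) of a candidate junction relative to an annotated
    one sharing a splice site. ``side`` reports where intronic sequence is
    added relative to the annotated exon, in transcript orientation."""
    share_left = candidate_junction.intron_start == annotated_junction.intron_start
    share_right = candidate_junction.intron_end == annotated_junction.intron_end
    if not (share_left or share_right):
        raise ContractError("junctions share neither splice site")
    if share_left and share_right:
        return 0, "five_prime_of_exon" if transcript.strand == "+" else "three_prime_of_exon"
    if share_left:
        # acceptor moved: affects the genomic-left edge of the downstream exon
        extension = abs(candidate_junction.intron_end - annotated_junction.intron_end)
        side = "five_prime_of_exon" if transcript.strand == "+" else "three_prime_of_exon"
    else:
        # donor moved: affects the genomic-right edge of the upstream exon
        extension = abs(candidate_junction.intron_start - annotated_junction.intron_start)
        side = "three_prime_of_exon" if transcript.strand == "+" else "five_prime_of_exon"
    return extension, side


# ---------------------------------------------------------------------------
# stop-codon scan of included intronic sequence
# ---------------------------------------------------------------------------

def stop_codon_scan(
    transcript: TranscriptModel,
    included_interval: GenomicInterval,
    genome,
) -> list:
    """Codon indices (0-based, in the modified CDS) of stop codons introduced
    upstream of the annotated stop when ``included_interval`` (a slice of an
    intron) is retained in the spliced transcript.

    The modified CDS is rebuilt from the genomic blocks overlapping the
    annotated CDS span plus the included block, reverse-complemented for
    '-' transcripts, and translated in the annotated frame.
    """
    if transcript.cds_span is None:
        raise ContractError("stop_codon_scan requires a coding transcript")
    if included_interval.chrom != transcript.chrom or not any(
        intron.contains(included_interval) for intron in transcript.introns
    ):
        raise ContractError("included interval does not lie within an intron")

    cds = transcript.cds_span
    blocks = []
    for e in transcript.exons:
        lo, hi = max(e.start, cds.start), min(e.end, cds.end)
        if lo < hi:
            blocks.append((lo, hi))
    inc_lo = max(included_interval.start, cds.start)
    inc_hi = min(included_interval.end, cds.end)
    if inc_lo < inc_hi:
        blocks.append((inc_lo, inc_hi))
    blocks.sort()
    seq = "".join(fetch_seq(genome, transcript.chrom, lo, hi) for lo, hi in blocks)
    if transcript.strand == "-":
        seq = revcomp(seq)

    n_codons = len(seq) // 3
    stops = [
        i // 3
        for i in range(0, n_codons * 3, 3)
        if seq[i : i + 3] in STOP_CODONS
    ]
    if not stops:
        return []
    annotated_last = n_codons - 1
    # stops strictly before the final (annotated) codon are "additional"
    return [s for s in stops if s < annotated_last]


CALL_COLUMNS = (
    "sva_id",
    "chrom",
    "intron_start",
    "intron_end",
    "partner_transcript_id",
    "partner_exon_index",
    "sva_end",
    "same_orientation",
    "n_samples",
    "total_reads",
)


def calls_to_frame(calls: Sequence[NovelExonisationCall]):
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "sva_id": c.sva_id,
                "chrom": c.junction.chrom,
                "intron_start": c.junction.intron_start,
                "intron_end": c.junction.intron_end,
                "partner_transcript_id": c.partner_transcript_id,
                "partner_exon_index": c.partner_exon_index,
                "sva_end": c.sva_end,
                "same_orientation": c.same_orientation,
                "n_samples": c.total_detections,
                "total_reads": c.junction.unique_reads,
            }
        )
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))
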