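"""Domain types and file I/O for the SVA exonisation pipeline.

Coordinate convention
---------------------
Every in-memory coordinate is **0-based half-open** ``[start, end)``.
External 1-based formats (GTF, VCF, STAR-style junction tables) are
converted at the boundary on read and converted back on write, so the
rest of the pipeline never sees a 1-based number.

The types here are deliberately thin: validated records plus a handful of
interval helpers. Anything statistical lives in the analysis modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

log = logging.getLogger("svaexo")

STRANDS = {"+", "-", "."}
SVA_SUBTYPES = {"A", "B", "C", "D", "E", "F", "F1", "unknown"}
RIP_GENOTYPES = {"PP", "PA", "AA", "missing"}
VCF_GENOTYPES = {"0/0", "0/1", "1/1", "missing"}

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


class ParseError(ValueError):
    """A file could not be parsed (malformed line, truncated record...)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class ContractError(ValueError):
    """An operation was called outside its stated preconditions."""


class AmbiguityError(ValidationError):
    """Two records compete for one slot where exactly one is allowed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 when chromosomes differ or disjoint."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(self), overlap/len(other)) — the SV-matching criterion."""
        ov = self.overlap_bp(other)
        return min(ov / self.length, ov / other.length)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SvaElement:
    """A reference SVA retrotransposon: the unit being screened."""

    sva_id: str
    interval: GenomicInterval
    subtype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sva_id:
            raise ValidationError("sva_id must be non-empty")
        if self.subtype not in SVA_SUBTYPES:
            raise ValidationError(
                f"SVA subtype {self.subtype!r} not in {sorted(SVA_SUBTYPES)}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons, optional genomic CDS extent, biotype."""

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: tuple  # tuple[GenomicInterval, ...] in genomic order
    cds_span: GenomicInterval | None = None
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError("transcript strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValidationError(f"{self.transcript_id}: exons on multiple chromosomes")
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e.end
        if self.cds_span is not None:
            if not (
                self.exons[0].start <= self.cds_span.start
                and self.cds_span.end <= self.exons[-1].end
            ):
                raise ValidationError(
                    f"{self.transcript_id}: CDS span outside transcript extent"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple:
        """Intron intervals (0-based half-open), genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class SpliceJunction:
    """One observed intron in one sample. Coordinates are the intronic bases:
    ``intron_start`` is the first intronic base (0-based), ``intron_end`` one
    past the last intronic base."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    unique_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValidationError(
                f"intron_start must be < intron_end: "
                f"[{self.intron_start}, {self.intron_end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad junction strand {self.strand!r}")
        if self.unique_reads < 0:
            raise ValidationError("unique_reads must be >= 0")

    @property
    def intron(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def coords(self) -> tuple:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class SvDeletionCall:
    """A structural-variant deletion with per-sample genotypes."""

    interval: GenomicInterval
    sample_genotypes: Mapping[str, str]
    filter_status: str
    genotype_qualities: Mapping[str, int | None] = field(default_factory=dict)
    variant_id: str = "."

    def __post_init__(self) -> None:
        if not self.filter_status:
            raise ValidationError("filter_status must be non-empty")
        bad = {g for g in self.sample_genotypes.values()} - VCF_GENOTYPES
        if bad:
            raise ValidationError(f"genotypes outside vocabulary: {bad}")


@dataclass
class RipGenotypeMatrix:
    """Presence/absence genotypes (PP/PA/AA/missing) per SVA x sample.

    P is the SVA-present allele (the reference), A the absent allele
    (seen as a deletion in SV calls).
    """

    genotypes: pd.DataFrame  # index = sva_ids, columns = sample_ids

    def __post_init__(self) -> None:
        bad = set(np.unique(self.genotypes.values.astype(str))) - RIP_GENOTYPES
        if bad:
            raise ValidationError(f"RIP genotypes outside vocabulary: {bad}")
        if self.genotypes.index.has_duplicates or self.genotypes.columns.has_duplicates:
            raise ValidationError("duplicate sva_id or sample_id in genotype matrix")

    @property
    def sva_ids(self) -> list:
        return list(self.genotypes.index)

    @property
    def sample_ids(self) -> list:
        return list(self.genotypes.columns)

    def genotype(self, sva_id: str, sample_id: str) -> str:
        return self.genotypes.at[sva_id, sample_id]


#: metadata columns expected alongside a count matrix
METADATA_COLUMNS = ("tissue", "diagnosis", "age", "sex", "platform")
TISSUES = ("MCX", "FCX", "SC", "CER")
DIAGNOSES = ("ALS", "ALSND", "NNC")


@dataclass
class CountMatrix:
    """Normalised transcript x sample counts with per-sample metadata."""

    counts: pd.DataFrame    # index = transcript_ids, columns = sample_ids
    metadata: pd.DataFrame  # index = sample_ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def transcript_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# BED: reference SVA coordinates
# ---------------------------------------------------------------------------

def read_sva_bed(path: str | Path) -> list:
    """Read reference SVAs from a BED6 file whose name column is
    ``sva_id|subtype`` (subtype optional -> 'unknown')."""
    out: list[SvaElement] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >= 6 BED columns")
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                strand = cols[5]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            name = cols[3]
            sva_id, _, subtype = name.partition("|")
            subtype = subtype or "unknown"
            if sva_id in seen:
                raise ValidationError(f"{path}: duplicate sva_id {sva_id!r}")
            seen.add(sva_id)
            try:
                out.append(
                    SvaElement(sva_id, GenomicInterval(chrom, start, end, strand), subtype)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_sva_bed(svas: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in svas:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.sva_id}|{s.subtype}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF: transcript annotation
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list:
    """Read transcript models from a GTF (Gencode-style attributes).

    1-based inclusive GTF coordinates become internal 0-based half-open
    ``(start-1, end)``. Exons are grouped per transcript and sorted; the CDS
    span is min(CDS start)..max(CDS end) when CDS records exist.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: could not parse GTF: {exc}") from exc

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    attrs: dict[str, dict] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            tids = feat.attributes.get("transcript_id")
            if not tids:
                raise ParseError(
                    f"{path}: {ftype} at {feat.seqid}:{feat.start} lacks transcript_id"
                )
            tid = tids[0]
            store.setdefault(tid, []).append(feat)
            if tid not in attrs:
                attrs[tid] = {
                    "gene_id": feat.attributes.get("gene_id", [tid])[0],
                    "gene_name": feat.attributes.get("gene_name", [""])[0],
                    "biotype": (
                        feat.attributes.get("transcript_type")
                        or feat.attributes.get("transcript_biotype")
                        or ["unknown"]
                    )[0],
                    "strand": feat.strand,
                }

    out = []
    for tid in exons:
        meta = attrs[tid]
        ivs = sorted(
            (
                GenomicInterval(f.seqid, f.start - 1, f.end, meta["strand"])
                for f in exons[tid]
            ),
            key=lambda iv: iv.start,
        )
        cds_span = None
        if tid in cds:
            lo = min(f.start - 1 for f in cds[tid])
            hi = max(f.end for f in cds[tid])
            cds_span = GenomicInterval(ivs[0].chrom, lo, hi, meta["strand"])
        gene_name = meta["gene_name"] or meta["gene_id"]
        try:
            out.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=meta["gene_id"],
                    gene_name=gene_name,
                    strand=meta["strand"],
                    exons=tuple(ivs),
                    cds_span=cds_span,
                    biotype=meta["biotype"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: transcript {tid}: {exc}") from exc
    out.sort(key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    return out


def write_gtf(transcripts: Sequence, path: str | Path, source: str = "svaexo") -> None:
    """Write transcript/exon/CDS records back to 1-based GTF."""
    def attr(t) -> str:
        return (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_name "{t.gene_name}"; transcript_type "{t.biotype}";'
        )

    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in ordered:
            sp = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{t.strand}\t.\t{attr(t)}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attr(t)}\n"
                )
                if t.cds_span is not None:
                    lo = max(e.start, t.cds_span.start)
                    hi = min(e.end, t.cds_span.end)
                    if lo < hi:
                        fh.write(
                            f"{t.chrom}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t"
                            f"{t.strand}\t0\t{attr(t)}\n"
                        )


# ---------------------------------------------------------------------------
# splice-junction tables
# ---------------------------------------------------------------------------

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_STRAND_TO_CODE = {".": 0, "+": 1, "-": 2}


def read_junction_table(
    path: str | Path,
    sample_id: str | None = None,
    dialect: str = "star",
) -> list:
    """Read one per-sample splice-junction table.

    ``star`` dialect is the canonical SJ.out.tab column order: chrom, first
    intronic base (1-based), last intronic base (1-based inclusive), strand
    code (0 undefined / 1 '+' / 2 '-'), then either the unique-read count
    (compact 5-column form) or the full 9-column layout where unique reads
    are column 7. ``subjunc`` accepts chrom, 1-based inclusive intron start
    and end, strand character, read count.
    """
    if dialect not in {"star", "subjunc"}:
        raise ContractError(f"unknown junction dialect {dialect!r}")
    label = sample_id if sample_id is not None else Path(path).stem
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            chrom = str(row[0])
            start1, end1 = int(row[1]), int(row[2])
            if dialect == "star":
                strand = _STRAND_CODE.get(int(row[3]))
                if strand is None:
                    raise ParseError(f"bad strand code {row[3]!r}")
                reads = int(row[6]) if len(row) >= 7 else int(row[4])
            else:
                strand = str(row[3])
                reads = int(row[4])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        if start1 > end1:
            raise ParseError(
                f"{path}: line {lineno}: intron start {start1} > end {end1}"
            )
        if reads < 0:
            raise ValidationError(f"{path}: line {lineno}: negative read count")
        out.append(
            SpliceJunction(
                chrom=chrom,
                intron_start=start1 - 1,
                intron_end=end1,
                strand=strand,
                unique_reads=reads,
                sample_id=label,
            )
        )
    return out


def write_junction_table(junctions: Sequence, path: str | Path) -> None:
    """Write junctions in the 9-column STAR-compatible layout."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.intron_start + 1}\t{j.intron_end}\t"
                f"{_STRAND_TO_CODE[j.strand]}\t0\t0\t{j.unique_reads}\t0\t0\n"
            )


def read_junction_dir(
    directory: str | Path, pattern: str = "*.tsv", dialect: str = "star"
) -> dict:
    """Read every junction table in a directory; sample ids from file stems."""
    out = {}
    for p in sorted(Path(directory).glob(pattern)):
        out[p.stem] = read_junction_table(p, dialect=dialect)
    return out


# ---------------------------------------------------------------------------
# VCF: structural-variant deletion calls
# ---------------------------------------------------------------------------

def read_sv_vcf(path: str | Path) -> list:
    """Read SVTYPE=DEL records with per-sample GT/GQ from a VCF.

    The deletion interval is (POS, END) converted to 0-based half-open.
    Non-DEL records are skipped; a DEL without INFO/END is logged and
    skipped (record-level error).
    """
    out = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open VCF: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.info.get("SVTYPE") != "DEL":
                continue
            # pysam folds INFO/END into rec.stop; a symbolic <DEL> whose stop
            # still equals pos + len(REF) had no END in the record
            symbolic = any(a and a.startswith("<") for a in (rec.alts or ()))
            if symbolic and rec.stop <= rec.start + len(rec.ref or "N"):
                log.warning("%s: DEL at %s:%s lacks END; skipped", path, rec.chrom, rec.pos)
                continue
            interval = GenomicInterval(rec.chrom, rec.pos - 1, rec.stop, ".")
            gts: dict[str, str] = {}
            gqs: dict[str, int | None] = {}
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    gts[s] = "missing"
                else:
                    gts[s] = f"{min(gt)}/{max(gt)}"
                gq = call.get("GQ")
                gqs[s] = int(gq) if gq is not None else None
            out.append(
                SvDeletionCall(
                    interval=interval,
                    sample_genotypes=gts,
                    filter_status=";".join(rec.filter.keys()) or "PASS",
                    genotype_qualities=gqs,
                    variant_id=rec.id or ".",
                )
            )
    return out


def write_sv_vcf(
    calls: Sequence, path: str | Path, contigs: Mapping[str, int] | None = None
) -> None:
    """Write deletion calls as a minimal plain-text VCF (GT:GQ per sample)."""
    samples: list[str] = []
    for c in calls:
        for s in c.sample_genotypes:
            if s not in samples:
                samples.append(s)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for c in calls:
            iv = c.interval
            info = f"SVTYPE=DEL;END={iv.end}"
            cells = []
            for s in samples:
                gt = c.sample_genotypes.get(s, "missing")
                gt = "./." if gt == "missing" else gt
                gq = c.genotype_qualities.get(s)
                cells.append(f"{gt}:{gq if gq is not None else '.'}")
            fh.write(
                f"{iv.chrom}\t{iv.start + 1}\t{c.variant_id}\tN\t<DEL>\t.\t"
                f"{c.filter_status}\t{info}\tGT:GQ\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV: RIP genotype matrix, counts, metadata
# ---------------------------------------------------------------------------

def read_rip_matrix(path: str | Path) -> RipGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = "sva_id"
    return RipGenotypeMatrix(df)


def write_rip_matrix(matrix: RipGenotypeMatrix, path: str | Path) -> None:
    df = matrix.genotypes.copy()
    df.index.name = "sva_id"
    df.to_csv(path, sep="\t")


def read_count_matrix(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"{metadata_path}: metadata lacks columns {missing}")
    return CountMatrix(counts=counts, metadata=meta)


def write_count_matrix(matrix: CountMatrix, counts_path, metadata_path) -> None:
    c = matrix.counts.copy()
    c.index.name = "transcript_id"
    c.to_csv(counts_path, sep="\t")
    m = matrix.metadata.copy()
    m.index.name = "sample_id"
    m.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA / sequence access
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_genome(path: str | Path) -> Fasta:
    """Open an indexed FASTA; slicing returns plain strings."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from a genome (dict of str or pyfaidx Fasta)."""
    return str(genome[chrom][start:end]).upper()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(transcript: TranscriptModel, genome) -> str:
    """mRNA-sense spliced sequence (reverse-complemented for '-' strand)."""
    s = "".join(
        fetch_seq(genome, transcript.chrom, e.start, e.end) for e in transcript.exons
    )
    return revcomp(s) if transcript.strand == "-" else s


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Single-header-line TSV with stable column order (all result writers)."""
    df.to_csv(path, sep="\t", index=False)
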