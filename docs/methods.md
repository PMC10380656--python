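# Methods

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GTF, VCF and junction
tables (1-based) are converted at the I/O boundary and converted back on
write, so coordinate arithmetic never mixes conventions. Junction tables
use the STAR `SJ.out.tab` column order with numeric strand codes
(0 undefined, 1 `+`, 2 `−`); both the compact 5-column and the full
9-column layout are read, and a `subjunc` dialect flag accepts
(chrom, 1-based inclusive intron start/end, strand character, count) for
junction callers that emit that form. A junction's coordinates are the
intronic bases: `intron_start` is the first intronic base and
`intron_end` one past the last.

## Annotation screen

The exon intersection uses a 1 bp minimum overlap — a plain coordinate
intersection; no biological threshold is implied. Placement is decided by
comparing the overlap segment with the genomic CDS extent in transcript
orientation: entirely 5′ of the CDS → `five_prime_utr`, entirely 3′ →
`three_prime_utr`, inside → `cds`, straddling an edge → `cds_and_utr`;
transcripts without CDS → `noncoding_exon`. The coding-exon position marks
whether the overlapped exon is the first or last CDS-containing exon in
transcript orientation; a single coding exon is reported as first. The
biotype → category mapping is a closed table (protein_coding, NMD,
lncRNA-family, processed_transcript, ...); unknown biotypes fall back on
CDS presence. The NMD fallback implements the classical 50-nt rule on
spliced coordinates with a strict `>`; it is used only when the biotype
carries no NMD annotation, because annotation-derived NMD counts come from
the biotype itself. A CDS whose spliced length is not a multiple of 3
yields a warning and a negative call rather than an exception.

For the orientation table, exonisation takes precedence: an SVA exonised
in one transcript and intronic in another counts as exonised. An intronic
SVA's orientation is judged against the host gene with the longest
overlap; ties spanning both strands are flagged ambiguous and excluded
from the table (they are reported in the count of exclusions). The Fisher
exact test sums hypergeometric log-probabilities of all tables at the
observed margins whose probability is at most that of the observed table,
with a 1e-7 relative tie tolerance — this matches enumeration exactly on
small tables and stays numerically stable at cohort-scale margins.

## Junction screen

A novel exonisation call requires (a) exactly one splice site inside an
SVA (the terminal intronic bases are the tested points), (b) the partner
site exactly on an annotated exon start/end (an optional tolerance knob
exists, default 0 bp — the strictest reproducible reading), (c) the intron
not annotated, (d) unique reads ≥ `min_reads` (default 1, since
single-sample detections are biologically expected). The partner exon may
belong to any annotated transcript, not only the SVA's host gene, because
an SVA can act as an alternative first exon pairing with downstream exons
of its neighbour. Donor/acceptor labelling of the SVA-internal site follows
the partner transcript's strand; junction strand "." is accepted
throughout. Calls are merged on identical intron coordinates; recurrence
counts samples, not reads.

The proximity screen reports intronic SVAs whose nearest boundary is
within a 100 bp window (inclusive) of a host-transcript exon boundary,
distance 0 meaning abutting; exonised SVAs are excluded. The
genotype-conditional test builds the 2×2 presence × (carries ≥1 absent
allele) table over genotyped samples and reuses the Fisher kernel; the
absence-model flag additionally requires at least one junction-positive
sample (an unobserved junction is not evidence for the model) and that
every positive sample carries an absent allele. Alternative-acceptor
extension is the absolute difference of the non-shared splice sites of two
junctions sharing one site, with the affected exon side reported in
transcript orientation. The stop-codon scan rebuilds the spliced CDS with
the retained intronic block inserted at its genomic position,
reverse-complements for minus-strand transcripts, and reports codon
indices of stops upstream of the final (annotated) stop.

## RIP genotyping and association

Deletion ↔ SVA matching uses reciprocal overlap ≥ 0.5 (standard SV-matching
practice; configurable) restricted to FILTER=PASS records. Genotype
mapping is 0/0→PP, 0/1→PA, 1/1→AA; GQ below 20 (configurable) becomes
missing, while calls without a GQ value are kept — the quality filter
removes *known* low-quality genotypes. A sample with no deletion call at a
genotyped locus, and every sample of an SVA with no matching deletion, is
PP: the reference genome carries the element, so absence of a deletion
call is the reference state. Two PASS deletions matching one SVA raise an
ambiguity error listing both rather than guessing.

MAF is computed over non-missing alleles; the minor allele is the rarer of
P/A overall with ties assigned to A; the filter keeps MAF strictly greater
than 0.05. Associations use additive minor-allele-dosage coding (the
conventional default for this kind of screen): logistic regression (IRLS
via a binomial GLM) with age, sex and platform covariates for case/control
status; OLS with sex, platform and onset-site covariates for age at onset
(cases only); Cox partial likelihood with sex, platform, onset age and
onset site for survival, honouring right-censoring. Categorical covariates
are dummy-coded and constant columns dropped, so degenerate covariates
reduce cleanly to the unadjusted fit. Separation is detected from the
fitted scale (|β| > 15 or exploding SE) and flagged not-estimable instead
of reporting a meaningless CI. The Bonferroni family m is the number of
loci surviving the MAF filter, separately per analysis. A Woolf-CI allelic
odds ratio from 2×2 allele counts (Haldane–Anscombe +0.5 on zero cells) is
provided as a sanity-check oracle, not as the primary statistic — note the
collapsed allelic OR does not in general equal the per-allele logistic OR.

## Expression statistics

Two groups: Wilcoxon rank-sum with the exact null when n ≤ 20 and the
pooled sample is untied, otherwise the tie- and continuity-corrected
normal approximation; an all-equal degenerate sample returns p = 1.
Three or more groups: one-way ANOVA with Tukey HSD pairwise p-values from
the studentized-range distribution with pooled within-group variance;
pairwise results are emitted only when ≥3 levels exist. BH correction is
applied across the transcripts of one screen invocation — the family is
one screen, since no wider family is well-defined. Group comparisons run
on the (already normalised) counts directly; a median-of-ratios normaliser
ships as a convenience only. Genotype–expression comparisons drop missing
genotypes and classes below n = 2 and degrade to the rank test when only
two classes remain; fewer than two classes is flagged not-estimable.
When grouping by diagnosis the two case labels (ALS, ALSND) are pooled
into one case level by default.

## Synthetic cohort

The generator emulates the study design end to end at desk scale: two 1 Mb
random-sequence chromosomes, 60 multi-exon transcripts on both strands
(protein-coding with CDS, lncRNA, NMD, processed-transcript biotypes),
40 SVAs of which 10 are planted inside exons following a placement mix
(default 20/20/40/20% across 5′UTR/CDS/3′UTR/non-coding exon) with an 82%
same-orientation fraction, and 30 intronic (29% same orientation): one
CASP8-like element just 5′ of an exon whose alternative-acceptor junction
is emitted only for absent-allele carriers, four more within the 100 bp
window, eight donors of novel SVA-to-exon junctions, and background
elements. Junction tables contain every annotated intron plus planted
junctions with per-sample Bernoulli dropout (default 0). Twenty RIP loci
receive Hardy–Weinberg genotypes at configured MAFs (15 common, 5 rare, so
the 5% filter has work to do); deletions are emitted coextensive with the
SVA at GQ 99. Disease labels come from a logistic model with a planted
per-allele OR of 0.78 at MAF 0.29 and mild sex/age/platform effects, the
intercept calibrated so the expected case fraction matches the cohort
design (600 samples by default; the published 2663/322 design via
`full_scale` or the lightweight replicate helper). Onset ages use a
baseline of 59.6 y with −1.15 y per present allele (σ = 8); survival is
exponential with HR 1.5 per absent allele and uniform censoring giving
roughly 60% events. Counts are negative-binomial (dispersion 0.2) with
log-linear diagnosis, tissue and genotype effects on designated
transcripts.

The expressed CASP8-like insert is fixed at 191 bp: in reference
coordinates the alternative acceptor sits 5′ of the SVA, so the expressed
insert in absent genomes is the 5′ flank plus the exon gap, while the
reference-coordinate extension additionally includes the SVA length; the
truth table records both.

A single seed drives everything; each stage derives its generator from
`default_rng([seed, stage_index])`, and identical seeds give byte-identical
output files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence-level splice-site motifs (junctions are
planted by coordinate, not discovered from sequence), alignment and
mapping artefacts, linkage disequilibrium between loci, population
structure and relatedness, covariate confounding beyond the mild planted
effects, SVA sequence composition (VNTR repeats), and overlapping gene
architecture. Recovery being perfect at zero noise is a correctness check
of the calling logic, not a sensitivity claim for real RNA-seq.

## Problem sizes and numerical choices

The default cohort (600 samples, 2 Mb genome) runs in seconds; association
recovery experiments use 200 replicates at the 2985-sample design for the
odds ratio and 60 replicates for onset slope and hazard ratio, sizes at
which the replicate means are stable to well under their tolerance bands.
Tests of "holds in ≥X% of replicates" claims use a one-sided binomial
lower-confidence check rather than a hard cut at X%, which would falsely
reject a process exactly at the claimed rate half the time. Fisher ties
use a 1e-7 relative tolerance; logistic fits cap at 100 IRLS iterations;
Tukey p-values come from the SciPy studentized-range distribution and are
cross-checked in the tests against direct numerical integration of the
distribution's double integral.

## Known limitations

Genotype-conditional junction analysis treats junction absence as observed
absence (no read-depth model of detectability). The annotation screen
assigns intronic hosts at transcript level and resolves multi-host
ambiguity by longest gene overlap, which discards strand-ambiguous
elements instead of modelling them. The NMD 50-nt rule ignores
selenocysteine recoding and readthrough. The association models do not
correct for relatedness or ancestry; they expect an already-subset
cohort. Survival and onset models assume the covariate columns provided
are complete cases; rows with missing values are dropped per locus.
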