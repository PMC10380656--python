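"""Novel exonisation calling, proximity screen, genotype-conditional
junctions, acceptor extensions and stop-codon scans."""

import numpy as np
import pandas as pd
import pytest

from helpers import fisher_enumeration, make_transcript

from svaexo.core_io import (
    ContractError,
    GenomicInterval,
    RipGenotypeMatrix,
    SpliceJunction,
    SvaElement,
    revcomp,
)
from svaexo.exon_screen import fisher_exact_2x2
from svaexo.junction_screen import (
    alt_acceptor_extension,
    call_novel_exonisation,
    genotype_conditional_junctions,
    proximal_sva_screen,
    recurrence_summary,
    stop_codon_scan,
)
from svaexo.synthetic_cohort import SimulationConfig, make_genome_and_annotation, make_junctions


def jx(start, end, sample="S1", reads=5, chrom="chr1", strand="."):
    return SpliceJunction(chrom, start, end, strand, reads, sample)


def sva(sva_id, start, end, strand="+", chrom="chr1"):
    return SvaElement(sva_id, GenomicInterval(chrom, start, end, strand), "E")


class TestCaller:
    """Toy: transcript exons (100,300),(400,600),(700,900); SVA in intron 1
    at [320,380)."""

    @pytest.fixture
    def setup(self, toy_transcript_plus):
        return [sva("SVA_X", 320, 380)], [toy_transcript_plus]

    def test_annotated_intron_not_called(self, setup):
        svas, ts = setup
        calls = call_novel_exonisation({"S1": [jx(300, 400)]}, svas, ts)
        assert calls == []

    def test_both_ends_in_sva_not_called(self, setup):
        svas, ts = setup
        calls = call_novel_exonisation({"S1": [jx(330, 370)]}, svas, ts)
        assert calls == []

    def test_no_exon_boundary_partner_not_called(self, setup):
        svas, ts = setup
        calls = call_novel_exonisation({"S1": [jx(350, 450)]}, svas, ts)
        assert calls == []

    def test_valid_call_donor_in_sva(self, setup):
        svas, ts = setup
        (call,) = call_novel_exonisation({"S1": [jx(350, 400)]}, svas, ts)
        assert call.sva_id == "SVA_X"
        assert call.partner_transcript_id == "TX1"
        assert call.partner_exon_index == 1
        assert call.sva_end == "donor"  # '+' partner: left splice site is donor
        assert call.samples_detected == frozenset({"S1"})

    def test_acceptor_in_sva_on_minus_partner(self):
        t = make_transcript(strand="-")
        (call,) = call_novel_exonisation(
            {"S1": [jx(350, 400)]}, [sva("SVA_X", 320, 380, "-")], [t]
        )
        assert call.sva_end == "acceptor"
        assert call.same_orientation is True

    def test_min_reads_floor(self, setup):
        svas, ts = setup
        assert call_novel_exonisation({"S1": [jx(350, 400, reads=2)]}, svas, ts,
                                      min_reads=3) == []

    def test_merging_across_samples(self, setup):
        svas, ts = setup
        calls = call_novel_exonisation(
            {"S1": [jx(350, 400, "S1")], "S2": [jx(350, 400, "S2")],
             "S3": []},
            svas, ts,
        )
        (call,) = calls
        assert call.total_detections == 2
        assert call.samples_detected == frozenset({"S1", "S2"})

    def test_noise_free_cohort_perfect_recovery(self, default_cohort):
        config, truth, outdir = default_cohort
        junctions = make_junctions(truth, config)
        calls = call_novel_exonisation(junctions, truth.svas, truth.transcripts,
                                       min_reads=1)
        planted = {
            (n["chrom"], n["intron_start"], n["intron_end"]): n["sva_id"]
            for n in truth.novel_junctions
        }
        found = {c.junction.coords: c.sva_id for c in calls}
        assert found == planted  # precision = recall = 1.0
        for c in calls:
            assert c.total_detections == config.n_junction_samples  # zero dropout

    def test_recall_degrades_monotonically_with_dropout(self, tmp_path):
        recalls = []
        for dropout in (0.0, 0.4, 0.8):
            config = SimulationConfig(seed=21, junction_dropout=dropout,
                                      n_junction_samples=4)
            truth = make_genome_and_annotation(config)
            junctions = make_junctions(truth, config)
            calls = call_novel_exonisation(junctions, truth.svas, truth.transcripts)
            planted = {(n["chrom"], n["intron_start"], n["intron_end"])
                       for n in truth.novel_junctions}
            found = {c.junction.coords for c in calls} & planted
            recalls.append(len(found) / len(planted))
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]


class TestRecurrence:
    def test_single_call_single_sample(self, toy_transcript_plus):
        calls = call_novel_exonisation(
            {"S1": [jx(350, 400)]}, [sva("SVA_X", 320, 380)], [toy_transcript_plus]
        )
        s = recurrence_summary(calls)
        assert s.mean_detections == 1.0 and s.histogram == {1: 1}

    def test_planted_detection_matrix_mean(self, toy_transcript_plus):
        # 3 events over 10 samples with 5, 2 and 1 detections -> mean 8/3
        svas = [sva("A", 320, 380), sva("B", 620, 680)]
        t = toy_transcript_plus
        pattern = {
            (350, 400): [f"S{i}" for i in range(5)],
            (650, 700): [f"S{i}" for i in range(2)],
            (300, 350): ["S9"],  # acceptor inside SVA A, donor at exon 0 end
        }
        by_sample = {f"S{i}": [] for i in range(10)}
        for (a, b), samples in pattern.items():
            for s in samples:
                by_sample[s].append(jx(a, b, s))
        calls = call_novel_exonisation(by_sample, svas, [t])
        s = recurrence_summary(calls)
        assert s.n_calls == 3
        assert s.mean_detections == pytest.approx((5 + 2 + 1) / 3)

    def test_saturation_and_empty(self, toy_transcript_plus):
        by_sample = {f"S{i}": [jx(350, 400, f"S{i}")] for i in range(10)}
        calls = call_novel_exonisation(
            by_sample, [sva("SVA_X", 320, 380)], [toy_transcript_plus]
        )
        assert recurrence_summary(calls).mean_detections == 10.0
        empty = recurrence_summary([])
        assert empty.mean_detections is None and empty.n_calls == 0


class TestProximityScreen:
    def test_abutting_distance_zero(self):
        t = make_transcript(exons=((100, 200), (1000, 1100)), cds=None, biotype="lncRNA")
        out = proximal_sva_screen([sva("S", 200, 400)], [t])
        assert out == [("S", "TX1", 0, 0)]

    @pytest.mark.parametrize("gap,included", [(100, True), (101, False)])
    def test_window_boundary_inclusive(self, gap, included):
        t = make_transcript(exons=((100, 200), (1000, 1100)), cds=None, biotype="lncRNA")
        element = sva("S", 200 + gap, 400 + gap)
        out = proximal_sva_screen([element], [t], window=100)
        assert bool(out) is included

    def test_exonised_sva_excluded(self):
        t = make_transcript(exons=((100, 200), (1000, 1100)), cds=None, biotype="lncRNA")
        assert proximal_sva_screen([sva("S", 150, 400)], [t]) == []

    def test_nearest_side_downstream(self):
        t = make_transcript(exons=((100, 200), (1000, 1100)), cds=None, biotype="lncRNA")
        out = proximal_sva_screen([sva("S", 900, 970)], [t])
        assert out == [("S", "TX1", 1, 30)]


class TestGenotypeConditional:
    @staticmethod
    def _matrix(genos):
        return RipGenotypeMatrix(
            pd.DataFrame([genos], index=["SVA_X"], columns=[f"S{i}" for i in range(len(genos))])
        )

    def test_absence_restricted_junction(self):
        genos = ["AA", "AA", "PA", "PA", "PP", "PP", "PP"]
        m = self._matrix(genos)
        by_sample = {
            f"S{i}": ([jx(10, 50, f"S{i}")] if genos[i] != "PP" else [])
            for i in range(7)
        }
        assoc = genotype_conditional_junctions(by_sample, m, "SVA_X", jx(10, 50))
        assert assoc.consistent_with_absence_model is True
        assert assoc.presence_by_genotype == {"AA": (2, 0), "PA": (2, 0), "PP": (0, 3)}
        # delegation identity + enumeration oracle
        table = [[4, 0], [0, 3]]
        assert assoc.p_value == pytest.approx(fisher_exact_2x2(table))
        assert assoc.p_value == pytest.approx(fisher_enumeration(table), abs=1e-9)

    def test_ubiquitous_junction_flag_false_p_one(self):
        genos = ["AA", "PA", "PP", "PP"]
        m = self._matrix(genos)
        by_sample = {f"S{i}": [jx(10, 50, f"S{i}")] for i in range(4)}
        assoc = genotype_conditional_junctions(by_sample, m, "SVA_X", jx(10, 50))
        assert assoc.p_value == pytest.approx(1.0)
        assert assoc.consistent_with_absence_model is False

    def test_missing_genotypes_excluded_and_empty_rejected(self):
        m = self._matrix(["missing", "missing"])
        by_sample = {"S0": [jx(10, 50, "S0")], "S1": []}
        with pytest.raises(ContractError):
            genotype_conditional_junctions(by_sample, m, "SVA_X", jx(10, 50))

    def test_casp8_like_cohort_recovered(self, tmp_path):
        """39-sample cohort with a planted absence-linked acceptor."""
        config = SimulationConfig(seed=31, n_junction_samples=39,
                                  n_cases=30, n_controls=9)
        truth = make_genome_and_annotation(config)
        junctions = make_junctions(truth, config)
        c8 = truth.casp8
        from svaexo.synthetic_cohort import truth_rip_matrix

        m = truth_rip_matrix(truth)
        cand = jx(c8["alt_intron"][0], c8["alt_intron"][1], chrom=c8["chrom"])
        assoc = genotype_conditional_junctions(junctions, m, c8["sva_id"], cand)
        assert assoc.consistent_with_absence_model is True
        carriers = sum(v[0] for g, v in assoc.presence_by_genotype.items() if g != "PP")
        assert carriers > 0
        assert assoc.presence_by_genotype["PP"][0] == 0


class TestAltAcceptorExtension:
    def test_identical_junctions(self, toy_transcript_plus):
        assert alt_acceptor_extension(jx(300, 400), jx(300, 400),
                                      toy_transcript_plus)[0] == 0

    def test_191bp_extension_plus_strand(self, toy_transcript_plus):
        annotated = jx(4000, 5000)
        candidate = jx(4000, 4809)  # same donor, acceptor 191 bp upstream
        ext, side = alt_acceptor_extension(candidate, annotated, toy_transcript_plus)
        assert ext == 191 and side == "five_prime_of_exon"

    def test_minus_strand_mirror(self, toy_transcript_minus):
        # mirrored geometry: shared acceptor-side coordinate, donor moved
        annotated = jx(4000, 5000)
        candidate = jx(4191, 5000)
        ext, side = alt_acceptor_extension(candidate, annotated, toy_transcript_minus)
        assert ext == 191 and side == "five_prime_of_exon"

    def test_disjoint_junctions_rejected(self, toy_transcript_plus):
        with pytest.raises(ContractError):
            alt_acceptor_extension(jx(1, 10), jx(20, 30), toy_transcript_plus)


class TestStopCodonScan:
    """Transcript exons (0,30),(60,90), CDS (0,90); spliced CDS = 20 codons."""

    def test_in_frame_stop_reported(self):
        t = make_transcript(exons=((0, 30), (60, 90)), cds=(0, 90))
        genome = {"chr1": "ATG" + "GCT" * 9 + "T" * 30 + "GCA" * 9 + "TAA"}
        # plant TAA in the intron at [40, 43) and retain exactly that slice
        seq = list(genome["chr1"])
        seq[40:43] = list("TAA")
        genome = {"chr1": "".join(seq)}
        stops = stop_codon_scan(t, GenomicInterval("chr1", 40, 43), genome)
        assert stops == [10]  # inserted codon sits right after exon 1's 10 codons

    def test_no_stop_in_included_sequence(self):
        t = make_transcript(exons=((0, 30), (60, 90)), cds=(0, 90))
        genome = {"chr1": "ATG" + "GCT" * 9 + "CCC" * 10 + "GCA" * 9 + "TAA"}
        stops = stop_codon_scan(t, GenomicInterval("chr1", 30, 60), genome)
        assert stops == []

    def test_minus_strand_matches_hand_translation(self):
        """Reported stops equal those from a hand reverse-complement
        translation of the modified CDS."""
        plus_mrna = "ATG" + "GCT" * 4 + "TAG" + "GCA" * 4 + "TAA"  # stop at codon 5
        # genomic '-' layout: exon2_rc | intron | exon1_rc, with the included
        # 3 nt being the TAG codon
        exon_tx1 = plus_mrna[:15]       # before the included codon
        included = plus_mrna[15:18]     # TAG
        exon_tx2 = plus_mrna[18:]
        genomic = revcomp(exon_tx2) + "T" * 10 + revcomp(included) + "T" * 10 + revcomp(exon_tx1)
        t = make_transcript(
            strand="-",
            exons=((0, 15), (25 + 3 + 10, 25 + 3 + 10 + 15)),
            cds=(0, 53),
        )
        genome = {"chr1": genomic}
        stops = stop_codon_scan(t, GenomicInterval("chr1", 25, 28), genome)
        # hand translation of plus_mrna: stops at codons 5 and 10 (annotated)
        assert stops == [5]

    def test_interval_outside_intron_rejected(self):
        t = make_transcript(exons=((0, 30), (60, 90)), cds=(0, 90))
        with pytest.raises(ContractError):
            stop_codon_scan(t, GenomicInterval("chr1", 10, 20), {"chr1": "A" * 90})
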