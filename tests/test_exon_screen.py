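"""Exonisation classification, orientation bias and the Fisher exact kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from helpers import fisher_enumeration, make_transcript

from svaexo.core_io import ContractError, GenomicInterval, SvaElement
from svaexo.exon_screen import (
    classify_placement,
    classify_transcript,
    fisher_exact_2x2,
    intersect_sva_exons,
    orientation_summary,
    ptc_nmd_rule,
)


def sva(sva_id, start, end, strand="+", chrom="chr1"):
    return SvaElement(sva_id, GenomicInterval(chrom, start, end, strand), "E")


class TestIntersect:
    def test_intronic_sva_yields_nothing(self, toy_transcript_plus):
        assert intersect_sva_exons([sva("S", 310, 390)], [toy_transcript_plus]) == []

    @pytest.mark.parametrize(
        "sva_span,exon_span,expected_overlap",
        [((100, 300), (50, 400), 200), ((100, 300), (250, 400), 50)],
    )
    def test_overlap_matches_per_base_count(self, sva_span, exon_span, expected_overlap):
        t = make_transcript(exons=(exon_span, (1000, 1100)), cds=None, biotype="lncRNA")
        (rec,) = intersect_sva_exons([sva("S", *sva_span)], [t])
        brute = len(
            set(range(*sva_span)) & set(range(*exon_span))
        )
        assert rec.overlap_bp == expected_overlap == brute

    def test_one_sva_many_transcripts(self):
        ts = [
            make_transcript(transcript_id=f"T{i}", exons=((100, 300),), cds=None,
                            biotype="lncRNA")
            for i in range(3)
        ]
        recs = intersect_sva_exons([sva("S", 150, 250)], ts)
        assert [r.transcript_id for r in recs] == ["T0", "T1", "T2"]


class TestPlacement:
    # toy: exons (100,300),(400,600),(700,900); CDS span (200,800)

    def test_noncoding(self):
        t = make_transcript(cds=None, biotype="lncRNA")
        (rec,) = intersect_sva_exons([sva("S", 150, 250)], [t])
        assert rec.placement == "noncoding_exon"
        assert rec.coding_exon_position == "not_applicable"

    def test_plus_strand_three_prime_last_coding(self, toy_transcript_plus):
        (rec,) = intersect_sva_exons([sva("S", 820, 880)], [toy_transcript_plus])
        assert rec.placement == "three_prime_utr"
        assert rec.coding_exon_position == "last_coding"

    def test_minus_strand_genomic_right_is_five_prime(self, toy_transcript_minus):
        (rec,) = intersect_sva_exons([sva("S", 820, 880, "-")], [toy_transcript_minus])
        assert rec.placement == "five_prime_utr"
        assert rec.coding_exon_position == "first_coding"

    def test_cds_and_straddle(self, toy_transcript_plus):
        (rec,) = intersect_sva_exons([sva("S", 450, 550)], [toy_transcript_plus])
        assert rec.placement == "cds"
        assert rec.coding_exon_position == "internal"
        (rec2,) = intersect_sva_exons([sva("S", 150, 250)], [toy_transcript_plus])
        assert rec2.placement == "cds_and_utr"

    def test_strand_flip_mirror_invariance(self):
        """Mirroring the whole toy genome (x -> L - x, strands flipped)
        leaves every placement call unchanged."""
        L = 1000
        t_plus = make_transcript()
        elements = [sva("A", 820, 880, "+"), sva("B", 110, 190, "-"),
                    sva("C", 450, 550, "+")]
        recs = intersect_sva_exons(elements, [t_plus])

        t_minus = make_transcript(
            strand="-",
            exons=tuple((L - b, L - a) for a, b in reversed(((100, 300), (400, 600), (700, 900)))),
            cds=(L - 800, L - 200),
        )
        mirrored = [
            SvaElement(
                s.sva_id,
                GenomicInterval(
                    "chr1",
                    L - s.interval.end,
                    L - s.interval.start,
                    "-" if s.interval.strand == "+" else "+",
                ),
                s.subtype,
            )
            for s in elements
        ]
        recs_m = intersect_sva_exons(mirrored, [t_minus])
        by_id = {r.sva_id: r for r in recs}
        by_id_m = {r.sva_id: r for r in recs_m}
        assert set(by_id) == set(by_id_m)
        for k in by_id:
            assert by_id[k].placement == by_id_m[k].placement
            assert by_id[k].coding_exon_position == by_id_m[k].coding_exon_position
            assert by_id[k].same_orientation == by_id_m[k].same_orientation

    def test_contract_error_on_mismatch(self, toy_transcript_plus):
        other = make_transcript(transcript_id="T2", exons=((0, 50),), cds=None)
        (rec,) = intersect_sva_exons([sva("S", 820, 880)], [toy_transcript_plus])
        with pytest.raises(ContractError):
            classify_placement(rec, other)


class TestTranscriptCategory:
    @pytest.mark.parametrize(
        "biotype,cds,expected",
        [
            ("protein_coding", (200, 800), "protein_coding"),
            ("nonsense_mediated_decay", (200, 800), "nmd"),
            ("lncRNA", None, "lncRNA"),
            ("processed_transcript", None, "processed_transcript"),
            ("weird_new_biotype", (200, 800), "other_coding"),
            ("weird_new_biotype", None, "other_noncoding"),
        ],
    )
    def test_mapping(self, biotype, cds, expected):
        t = make_transcript(biotype=biotype, cds=cds)
        assert classify_transcript(t) == expected


class TestPtcRule:
    """Two exons: (0,200) and (250,350); CDS (0,350) -> 300 nt spliced CDS.
    The final exon-exon junction is at spliced position 200."""

    @staticmethod
    def _genome(stop_codon_index=None):
        codons = ["GCT"] * 100
        if stop_codon_index is not None:
            codons[stop_codon_index] = "TAA"
        cds = "".join(codons)
        # genomic layout: exon1 = cds[:200], intron 50 nt, exon2 = cds[200:300]
        return {"chr1": cds[:200] + "G" * 50 + cds[200:]}

    @staticmethod
    def _transcript():
        return make_transcript(exons=((0, 200), (250, 350)), cds=(0, 350))

    def test_stop_in_last_exon_is_false(self):
        # stop at codon 70 -> ends at nt 213, inside exon 2
        assert ptc_nmd_rule(self._transcript(), self._genome(70)) is False

    def test_stop_100nt_upstream_is_true(self):
        # stop at codon 32 -> stop ends at nt 99; junction - 99 = 101 > 50
        assert ptc_nmd_rule(self._transcript(), self._genome(32)) is True

    def test_exactly_50nt_is_false(self):
        # stop at codon 49 -> ends at nt 150; 200 - 150 = 50, strict '>'
        assert ptc_nmd_rule(self._transcript(), self._genome(49)) is False

    def test_frameshifted_cds_warns_false(self):
        t = make_transcript(exons=((0, 200), (250, 351)), cds=(0, 351))
        genome = {"chr1": self._genome(10)["chr1"] + "GG"}
        with pytest.warns(UserWarning):
            assert ptc_nmd_rule(t, genome) is False

    def test_requires_cds_and_two_exons(self):
        t = make_transcript(exons=((0, 300),), cds=(0, 300))
        with pytest.raises(ContractError):
            ptc_nmd_rule(t, self._genome())


class TestOrientationSummary:
    def test_no_exonised_first_row_zero(self):
        t = make_transcript()
        table = orientation_summary([sva("S", 310, 390, "+")], [t])
        assert table.exonised_same == table.exonised_opposite == 0
        assert table.intronic_same == 1

    def test_row_sums_conserve_group_counts(self, default_cohort):
        _, truth, _ = default_cohort
        table = orientation_summary(truth.svas, truth.transcripts)
        n_exonised = table.exonised_same + table.exonised_opposite
        n_intronic = table.intronic_same + table.intronic_opposite
        assert n_exonised == len(truth.exonised)
        assert n_intronic + table.n_ambiguous_excluded == len(
            truth.intronic_orientation
        )

    def test_planted_orientation_fractions_recovered(self, default_cohort):
        """Observed same-orientation fractions sit within binomial sampling
        error of the generator's planted fractions."""
        config, truth, _ = default_cohort
        table = orientation_summary(truth.svas, truth.transcripts)
        for frac, p0 in [
            (table.exonised_same_fraction, config.same_orientation_fraction),
            (table.intronic_same_fraction, config.intronic_same_orientation_fraction),
        ]:
            n = 10 if p0 > 0.5 else len(truth.intronic_orientation)
            se = np.sqrt(p0 * (1 - p0) / max(n, 1))
            assert abs(frac - p0) <= 3 * se + 1e-9

    def test_exonised_takes_precedence(self):
        host_a = make_transcript(transcript_id="TA", exons=((100, 300),), cds=None,
                                 biotype="lncRNA")
        host_b = make_transcript(transcript_id="TB", gene_id="GB",
                                 exons=((0, 50), (500, 600)), cds=None, biotype="lncRNA")
        table = orientation_summary([sva("S", 150, 250, "+")], [host_a, host_b])
        assert table.exonised_same + table.exonised_opposite == 1
        assert table.intronic_same + table.intronic_opposite == 0

    def test_opposite_strand_hosts_ambiguous_excluded(self):
        host_a = make_transcript(transcript_id="TA", gene_id="GA", strand="+",
                                 exons=((0, 50), (500, 600)), cds=None, biotype="lncRNA")
        host_b = make_transcript(transcript_id="TB", gene_id="GB", strand="-",
                                 exons=((0, 50), (500, 600)), cds=None, biotype="lncRNA")
        table = orientation_summary([sva("S", 100, 400, "+")], [host_a, host_b])
        assert table.n_ambiguous_excluded == 1
        assert table.intronic_same + table.intronic_opposite == 0


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_hand_enumerated_value(self):
        # margins 4/4; outcomes k=0..4 with probs 1/70,16/70,36/70,16/70,1/70
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(0.4857, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ContractError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle_small_tables(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_enumeration(table), abs=1e-9
        )

    @pytest.mark.parametrize(
        "table", [[[3, 1], [1, 3]], [[10, 2], [3, 15]], [[50, 10], [20, 40]],
                  [[0, 5], [5, 0]], [[1, 0], [0, 1]]]
    )
    def test_matches_scipy_reference(self, table):
        assert fisher_exact_2x2(table) == pytest.approx(
            scipy_fisher(table).pvalue, rel=1e-9, abs=1e-12
        )

    def test_large_margin_log_space(self):
        # reconstructed orientation table: log-space summation stays finite
        p = fisher_exact_2x2([[103, 23], [448, 1096]])
        assert 0 < p < 1e-5
        assert p == pytest.approx(scipy_fisher([[103, 23], [448, 1096]]).pvalue, rel=1e-6)
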