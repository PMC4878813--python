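"""Feature prediction rules (alpha, beta, gamma) and merging."""

import pytest

from splicegraphs import (
    Exon,
    Features,
    GenomicRange,
    PredictionParams,
    SampleInfo,
    SpliceJunction,
    merge_predictions,
    predict_internal_exons,
    predict_junctions,
    predict_terminal_exons,
)
from splicegraphs.core import (
    FIVE_PRIME_TERMINAL,
    INTERNAL,
    THREE_PRIME_TERMINAL,
)

from helpers import frag, predict_from_sam, simulate_sam


def junction(start, end, count, strand="+", seqname="chr1"):
    return SpliceJunction(GenomicRange(seqname, start, end, strand), count=count)


def split_read(gap_start, gap_end, anchor=30, **kw):
    return frag(
        [(gap_start - anchor, gap_start - 1), (gap_end + 1, gap_end + anchor)],
        strand=kw.pop("strand", "+"),
        **kw,
    )


SAMPLE = SampleInfo("s1", paired=True, read_length=76, frag_length=200,
                    library_size=61_300_000)


class TestPredictJunctions:
    def _reads(self, n):
        return [split_read(1031, 1130, name=f"r{i}") for i in range(n)]

    def test_alpha_zero_keeps_everything(self):
        out = predict_junctions(self._reads(1), SAMPLE, PredictionParams(alpha=0))
        assert len(out) == 1

    def test_count_below_threshold_filtered(self):
        # FPKM of 18 fragments at lambda=150, rho=61.3M is 1.96 < 2
        out = predict_junctions(self._reads(18), SAMPLE, PredictionParams(alpha=2))
        assert out == []

    def test_count_at_threshold_retained(self):
        out = predict_junctions(self._reads(19), SAMPLE, PredictionParams(alpha=2))
        assert len(out) == 1
        assert out[0].count == 19
        assert out[0].fpkm >= 2


class TestPredictInternalExons:
    # acceptor at 501 (intron ends 500), donor at 600 (intron starts 601)
    JUNCTIONS = [junction(450, 500, 50), junction(601, 650, 40)]

    def _coverage_reads(self, n, start=501, end=600):
        return [frag([(start, end)], strand="+", name=f"c{i}") for i in range(n)]

    def test_sufficient_relative_coverage_accepted(self):
        # threshold with the conservative max rule: 0.2 * 50 = 10 <= 12
        out = predict_internal_exons(
            self.JUNCTIONS, self._coverage_reads(12), PredictionParams(beta=0.2)
        )
        assert [(e.range.start, e.range.end) for e in out] == [(501, 600)]
        assert out[0].kind == INTERNAL

    def test_insufficient_coverage_rejected(self):
        out = predict_internal_exons(
            self.JUNCTIONS, self._coverage_reads(5), PredictionParams(beta=0.2)
        )
        assert out == []

    def test_no_acceptor_donor_pair_yields_nothing(self):
        # two donors only: no candidate region
        out = predict_internal_exons(
            [junction(601, 650, 10), junction(801, 850, 10)],
            self._coverage_reads(100),
            PredictionParams(),
        )
        assert out == []

    def test_intervening_splice_site_splits_candidates(self):
        # a retained junction landing inside [501, 800] forbids the long pair
        junctions = self.JUNCTIONS + [
            junction(801, 850, 40),
            junction(651, 700, 40),
        ]
        cov = self._coverage_reads(100, 501, 600) + self._coverage_reads(
            100, 701, 800
        )
        out = predict_internal_exons(junctions, cov, PredictionParams())
        assert [(e.range.start, e.range.end) for e in out] == [
            (501, 600),
            (701, 800),
        ]

    def test_aggregation_rule_max_is_conservative(self):
        # coverage 9 passes only with the lenient min rule (0.2*40=8)
        cov = self._coverage_reads(9)
        assert (
            predict_internal_exons(
                self.JUNCTIONS, cov, PredictionParams(n_spliced_agg="max")
            )
            == []
        )
        assert (
            len(
                predict_internal_exons(
                    self.JUNCTIONS, cov, PredictionParams(n_spliced_agg="min")
                )
            )
            == 1
        )

    def test_boundaries_coincide_with_junction_boundaries(self, tmp_path):
        sam, models, _ = simulate_sam(tmp_path, "skipped_exon", seed=3)
        _, _, features = predict_from_sam(sam)
        sites = set()
        for j in features.junctions:
            sites.add(j.range.end + 1)
            sites.add(j.range.start - 1)
        for e in features.internal_exons:
            assert e.range.start in sites
            assert e.range.end in sites


class TestPredictTerminalExons:
    def test_extension_stops_at_coverage_drop(self):
        # acceptor at 1001 with 30 spliced reads; threshold 0.2 * 30 = 6
        junctions = [junction(950, 1000, 30)]
        cov = [frag([(1001, 1080)], name=f"a{i}") for i in range(6)] + [
            frag([(1001, 1090)], name=f"b{i}") for i in range(4)
        ]
        out = predict_terminal_exons(junctions, [], cov, PredictionParams(gamma=0.2))
        three_prime = [e for e in out if e.kind == THREE_PRIME_TERMINAL]
        assert [(e.range.start, e.range.end) for e in three_prime] == [(1001, 1080)]

    def test_boundary_shared_with_internal_exon_excluded(self):
        junctions = [junction(950, 1000, 30)]
        internal = [Exon(GenomicRange("chr1", 1001, 1100, "+"), INTERNAL)]
        cov = [frag([(1001, 1080)], name=f"a{i}") for i in range(10)]
        out = predict_terminal_exons(junctions, internal, cov, PredictionParams())
        assert all(e.range.start != 1001 for e in out)

    def test_zero_coverage_beyond_boundary_gives_single_base(self):
        junctions = [junction(950, 1000, 30)]
        out = predict_terminal_exons(junctions, [], [], PredictionParams())
        three_prime = [e for e in out if e.kind == THREE_PRIME_TERMINAL]
        assert [(e.range.start, e.range.end) for e in three_prime] == [(1001, 1001)]

    def test_strand_determines_kind(self):
        plus = predict_terminal_exons(
            [junction(950, 1000, 10, "+")], [], [], PredictionParams()
        )
        minus = predict_terminal_exons(
            [junction(950, 1000, 10, "-")], [], [], PredictionParams()
        )
        assert {e.kind for e in plus} == {FIVE_PRIME_TERMINAL, THREE_PRIME_TERMINAL}
        # on the minus strand the downstream side is genomically left
        left_plus = next(e for e in plus if e.range.end == 949)
        left_minus = next(e for e in minus if e.range.end == 949)
        assert left_plus.kind == FIVE_PRIME_TERMINAL
        assert left_minus.kind == THREE_PRIME_TERMINAL


class TestMergePredictions:
    def test_identical_junctions_union_samples(self):
        a = Features(junctions=[junction(100, 200, 5)])
        b = Features(junctions=[junction(100, 200, 7)])
        merged = merge_predictions({"s1": a, "s2": b})
        (j,) = merged.junctions
        assert j.samples == ("s1", "s2")
        assert j.sample_counts == {"s1": 5, "s2": 7}
        assert j.count == 12

    def test_disjoint_junctions_union(self):
        a = Features(junctions=[junction(100, 200, 5)])
        b = Features(junctions=[junction(300, 400, 7)])
        merged = merge_predictions({"s1": a, "s2": b})
        assert len(merged.junctions) == 2

    def test_terminal_exons_merge_to_maximal_extent(self):
        def terminal(end):
            return Features(
                exons=[
                    Exon(
                        GenomicRange("chr1", 1001, end, "+"),
                        THREE_PRIME_TERMINAL,
                        spliced_left=True,
                        spliced_right=False,
                    )
                ]
            )

        merged = merge_predictions({"s1": terminal(1080), "s2": terminal(1120)})
        (e,) = merged.exons
        assert (e.range.start, e.range.end) == (1001, 1120)
        assert e.samples == ("s1", "s2")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_predictions({})


class TestThresholdMonotonicity:
    def test_junction_sets_nest_in_alpha(self, tmp_path):
        sam, _, _ = simulate_sam(tmp_path, "skipped_exon", depth=500, seed=5)
        fragments, info, _ = predict_from_sam(sam)
        previous = None
        for alpha in [0.0, 1.0, 2.0, 10.0, 100.0]:
            kept = {
                j.key()
                for j in predict_junctions(
                    fragments, info, PredictionParams(alpha=alpha)
                )
            }
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_internal_exon_sets_nest_in_beta(self, tmp_path):
        sam, _, _ = simulate_sam(
            tmp_path, "skipped_exon", psi=(0.35, 0.65), depth=500, seed=5
        )
        fragments, info, _ = predict_from_sam(sam)
        junctions = predict_junctions(fragments, info, PredictionParams(alpha=2))
        previous = None
        for beta in [0.0, 0.1, 0.2, 0.5, 1.0]:
            kept = {
                e.key()
                for e in predict_internal_exons(
                    junctions, fragments, PredictionParams(beta=beta)
                )
            }
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestNoiseRejection:
    def test_low_relative_coverage_from_intronic_noise_rejected(self):
        """Pre-mRNA background below beta times the boundary support must
        not create an internal exon, while genuine exonic coverage does."""
        junctions = [junction(450, 500, 50), junction(601, 650, 50)]
        noise = [frag([(501, 600)], name=f"n{i}") for i in range(8)]
        signal = noise + [
            frag([(501, 600)], name=f"s{i}") for i in range(20)
        ]
        params = PredictionParams(beta=0.2)
        assert predict_internal_exons(junctions, noise, params) == []
        assert len(predict_internal_exons(junctions, signal, params)) == 1
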