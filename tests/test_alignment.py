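"""Alignment parsing, junction extraction, coverage and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicegraphs import (
    GenomicRange,
    SampleInfo,
    SpliceJunction,
    compatible_coverage,
    count_compatible_fragments,
    effective_length,
    estimate_sample_info,
    extract_junctions,
    fpkm,
    min_count_for_fpkm,
    read_fragments,
)
from splicegraphs.core import Exon, INTERNAL

from helpers import frag

HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(name, flag, pos, cigar, mate_pos=0, tlen=0, tags=""):
    seq = "A" * 76
    qual = "I" * 76
    rnext = "=" if mate_pos else "*"
    line = (
        f"{name}\t{flag}\tchr1\t{pos}\t60\t{cigar}\t{rnext}\t{mate_pos}"
        f"\t{tlen}\t{seq}\t{qual}"
    )
    return line + (f"\t{tags}" if tags else "")


def write_sam(tmp_path, lines, name="test.sam"):
    path = tmp_path / name
    path.write_text(HEADER + "\n".join(lines) + "\n")
    return str(path)


class TestReadFragments:
    def test_single_end_unspliced_block(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r1", 0, 1001, "76M")])
        (f,) = read_fragments(path)
        assert f.blocks_read1 == (GenomicRange("chr1", 1001, 1076),)
        assert not f.paired and f.strand == "*"

    def test_spliced_cigar_walk(self, tmp_path):
        path = write_sam(
            tmp_path, [sam_line("r1", 0, 1001, "30M100N46M", tags="XS:A:+")]
        )
        (f,) = read_fragments(path)
        assert [(b.start, b.end) for b in f.blocks_read1] == [
            (1001, 1030),
            (1131, 1176),
        ]
        assert f.strand == "+"

    def test_deletion_stays_within_block(self, tmp_path):
        # D consumes reference without splitting the block
        path = write_sam(tmp_path, [sam_line("r1", 0, 1001, "30M5D46M")])
        (f,) = read_fragments(path)
        assert [(b.start, b.end) for b in f.blocks_read1] == [(1001, 1081)]

    def test_secondary_alignment_not_emitted(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r1", 256, 1001, "76M")])
        assert list(read_fragments(path)) == []

    def test_mates_combined_into_one_fragment(self, tmp_path):
        path = write_sam(
            tmp_path,
            [
                sam_line("p1", 99, 1001, "76M", mate_pos=1125, tlen=200),
                sam_line("p1", 147, 1125, "76M", mate_pos=1001, tlen=-200),
            ],
        )
        (f,) = read_fragments(path)
        assert f.paired
        assert f.span == (1001, 1200)

    def test_conflicting_mate_strands_dropped(self, tmp_path):
        path = write_sam(
            tmp_path,
            [
                sam_line(
                    "p1", 99, 1001, "30M100N46M", mate_pos=1301, tags="XS:A:+"
                ),
                sam_line(
                    "p1", 147, 1301, "30M100N46M", mate_pos=1001, tags="XS:A:-"
                ),
            ],
        )
        assert list(read_fragments(path)) == []


class TestEstimateSampleInfo:
    def _pair(self, name, start, span):
        mate = start + span - 76
        return [
            sam_line(name, 99, start, "76M", mate_pos=mate, tlen=span),
            sam_line(name, 147, mate, "76M", mate_pos=start, tlen=-span),
        ]

    def test_median_fragment_length_odd(self, tmp_path):
        lines = sum(
            (self._pair(f"p{i}", 1001 + i, s) for i, s in enumerate([180, 200, 220])),
            [],
        )
        info = estimate_sample_info(write_sam(tmp_path, lines))
        assert info.paired
        assert info.frag_length == 200
        assert info.read_length == 76
        assert info.library_size == 3

    def test_median_fragment_length_even(self, tmp_path):
        lines = sum(
            (
                self._pair(f"p{i}", 1001 + i, s)
                for i, s in enumerate([180, 200, 220, 240])
            ),
            [],
        )
        info = estimate_sample_info(write_sam(tmp_path, lines))
        assert info.frag_length == 210

    def test_single_end_has_no_fragment_length(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r1", 0, 1001, "76M")])
        info = estimate_sample_info(path)
        assert not info.paired and info.frag_length is None

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text(HEADER)
        with pytest.raises(ValueError):
            estimate_sample_info(str(path))


class TestExtractJunctions:
    def test_single_junction(self):
        f = frag([(1001, 1030), (1131, 1176)], strand="+")
        (j,) = extract_junctions([f])
        assert (j.range.start, j.range.end, j.range.strand) == (1031, 1130, "+")
        assert j.count == 1

    def test_two_gap_read(self):
        f = frag([(2001, 2020), (2071, 2090), (2151, 2186)], strand="+")
        out = extract_junctions([f])
        assert [(j.range.start, j.range.end) for j in out] == [
            (2021, 2070),
            (2091, 2150),
        ]

    def test_unspliced_and_unstranded_excluded(self):
        unspliced = frag([(1001, 1076)], strand="+")
        unstranded = frag([(1001, 1030), (1131, 1176)], strand="*")
        assert extract_junctions([unspliced, unstranded]) == []

    def test_gap_in_both_mates_counts_once(self):
        f = frag(
            [(1001, 1030), (1131, 1176)],
            [(1011, 1030), (1131, 1186)],
            strand="+",
        )
        (j,) = extract_junctions([f])
        assert j.count == 1


class TestCompatibleCoverage:
    def test_unspliced_read_covers_its_span(self):
        cov = compatible_coverage(
            GenomicRange("chr1", 101, 200), [frag([(101, 176)])]
        )
        assert cov[:76].tolist() == [1] * 76
        assert cov[76:].sum() == 0

    def test_spliced_into_range_is_incompatible_everywhere(self):
        f = frag([(101, 149), (181, 220)], strand="+")
        cov = compatible_coverage(GenomicRange("chr1", 101, 200), [f])
        assert cov.sum() == 0

    def test_additivity(self):
        reads = [frag([(101, 176)]), frag([(101, 176)])]
        cov = compatible_coverage(GenomicRange("chr1", 101, 200), reads)
        assert cov.max() == 2

    def test_mate_overlap_counted_once(self):
        f = frag([(101, 176)], [(150, 225)])
        cov = compatible_coverage(GenomicRange("chr1", 101, 250), [f])
        assert cov.max() == 1

    def test_matches_per_fragment_oracle(self):
        """Coverage equals the sum of per-fragment indicator vectors."""
        rng = np.random.default_rng(7)
        grange = GenomicRange("chr1", 500, 700, "+")
        fragments = []
        for _ in range(30):
            start = int(rng.integers(400, 700))
            if rng.random() < 0.4:
                gap = int(rng.integers(20, 120))
                fragments.append(
                    frag(
                        [(start, start + 39), (start + 40 + gap, start + 79 + gap)],
                        strand="+",
                    )
                )
            else:
                fragments.append(frag([(start, start + 79)], strand="+"))
        expected = np.zeros(len(grange), dtype=int)
        for f in fragments:
            expected += compatible_coverage(grange, [f])
        assert (compatible_coverage(grange, fragments) == expected).all()


class TestCountCompatibleFragments:
    def test_junction_count(self):
        j = SpliceJunction(GenomicRange("chr1", 1031, 1130, "+"))
        f = frag([(1001, 1030), (1131, 1176)], strand="+")
        assert count_compatible_fragments(j, [f]) == 1

    def test_exon_with_internal_intron_boundary_is_incompatible(self):
        e = Exon(GenomicRange("chr1", 101, 200, "+"), INTERNAL)
        f = frag([(120, 149), (181, 220)], strand="+")
        assert count_compatible_fragments(e, [f]) == 0

    def test_exon_counts_overlapping_unspliced(self):
        e = Exon(GenomicRange("chr1", 101, 200, "+"), INTERNAL)
        reads = [frag([(90, 165)]), frag([(150, 225)]), frag([(101, 176)])]
        assert count_compatible_fragments(e, reads) == 3

    def test_junction_count_matches_extraction(self):
        fragments = [
            frag([(1001, 1030), (1131, 1176)], strand="+", name=f"f{i}")
            for i in range(5)
        ] + [frag([(900, 975)], strand="+")]
        (j,) = extract_junctions(fragments)
        assert count_compatible_fragments(j, fragments) == j.count == 5


class TestNormalization:
    def test_single_end_effective_length(self):
        s = SampleInfo("s", paired=False, read_length=76)
        assert effective_length(100, s) == 175

    def test_paired_junction_effective_length_is_2r_minus_2(self):
        s = SampleInfo("s", paired=True, read_length=76, frag_length=200)
        assert effective_length(0, s) == 150

    def test_paired_long_feature(self):
        s = SampleInfo("s", paired=True, read_length=76, frag_length=200)
        assert effective_length(300, s) == 499

    def test_fpkm_value(self):
        assert fpkm(35, 175, 1e7) == pytest.approx(20.0)
        assert fpkm(0, 175, 1e7) == 0.0

    def test_fpkm_scale_invariance(self):
        assert fpkm(35, 175, 1e7) == pytest.approx(fpkm(70, 175, 2e7))

    def test_fpkm_requires_positive_denominators(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 1e7)
        with pytest.raises(ValueError):
            fpkm(1, 175, 0)

    @pytest.mark.parametrize(
        "rho, expected",
        [(61.3e6, 19), (57.8e6, 18), (72.2e6, 22), (33.3e6, 10)],
    )
    def test_min_count_for_threshold(self, rho, expected):
        """Smallest junction count reaching FPKM 2 at lambda = 2r - 2."""
        s = SampleInfo("s", paired=True, read_length=76, frag_length=200)
        lam = effective_length(0, s)
        assert min_count_for_fpkm(2.0, lam, rho) == expected

    def test_min_count_zero_threshold(self):
        assert min_count_for_fpkm(0.0, 150, 1e7) == 0

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(0.01, 50),
        st.floats(1, 1e4),
        st.floats(1e3, 1e9),
    )
    def test_min_count_is_tight(self, alpha, lam, rho):
        x = min_count_for_fpkm(alpha, lam, rho)
        assert fpkm(x, lam, rho) >= alpha * (1 - 1e-9)
        if x > 0:
            assert fpkm(x - 1, lam, rho) < alpha * (1 + 1e-9)
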