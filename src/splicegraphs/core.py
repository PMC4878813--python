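"""Core genomic interval types and interval algebra.

All coordinates in this package are 1-based closed intervals on a named
reference sequence, following the GFF/SAM convention.  Conversion to the
0-based half-open BED convention happens only in the BED writer
(:mod:`splicegraphs.io`).

The central operation is :func:`disjoin_exons`, which partitions a set of
(possibly overlapping) exons into disjoint exon bins.  Exon bins are the
exonic edge units of the splice graph: every bin is contained in, or
disjoint from, every input exon, and bin boundaries occur exactly at input
exon starts and ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

STRANDS = ("+", "-", "*")

#: Exon kinds.  An internal exon is flanked by an acceptor (5') and a donor
#: (3'); a terminal exon has exactly one spliced boundary.
INTERNAL = "internal"
FIVE_PRIME_TERMINAL = "five_prime_terminal"
THREE_PRIME_TERMINAL = "three_prime_terminal"
EXON_KINDS = (INTERNAL, FIVE_PRIME_TERMINAL, THREE_PRIME_TERMINAL)


@dataclass(frozen=True, order=True)
class GenomicRange:
    """A stranded 1-based closed interval on a named reference sequence."""

    seqname: str
    start: int
    end: int
    strand: str = "*"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def strand_compatible(self, other: "GenomicRange | str") -> bool:
        """True if strands are equal or either is ``*``."""
        s = other.strand if isinstance(other, GenomicRange) else other
        return self.strand == "*" or s == "*" or self.strand == s

    def overlaps(self, other: "GenomicRange", ignore_strand: bool = False) -> bool:
        if self.seqname != other.seqname:
            return False
        if not ignore_strand and not self.strand_compatible(other):
            return False
        return max(self.start, other.start) <= min(self.end, other.end)

    def contains(self, other: "GenomicRange") -> bool:
        return (
            self.seqname == other.seqname
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Exon:
    """A predicted or annotated exon.

    ``spliced_left`` / ``spliced_right`` record whether the genomically
    left / right boundary is defined by a splice site.  Internal exons are
    spliced on both sides; a terminal exon has exactly one spliced
    boundary (its other boundary is a transcript start or end).
    """

    range: GenomicRange
    kind: str = INTERNAL
    spliced_left: bool = True
    spliced_right: bool = True
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in EXON_KINDS:
            raise ValueError(f"unknown exon kind {self.kind!r}")
        if self.kind == INTERNAL:
            if not (self.spliced_left and self.spliced_right):
                raise ValueError("internal exons must be spliced on both sides")
        else:
            if self.spliced_left == self.spliced_right:
                raise ValueError(
                    "terminal exons must have exactly one spliced boundary"
                )

    @property
    def spliced_boundary(self) -> int:
        """Coordinate of the spliced boundary (terminal exons only)."""
        if self.kind == INTERNAL:
            raise ValueError("internal exons have two spliced boundaries")
        return self.range.start if self.spliced_left else self.range.end

    def key(self) -> tuple:
        r = self.range
        return (r.seqname, r.start, r.end, r.strand, self.kind)


@dataclass
class SpliceJunction:
    """A splice junction, represented by its intron (first to last intronic
    base), with per-sample structurally-compatible fragment counts."""

    range: GenomicRange
    count: int = 0
    fpkm: float | None = None
    samples: tuple[str, ...] = ()
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def donor(self) -> int:
        """Exonic base adjacent to the intron's 5' end (transcript sense)."""
        return self.range.start - 1 if self.range.strand == "+" else self.range.end + 1

    @property
    def acceptor(self) -> int:
        """Exonic base adjacent to the intron's 3' end (transcript sense)."""
        return self.range.end + 1 if self.range.strand == "+" else self.range.start - 1

    def key(self) -> tuple:
        r = self.range
        return (r.seqname, r.start, r.end, r.strand)


@dataclass(frozen=True)
class ExonBin:
    """A disjoint exon bin, with indices of the source exons it derives from."""

    range: GenomicRange
    source_exons: tuple[int, ...] = ()


@dataclass
class Features:
    """A set of transcript features (junctions plus exons) on one genome."""

    junctions: list[SpliceJunction] = field(default_factory=list)
    exons: list[Exon] = field(default_factory=list)

    @property
    def internal_exons(self) -> list[Exon]:
        return [e for e in self.exons if e.kind == INTERNAL]

    @property
    def terminal_exons(self) -> list[Exon]:
        return [e for e in self.exons if e.kind != INTERNAL]

    def __len__(self) -> int:
        return len(self.junctions) + len(self.exons)


def reduce_ranges(ranges: Iterable[GenomicRange]) -> list[GenomicRange]:
    """Merge overlapping or book-ended (end + 1 == next start) ranges.

    Ranges are merged only within the same (seqname, strand) group; the
    result is sorted by (seqname, start, end, strand).
    """
    groups: dict[tuple[str, str], list[GenomicRange]] = {}
    for r in ranges:
        groups.setdefault((r.seqname, r.strand), []).append(r)
    out: list[GenomicRange] = []
    for (seqname, strand), rs in groups.items():
        rs.sort(key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end + 1:
                cur_end = max(cur_end, r.end)
            else:
                out.append(GenomicRange(seqname, cur_start, cur_end, strand))
                cur_start, cur_end = r.start, r.end
        out.append(GenomicRange(seqname, cur_start, cur_end, strand))
    out.sort()
    return out


def _partition(
    ranges: Sequence[GenomicRange], extra_breaks: Iterable[int] = ()
) -> list[tuple[int, int]]:
    """Partition the union of ``ranges`` at range starts/ends (and
    ``extra_breaks``, interpreted as boundary coordinates *before* a base).

    Returns (start, end) pairs covering exactly the union.
    """
    if not ranges:
        return []
    # boundary b means "a bin boundary lies before base b"
    breaks: set[int] = set(extra_breaks)
    for r in ranges:
        breaks.add(r.start)
        breaks.add(r.end + 1)
    union = reduce_ranges(
        [GenomicRange(r.seqname, r.start, r.end, "*") for r in ranges]
    )
    bins: list[tuple[int, int]] = []
    ordered = sorted(breaks)
    for u in union:
        inner = [b for b in ordered if u.start < b <= u.end]
        lo = u.start
        for b in inner:
            bins.append((lo, b - 1))
            lo = b
        bins.append((lo, u.end))
    return bins


def disjoin_exons(
    exons: Sequence[Exon], extra_breaks: Iterable[int] = ()
) -> list[ExonBin]:
    """Split overlapping exons into disjoint exon bins.

    All exons must share seqname and strand.  The result is the coarsest
    partition of the exon union such that every bin is contained in, or
    disjoint from, every input exon; bin boundaries occur exactly at input
    exon starts/ends (plus any ``extra_breaks`` boundary coordinates, used
    by the splice-graph builder to split bins at splice sites).
    """
    if not exons:
        return []
    seqnames = {e.range.seqname for e in exons}
    strands = {e.range.strand for e in exons}
    if len(seqnames) > 1 or len(strands) > 1:
        raise ValueError(
            f"exons must share seqname and strand, got {seqnames} / {strands}"
        )
    seqname = seqnames.pop()
    strand = strands.pop()
    bins = []
    for start, end in _partition([e.range for e in exons], extra_breaks):
        src = tuple(
            i
            for i, e in enumerate(exons)
            if e.range.start <= start and end <= e.range.end
        )
        bins.append(ExonBin(GenomicRange(seqname, start, end, strand), src))
    return bins
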