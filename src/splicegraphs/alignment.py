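"""Reading SAM/BAM alignments and fragment-level counting.

A *fragment* is the unit of observation: a single-end read, or the two
mates of a properly paired read pair combined.  Splice junctions are
extracted from alignment gaps (CIGAR ``N`` operations); coverage and
feature counts are computed from *structurally compatible* fragments, i.e.
fragments whose aligned blocks and gaps are consistent with the feature's
exon/intron structure.

Normalization uses FPKM (fragments per kilobase of effective feature
length per million aligned fragments), where the effective length lambda
of a feature of length l is the number of possible placements of a
compatible fragment:

* single-end: ``lambda = l + r - 1`` with read length r,
* paired-end: ``lambda = l + f - 1 - max(i - l + 1, 0)`` with fragment
  length f and inner distance ``i = f - 2 r``.

A splice junction has length l = 0, hence ``lambda = 2 r - 2`` for
paired-end data (any f with non-negative inner distance).
"""

from __future__ import annotations

import logging
import math
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .core import Exon, ExonBin, GenomicRange, SpliceJunction

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_CONSUMES_REF_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X
_REF_SKIP = 3  # N


@dataclass
class FragmentAlignment:
    """One aligned fragment: blocks of one read, or of two combined mates.

    ``strand`` is the transcriptional strand taken from the spliced
    alignment strand tag where present, ``*`` otherwise.  Gaps between
    consecutive blocks within a read are introns.
    """

    seqname: str
    strand: str
    blocks_read1: tuple[GenomicRange, ...]
    blocks_read2: tuple[GenomicRange, ...] = ()
    paired: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        for blocks in (self.blocks_read1, self.blocks_read2):
            for a, b in zip(blocks, blocks[1:]):
                if b.start <= a.end + 1:
                    raise ValueError(
                        f"read blocks must be increasing with gaps >= 1: {a} {b}"
                    )

    @property
    def reads(self) -> tuple[tuple[GenomicRange, ...], ...]:
        if self.blocks_read2:
            return (self.blocks_read1, self.blocks_read2)
        return (self.blocks_read1,)

    def gaps(self) -> list[tuple[int, int]]:
        """Distinct intron gaps (first, last intronic base) of the fragment.

        A gap present in both mates is reported once.
        """
        seen: set[tuple[int, int]] = set()
        out: list[tuple[int, int]] = []
        for blocks in self.reads:
            for a, b in zip(blocks, blocks[1:]):
                g = (a.end + 1, b.start - 1)
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    @property
    def span(self) -> tuple[int, int]:
        starts = [b.start for blocks in self.reads for b in blocks]
        ends = [b.end for blocks in self.reads for b in blocks]
        return min(starts), max(ends)

    def blocks(self) -> list[GenomicRange]:
        return [b for blocks in self.reads for b in blocks]


def _cigar_blocks(aln: pysam.AlignedSegment) -> tuple[GenomicRange, ...]:
    """Aligned reference blocks of one read, 1-based closed, split at N.

    M/=/X and D consume reference within a block; N closes the current
    block; I/S/H/P do not consume reference.
    """
    blocks: list[GenomicRange] = []
    pos = aln.reference_start + 1  # to 1-based
    block_start = pos
    for op, length in aln.cigartuples:
        if op in _CONSUMES_REF_IN_BLOCK:
            pos += length
        elif op == _REF_SKIP:
            if pos > block_start:
                blocks.append(GenomicRange(aln.reference_name, block_start, pos - 1))
            pos += length
            block_start = pos
    if pos > block_start:
        blocks.append(GenomicRange(aln.reference_name, block_start, pos - 1))
    return tuple(blocks)


def _is_spliced(aln: pysam.AlignedSegment) -> bool:
    return any(op == _REF_SKIP for op, _ in aln.cigartuples)


def _aln_strand(aln: pysam.AlignedSegment) -> str:
    try:
        return aln.get_tag("XS")
    except KeyError:
        return "*"


def _usable(aln: pysam.AlignedSegment) -> bool:
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_qcfail:
        return False
    if aln.is_paired and not aln.is_proper_pair:
        return False
    return True


def read_fragments(
    path: str, region: tuple[str, int, int] | None = None
) -> Iterator[FragmentAlignment]:
    """Stream fragments from a SAM/BAM file.

    Only primary, properly paired (if paired) alignments are used.  Mates
    of a pair are combined into one :class:`FragmentAlignment`; the
    transcriptional strand is taken from the spliced-alignment strand tag
    when present, ``*`` otherwise.  Fragments whose mates carry
    conflicting strand tags are dropped with a logged count, as are
    fragments whose mate is never seen (e.g. outside the queried region).

    Querying a ``region`` (seqname, start, end; 1-based closed) requires
    an index.
    """
    with pysam.AlignmentFile(path) as af:
        if region is None:
            it = af.fetch(until_eof=True)
        else:
            seqname, start, end = region
            it = af.fetch(seqname, start - 1, end)
        pending: dict[str, pysam.AlignedSegment] = {}
        n_orphans = 0
        n_conflict = 0
        for aln in it:
            if not _usable(aln):
                continue
            if not aln.is_paired:
                yield FragmentAlignment(
                    seqname=aln.reference_name,
                    strand=_aln_strand(aln),
                    blocks_read1=_cigar_blocks(aln),
                    paired=False,
                    name=aln.query_name,
                )
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            first, second = (mate, aln) if mate.is_read1 else (aln, mate)
            strands = {s for s in (_aln_strand(first), _aln_strand(second)) if s != "*"}
            if len(strands) > 1:
                n_conflict += 1
                continue
            strand = strands.pop() if strands else "*"
            b1, b2 = _cigar_blocks(first), _cigar_blocks(second)
            if b1 and b2 and b2[0].start < b1[0].start:
                b1, b2 = b2, b1
            yield FragmentAlignment(
                seqname=first.reference_name,
                strand=strand,
                blocks_read1=b1,
                blocks_read2=b2,
                paired=True,
                name=first.query_name,
            )
        n_orphans = len(pending)
        if n_orphans:
            logger.info("skipped %d fragments with missing mates", n_orphans)
        if n_conflict:
            logger.info(
                "dropped %d fragments with conflicting mate strand tags", n_conflict
            )


@dataclass
class SampleInfo:
    """Per-sample library parameters.

    r = read length (nt), f = median fragment span (paired-end only),
    rho = library size (number of aligned fragments).
    """

    name: str
    paired: bool
    read_length: int
    frag_length: float | None = None
    library_size: int = 0


def estimate_sample_info(
    path: str, name: str | None = None, max_fragments: int | None = None
) -> SampleInfo:
    """Estimate read length, fragment length and library size from a file.

    The read length is the most frequent observed read length; the
    fragment length is the median span (leftmost start to rightmost end)
    of unspliced properly paired fragments; the library size is the number
    of aligned fragments.
    """
    read_lengths: Counter[int] = Counter()
    spans: list[int] = []
    pending: dict[str, tuple[int, int, bool]] = {}
    n_fragments = 0
    paired = False
    with pysam.AlignmentFile(path) as af:
        for aln in af.fetch(until_eof=True):
            if not _usable(aln):
                continue
            read_lengths[aln.query_length] += 1
            if aln.is_paired:
                paired = True
                if aln.is_read1:
                    n_fragments += 1
                start = aln.reference_start + 1
                end = aln.reference_end
                mate = pending.pop(aln.query_name, None)
                if mate is None:
                    pending[aln.query_name] = (start, end, _is_spliced(aln))
                else:
                    mstart, mend, mspliced = mate
                    if not mspliced and not _is_spliced(aln):
                        spans.append(max(end, mend) - min(start, mstart) + 1)
            else:
                n_fragments += 1
            if max_fragments is not None and n_fragments >= max_fragments:
                break
    if n_fragments == 0:
        raise ValueError(f"no usable alignments in {path}")
    if name is None:
        name = path
    return SampleInfo(
        name=name,
        paired=paired,
        read_length=read_lengths.most_common(1)[0][0],
        frag_length=float(statistics.median(spans)) if spans else None,
        library_size=n_fragments,
    )


def extract_junctions(fragments: Iterable[FragmentAlignment]) -> list[SpliceJunction]:
    """Collect splice junctions from split-read fragments.

    One junction per distinct (seqname, intron start, intron end, strand);
    the count is the number of fragments containing that exact gap (a gap
    present in both mates counts once).  Fragments with strand ``*`` carry
    no usable donor/acceptor orientation and are excluded.
    """
    counts: Counter[tuple[str, int, int, str]] = Counter()
    for frag in fragments:
        if frag.strand == "*":
            continue
        for gs, ge in frag.gaps():
            counts[(frag.seqname, gs, ge, frag.strand)] += 1
    junctions = [
        SpliceJunction(GenomicRange(seqname, gs, ge, strand), count=c)
        for (seqname, gs, ge, strand), c in counts.items()
    ]
    junctions.sort(key=lambda j: j.key())
    return junctions


def _compatible_with_range(frag: FragmentAlignment, grange: GenomicRange) -> bool:
    """True if the fragment's structure is consistent with ``grange`` being
    exonic: no intron gap of the fragment partially overlaps the range
    (a gap must be disjoint from the range or fully contain it), and the
    strand is compatible."""
    if frag.seqname != grange.seqname or not grange.strand_compatible(frag.strand):
        return False
    for gs, ge in frag.gaps():
        if max(gs, grange.start) <= min(ge, grange.end):  # gap overlaps range
            if not (gs <= grange.start and grange.end <= ge):
                return False
    return True


def compatible_coverage(
    grange: GenomicRange, fragments: Iterable[FragmentAlignment]
) -> np.ndarray:
    """Per-base count of structurally compatible fragments over ``grange``.

    A fragment contributes at position p if it has a read base aligned at
    p and its alignment is compatible with the queried range being exonic
    (:func:`_compatible_with_range`).  Overlapping mates contribute at
    most 1 per fragment and position.
    """
    cov = np.zeros(len(grange), dtype=int)
    for frag in fragments:
        if not _compatible_with_range(frag, grange):
            continue
        mask = np.zeros(len(grange), dtype=bool)
        for b in frag.blocks():
            lo = max(b.start, grange.start) - grange.start
            hi = min(b.end, grange.end) - grange.start
            if hi >= lo:
                mask[lo : hi + 1] = True
        cov += mask
    return cov


def base_coverage(
    grange: GenomicRange, fragments: Iterable[FragmentAlignment]
) -> np.ndarray:
    """Per-base fragment coverage with per-base compatibility only.

    Unlike :func:`compatible_coverage`, compatibility is judged per base:
    a fragment contributes at p if it has an aligned base at p (which a
    gap can never contradict) and a compatible strand.  Used for
    terminal-exon extension, where the candidate region grows base by
    base.
    """
    cov = np.zeros(len(grange), dtype=int)
    for frag in fragments:
        if frag.seqname != grange.seqname or not grange.strand_compatible(frag.strand):
            continue
        mask = np.zeros(len(grange), dtype=bool)
        for b in frag.blocks():
            lo = max(b.start, grange.start) - grange.start
            hi = min(b.end, grange.end) - grange.start
            if hi >= lo:
                mask[lo : hi + 1] = True
        cov += mask
    return cov


def count_compatible_fragments(
    feature: Exon | ExonBin | SpliceJunction,
    fragments: Iterable[FragmentAlignment],
) -> int:
    """Count fragments structurally compatible with a feature.

    For a junction: fragments containing exactly that intron gap.  For an
    exon or exon bin: fragments overlapping the feature, with no intron
    boundary strictly inside it and a compatible strand.
    """
    if isinstance(feature, SpliceJunction):
        r = feature.range
        n = 0
        for frag in fragments:
            if frag.seqname != r.seqname or not r.strand_compatible(frag.strand):
                continue
            if (r.start, r.end) in frag.gaps():
                n += 1
        return n
    r = feature.range
    n = 0
    for frag in fragments:
        if not _compatible_with_range(frag, r):
            continue
        if any(b.overlaps(r, ignore_strand=True) for b in frag.blocks()):
            n += 1
    return n


def effective_length(l: int, sample: SampleInfo) -> float:
    """Effective feature length: the number of possible positions for a
    compatible fragment.  Junctions have l = 0.  May be non-positive for
    features shorter than the minimal compatible placement allows; callers
    treat non-positive values as "FPKM undefined"."""
    if l < 0:
        raise ValueError("feature length must be >= 0")
    r = sample.read_length
    if not sample.paired:
        return l + r - 1
    if sample.frag_length is None:
        raise ValueError("paired sample without fragment length estimate")
    f = sample.frag_length
    i = f - 2 * r
    return l + f - 1 - max(i - l + 1, 0)


def fpkm(x: float, lam: float, rho: float) -> float:
    """Fragments per kilobase of effective length per million fragments:
    ``x * 1e9 / (lam * rho)``."""
    if lam <= 0:
        raise ValueError(f"effective length must be positive, got {lam}")
    if rho <= 0:
        raise ValueError(f"library size must be positive, got {rho}")
    return x * 1e9 / (lam * rho)


def min_count_for_fpkm(alpha: float, lam: float, rho: float) -> int:
    """Smallest integer count x with ``fpkm(x, lam, rho) >= alpha``.

    The boundary case ``x * 1e9 == alpha * lam * rho`` passes.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return 0
    if lam <= 0 or rho <= 0:
        raise ValueError("lam and rho must be positive")
    x = math.ceil(alpha * lam * rho / 1e9)
    # guard against float fuzz on the boundary
    if x >= 1 and (x - 1) * 1e9 >= alpha * lam * rho:
        x -= 1
    return x
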