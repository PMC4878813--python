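"""Per-sample prediction of splice junctions and exons, and merging.

Prediction proceeds in three stages, each controlled by one parameter:

* ``alpha`` -- junctions observed in split reads are kept if their
  normalized count (FPKM, with junction effective length) is at least
  ``alpha``.
* ``beta`` -- a genomic region flanked by a splice acceptor on the left
  and a splice donor on the right (in genome orientation; roles are
  mirrored on the minus strand) is predicted as an internal exon if its
  minimum compatible coverage is at least ``beta`` times the number of
  spliced reads supporting the exon boundaries.
* ``gamma`` -- at each remaining junction boundary, a terminal exon is
  grown away from the intron for as long as per-base coverage stays at or
  above ``gamma`` times the spliced-read support of the boundary.
  Terminal exons sharing a splice donor or acceptor with a predicted
  internal exon are excluded.

Prediction is strictly per sample; multi-sample analyses merge per-sample
feature sets afterwards with :func:`merge_predictions`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import (
    FragmentAlignment,
    SampleInfo,
    base_coverage,
    compatible_coverage,
    effective_length,
    extract_junctions,
    fpkm,
)
from .core import (
    FIVE_PRIME_TERMINAL,
    INTERNAL,
    THREE_PRIME_TERMINAL,
    Exon,
    Features,
    GenomicRange,
    SpliceJunction,
)

logger = logging.getLogger(__name__)

_AGGREGATORS = {
    "max": max,
    "min": min,
    "mean": lambda a, b=None: a if b is None else (a + b) / 2,
}


@dataclass
class PredictionParams:
    """Thresholds for feature prediction.

    alpha: minimum junction FPKM; beta: minimum coverage for internal
    exons relative to boundary spliced-read support; gamma: minimum
    relative coverage for terminal-exon extension.
    ``n_spliced_agg`` chooses how the spliced-read support of the two
    boundaries of a candidate internal exon is aggregated (max is the
    conservative default; the threshold is hardest to pass).
    """

    alpha: float = 2.0
    beta: float = 0.2
    gamma: float = 0.2
    max_terminal_extension: int = 10_000
    n_spliced_agg: str = "max"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        for name in ("beta", "gamma"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_spliced_agg not in _AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.n_spliced_agg!r}")


def predict_junctions(
    fragments: Sequence[FragmentAlignment],
    sample: SampleInfo,
    params: PredictionParams = PredictionParams(),
) -> list[SpliceJunction]:
    """Junctions from split reads whose FPKM is at least ``alpha``."""
    lam = effective_length(0, sample)
    junctions = []
    for j in extract_junctions(fragments):
        j.fpkm = (
            fpkm(j.count, lam, sample.library_size) if lam > 0 else None
        )
        if params.alpha == 0 or (j.fpkm is not None and j.fpkm >= params.alpha):
            j.samples = (sample.name,)
            j.sample_counts = {sample.name: j.count}
            junctions.append(j)
    return junctions


def _boundary_support(
    junctions: Iterable[SpliceJunction],
) -> tuple[dict[tuple[str, str, int], int], dict[tuple[str, str, int], int]]:
    """Spliced-read support at exon boundaries implied by junctions.

    Returns (left, right): ``left[(seqname, strand, p)]`` is the number of
    spliced reads with an intron ending at p - 1 (exon starts at p);
    ``right`` mirrors for introns starting at p + 1 (exon ends at p).
    """
    left: dict[tuple[str, str, int], int] = {}
    right: dict[tuple[str, str, int], int] = {}
    for j in junctions:
        r = j.range
        k_left = (r.seqname, r.strand, r.end + 1)
        k_right = (r.seqname, r.strand, r.start - 1)
        left[k_left] = left.get(k_left, 0) + j.count
        right[k_right] = right.get(k_right, 0) + j.count
    return left, right


def predict_internal_exons(
    junctions: Sequence[SpliceJunction],
    fragments: Sequence[FragmentAlignment],
    params: PredictionParams = PredictionParams(),
) -> list[Exon]:
    """Internal exons between adjacent intron boundaries.

    For every same-strand pair of an exon-start boundary (intron end + 1)
    and an exon-end boundary (intron start - 1) with no other retained
    splice site strictly inside, the candidate region is accepted iff its
    minimum compatible coverage is at least ``beta`` times the aggregated
    spliced-read support of its two boundaries.
    """
    agg = _AGGREGATORS[params.n_spliced_agg]
    left, right = _boundary_support(junctions)
    by_group: dict[tuple[str, str], set[int]] = {}
    for key in list(left) + list(right):
        seqname, strand, p = key
        by_group.setdefault((seqname, strand), set()).add(p)
    sample_name = None
    exons: list[Exon] = []
    for (seqname, strand), sites in by_group.items():
        ordered = sorted(sites)
        starts = sorted(
            p for (s, st, p) in left if (s, st) == (seqname, strand)
        )
        ends = sorted(
            p for (s, st, p) in right if (s, st) == (seqname, strand)
        )
        for a in starts:
            # nearest candidate end at or after the start; any other
            # retained splice site strictly between disqualifies the pair
            for d in ends:
                if d < a:
                    continue
                if any(a < p < d for p in ordered):
                    break
                n_spliced = agg(
                    left[(seqname, strand, a)], right[(seqname, strand, d)]
                )
                region = GenomicRange(seqname, a, d, strand)
                cov = compatible_coverage(region, fragments)
                if cov.min() >= params.beta * n_spliced:
                    exons.append(
                        Exon(region, INTERNAL, spliced_left=True, spliced_right=True)
                    )
                break
    exons.sort(key=lambda e: e.key())
    return exons


def predict_terminal_exons(
    junctions: Sequence[SpliceJunction],
    internal_exons: Sequence[Exon],
    fragments: Sequence[FragmentAlignment],
    params: PredictionParams = PredictionParams(),
) -> list[Exon]:
    """Terminal exons grown from junction boundaries by coverage.

    Each junction boundary that is not already a spliced boundary of a
    predicted internal exon seeds a terminal exon: starting at the exonic
    base adjacent to the intron, the exon is extended away from the
    intron one base at a time while per-base coverage is at least
    ``gamma`` times the boundary's spliced-read support, up to
    ``max_terminal_extension`` nt.  Terminal exons sharing a splice donor
    or acceptor with a predicted internal exon are then excluded (the
    seeding step already guarantees this).
    """
    left, right = _boundary_support(junctions)
    internal_left = {
        (e.range.seqname, e.range.strand, e.range.start) for e in internal_exons
    }
    internal_right = {
        (e.range.seqname, e.range.strand, e.range.end) for e in internal_exons
    }
    exons: list[Exon] = []
    # boundaries where the exon lies right of the intron (exon start)
    for (seqname, strand, pos), support in left.items():
        if (seqname, strand, pos) in internal_left:
            continue
        window = GenomicRange(
            seqname, pos, pos + params.max_terminal_extension, strand
        )
        cov = base_coverage(window, fragments)
        hi = pos
        threshold = params.gamma * support
        for offset in range(1, len(cov)):
            if cov[offset] >= threshold and cov[offset] > 0:
                hi = pos + offset
            else:
                break
        kind = THREE_PRIME_TERMINAL if strand == "+" else FIVE_PRIME_TERMINAL
        exons.append(
            Exon(
                GenomicRange(seqname, pos, hi, strand),
                kind,
                spliced_left=True,
                spliced_right=False,
            )
        )
    # boundaries where the exon lies left of the intron (exon end)
    for (seqname, strand, pos), support in right.items():
        if (seqname, strand, pos) in internal_right:
            continue
        lo_window = max(1, pos - params.max_terminal_extension)
        window = GenomicRange(seqname, lo_window, pos, strand)
        cov = base_coverage(window, fragments)
        lo = pos
        threshold = params.gamma * support
        for offset in range(1, len(cov)):
            idx = len(cov) - 1 - offset
            if cov[idx] >= threshold and cov[idx] > 0:
                lo = pos - offset
            else:
                break
        kind = FIVE_PRIME_TERMINAL if strand == "+" else THREE_PRIME_TERMINAL
        exons.append(
            Exon(
                GenomicRange(seqname, lo, pos, strand),
                kind,
                spliced_left=False,
                spliced_right=True,
            )
        )
    exons.sort(key=lambda e: e.key())
    return exons


def predict_features(
    fragments: Sequence[FragmentAlignment],
    sample: SampleInfo,
    params: PredictionParams = PredictionParams(),
) -> Features:
    """Full per-sample prediction: junctions, internal and terminal exons."""
    junctions = predict_junctions(fragments, sample, params)
    internal = predict_internal_exons(junctions, fragments, params)
    terminal = predict_terminal_exons(junctions, internal, fragments, params)
    for e in internal + terminal:
        e.samples = (sample.name,)
    return Features(junctions=junctions, exons=internal + terminal)


def merge_predictions(per_sample: Mapping[str, Features]) -> Features:
    """Merge per-sample predictions into a common feature set.

    Junctions and internal exons are merged by exact coordinates and
    strand (union); terminal exons sharing the same spliced boundary are
    merged to the maximal extent.  Each merged feature records its
    supporting samples; junction counts are kept per sample and summed.
    """
    if not per_sample:
        raise ValueError("at least one sample is required")
    merged_j: dict[tuple, SpliceJunction] = {}
    merged_internal: dict[tuple, Exon] = {}
    merged_terminal: dict[tuple, Exon] = {}
    for sample_name, features in per_sample.items():
        for j in features.junctions:
            key = j.key()
            if key not in merged_j:
                merged_j[key] = SpliceJunction(j.range)
            m = merged_j[key]
            m.samples = tuple(sorted(set(m.samples) | {sample_name}))
            m.sample_counts[sample_name] = j.count
            m.count = sum(m.sample_counts.values())
        for e in features.internal_exons:
            key = e.key()
            if key not in merged_internal:
                merged_internal[key] = Exon(e.range, INTERNAL)
            m = merged_internal[key]
            m.samples = tuple(sorted(set(m.samples) | {sample_name}))
        for e in features.terminal_exons:
            r = e.range
            key = (r.seqname, r.strand, e.kind, e.spliced_boundary)
            if key not in merged_terminal:
                merged_terminal[key] = Exon(
                    e.range, e.kind, e.spliced_left, e.spliced_right
                )
            m = merged_terminal[key]
            if e.spliced_left:
                new_end = max(m.range.end, r.end)
                m.range = GenomicRange(r.seqname, r.start, new_end, r.strand)
            else:
                new_start = min(m.range.start, r.start)
                m.range = GenomicRange(r.seqname, new_start, r.end, r.strand)
            m.samples = tuple(sorted(set(m.samples) | {sample_name}))
    junctions = sorted(merged_j.values(), key=lambda j: j.key())
    exons = sorted(
        list(merged_internal.values()) + list(merged_terminal.values()),
        key=lambda e: e.key(),
    )
    return Features(junctions=junctions, exons=exons)
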