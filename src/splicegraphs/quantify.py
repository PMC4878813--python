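"""Local quantification of relative splice variant usage (PSI).

For an event with n variants, each variant i receives two boundary
counts: ``x_i^D``, the number of compatible fragments with a read
overlapping the splice donor at the event start, and ``x_i^A``, the same
at the splice acceptor at the event end.  With per-side totals
``m^S = sum_k x_k^S``, the local estimates are ``psi_i^S = x_i^S / m^S``
and the combined estimate is their weighted mean

    psi_i = (x_i^D + x_i^A) / (m^D + m^A),

which weights each side by its total count.  Counts at the event start
are valid only if the event is right-closed, counts at the end only if
it is left-closed; events starting at the source (alternative first
exons) have no donor side and events ending at the sink no acceptor
side.  Estimates based on fewer than ``min_total`` informative fragments
(m^D + m^A) are masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import FragmentAlignment
from .core import GenomicRange
from .events import SpliceEvent, SpliceVariant
from .graph import AUGMENT, EXONIC, JUNCTION, SINK, SOURCE, SpliceGraph

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 20


@dataclass
class PsiEstimate:
    """Per-variant boundary counts and combined relative-usage estimate."""

    event_id: str
    variant_id: str
    x_D: int | None
    x_A: int | None
    m_D: int | None
    m_A: int | None
    psi: float | None
    flagged: bool = False


def _variant_structure(variant: SpliceVariant):
    """Exonic ranges, intron gaps and genomic base extent of a variant."""
    exonic: list[GenomicRange] = []
    introns: set[tuple[int, int]] = set()
    coords: list[int] = []
    for u, v, kind, feature in variant.edges:
        for n in (u, v):
            if isinstance(n, int):
                coords.append(n)
        if kind == EXONIC:
            exonic.append(feature.range)
        elif kind == JUNCTION:
            introns.add((feature.range.start, feature.range.end))
    if not coords:
        return exonic, introns, None
    lo, hi = min(coords), max(coords) - 1  # boundary coords -> base extent
    return exonic, introns, (lo, hi)


def _compatible_with_variant(
    frag: FragmentAlignment,
    strand: str,
    exonic: Sequence[GenomicRange],
    introns: set[tuple[int, int]],
    extent: tuple[int, int] | None,
) -> bool:
    """Structural compatibility of a fragment with a variant path, over
    the genomic extent the fragment covers.

    Within the event extent, every fragment gap must exactly match a
    variant intron, and every aligned base must fall in the variant's
    exonic regions.  Outside the extent the fragment is unconstrained.
    """
    if not (strand == "*" or frag.strand == "*" or strand == frag.strand):
        return False
    if extent is None:
        return True
    lo, hi = extent
    for gs, ge in frag.gaps():
        if max(gs, lo) <= min(ge, hi) and (gs, ge) not in introns:
            return False
    for b in frag.blocks():
        blo, bhi = max(b.start, lo), min(b.end, hi)
        if blo > bhi:
            continue
        pos = blo
        for er in sorted(exonic, key=lambda r: r.start):
            if er.start <= pos <= er.end:
                pos = er.end + 1
                if pos > bhi:
                    break
        if pos <= bhi:
            return False
    return True


def _spans_boundary(frag: FragmentAlignment, boundary: int) -> bool:
    """True if some single read of the fragment has aligned bases on both
    sides of the boundary coordinate (before base ``boundary``)."""
    for blocks in frag.reads:
        left = any(b.start <= boundary - 1 for b in blocks)
        right = any(b.end >= boundary for b in blocks)
        if left and right:
            return True
    return False


def boundary_fragment_indices(
    event: SpliceEvent,
    variant: SpliceVariant,
    side: str,
    fragments: Sequence[FragmentAlignment],
    sg: SpliceGraph,
) -> list[int]:
    """Indices of fragments counted for a variant at one event boundary.

    A fragment is counted if (a) one of its reads has at least one
    aligned base on each side of the boundary node (spliced via the
    variant's first/last junction, or unspliced across adjacent exon
    bins) and (b) it is structurally compatible with the variant's path
    over the extent it covers.
    """
    if side not in ("D", "A"):
        raise ValueError("side must be 'D' or 'A'")
    if side == "D" and not event.right_closed:
        raise ValueError("donor-side counts require a right-closed event")
    if side == "A" and not event.left_closed:
        raise ValueError("acceptor-side counts require a left-closed event")
    node = variant.nodes[0] if side == "D" else variant.nodes[-1]
    if node in (SOURCE, SINK):
        raise ValueError(f"event boundary {node!r} has no countable side")
    exonic, introns, extent = _variant_structure(variant)
    out = []
    for i, frag in enumerate(fragments):
        if frag.seqname != sg.seqname:
            continue
        if not _spans_boundary(frag, node):
            continue
        if _compatible_with_variant(frag, sg.strand, exonic, introns, extent):
            out.append(i)
    return out


def count_variant_boundary(
    event: SpliceEvent,
    variant: SpliceVariant,
    side: str,
    fragments: Sequence[FragmentAlignment],
    sg: SpliceGraph,
) -> int:
    return len(boundary_fragment_indices(event, variant, side, fragments, sg))


def estimate_psi(
    event: SpliceEvent,
    counts: Mapping[str, Mapping[str, int | None]],
) -> list[PsiEstimate]:
    """Combine boundary counts into per-variant PSI estimates.

    ``counts`` maps variant id to ``{"D": x or None, "A": x or None}``;
    a side that is None for all variants is invalid for the event.  The
    combined estimate is the count sum over valid sides divided by the
    total over variants; with no valid side or all-zero totals, psi is
    missing.
    """
    for vid, c in counts.items():
        for side in ("D", "A"):
            x = c.get(side)
            if x is not None and x < 0:
                raise ValueError(f"negative count for {vid} side {side}")
    sides = [
        s
        for s in ("D", "A")
        if any(counts[v.id].get(s) is not None for v in event.variants)
    ]
    totals = {
        s: sum(counts[v.id].get(s) or 0 for v in event.variants) for s in sides
    }
    m = sum(totals.values())
    out = []
    for v in event.variants:
        x = {s: counts[v.id].get(s) for s in ("D", "A")}
        psi = None
        if sides and m > 0:
            psi = sum(x[s] or 0 for s in sides) / m
        out.append(
            PsiEstimate(
                event_id=event.id,
                variant_id=v.id,
                x_D=x["D"],
                x_A=x["A"],
                m_D=totals.get("D"),
                m_A=totals.get("A"),
                psi=psi,
            )
        )
    return out


def filter_psi(
    estimates: Iterable[PsiEstimate], min_total: int = DEFAULT_MIN_TOTAL
) -> list[PsiEstimate]:
    """Mask psi where the informative-fragment total m_D + m_A is below
    ``min_total``; counts are retained."""
    out = []
    for est in estimates:
        total = (est.m_D or 0) + (est.m_A or 0)
        if total < min_total and est.psi is not None:
            est = PsiEstimate(
                est.event_id,
                est.variant_id,
                est.x_D,
                est.x_A,
                est.m_D,
                est.m_A,
                None,
                est.flagged,
            )
        out.append(est)
    return out


def quantify_event(
    event: SpliceEvent,
    fragments: Sequence[FragmentAlignment],
    sg: SpliceGraph,
) -> list[PsiEstimate]:
    """Count both valid boundaries of an event and estimate PSI.

    Fragments assigned to more than one variant at a boundary (variants
    sharing their first or last edge) count toward each; if more than
    half of the boundary fragments of the event are multiply assigned,
    the event's estimates are flagged.
    """
    sides = []
    if event.right_closed and event.start not in (SOURCE, SINK):
        sides.append("D")
    if event.left_closed and event.end not in (SOURCE, SINK):
        sides.append("A")
    counts: dict[str, dict[str, int | None]] = {
        v.id: {"D": None, "A": None} for v in event.variants
    }
    assigned: dict[tuple[str, int], int] = {}
    for side in sides:
        for v in event.variants:
            idx = boundary_fragment_indices(event, v, side, fragments, sg)
            counts[v.id][side] = len(idx)
            for i in idx:
                assigned[(side, i)] = assigned.get((side, i), 0) + 1
    flagged = False
    if assigned:
        multi = sum(1 for n in assigned.values() if n > 1)
        flagged = multi / len(assigned) > 0.5
    estimates = estimate_psi(event, counts)
    for est in estimates:
        est.flagged = flagged
    return estimates


def quantify_events(
    events_by_graph: Iterable[tuple[SpliceGraph, Sequence[SpliceEvent]]],
    fragments: Sequence[FragmentAlignment],
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Quantify all events of a set of gene graphs into a table."""
    rows = []
    for sg, events in events_by_graph:
        for event in events:
            estimates = filter_psi(
                quantify_event(event, fragments, sg), min_total=min_total
            )
            for est in estimates:
                rows.append(
                    {
                        "event_id": est.event_id,
                        "variant_id": est.variant_id,
                        "gene_id": event.gene_id,
                        "event_type": event.event_type,
                        "x_D": est.x_D,
                        "x_A": est.x_A,
                        "m_D": est.m_D,
                        "m_A": est.m_A,
                        "psi": est.psi,
                        "flagged": est.flagged,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "variant_id",
            "gene_id",
            "event_type",
            "x_D",
            "x_A",
            "m_D",
            "m_A",
            "psi",
            "flagged",
        ],
    )
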