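"""Identification and classification of splice events from a splice graph.

A splice event is a pair of nodes (start, end) connected by at least two
paths such that no intervening node lies on all of them.  Each path is a
splice variant.  Events whose endpoints both lie strictly inside another
event's variant are *nested* in that variant; nesting is recorded and
nested events are also reported standalone.

An event is *left-closed* if its interior can only be entered through the
event start, and *right-closed* if its interior can only be left through
the event end.  Closure determines which event boundary yields valid
counts for quantification (see :mod:`splicegraphs.quantify`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .graph import AUGMENT, EXONIC, JUNCTION, SINK, SOURCE, SpliceGraph

logger = logging.getLogger(__name__)

SKIPPED_EXON = "skipped_exon"
ALT_5SS = "alternative_5prime_splice_site"
ALT_3SS = "alternative_3prime_splice_site"
ALT_FIRST = "alternative_first_exon"
ALT_LAST = "alternative_last_exon"
RETAINED_INTRON = "retained_intron"
MXE = "mutually_exclusive_exons"
COMPLEX = "complex"


@dataclass
class SpliceVariant:
    """One path of a splice event.

    ``edges`` is the ordered list of (u, v, kind, feature) tuples from the
    event start to the event end; ``nested_events`` lists ids of events
    fully contained in this path's internal nodes.
    """

    id: str
    nodes: tuple
    edges: tuple
    edge_keys: tuple = ()  # multigraph keys, distinguish parallel edges
    nested_events: list[str] = field(default_factory=list)

    @property
    def internal_nodes(self) -> frozenset:
        return frozenset(self.nodes[1:-1])

    @property
    def edge_kinds(self) -> tuple[str, ...]:
        return tuple(kind for _, _, kind, _ in self.edges)


@dataclass
class SpliceEvent:
    id: str
    gene_id: str
    start: object
    end: object
    variants: list[SpliceVariant]
    left_closed: bool = True
    right_closed: bool = True
    event_type: str = COMPLEX
    parents: list[str] = field(default_factory=list)

    @property
    def closed(self) -> bool:
        return self.left_closed and self.right_closed

    @property
    def internal_nodes(self) -> frozenset:
        out: set = set()
        for v in self.variants:
            out |= v.internal_nodes
        return frozenset(out)


def _edge_paths(g: nx.MultiDiGraph, s, e, limit: int):
    """Up to ``limit`` simple edge paths from s to e, as lists of
    (u, v, key) triples."""
    return list(itertools.islice(nx.all_simple_edge_paths(g, s, e), limit))


def find_events(
    sg: SpliceGraph | nx.MultiDiGraph,
    max_variants: int = 20,
    gene_id: str | None = None,
) -> list[SpliceEvent]:
    """Enumerate splice events of a gene graph.

    Every ordered node pair (s, e) with at least two s->e paths and no
    intermediate node common to all of them defines an event; its
    variants are all s->e paths.  Events with more than ``max_variants``
    paths are skipped with a logged warning.  Nested events are attached
    to the enclosing variants and also reported standalone.
    """
    if isinstance(sg, SpliceGraph):
        g = sg.graph
        gene_id = gene_id or sg.gene_id
    else:
        g = sg
        gene_id = gene_id or "G"
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("event identification requires a DAG")
    order = list(nx.topological_sort(g))
    index = {n: i for i, n in enumerate(order)}
    descendants = {n: nx.descendants(g, n) for n in order}

    events: list[SpliceEvent] = []
    for i, s in enumerate(order):
        for e in order[i + 1 :]:
            if e not in descendants[s]:
                continue
            paths = _edge_paths(g, s, e, max_variants + 1)
            if len(paths) < 2:
                continue
            if len(paths) > max_variants:
                logger.warning(
                    "event (%s, %s) in %s has more than %d variants; skipped",
                    s,
                    e,
                    gene_id,
                    max_variants,
                )
                continue
            node_paths = [tuple([s] + [v for _, v, _ in p]) for p in paths]
            common = set(node_paths[0][1:-1])
            for np_ in node_paths[1:]:
                common &= set(np_[1:-1])
            if common:
                continue
            # deterministic variant order by topological position
            keyed = sorted(
                zip(paths, node_paths),
                key=lambda pn: (
                    tuple(index[n] for n in pn[1]),
                    tuple(k for _, _, k in pn[0]),
                ),
            )
            event_id = f"{gene_id}:E{len(events) + 1}"
            variants = []
            for vi, (p, np_) in enumerate(keyed):
                edges = tuple(
                    (
                        u,
                        v,
                        g.edges[u, v, k].get("kind", ""),
                        g.edges[u, v, k].get("feature"),
                    )
                    for u, v, k in p
                )
                variants.append(
                    SpliceVariant(
                        id=f"{event_id}:V{vi + 1}",
                        nodes=np_,
                        edges=edges,
                        edge_keys=tuple(k for _, _, k in p),
                    )
                )
            ev = SpliceEvent(
                id=event_id, gene_id=gene_id, start=s, end=e, variants=variants
            )
            ev.left_closed, ev.right_closed = classify_closure(ev, g)
            events.append(ev)

    for ev in events:
        ev.event_type = classify_event_type(ev, g)

    # nesting: an event is nested in a variant if both its endpoints lie
    # strictly inside that variant's path
    for parent in events:
        for variant in parent.variants:
            inner = variant.internal_nodes
            for child in events:
                if child is parent:
                    continue
                if child.start in inner and child.end in inner:
                    variant.nested_events.append(child.id)
                    if parent.id not in child.parents:
                        child.parents.append(parent.id)
    return events


def classify_closure(
    event: SpliceEvent, sg: SpliceGraph | nx.MultiDiGraph
) -> tuple[bool, bool]:
    """Closure flags of an event.

    Left-closed: every edge entering an internal event node originates
    inside the event or at its start.  Right-closed: every edge leaving
    an internal node stays inside the event or reaches its end.
    """
    g = sg.graph if isinstance(sg, SpliceGraph) else sg
    inside = event.internal_nodes
    allowed_in = inside | {event.start}
    allowed_out = inside | {event.end}
    left_closed = all(
        u in allowed_in for n in inside for u, _ in g.in_edges(n)
    )
    right_closed = all(
        v in allowed_out for n in inside for _, v in g.out_edges(n)
    )
    return left_closed, right_closed


def _pair_type(v1: SpliceVariant, v2: SpliceVariant, event: SpliceEvent) -> str:
    """Pattern-match a pair of variants to a basic event type."""
    if event.start == SOURCE and event.end == SINK:
        return COMPLEX
    if v1.internal_nodes & v2.internal_nodes:
        # partially shared paths are never a basic binary pattern
        return COMPLEX
    if event.start == SOURCE:
        return ALT_FIRST
    if event.end == SINK:
        return ALT_LAST
    k1, k2 = v1.edge_kinds, v2.edge_kinds
    # orient so that the single-junction variant (if any) comes first
    if k2 == (JUNCTION,):
        v1, v2 = v2, v1
        k1, k2 = k2, k1
    if k1 == (JUNCTION,):
        if all(k == EXONIC for k in k2):
            return RETAINED_INTRON
        if k2[0] == JUNCTION and k2[-1] == JUNCTION and len(k2) >= 3:
            return SKIPPED_EXON
        if k2[-1] == JUNCTION and all(k == EXONIC for k in k2[:-1]):
            return ALT_5SS
        if k2[0] == JUNCTION and all(k == EXONIC for k in k2[1:]):
            return ALT_3SS
        return COMPLEX
    # two spliced-in exon paths with disjoint interiors
    if (
        k1[0] == JUNCTION
        and k1[-1] == JUNCTION
        and k2[0] == JUNCTION
        and k2[-1] == JUNCTION
        and len(k1) >= 3
        and len(k2) >= 3
        and not (v1.internal_nodes & v2.internal_nodes)
    ):
        return MXE
    return COMPLEX


def classify_event_type(
    event: SpliceEvent, sg: SpliceGraph | nx.MultiDiGraph | None = None
) -> str:
    """Label an event by pattern-matching its variants.

    Binary events map to the standard taxonomy (skipped exon, alternative
    5'/3' splice site, alternative first/last exon, retained intron,
    mutually exclusive exons); events with more than two variants get the
    common pairwise label if one exists, otherwise ``complex``.
    """
    labels = {
        _pair_type(v1, v2, event)
        for v1, v2 in itertools.combinations(event.variants, 2)
    }
    if len(labels) == 1:
        return labels.pop()
    return COMPLEX
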