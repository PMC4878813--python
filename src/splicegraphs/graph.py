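"""Assembly of features into per-gene splice graphs.

The splice graph is a directed acyclic multigraph.  Nodes are boundary
coordinates: node ``p`` denotes the boundary immediately before base
``p``, so an exon bin [s, e] connects nodes ``s`` and ``e + 1`` and a
junction with intron [gs, ge] connects donor node ``gs`` and acceptor
node ``ge + 1``.  Adjacent bins and junctions landing on an exon
boundary therefore share nodes automatically.  Edges are directed 5' to
3' in transcript orientation, i.e. genomically right-to-left on the
minus strand.  Parallel edges (a retained intron next to its spliced
junction) are first-class, hence the multigraph.

Genes are weakly connected components; each gene graph is augmented with
a unique ``source`` node connected to all transcript starts and a unique
``sink`` node reachable from all transcript ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .core import (
    Exon,
    ExonBin,
    Features,
    GenomicRange,
    SpliceJunction,
    disjoin_exons,
    reduce_ranges,
)

logger = logging.getLogger(__name__)

SOURCE = "source"
SINK = "sink"

EXONIC = "exonic"
JUNCTION = "junction"
AUGMENT = "augment"


@dataclass
class SpliceGraph:
    """Per-gene splice graph: a DAG of boundary nodes with exonic and
    junction edges carrying their features."""

    gene_id: str
    seqname: str
    strand: str
    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    @property
    def augmented(self) -> bool:
        return SOURCE in self.graph

    def node_positions(self) -> list[int]:
        return sorted(n for n in self.graph if isinstance(n, int))

    def span(self) -> GenomicRange:
        pos = self.node_positions()
        return GenomicRange(self.seqname, pos[0], pos[-1] - 1, self.strand)

    def features(self) -> Features:
        """Decompose the graph back into its features (bins as exons)."""
        junctions, exons = [], []
        for u, v, data in self.graph.edges(data=True):
            if data["kind"] == JUNCTION:
                junctions.append(data["feature"])
            elif data["kind"] == EXONIC:
                exons.append(data["feature"])
        return Features(junctions=junctions, exons=exons)

    def exon_union(self) -> list[GenomicRange]:
        return reduce_ranges(
            [
                data["feature"].range
                for _, _, data in self.graph.edges(data=True)
                if data["kind"] == EXONIC
            ]
        )


def _oriented(strand: str, left: int, right: int) -> tuple[int, int]:
    """Direct an edge 5'->3' in transcript orientation."""
    return (left, right) if strand == "+" else (right, left)


def build_splice_graph(features: Features) -> list[SpliceGraph]:
    """Assemble merged features into one splice graph per gene.

    Exons are disjoined into bins (split additionally at junction donor
    and acceptor boundaries); nodes are created at bin boundaries and
    splice sites; exonic edges connect the boundary nodes of each bin and
    junction edges connect donor to acceptor nodes.  Genes are the weakly
    connected components of the resulting graph, labelled in genomic
    order.  Acyclicity is verified for every gene.
    """
    by_group: dict[tuple[str, str], tuple[list[SpliceJunction], list[Exon]]] = {}
    for j in features.junctions:
        r = j.range
        by_group.setdefault((r.seqname, r.strand), ([], []))[0].append(j)
    for e in features.exons:
        r = e.range
        by_group.setdefault((r.seqname, r.strand), ([], []))[1].append(e)

    graphs: list[SpliceGraph] = []
    for (seqname, strand), (junctions, exons) in sorted(by_group.items()):
        g = nx.MultiDiGraph()
        breaks: set[int] = set()
        for j in junctions:
            breaks.add(j.range.start)  # donor boundary (before first intronic base)
            breaks.add(j.range.end + 1)  # acceptor boundary
        for b in disjoin_exons(exons, extra_breaks=breaks) if exons else []:
            u, v = _oriented(strand, b.range.start, b.range.end + 1)
            g.add_edge(u, v, kind=EXONIC, feature=b)
        for j in junctions:
            u, v = _oriented(strand, j.range.start, j.range.end + 1)
            g.add_edge(u, v, kind=JUNCTION, feature=j)
        for comp_idx, comp in enumerate(
            sorted(nx.weakly_connected_components(g), key=min)
        ):
            sub = g.subgraph(comp).copy()
            gene_id = f"{seqname}{strand}:G{comp_idx + 1}"
            if not nx.is_directed_acyclic_graph(sub):
                raise ValueError(f"splice graph for {gene_id} contains a cycle")
            _annotate_nodes(sub)
            graphs.append(
                SpliceGraph(gene_id=gene_id, seqname=seqname, strand=strand, graph=sub)
            )
    return graphs


def _annotate_nodes(g: nx.MultiDiGraph) -> None:
    for n in g.nodes:
        kinds = set()
        if any(d["kind"] == JUNCTION for _, _, d in g.out_edges(n, data=True)):
            kinds.add("donor")
        if any(d["kind"] == JUNCTION for _, _, d in g.in_edges(n, data=True)):
            kinds.add("acceptor")
        if g.in_degree(n) == 0:
            kinds.add("transcript_start")
        if g.out_degree(n) == 0:
            kinds.add("transcript_end")
        g.nodes[n]["kinds"] = frozenset(kinds)


def add_source_sink(sg: SpliceGraph) -> SpliceGraph:
    """Augment a gene graph with unique source and sink nodes.

    The source connects to every transcript start (in-degree 0) node and
    every transcript end (out-degree 0) node connects to the sink.
    Idempotent: an already augmented graph is returned unchanged.
    """
    if sg.augmented:
        return sg
    g = sg.graph
    starts = [n for n in g.nodes if g.in_degree(n) == 0]
    ends = [n for n in g.nodes if g.out_degree(n) == 0]
    g.add_node(SOURCE, kinds=frozenset({"source"}))
    g.add_node(SINK, kinds=frozenset({"sink"}))
    for n in starts:
        g.add_edge(SOURCE, n, kind=AUGMENT, feature=None)
    for n in ends:
        g.add_edge(n, SINK, kind=AUGMENT, feature=None)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError(f"augmented graph for {sg.gene_id} contains a cycle")
    return sg
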