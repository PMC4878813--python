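"""Serialization: GFF3 and BED feature writers, feature reader, tables.

Internally all coordinates are 1-based closed; the BED writer converts to
0-based half-open on output.  The GFF3 dialect written here is also the
interchange format between CLI subcommands: junctions as
``splice_junction`` records (spanning the intron) and exons as ``exon``
records with a ``kind`` attribute.
"""

from __future__ import annotations

import urllib.parse
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .core import Exon, ExonBin, Features, GenomicRange, SpliceJunction
from .events import SpliceEvent
from .graph import SpliceGraph

_GFF_SOURCE = "splicegraphs"


def _attr_escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :/,_|+.-")


def _gff3_line(
    seqname: str,
    ftype: str,
    start: int,
    end: int,
    strand: str,
    attributes: dict[str, object],
    score: object = ".",
) -> str:
    attrs = ";".join(
        f"{k}={_attr_escape(v)}" for k, v in attributes.items() if v is not None
    )
    strand = strand if strand in "+-" else "."
    return f"{seqname}\t{_GFF_SOURCE}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}"


def write_features_gff3(features: Features, path: str) -> None:
    """Write a feature set as GFF3 (the CLI interchange format)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, j in enumerate(features.junctions):
            r = j.range
            fh.write(
                _gff3_line(
                    r.seqname,
                    "splice_junction",
                    r.start,
                    r.end,
                    r.strand,
                    {
                        "ID": f"J{i + 1}",
                        "count": j.count,
                        "fpkm": None if j.fpkm is None else f"{j.fpkm:.6g}",
                        "samples": ",".join(j.samples) or None,
                    },
                )
                + "\n"
            )
        for i, e in enumerate(features.exons):
            r = e.range
            fh.write(
                _gff3_line(
                    r.seqname,
                    "exon",
                    r.start,
                    r.end,
                    r.strand,
                    {
                        "ID": f"E{i + 1}",
                        "kind": e.kind,
                        "spliced_left": int(e.spliced_left),
                        "spliced_right": int(e.spliced_right),
                        "samples": ",".join(e.samples) or None,
                        "annotated": (
                            int(e.annotated) if hasattr(e, "annotated") else None
                        ),
                    },
                )
                + "\n"
            )


def read_features_gff3(path: str) -> Features:
    """Read a feature set previously written by :func:`write_features_gff3`."""
    junctions: list[SpliceJunction] = []
    exons: list[Exon] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqname, _, ftype, start, end, _, strand, _, attr_str = fields
            attrs = {
                k: urllib.parse.unquote(v)
                for k, v in (
                    kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv
                )
            }
            strand = strand if strand in "+-" else "*"
            grange = GenomicRange(seqname, int(start), int(end), strand)
            samples = (
                tuple(attrs["samples"].split(",")) if attrs.get("samples") else ()
            )
            if ftype == "splice_junction":
                j = SpliceJunction(
                    grange,
                    count=int(attrs.get("count", 0)),
                    fpkm=float(attrs["fpkm"]) if "fpkm" in attrs else None,
                    samples=samples,
                )
                junctions.append(j)
            elif ftype == "exon":
                exons.append(
                    Exon(
                        grange,
                        kind=attrs.get("kind", "internal"),
                        spliced_left=bool(int(attrs.get("spliced_left", 1))),
                        spliced_right=bool(int(attrs.get("spliced_right", 1))),
                        samples=samples,
                    )
                )
    return Features(junctions=junctions, exons=exons)


def write_bed(
    features: Iterable[Exon | ExonBin | SpliceJunction], path: str
) -> None:
    """Write features as BED6 (0-based half-open, converted on output)."""
    with open(path, "w") as fh:
        for i, f in enumerate(f for f in features):
            r = f.range
            name = f"F{i + 1}"
            score = getattr(f, "count", 0)
            strand = r.strand if r.strand in "+-" else "."
            fh.write(
                f"{r.seqname}\t{r.start - 1}\t{r.end}\t{name}\t{score}\t{strand}\n"
            )


def write_junction_table(
    junctions: Sequence[SpliceJunction], path: str
) -> None:
    rows = [
        {
            "seqname": j.range.seqname,
            "start": j.range.start,
            "end": j.range.end,
            "strand": j.range.strand,
            "count": j.count,
            "fpkm": j.fpkm,
        }
        for j in junctions
    ]
    pd.DataFrame(
        rows, columns=["seqname", "start", "end", "strand", "count", "fpkm"]
    ).to_csv(path, sep="\t", index=False)


def event_table(
    pairs: Iterable[tuple[SpliceGraph, Sequence[SpliceEvent]]]
) -> pd.DataFrame:
    """Tabulate events: one row per event with coordinates and flags."""
    rows = []
    for sg, events in pairs:
        for ev in events:
            coords = [n for n in [ev.start, ev.end] if isinstance(n, int)]
            coords += [n for n in ev.internal_nodes if isinstance(n, int)]
            lo, hi = (min(coords), max(coords) - 1) if coords else (0, 0)
            rows.append(
                {
                    "event_id": ev.id,
                    "gene_id": ev.gene_id,
                    "seqname": sg.seqname,
                    "start": lo,
                    "end": hi,
                    "strand": sg.strand,
                    "type": ev.event_type,
                    "n_variants": len(ev.variants),
                    "left_closed": ev.left_closed,
                    "right_closed": ev.right_closed,
                    "parent_event": ",".join(ev.parents),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "seqname",
            "start",
            "end",
            "strand",
            "type",
            "n_variants",
            "left_closed",
            "right_closed",
            "parent_event",
        ],
    )


def write_edge_list(graphs: Sequence[SpliceGraph], path: str) -> None:
    """Tab-separated edge list (gene_id, from, to, kind, feature coords)."""
    rows = []
    for sg in graphs:
        for u, v, data in sg.graph.edges(data=True):
            feature = data.get("feature")
            if feature is not None:
                r = feature.range
                fid = f"{r.seqname}:{r.start}-{r.end}:{r.strand}"
            else:
                fid = "."
            rows.append(
                {
                    "gene_id": sg.gene_id,
                    "from_node": u,
                    "to_node": v,
                    "edge_kind": data.get("kind", ""),
                    "feature_id": fid,
                }
            )
    pd.DataFrame(
        rows, columns=["gene_id", "from_node", "to_node", "edge_kind", "feature_id"]
    ).to_csv(path, sep="\t", index=False)


def to_dot(sg: SpliceGraph) -> str:
    """DOT serialization of one gene graph for visualization."""
    lines = [f'digraph "{sg.gene_id}" {{', "  rankdir=LR;"]
    for n in sg.graph.nodes:
        kinds = ",".join(sorted(sg.graph.nodes[n].get("kinds", ())))
        lines.append(f'  "{n}" [label="{n}\\n{kinds}"];')
    for u, v, data in sg.graph.edges(data=True):
        style = "solid" if data.get("kind") == "exonic" else "dashed"
        lines.append(f'  "{u}" -> "{v}" [style={style}, label="{data.get("kind", "")}"];')
    lines.append("}")
    return "\n".join(lines)
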