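"""Transcript annotation import and comparison with predicted features.

Transcript models are read from GTF/GFF3, decomposed into the same
feature vocabulary used for prediction (junctions, internal exons,
terminal exons), and used either to build annotation-based splice graphs
or to annotate predicted features.  The matching criteria mirror common
practice: junctions and internal exons must be coordinate-identical to an
annotated counterpart, while terminal exons only need to share their
splice donor/acceptor with an annotated terminal or internal exon
(transcript starts and ends are too variable in coverage to call
precisely from RNA-seq).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .core import (
    FIVE_PRIME_TERMINAL,
    INTERNAL,
    THREE_PRIME_TERMINAL,
    Exon,
    Features,
    GenomicRange,
    SpliceJunction,
    reduce_ranges,
)

logger = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    """An annotated transcript: ordered exons on one strand.

    Exons are stored 5' to 3' in transcript orientation, i.e. in
    descending genomic order on the minus strand.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicRange]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        genomic = sorted(self.exons, key=lambda r: r.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def seqname(self) -> str:
        return self.exons[0].seqname

    def introns(self) -> list[GenomicRange]:
        genomic = sorted(self.exons, key=lambda r: r.start)
        return [
            GenomicRange(self.seqname, a.end + 1, b.start - 1, self.strand)
            for a, b in zip(genomic, genomic[1:])
        ]


def _transcript_key(feature: gffutils.Feature) -> str | None:
    for attr in ("transcript_id", "Parent"):
        if attr in feature.attributes:
            return feature.attributes[attr][0]
    return None


def _gene_key(feature: gffutils.Feature) -> str:
    for attr in ("gene_id", "gene"):
        if attr in feature.attributes:
            return feature.attributes[attr][0]
    return ""


def load_transcripts(path: str) -> list[TranscriptModel]:
    """Load transcript models from a GTF or GFF3 file.

    Builds one model per transcript from its exon records; exon order is
    normalized by strand.  Transcripts without exons are skipped with a
    warning; a transcript id used on multiple seqnames or strands is an
    error.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[gffutils.Feature]] = {}
    gene_by_tx: dict[str, str] = {}
    n_records = 0
    for f in db.all_features():
        n_records += 1
        if f.featuretype != "exon":
            continue
        tx = _transcript_key(f)
        if tx is None:
            raise ValueError(
                f"exon record without transcript attribute at line {f.start}"
            )
        exons_by_tx.setdefault(tx, []).append(f)
        gene_by_tx.setdefault(tx, _gene_key(f))
    if n_records and not exons_by_tx:
        logger.warning("no exon records found in %s", path)
    models = []
    for tx, exons in exons_by_tx.items():
        seqnames = {e.seqid for e in exons}
        strands = {e.strand for e in exons}
        if len(seqnames) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript id {tx!r} spans multiple seqnames or strands"
            )
        strand = strands.pop()
        if strand not in ("+", "-"):
            logger.warning("transcript %s lacks a strand; skipped", tx)
            continue
        models.append(
            TranscriptModel(
                transcript_id=tx,
                gene_id=gene_by_tx[tx],
                strand=strand,
                exons=[
                    GenomicRange(e.seqid, e.start, e.end, strand) for e in exons
                ],
            )
        )
    models.sort(key=lambda m: (m.seqname, m.exons[0].start, m.transcript_id))
    return models


def transcripts_to_features(models: Sequence[TranscriptModel]) -> Features:
    """Decompose transcript models into junctions and exons.

    Junctions are all introns; non-first/non-last exons become internal
    exons; first and last exons become 5'/3'-terminal features.
    Single-exon transcripts contribute nothing (no spliced boundary).
    Duplicates across transcripts are collapsed.
    """
    junctions: dict[tuple, SpliceJunction] = {}
    exons: dict[tuple, Exon] = {}
    for m in models:
        if len(m.exons) < 2:
            continue
        for intron in m.introns():
            j = SpliceJunction(intron)
            junctions.setdefault(j.key(), j)
        for i, exon_range in enumerate(m.exons):  # transcript order
            if 0 < i < len(m.exons) - 1:
                e = Exon(exon_range, INTERNAL)
            else:
                five_prime = i == 0
                kind = FIVE_PRIME_TERMINAL if five_prime else THREE_PRIME_TERMINAL
                # the spliced boundary faces the gene body
                spliced_left = (m.strand == "+") != five_prime
                e = Exon(
                    exon_range,
                    kind,
                    spliced_left=spliced_left,
                    spliced_right=not spliced_left,
                )
            exons.setdefault(e.key(), e)
    # an exon that is internal in one transcript wins over a terminal copy
    internal_ranges = {
        k[:4] for k, e in exons.items() if e.kind == INTERNAL
    }
    kept = [
        e
        for k, e in exons.items()
        if e.kind == INTERNAL or k[:4] not in internal_ranges
    ]
    return Features(
        junctions=sorted(junctions.values(), key=lambda j: j.key()),
        exons=sorted(kept, key=lambda e: e.key()),
    )


def annotate_features(predicted: Features, annotated: Features) -> dict[str, bool]:
    """Flag predicted features that match the annotation.

    Returns a mapping from feature key (as produced by ``.key()``) to a
    boolean flag; the flag is also stored on each feature as an
    ``annotated`` attribute.  Junctions and internal exons match iff
    coordinate-identical (same strand); terminal exons match iff their
    spliced boundary coincides with an annotated donor/acceptor of a
    terminal or internal exon.
    """
    known_junctions = {j.key() for j in annotated.junctions}
    known_internal = {e.key() for e in annotated.internal_exons}
    known_boundaries: set[tuple[str, str, int, bool]] = set()
    for e in annotated.exons:
        r = e.range
        if e.kind == INTERNAL or e.spliced_left:
            known_boundaries.add((r.seqname, r.strand, r.start, True))
        if e.kind == INTERNAL or e.spliced_right:
            known_boundaries.add((r.seqname, r.strand, r.end, False))
    flags: dict[tuple, bool] = {}
    for j in predicted.junctions:
        flag = j.key() in known_junctions
        j.annotated = flag
        flags[j.key()] = flag
    for e in predicted.exons:
        if e.kind == INTERNAL:
            flag = e.key() in known_internal
        else:
            r = e.range
            flag = (
                r.seqname,
                r.strand,
                e.spliced_boundary,
                e.spliced_left,
            ) in known_boundaries
        e.annotated = flag
        flags[e.key()] = flag
    return flags


def annotation_report(predicted: Features, annotated: Features) -> pd.DataFrame:
    """Tabulate predicted vs annotated feature counts by feature type."""
    annotate_features(predicted, annotated)
    rows = []
    groups = [
        ("splice_junction", predicted.junctions),
        ("internal_exon", predicted.internal_exons),
        (
            "five_prime_exon",
            [e for e in predicted.exons if e.kind == FIVE_PRIME_TERMINAL],
        ),
        (
            "three_prime_exon",
            [e for e in predicted.exons if e.kind == THREE_PRIME_TERMINAL],
        ),
    ]
    for name, feats in groups:
        n = len(feats)
        k = sum(1 for f in feats if f.annotated)
        rows.append(
            {
                "feature_type": name,
                "predicted": n,
                "annotated": k,
                "pct_annotated": round(100 * k / n, 1) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def candidate_novel_exons(
    predicted: Features, annotated: Features, models: Sequence[TranscriptModel]
) -> list[Exon]:
    """Predicted internal exons of known genes unrelated to annotated exons.

    An internal exon qualifies if it (1) overlaps an annotated gene locus,
    (2) is spliced to annotated splice sites on both flanks (its boundaries
    coincide with boundaries of retained annotated junctions' exons), and
    (3) overlaps no annotated exon.
    """
    loci = reduce_ranges(
        [r for m in models for r in m.exons]
        + [r for m in models for r in m.introns()]
    )
    annotated_exon_ranges = [e.range for e in annotated.exons]
    # splice sites adjacent to annotated introns
    donor_acceptor: set[tuple[str, str, int]] = set()
    for j in annotated.junctions:
        r = j.range
        donor_acceptor.add((r.seqname, r.strand, r.start - 1))
        donor_acceptor.add((r.seqname, r.strand, r.end + 1))
    pred_junction_flanks: dict[tuple[str, str, int], set[int]] = {}
    for j in predicted.junctions:
        r = j.range
        pred_junction_flanks.setdefault(
            (r.seqname, r.strand, r.end + 1), set()
        ).add(r.start - 1)
        pred_junction_flanks.setdefault(
            (r.seqname, r.strand, r.start - 1), set()
        ).add(r.end + 1)
    out = []
    for e in predicted.internal_exons:
        r = e.range
        if not any(r.overlaps(locus, ignore_strand=True) for locus in loci):
            continue
        if any(r.overlaps(a) for a in annotated_exon_ranges):
            continue
        # flanking junctions must land on annotated splice sites
        partners = pred_junction_flanks.get(
            (r.seqname, r.strand, r.start), set()
        ) | pred_junction_flanks.get((r.seqname, r.strand, r.end), set())
        if not partners or not all(
            (r.seqname, r.strand, p) in donor_acceptor for p in partners
        ):
            continue
        out.append(e)
    return out
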