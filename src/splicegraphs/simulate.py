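"""Synthetic gene models and RNA-seq alignments for testing.

The simulator emulates the boundary-count statistics a splice-event
quantifier sees: paired 76 nt reads from a small set of isoforms with a
controlled true PSI, uniform fragment starts along the transcript, a
truncated discrete normal fragment-length distribution, spliced
alignments with N CIGAR operations and transcriptional-strand tags, and
optionally unspliced "pre-mRNA" noise fragments placed along the gene
body.  It does not model sequencing errors, positional bias or
expression variation across genes.

Two synthetic contigs (chrA, chrB; 100 kb each) back all fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import TranscriptModel
from .core import GenomicRange

logger = logging.getLogger(__name__)

CONTIGS = {"chrA": 100_000, "chrB": 100_000}

PATTERNS = (
    "skipped_exon",
    "alt_5ss",
    "alt_3ss",
    "alt_first_exon",
    "alt_last_exon",
    "mutually_exclusive",
    "retained_intron",
)


def make_gene_models(
    pattern: str,
    seqname: str = "chrA",
    strand: str = "+",
    start: int = 10_001,
    flank_len: int = 400,
    alt_len: int = 150,
    intron_len: int = 300,
    alt_shift: int = 60,
    gene_id: str = "G1",
) -> list[TranscriptModel]:
    """A minimal isoform pair realizing one splice-event pattern.

    Flanking/terminal exons default to 400 nt so that every alternative
    boundary lies further from the transcript ends than a fragment
    length; otherwise end effects truncate the window of fragment
    placements whose reads cross a boundary, differently per isoform,
    and bias boundary counts.  Patterns are named for the event they
    produce on the plus strand; on the minus strand the construction is
    mirrored (an ``alt_5ss`` gene model realizes an alternative 3'
    splice site, and first/last exon patterns swap).
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    s, fl, al, il = start, flank_len, alt_len, intron_len

    def rng(a: int, b: int) -> GenomicRange:
        return GenomicRange(seqname, a, b, strand)

    def chain(*lengths: int) -> list[GenomicRange]:
        """Exons of the given lengths separated by standard introns."""
        out, a = [], s
        for ln in lengths:
            out.append(rng(a, a + ln - 1))
            a += ln + il
        return out

    if pattern == "skipped_exon":
        e1, e2, e3 = chain(fl, al, fl)
        iso = [[e1, e2, e3], [e1, e3]]
    elif pattern == "alt_5ss":
        e1, e2 = chain(fl, fl)
        iso = [[e1, e2], [rng(e1.start, e1.end + alt_shift), e2]]
    elif pattern == "alt_3ss":
        e1, e2 = chain(fl, fl)
        iso = [[e1, e2], [e1, rng(e2.start + alt_shift, e2.end)]]
    elif pattern == "alt_first_exon":
        f1 = rng(s, s + fl - 1)
        f2 = rng(f1.end + il // 2 + 1, f1.end + il // 2 + fl)
        common = rng(f2.end + il + 1, f2.end + il + fl)
        iso = [[f1, common], [f2, common]]
    elif pattern == "alt_last_exon":
        e0, l1, l2 = chain(fl, fl, fl)
        iso = [[e0, l1], [e0, l2]]
    elif pattern == "mutually_exclusive":
        e1, m1, m2, e4 = chain(fl, al, al, fl)
        iso = [[e1, m1, e4], [e1, m2, e4]]
    else:  # retained_intron: second isoform keeps the intron between
        # exons 2 and 3 (a merged terminal exon, so both isoforms remain
        # multi-exonic)
        e1, e2, e3 = chain(fl, al, fl)
        iso = [[e1, e2, e3], [e1, rng(e2.start, e3.end)]]
    return [
        TranscriptModel(
            transcript_id=f"{gene_id}.T{i + 1}",
            gene_id=gene_id,
            strand=strand,
            exons=exons,
        )
        for i, exons in enumerate(iso)
    ]


@dataclass
class SimSpec:
    """Study conditions for one simulated gene.

    ``psi`` gives the true relative usage per isoform as a fraction of
    transcript *molecules* (must sum to 1) -- the quantity a boundary-read
    estimator measures.  Fragment counts per isoform are therefore
    length-weighted: a longer isoform yields proportionally more
    fragments per molecule under uniform fragmentation.  ``depth`` is the
    number of fragments; read/fragment lengths default to 76 nt paired
    reads with a 200 +/- 20 nt fragment span.
    """

    models: list[TranscriptModel]
    psi: tuple[float, ...]
    depth: int = 2000
    read_length: int = 76
    frag_mean: float = 200.0
    frag_sd: float = 20.0
    intronic_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.psi) != len(self.models):
            raise ValueError("one psi value per isoform is required")
        if abs(sum(self.psi) - 1.0) > 1e-9:
            raise ValueError("psi values must sum to 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def _transcript_positions(model: TranscriptModel) -> np.ndarray:
    """Genomic position of each transcript base, 5' to 3'."""
    chunks = []
    for e in model.exons:  # already in transcript order
        block = np.arange(e.start, e.end + 1)
        if model.strand == "-":
            block = block[::-1]
        chunks.append(block)
    return np.concatenate(chunks)


def _runs(positions: np.ndarray) -> list[tuple[int, int]]:
    """Sorted genomic positions -> maximal consecutive runs (blocks)."""
    pos = np.sort(positions)
    breaks = np.where(np.diff(pos) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pos) - 1]])
    return [(int(pos[a]), int(pos[b])) for a, b in zip(starts, ends)]


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    seqname: str,
    blocks: list[tuple[int, int]],
    read_length: int,
    flag: int,
    strand_tag: str | None,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.flag = flag
    seg.reference_id = header.get_tid(seqname)
    seg.reference_start = blocks[0][0] - 1
    cigar = []
    for i, (a, b) in enumerate(blocks):
        if i:
            cigar.append((3, a - blocks[i - 1][1] - 1))  # N
        cigar.append((0, b - a + 1))  # M
    seg.cigartuples = cigar
    seg.query_sequence = "A" * read_length
    seg.query_qualities = pysam.qualitystring_to_array("I" * read_length)
    seg.mapping_quality = 60
    if strand_tag is not None and len(blocks) > 1:
        seg.set_tag("XS", strand_tag)
    return seg


def simulate_fragments(spec: SimSpec, sam_path: str) -> pd.DataFrame:
    """Simulate paired-end fragments from a gene and write a SAM file.

    Per fragment, the isoform is drawn from the true psi, the fragment
    length from a truncated normal, and the start uniformly along the
    isoform.  Mates are written as split alignments with N CIGAR
    operations at introns and an XS strand tag on spliced reads.  At
    ``intronic_noise_rate``, the fragment is instead an unspliced
    pre-mRNA fragment placed uniformly along the gene body (no strand
    tag).  Deterministic given the seed.  Returns the per-fragment truth
    table.
    """
    rng = np.random.default_rng(spec.seed)
    models = spec.models
    seqname = models[0].seqname
    strand = models[0].strand
    positions = [_transcript_positions(m) for m in models]
    gene_lo = min(e.start for m in models for e in m.exons)
    gene_hi = max(e.end for m in models for e in m.exons)
    r = spec.read_length

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": sn, "LN": ln} for sn, ln in CONTIGS.items()],
        }
    )
    segments: list[pysam.AlignedSegment] = []
    truth_rows = []
    n_resampled = 0
    for i in range(spec.depth):
        name = f"frag{i + 1}"
        noise = spec.intronic_noise_rate > 0 and rng.random() < spec.intronic_noise_rate
        flen = max(r, int(round(rng.normal(spec.frag_mean, spec.frag_sd))))
        if noise:
            flen = min(flen, gene_hi - gene_lo + 1)
            g0 = int(rng.integers(gene_lo, gene_hi - flen + 2))
            blocks1 = [(g0, g0 + r - 1)]
            blocks2 = [(g0 + flen - r, g0 + flen - 1)]
            iso_label = "noise"
            tag = None
        else:
            # isoform probability = molar usage x number of fragment
            # placements, so boundary-spanning fragments occur in
            # proportion to molar usage
            placements = np.array(
                [max(len(p) - flen + 1, 1) for p in positions], dtype=float
            )
            weights = np.asarray(spec.psi) * placements
            iso = int(rng.choice(len(models), p=weights / weights.sum()))
            pos = positions[iso]
            length = len(pos)
            if flen > length:
                n_resampled += 1
                flen = min(flen, length)
            t0 = int(rng.integers(0, length - flen + 1))
            read_a = pos[t0 : t0 + r]
            read_b = pos[t0 + flen - r : t0 + flen]
            blocks1, blocks2 = _runs(read_a), _runs(read_b)
            if blocks2[0][0] < blocks1[0][0]:
                blocks1, blocks2 = blocks2, blocks1
            iso_label = models[iso].transcript_id
            tag = strand
        seg1 = _make_segment(header, name, seqname, blocks1, r, 99, tag)
        seg2 = _make_segment(header, name, seqname, blocks2, r, 147, tag)
        for seg, other in ((seg1, seg2), (seg2, seg1)):
            seg.next_reference_id = other.reference_id
            seg.next_reference_start = other.reference_start
        tlen = blocks2[-1][1] - blocks1[0][0] + 1
        seg1.template_length = tlen
        seg2.template_length = -tlen
        segments.extend([seg1, seg2])
        truth_rows.append(
            {"fragment": name, "isoform": iso_label, "length": flen}
        )
    if n_resampled:
        logger.info(
            "clamped %d fragments longer than their isoform", n_resampled
        )
    segments.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for seg in segments:
            out.write(seg)
    return pd.DataFrame(truth_rows, columns=["fragment", "isoform", "length"])


def write_models_gtf(models: Sequence[TranscriptModel], path: str) -> None:
    """Write transcript models as a minimal GTF (exon records only)."""
    with open(path, "w") as fh:
        for m in models:
            for e in sorted(m.exons, key=lambda r: r.start):
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.seqname}\tsim\texon\t{e.start}\t{e.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
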