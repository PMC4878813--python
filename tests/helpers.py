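"""Shared helpers for building fixtures in tests."""

from __future__ import annotations

from splicegraphs import (
    Features,
    FragmentAlignment,
    GenomicRange,
    PredictionParams,
    SimSpec,
    add_source_sink,
    build_splice_graph,
    estimate_sample_info,
    find_events,
    make_gene_models,
    merge_predictions,
    predict_features,
    quantify_events,
    read_fragments,
    simulate_fragments,
    transcripts_to_features,
)


def frag(
    read1,
    read2=None,
    seqname: str = "chr1",
    strand: str = "*",
    name: str = "f",
) -> FragmentAlignment:
    """Build a FragmentAlignment from (start, end) block tuples."""

    def blocks(spec):
        return tuple(GenomicRange(seqname, a, b) for a, b in spec)

    return FragmentAlignment(
        seqname=seqname,
        strand=strand,
        blocks_read1=blocks(read1),
        blocks_read2=blocks(read2) if read2 else (),
        paired=read2 is not None,
        name=name,
    )


def simulate_sam(
    tmp_path,
    pattern: str = "skipped_exon",
    psi=(0.3, 0.7),
    depth: int = 2000,
    seed: int = 0,
    noise: float = 0.0,
    **model_kw,
):
    """Simulate one gene's alignments into tmp_path; returns
    (sam_path, models, truth_table)."""
    models = make_gene_models(pattern, **model_kw)
    spec = SimSpec(
        models=models,
        psi=psi,
        depth=depth,
        intronic_noise_rate=noise,
        seed=seed,
    )
    path = str(tmp_path / f"{pattern}_s{seed}.sam")
    truth = simulate_fragments(spec, path)
    return path, models, truth


def predict_from_sam(sam_path, params: PredictionParams | None = None):
    """Run per-sample prediction; returns (fragments, sample_info, features)."""
    fragments = list(read_fragments(sam_path))
    info = estimate_sample_info(sam_path, name="s1")
    features = predict_features(fragments, info, params or PredictionParams())
    return fragments, info, features


def psi_table(features: Features, fragments, min_total: int = 0):
    """Graph + events + quantification for a single-gene feature set."""
    graphs = [add_source_sink(g) for g in build_splice_graph(features)]
    pairs = [(g, find_events(g)) for g in graphs]
    return quantify_events(pairs, fragments, min_total=min_total), pairs


def predicted_psi(tmp_path, pattern: str, psi, depth: int, seed: int):
    """End-to-end: simulate, predict features, quantify.  Returns the
    PSI table and the truth table."""
    sam, models, truth = simulate_sam(
        tmp_path, pattern=pattern, psi=psi, depth=depth, seed=seed
    )
    fragments, info, features = predict_from_sam(sam)
    merged = merge_predictions({"s1": features})
    table, pairs = psi_table(merged, fragments)
    return table, truth, pairs
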