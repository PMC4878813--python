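# Methods

This note documents the model and procedure implemented by
`splicegraphs`, its tunable parameters, the numerical and design choices
made where the design was open, what the synthetic-data generator does
and does not emulate, and known limitations.

## Coordinates and feature model

All coordinates are 1-based closed intervals (GFF/SAM convention);
conversion to 0-based half-open BED happens only in the BED writer. A
splice junction is represented by its intron, first to last intronic
base. Fragments (a single-end read, or the two mates of a properly
paired read pair combined) are the unit of observation everywhere; a gap
present in both mates counts once, and overlapping mates contribute at
most one per base to coverage. Strand `*` is permitted on fragments
(unstranded or unspliced reads) but never on predicted features: the
transcriptional strand of a spliced fragment is taken from the spliced
alignment strand tag (`XS`), fragments with conflicting mate tags are
dropped with a logged count, and untagged fragments contribute to
coverage but not to junction evidence.

## Structural compatibility

A fragment is *structurally compatible* with a range being exonic when
none of its intron gaps partially overlaps the range — each gap is
either disjoint from the range or fully contains it — and the strands
are compatible. Fragments merely overhanging a feature's ends remain
compatible; this is what lets flanking junction reads plus internal
coverage support an internal exon. For variant-level compatibility
during quantification, the same idea is applied over the genomic extent
of the event: every fragment gap inside the extent must exactly match a
variant intron and every aligned base inside the extent must fall in the
variant's exon bins. Outside the event the fragment is unconstrained.

## Prediction parameters

| parameter | meaning | default |
|---|---|---|
| *α* | minimum junction FPKM | 2 |
| *β* | minimum internal-exon coverage relative to boundary spliced-read support | 0.2 |
| *γ* | minimum relative coverage for terminal-exon extension | 0.2 |
| max terminal extension | cap on terminal-exon growth | 10 000 nt |
| min_total | minimum `m^D + m^A` for a reported Ψ | 20 |
| max_variants | per-event path cap | 20 |

*α* sets the minimum expression level for junctions of interest and
controls the false discovery rate from spurious split alignments; at the
defaults, a paired-end library with 76 nt reads has junction effective
length `2r − 2 = 150`, so the implied minimum fragment count scales
linearly with library size (19 at 61.3M fragments, 10 at 33.3M). *β*
guards exon prediction against reads derived from introns of unspliced
pre-mRNA, which produce low uniform coverage between genuine splice
sites. *γ* trades terminal-exon length against precision at the ragged
coverage ends of transcripts. The 10 kb extension cap bounds scans
through high-coverage intergenic runs and was chosen well above any
plausible terminal exon. All threshold comparisons are inclusive (≥).

Open choices resolved here:

* **Boundary-support aggregation.** The spliced-read support of an
  internal-exon candidate has two boundaries; the support statistic
  aggregates them with `max` by default (the most conservative choice —
  the threshold is hardest to pass). `min` and `mean` are available via
  `PredictionParams.n_spliced_agg`.
* **Candidate pairing.** Only adjacent acceptor→donor pairs with no
  other retained splice site strictly inside are tested; interior sites
  would split the region into smaller candidates anyway, and this bounds
  the number of candidates linearly.
* **Terminal-exon coverage.** Internal-exon filtering uses range-level
  compatible coverage (a fragment spliced into the candidate region
  contributes nowhere). Terminal extension grows base by base, where
  range-level compatibility degenerates to plain per-base coverage; a
  boundary base is always included, so a boundary with no outward
  coverage yields a single-base terminal exon.
* **Strand independence.** Strands are processed independently
  throughout; a candidate exon is unaffected by opposite-strand
  junctions.

Prediction is strictly per sample (scalable to large cohorts) and
per-sample feature sets are merged afterwards: junctions and internal
exons by exact coordinates, terminal exons sharing a spliced boundary to
the maximal observed extent, with supporting samples recorded.

## Splice graph

Nodes are boundary coordinates (node *p* = boundary before base *p*), so
an exon bin [s, e] spans nodes s → e+1 and a junction [gs, ge] spans
gs → ge+1; adjacent bins and junctions landing on exon boundaries share
nodes with no special casing. Edges are directed in transcript
orientation (genomically right-to-left on the minus strand). The graph
is a multigraph: a retained intron and its spliced junction are parallel
edges between the same nodes. Exons are disjoined into bins with
additional breakpoints at junction boundaries, genes are weakly
connected components, and acyclicity is verified per gene. Bin
boundaries that coincide with no splice site survive as pass-through
nodes; they are harmless for event detection because a pass-through node
lies on every path through its bin. Each gene graph gains a unique
source node feeding all in-degree-0 nodes and a sink fed by all
out-degree-0 nodes, so alternative transcript starts and ends are
ordinary events.

## Events, closure, quantification

An event is an ordered node pair (s, e) with at least two s→e paths and
no intervening node on all of them; its variants are all such paths,
enumerated as edge paths so parallel edges yield distinct variants.
Events with more than `max_variants` paths are skipped with a logged
warning, never silently. All qualifying pairs are reported, including
pairs sharing endpoints; an event whose endpoints both lie strictly
inside another event's variant is recorded as nested in that variant and
also reported standalone.

An event is left-closed when every edge entering its interior originates
at the start (or inside), right-closed symmetrically. Donor-side counts
are valid only for right-closed events and acceptor-side counts only for
left-closed events; source-anchored events have no donor side,
sink-anchored events no acceptor side.

A fragment counts for variant *i* at a boundary when one of its reads
has at least one aligned base on each side of the boundary node (a
configurable minimum anchor, default 1) and the fragment is structurally
compatible with the variant's path. A fragment compatible with several
variants that share their boundary edge counts toward each of them — the
per-side total `m^S = Σ_k x_k^S` is applied as defined — and events
where more than half of the boundary fragments are multiply assigned are
flagged in the output. Local estimates `x_i^S / m^S` from the two sides
combine into the count-weighted mean `(x_i^D + x_i^A)/(m^D + m^A)`;
with one valid side the local estimate is used; with none, or all-zero
totals, Ψ is missing. Estimates with `m^D + m^A` below `min_total`
(default 20) are masked while their counts are retained.

Event types are assigned by pattern-matching variant pairs (skipped
exon, alternative 5′/3′ splice site, alternative first/last exon,
retained intron, mutually exclusive exons); variants that share internal
nodes are never a basic binary pattern, events with more than two
variants take the common pairwise label if one exists, and everything
else is `complex`.

## Annotation comparison

Junctions and internal exons count as annotated only if coordinate- and
strand-identical to an annotated counterpart. Terminal exons match if
their spliced boundary coincides with an annotated donor/acceptor of a
terminal *or* internal exon — transcript starts and ends are too
coverage-dependent to call at base precision. Annotation summaries run
on predicted exons prior to disjoining. Candidate novel exons are
internal exons overlapping an annotated gene locus, spliced to annotated
splice sites, and overlapping no annotated exon.

## Synthetic data

The generator emulates exactly what the quantifier consumes: paired
76 nt reads, uniform fragment starts, a truncated discrete normal
fragment length (200 ± 20 nt), split alignments with `N` CIGAR
operations and strand tags on spliced reads, and optional unspliced
pre-mRNA background fragments placed along the gene body. True Ψ is
specified as *molar* isoform usage — the quantity boundary reads
measure — so per-isoform fragment counts are weighted by the number of
fragment placements; for equal-length isoforms this coincides with the
fragment fraction. Fixture genes use 400 nt flanking exons so that
alternative boundaries lie further from transcript ends than a fragment
length; otherwise placement-window truncation biases boundary counts
between isoforms of different lengths, an effect absent from real
transcripts at realistic lengths. Two synthetic 100 kb contigs back all
fixtures.

Not modelled: sequencing errors, positional/GC bias, indels, multi-gene
expression variation, multi-mappers. Passing recovery tests on this
generator therefore demonstrates correctness of the counting and
estimation machinery under the stated sampling model, not robustness to
alignment artefacts in real libraries. Prediction from coverage also
cannot place an exon across a retained intron without annotation — the
retained-intron fixture is quantified from annotation-derived features.

Recovery tests run at 2000 fragments per gene across ≥ 20 seeds and
check Ψ̂ within three binomial standard errors of the truth; the
brute-force event oracle uses 200+ random DAGs of ≤ 12 nodes. These
sizes keep the whole suite under a minute while leaving the binomial
bounds meaningful.

## Numerical notes and degenerate inputs

* `min_count_for_fpkm` computes `ceil(α λ ρ / 10⁹)` with an explicit
  boundary correction so that counts sitting exactly on the threshold
  pass despite float rounding.
* Non-positive effective lengths (features shorter than the minimal
  compatible placement) leave the raw count intact and report FPKM as
  missing; FPKM with `λ ≤ 0` or `ρ = 0` raises.
* The paired-end fragment length is estimated as the median genomic span
  of unspliced properly paired fragments. Spans crossing introns inflate
  the estimate, but the junction effective length `2r − 2` is invariant
  to *f* (for non-negative inner distance), so junction filtering is
  unaffected.
* Ties in event-variant ordering are broken by topological node index,
  then edge kind, making outputs deterministic for fixed inputs.
* Empty inputs: an empty feature set builds an empty graph list; a
  depth-0 simulation writes a header-only SAM; an alignment file with no
  usable records is an error.

## Limitations

Full-length transcript structure is out of scope by design, as are
probabilistic event models, credible intervals, differential-usage
testing, multi-mapper reweighting and base-quality handling. Terminal
exon extents depend on coverage and should not be interpreted as precise
transcript starts/ends. PSI estimates at events with heavily shared
variant boundaries (flagged in the output) mix evidence between variants
and should be treated with caution.
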