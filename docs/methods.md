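# Methods

## Model and assumptions

The pipeline treats circRNA–disease association prediction as bipartite link
prediction with side information. Its central assumption is guilt by
association on both sides of the bipartite graph: circRNAs that are similar —
in sequence composition, in gene targets, or in their association profiles —
tend to share diseases, and diseases that are similar — semantically in a
curated hierarchy, or in their association profiles — tend to share
circRNAs. Each candidate pair is therefore described by how similar its
disease is to every disease and its circRNA to every circRNA (one row of
each fused similarity matrix, concatenated), and a binary classifier learns
which similarity profiles mark true associations.

Confirmed associations are treated as certain positives; *unknown* cells are
not certain negatives, only unconfirmed, so the negative class is an
equal-size uniform sample of unknown cells. This mislabels any truly
associated unknown cell as negative — standard in this setting, and one
reason ranking (not calibrated probability) is the primary output.

## CGR sequence similarity

The chaos-game map is the contraction `P_i = P_{i-1} + ν (g_i − P_{i-1})`,
`P_0 = (0.5, 0.5)`, corners A=(0,0), C=(0,1), G=(1,1), T=(1,0). For ν = 0.5
each update halves the distance to the corner; the image of the full square
under the update for corner g is exactly g's quadrant, so quadrant membership
of `P_i` identifies the i-th base and the inversion
(`circda.cgr.invert_trajectory`) reads the sequence back position by
position, exactly, for any length. Inversion is refused for ν < 0.5, where
quadrant images overlap and the map is no longer decodable this way.

Grid descriptors partition the square into `2^s × 2^s` half-open cells
(top/right edge closed on the last row/column, so each point maps to exactly
one cell). Per cell: summed x, summed y, and the z-score of the occupancy
count using the *population* standard deviation across cells. `P_0` is
excluded from occupancy — it encodes no base, and counts then total the
sequence length. Degenerate cases are pinned: equal counts in all cells give
all-zero z-scores; an empty sequence gives an all-zero descriptor with a
logged warning. Cells are flattened bottom-row-first, x within a row, with
(X, Y, Z) interleaved per cell; the Pearson correlation of two flattened
descriptors is invariant to any fixed cell order, so the choice is purely a
serialization convention. Coordinate accumulation defaults to sums
(`coord_stat="sum"`); a `"mean"` mode is provided because per-cell averages
are the other natural reading of the construction.

A descriptor with zero variance (possible only for pathological inputs, e.g.
a one-base sequence) correlates 0 with everything except an identical
descriptor, which scores 1, keeping the unit-diagonal invariant.

## Kernels and fusion

Interaction-profile kernel width is `τ = 1 / mean ‖profile‖²`; when every
profile is all-zero the mean vanishes and τ falls back to 1 with a warning
(the kernel then reports all pairs maximally similar, which fusion dilutes).

The semantic contribution `S(r) = ln(1 + n(DAGs ∋ r)/n(disease))` uses the
natural logarithm (the base is unstated by the construction; the ratio
structure of the similarity makes the result only weakly base-dependent, so
the choice is pinned and documented rather than exposed). `n(disease)`
counts diseases that have a hierarchy entry by default
(`semantic_universe="with_dag"`); counting all diseases is available as
`"all"`. Note the contribution of a node is global — it does not depend on
which disease's closure it is viewed from — so the pairwise numerator is
`2 S(r)` per shared node.

The gene-based circRNA similarity `A_cg · K_gene · A_cgᵀ` is an unbounded
weighted co-association count, while every other fused component lies in
[0, 1]; by default it is symmetrically normalized,
`R(i,j)/√(R(i,i) R(j,j))`, with rows of gene-less circRNAs set to 0 (raw
mode is retained via `gene_mode="raw"`). Gene kernel profiles are the
*columns* of `A_cg` — the gene×gene kernel is the only dimensionally
consistent reading.

Fusion rules: disease similarity is the mean of semantic and profile-kernel
values when **both** diseases have a hierarchy entry, the kernel value
otherwise; circRNA similarity is the mean of gene, kernel and sequence
values when the sequence value is **available**, the mean of gene and kernel
otherwise. Availability is tracked with an explicit mask so that a genuine
zero correlation still participates; `seq_fusion_mode="zero_sentinel"`
reproduces the literal "nonzero means available" rule for compatibility.
Negative sequence correlations pass through unclamped.

## Classifier and ranking

Defaults: RBF-kernel SVM, C = 1, γ by the `1/(n_features · var(X))` scale
heuristic, equal class weights, no feature scaling (fused similarity rows
already share a comparable range; a standardization flag exists). Ranking
uses the continuous decision value — the margin — not the hard label; the
positive-call threshold for accuracy-type metrics is 0 on margins (0.5 when
a probability-producing classifier is configured). KNN, random-forest and
decision-tree alternatives are available through the same configuration for
classifier comparison. Ties in ranking break deterministically by (circRNA
index, disease index).

## Evaluation protocol

Balanced, stratified 5-fold cross-validation: per-class fold sizes differ by
at most one, folds are disjoint and cover the pooled sample, splits are
seed-deterministic. Metrics: accuracy, sensitivity, precision,
F1 = 2·Sen·Prec/(Sen + Prec), trapezoidal ROC AUC (equivalently the
probability a positive outranks a negative, ties half-credit — verified in
the tests against an exhaustive pair-counting oracle), and trapezoidal
precision–recall area. Zero-denominator metrics report 0 with an
`undefined` flag rather than raising.

By default the interaction-profile kernels are built from the **full**
association matrix, replicating the common protocol in this literature; that
lets test-fold labels leak into the features and inflates the estimate.
`fold_safe=True` zeroes test-fold positives before building the kernels each
fold (sequence, gene and semantic similarities do not depend on
associations and are computed once). An instrumentation test verifies the
masking. Both modes are exposed so users can report both numbers.

Independent validation scores externally confirmed pairs that are *unknown*
to the training benchmark; since every test pair is a true positive by
construction, accuracy is the fraction called positive. Unmappable entity
names are reported, never dropped silently.

## Synthetic data generator

The generator plants one latent block structure across all four inputs:
associations are Bernoulli(signal) within a block and Bernoulli(noise)
outside; same-block circRNAs draw sequences from a block-specific
first-order Markov chain (dinucleotide bias) and share per-block gene pools;
same-block diseases hang under a shared branch of a rooted hierarchy, with a
configurable fraction of diseases omitted from the hierarchy to exercise the
fusion fallback. A single master seed derives all sub-generator streams.

Defaults — 60 circRNAs × 12 diseases, 3 blocks, signal 0.9, noise 0.02,
30 genes (2 per circRNA), sequence lengths 200–1000 nt, 20% of diseases
without a hierarchy entry — are the package's standing study conditions,
sized so a full cross-validation runs in seconds on one core.

What the generator does **not** emulate: real circRNA biology (backsplice
junctions, isoforms, expression), the long-tailed degree distributions of
curated databases, annotation noise, and name-matching ambiguity. Passing
tests on planted data therefore demonstrate that the pipeline recovers the
structural signal it models, not that real benchmarks will reach the same
numbers; published-benchmark performance additionally depends on the
database snapshots and classifier settings used there.

## Numerical choices and limitations

- Matrices are written with 12 significant digits; round trips are lossless
  beyond the 10-digit contract.
- Symmetry is enforced to 1e−10 on construction of every similarity matrix;
  the gene triple product is explicitly symmetrized against float noise.
- Gaussian kernel diagonals are set to exactly 1.
- Problem sizes in the test suite and the acceptance script (≤ 60×12
  entities, five replicate seeds) keep the full run within seconds while
  leaving the stochastic margins wide; the planted-signal criterion
  (mean AUC > 0.9) passes with ~0.07 of headroom.
- The balanced negative sample means reported precision/accuracy refer to a
  1:1 class mix, not to the ~1:75 prevalence of the full candidate pool;
  ranking metrics (AUC, AUPR) are the ones that transfer.
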