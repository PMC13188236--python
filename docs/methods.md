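# Methods

`mdagraph` predicts miRNA–disease associations (MDAs) by learning joint
embeddings of miRNAs and diseases from three graphs and, optionally, a
histopathology image branch. This note documents the model, the choices
made where the design was genuinely open, the synthetic data the package
is validated on, and the limits of what those validations show.

## Problem setting

The input is a binary association matrix `A ∈ {0,1}^{M×D}` over `M`
miRNAs and `D` diseases, with `A[i,j] = 1` for a curated, experimentally
supported association. The setting is positive–unlabeled: a zero means
*no recorded evidence*, not a confirmed non-association. The task is to
rank unobserved pairs so that true-but-unrecorded associations surface.

## Similarity layer

Four similarity sources are computed, all in `[0, 1]`:

* **Disease semantic similarity** `S_D`. Each disease `d` is represented
  by the sub-DAG of its ontology term and all ancestors. Two per-node
  contribution schemes are averaged:
  * *decay*: the disease's own term contributes 1 and each ancestor `u`
    contributes `max_c λ·φ(c)` over its children inside the sub-DAG
    (`λ = 0.5`), i.e. `λ^depth` along the best descending path;
  * *information content*: each node contributes `−log(f(u)/|V|)`, where
    `f(u)` counts the per-disease DAGs containing `u` and `|V|` is the
    multiset total of nodes over all per-disease DAGs. The IC
    contribution of a node is independent of which disease's DAG it sits
    in; the natural logarithm is used.
  Pair similarity is the shared-ancestor contribution sum normalised by
  the two semantic-value totals, so `S(d,d) = 1`.
* **miRNA functional similarity** `FS`: best-match-average of `S_D` over
  the two miRNAs' disease sets, normalised by `p + q`. Computed from the
  *raw* `S_D`, not the GIP-backfilled matrix, because `FS` precedes
  integration; miRNAs with empty disease sets get similarity 0 with a
  logged warning rather than an error, so sparse data runs end to end.
* **GIP kernels** `K_m`, `K_d`: Gaussian kernels on interaction-profile
  rows/columns with bandwidth `γ′ / mean‖IP‖²` and `γ′ = 1`.
* **Integrated similarities** `IS_M`, `IS_D`: the semantic/functional
  value where positive, the GIP value where it is zero (piecewise
  selection, not a weighted blend).

Anything derived from the association matrix (`FS`, GIP, the bipartite
graph) is recomputed per evaluation fold from training positives only.

## Graphs and encoders

Two KNN graphs (over `IS_M` and `IS_D`, `K = 20`, mutual-or rule, ties
broken by ascending index, self-loops explicit but excluded from a
node's own top-K candidates) and the bipartite association graph. The
association graph is encoded as one homogeneous graph over `M + D`
nodes; association-profile features are linearly projected to the
shared 128-wide latent space, as are the similarity-profile features
(miRNAs: raw `FS` rows; diseases: `IS_D` rows — asymmetric by design,
flagged for users).

Each graph is encoded by a three-layer mean-aggregation GraphSAGE stack
(hidden widths 128, 64, d with `d = 128`): the neighbour mean excludes
the node itself (its own state enters through the concatenation), the
concatenated pair passes through a trainable matrix and an ELU, and a
linear residual projection of the layer input is added to a second ELU
of the update. The two stacked ELUs follow the published update rule as
printed. Dropout sits after each residual sum, training mode only.
Isolated nodes aggregate the zero vector.

## Fusion and prediction

Per entity type, the two view embeddings are fused by a learned
per-node scalar gate (`H = ReLU(W1[X1;X2])`, `α = σ(W2 H)`,
`Z = α⊙X1 + (1−α)⊙X2`); miRNAs and diseases have separate fusion
parameters. A global-context stage then mixes each node's embedding
with the dataset mean through a two-layer scalar gate; this preserves
column means exactly for any gate value. The prediction head
concatenates the miRNA embedding, disease embedding and the disease's
image feature, applies one hidden ReLU layer of width `d` and a single
sigmoid output unit.

## Image branch

Source images per disease class are tiled at 512, 256 and 16 pixels
with 50% overlap (strides 256/128/8; a final window flush with each
border is added so coverage is complete; coordinates are 0-based,
windows half-open). 300 patches per scale per class are sampled without
replacement, seeded. Patches are encoded by a pluggable backbone; the
default offline backbone is a seeded random linear projection of
32×32 block-averaged grayscale pixels to width 512 — deterministic and
dependency-free, with a pretrained CNN as a drop-in through the same
contract. The 512-scale features act as cross-attention queries against
each finer scale (single-head, scaled dot-product); the attention
outputs and the raw 512-scale features are pooled by patch-mean,
averaged across the scale axis, and projected by a trainable linear
layer to the image-feature width. Diseases without imagery share one
trainable null embedding — a zero vector is rejected because it would
silently bias the head.

## Objective and training

The loss is the unweighted sum of (a) mean binary cross-entropy over
scored pairs (training positives plus 1:1 negatives resampled each
epoch from unknown pairs; predictions clipped to `[1e−7, 1−1e−7]`) and
(b) a triplet hinge `max(0, ‖z_m−z_{d+}‖² − ‖z_m−z_{d−}‖² + δ)` with
margin `δ = 1` (the margin is not stated in the source configuration;
1.0 is the conventional default). Triplets are anchored on miRNAs, one
per training positive per epoch, on the post-global-fusion embeddings
(the representations that feed prediction). Negatives are mined
semi-hard within the batch — among non-positive diseases whose squared
distance lies in `(d_pos, d_pos + δ)`, the closest — falling back to a
degree-balanced draw with weights `1/(degree+1)` so zero-degree
diseases remain sampleable.

Optimisation is Adam with weight decay `1e−3`. 10% of training
positives (plus matched 1:1 negatives) are carved out as a frozen
validation set; those edges are also excluded from the graphs so the
monitored metric reflects genuinely unseen edges. Early stopping
restores the best-validation-AUC parameters after `patience` epochs
without improvement. One master seed fans out to all randomness
(fold assignment, initialisation, negative sampling, dropout) through
`SeedSequence` spawn keys.

**Default vs demonstration configuration.** The package defaults follow
the selected full-scale configuration: learning rate `1e−4`, dropout
0.3, weight decay `1e−3`, patience 20, `K = 20`, hidden dims
(128, 64, 128). The scaled-down synthetic studies that the tests and
the acceptance script run use `TrainConfig.scaled_demo`: full-batch
edge losses, learning rate `3e−4`, dropout 0, at most 300 epochs,
patience 40. At a few hundred nodes, dropout 0.3 injects enough
gradient noise that validation AUC never improves within a tractable
epoch budget (~0.6 versus ~0.93 without); weight decay and early
stopping carry the regularisation instead. Smaller datasets favouring
stronger-but-different regularisation is expected; the defaults remain
the full-scale values.

## Evaluation protocols

* **Five-fold CV**: positives are partitioned edge-wise; per fold the
  training table, similarities and graphs are rebuilt from training
  positives only. Test negatives are drawn from pairs unknown in the
  full matrix and frozen per fold and seed; the negative ordering is a
  permutation, so the 1:r evaluation set is a strict prefix-superset of
  the 1:1 set and all compared methods see identical evaluation sets.
* **Cold start**: node-level five-fold partition of one entity type;
  every edge touching a held-out node is removed from training. Test
  negatives are unknown pairs touching held-out nodes, sampled after
  the split.
* **Metrics**: AUC as the tie-averaged rank statistic, AUPRC by
  step-wise PR integration (scikit-learn's implementations; an O(n²)
  pairwise oracle cross-checks AUC in the tests), plus ACC/F1/Recall/
  Precision at a fixed threshold of 0.5.
* **Significance**: two-sided paired t-tests on fold-wise differences
  with Holm–Bonferroni adjustment. All-zero differences give p = 1;
  constant non-zero differences are flagged degenerate rather than
  producing an infinite statistic.
* A leakage audit (empty train/test intersections; zero training degree
  for held-out nodes) runs before each fold and is exercised over
  hundreds of seeded plans in the tests.

## Synthetic data

The generator emulates the three real inputs:

* **Association matrix**: latent factors `U (M×r)`, `V (D×r)` from a
  seeded standard normal; true probability `σ(scale·UVᵀ + bias)` with
  the bias calibrated by bisection to the target density. The default
  logit scale is 3.0, which makes the planted structure strongly
  separable (the Bayes-optimal ranker on the package's own evaluation
  protocol reaches AUC ≈ 0.99; at scale 1 it would be ≈ 0.86, i.e. the
  generator itself, not the method, would bound recovery). *Noise* is
  one-directional masking: each true association is hidden (set to 0)
  with the given probability, and the pre-mask rate is calibrated so
  the observed density hits the target. This mirrors curated databases,
  where recorded positives are reliable and the noise is missing
  associations; symmetric flips would instead make a large fraction of
  observed positives pure noise (at density 0.08 and 2% flips, ~23%)
  and cap every method's AUC near 0.88. Ground-truth probabilities are
  returned alongside the labels so evaluation against true labels
  versus sampled labels can be compared.
* **Ontology**: the term hierarchy is built by Ward clustering of the
  *same* latent disease factors — each disease maps to a leaf term,
  each merge becomes an internal term, the final merge is the single
  root, and ~30% of leaves also attach to their grandparent so the
  result is a DAG (1–2 parents per term). This makes ontology-based
  semantic similarity informative about association structure, as MeSH
  similarity is for real diseases; with a hierarchy drawn independently
  of the factors, the similarity view would be pure noise and the
  multi-view design untestable.
* **Images**: per class, smoothed-noise ("Gaussian blob") textures
  whose blob scale and mean intensity are class-specific, with the
  intensity spacing wide relative to the texture amplitude so patches
  are attributable to their class. The default source size (4864 px)
  gives ≥ 300 candidate windows per class at the coarsest scale, so the
  full 5 × 3 × 300 sampling protocol runs on one image per class.

**What passing on synthetic data does and does not show.** The planted
low-rank world validates the machinery: leakage-safe protocol, learning
dynamics, directional behaviour under imbalance and ablation. It does
not reproduce real degree distributions, ontology topology, literature
biases in curation, or histology appearance, and absolute metric values
on it say nothing about performance on curated databases.

## Numerical choices and degenerate inputs

* KNN ties break by ascending node index; a node never occupies its
  own top-K slot.
* Degenerate denominators (empty disease sets, zero semantic-value
  sums) yield similarity 0 with a warning, not an error.
* Projection/gate/head weights initialise Glorot-uniform; feature
  projections uniform in `±1/√F`; seeded.
* Predictions are clipped before the log; the clip passes no gradient
  outside its bounds.
* The trainable components run on an in-package reverse-mode
  automatic-differentiation engine over numpy arrays (`mdagraph.nn`)
  supporting exactly the operations the model needs; gradients are
  verified against central finite differences in the test suite.
* Problem sizes in the shipped studies: M = 150, D = 100, r = 5,
  density 0.08, noise 0.02; five folds; ablations on one fold across
  five seeds. These sizes were chosen so a full study runs on a single
  CPU core in minutes.

## Known limitations

* **Multi-view fusion adds little on the planted benchmark.** On the
  synthetic low-rank conditions the association view alone is
  information-sufficient: each single-view variant reaches roughly the
  same cross-validated AUC as the fused model (differences within
  ±0.01, inside run-to-run variability), because the similarity view's
  content is either derived from the association matrix (functional
  similarity, GIP) or redundant with the latent factors the association
  view already observes. The advantage of fusing independently curated
  similarity sources — the motivation for the multi-view design on real
  databases — is therefore not expected to reproduce on this generator,
  and the shipped ablation comparison reflects that.

* The double-ELU composition in the residual update follows the
  published rule as printed; a pre-activation residual would be the
  more conventional design.
* The semantic-similarity IC contribution assumes the standard
  information-content form; the source defines the aggregate but not
  the per-node term.
* Whether triplet embeddings are taken before or after global-context
  fusion is an assumption (after), flagged here.
* The image branch's contribution is only meaningful when disease
  classes with imagery map onto diseases whose associations correlate
  with morphology; the synthetic textures exercise the plumbing, not
  that biological claim.
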