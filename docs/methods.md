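# Methods

`snfnn` predicts drug–disease interactions from a binary gold standard and a
collection of heterogeneous similarity networks. This note documents the
model, the numerical choices, the synthetic benchmark the test suite runs
on, and the limitations of both.

## Problem setting

The gold standard is a binary matrix *Y* ∈ {0,1}^(m×n): *y₍ᵢⱼ₎* = 1 when drug
*rᵢ* is clinically validated to treat disease *dⱼ*, 0 when the pair is
*unknown* (not confirmed-negative). Alongside *Y* come *k* drug–drug and *l*
disease–disease similarity matrices in [0,1], one per data view (chemical
structure, side effects, phenotype semantics, …). The task is link
prediction on the unknown cells of *Y* under extreme skew (the public
benchmarks are 98.7–99.4% sparse).

## Pipeline

### 1. Gaussian interaction-profile (GIP) kernels

Each drug is represented by its interaction profile *f(r)* (its row of *Y*),
each disease by its column profile *g(d)*. Profile similarity is

  sr(rₐ, r_b) = exp(−τ·m·‖f(rₐ)−f(r_b)‖² / Σᵢ‖f(rᵢ)‖²),

and symmetrically for diseases with *n* and *g*. For binary profiles
Σᵢ‖f(rᵢ)‖² is the total interaction count, so the exponent is the squared
distance divided by the *mean interactions per drug* — the kernel bandwidth
adapts to the dataset's density. τ (default 1) rescales the bandwidth;
τ = 2 exactly squares every off-diagonal entry.

Because the profiles *are* the labels, a GIP matrix computed on the full *Y*
carries information about every held-out fold. The default pipeline computes
GIP once on the full gold standard — matching how these kernels are normally
used in benchmark evaluations of this method family — and therefore the
cross-validated numbers partly reflect that leakage. A `strict_no_leakage`
mode recomputes GIP, selection and fusion inside every training fold with
the held-out positives masked; it is markedly slower and gives lower,
leak-free estimates. Both modes are first-class; the default replicates the
benchmark protocol.

### 2. Similarity-view selection

Views are filtered in four steps, separately for drugs and diseases:
per-view mean row entropy (off-diagonals row-normalized to a probability
vector, in bits, bounded by log₂(p−1)); drop views whose entropy exceeds
`entropy_cutoff_fraction` of the bound; Spearman correlation of the
surviving views' off-diagonal entries as pairwise redundancy; greedy scan in
decreasing redundancy, dropping the higher-entropy member of every pair
above `redundancy_threshold` (0.6). Ties break lexicographically on view
name, so selection is deterministic and order-independent. If every view
fails the entropy filter the single lowest-entropy view is kept.

The entropy cutoff defaults to 0.99. This is deliberate: mean row entropy of
any dense similarity matrix concentrates near the log₂(p−1) bound — at
p = 120, a view with four clean planted clusters sits at 0.89 of the bound
and an informative GIP kernel at 0.98, while a truly uniform view sits at
1.0 exactly. "Noisy" here means *statistically indistinguishable from
uniform*; anything structured-but-diffuse should survive to the redundancy
step rather than be discarded by the entropy screen. A lower cutoff (say
0.6) silently reduces every realistic multi-view dataset to a single view.

### 3. Similarity network fusion

The selected views are merged by KNN-sparsified cross-diffusion. Each view
becomes a row-stochastic status matrix *P* (off-diagonal *S(i,j)/2Σ*,
diagonal ½) and a local kernel *L* keeping each row's K strongest
neighbours (ties to the lower column index), row-normalized. For T
iterations each status matrix is updated as
*P_v ← L_v · mean_{w≠v}(P_w) · L_vᵀ*, then symmetrized and row-renormalized
(diagonal pinned at ½). The fused network is the average of the status
matrices, projected to symmetric row-stochastic form by a short
Sinkhorn-style alternation so the output invariants (symmetry, unit row
sums) hold to 1e-8 regardless of float drift. K = 20 and T = 20 follow the
fusion method's recommended operating range; K is clipped to p−1.

Two deliberate semantics:

* **Duplicate views are collapsed before diffusion.** A view that is
  bit-identical to another adds no information, but cross-diffusion would
  double-count it and shift the fixed point. Fusing {A, A} is therefore
  defined to equal fusing {A}. (Exact duplicates are normally removed by the
  selection stage anyway; this makes fusion itself invariant.) Cross-
  diffusion is *not* stationary on duplicated inputs — the iteration
  converges to its own fixed point roughly 0.05 away from the single-view
  kernel on random fixtures — so this invariance must be imposed at the
  semantic level, not expected of the iteration.
* **No scaled-exponential affinity transform** is applied before fusion:
  the inputs are already similarities in [0,1].

### 4. Pair features and class balancing

The feature vector of pair (rᵢ, dⱼ) is row *i* of the fused drug network
concatenated with row *j* of the fused disease network (length m+n). Since
fused rows are row-stochastic (entries ~1/p), the off-diagonal is min–max
rescaled to [0,1] by default before feature construction: the network
consumes similarity-scale inputs, and He-initialized layers assume O(1)
activations — raw status-scale features measurably underfit. `rescale_fused
= False` feeds the raw rows.

Training sets contain every known interaction plus an equal-sized uniform
random sample (seeded, without replacement) of unknown cells, giving an
exact 1:1 balance. A fresh negative sample is drawn per CV repeat seed.

### 5. Neural network

A fully connected MLP in numpy: input (m+n) → 4 hidden layers × 300 ReLU
neurons, inverted dropout 0.35 after each hidden layer → 1 sigmoid output;
binary cross-entropy; He-initialized weights (biases zero); Adam with
α = 1e-3, β₁ = 0.9, β₂ = 0.999, ε = 1e-7; shuffled mini-batches of 100 (last
batch may be smaller); 100 epochs. One seed drives initialization,
shuffling and dropout masks, so training is bit-reproducible; dropout is
off at inference. Internals run in float32 (training is memory-bandwidth
bound; reported metrics are unaffected at the printed precision). Per-epoch
history records the batch-weighted mean of the training loss/accuracy as
seen during optimization. The classification threshold for confusion
metrics is 0.5.

The architecture grid {1–5 layers} × {100–500 neurons} × {sigmoid, tanh,
ReLU} × {dropout 0.3–0.5} (375 combinations) can be re-searched with
3-fold CV (`tune_hyperparameters`, inner metric AUC-ROC, ties broken toward
the simpler model); the default pipeline uses the winning configuration
directly since re-running the full grid costs hundreds of model fits.

### 6. Evaluation protocol

Balanced pairs are split into stratified k folds (default 10; each fold has
near-equal positives and negatives), the model trains on k−1 folds and
scores the held-out fold; the procedure repeats with distinct seeds
(default 5) and the report aggregates the unweighted mean ± sd over all
fold-level values of the eight metrics: accuracy, specificity, precision,
recall, F1, MCC, AUC-ROC and AUC-PR. AUC-PR uses step-wise
(non-interpolated) integration; AUC-ROC handles score ties by rank
averaging. Metrics with zero denominators (possible on tiny folds) are
reported as 0 and flagged `degenerate` rather than raising.

Candidate ranking scores user-supplied unknown cells, flags scores > 0.5 as
predicted novel interactions and reports the list sorted by score with
per-drug counts.

## Synthetic benchmark

The generator plants matched drug/disease clusters: block g of drugs treats
block g of diseases. Interactions are Bernoulli(p_in = 0.3) inside matched
blocks and Bernoulli(p_out = 0.005) outside; each structural similarity
view is sim_signal = 0.8 within clusters over a 0.1 baseline, plus
symmetric Gaussian noise (sd 0.05) clipped to [0,1] with unit diagonal. The
default has one structural view per entity type — the regime of the
single-view public benchmarks — plus two probe views exercising selection:
a near-exact duplicate of the first view (Spearman ≈ 1, must be dropped as
redundant) and a uniform all-0.5 view (exactly maximal entropy, must be
dropped as noisy). At the default 120×120 with 4 blocks the gold standard
is ≈ 92% sparse; the 98–99.5% benchmark regime is reached by lowering
p_in/p_out or shrinking blocks.

What passing on this generator shows: the pipeline recovers planted
block-level structure and the GIP kernel's profile information through
selection, fusion and the network. What it does not show: performance on
real chemical/phenotype similarity distributions (heavy-tailed, not
block-plus-noise), on datasets whose views disagree, or absent the GIP
leakage discussed above.

The standard experiment in the test suite and acceptance script runs this
generator at 120×120 with 10-fold × 3-repeat cross-validation (30 model
fits, ~10–15 minutes on one core) — the repeat count is scaled to three to
keep the experiment a single coffee long while the per-fold variance is
already far below the margins being checked.

## Numerical details and edge cases

* Matrix files: labeled TSV (CSV by extension), first header cell empty;
  unparseable cells are errors, never imputed. Diagonals are forced to 1 on
  load (warned if off by > 1e-6); asymmetry beyond 1e-6 is an error unless
  symmetrization is requested.
* Identifier matching is exact and case-sensitive; alignment restricts all
  matrices to the identifier intersection in interaction-axis order and is
  idempotent.
* Degenerate rows (all-zero off-diagonal) get uniform off-diagonal mass in
  the fusion kernels and entropy 0 in selection.
* An all-zero *Y* makes the GIP bandwidth undefined and raises.
* Ranking output is sorted stably, so equal scores keep input order.

## Known limitations

* The four-step selection heuristic's exact scoring functions and cutoffs
  are this package's formalization; published results that depend on a
  particular unstated variant cannot be matched bit-for-bit.
* The default protocol inherits the GIP label-leakage of the benchmark
  tradition it reproduces; use `strict_no_leakage` for honest
  generalization estimates.
* Reproducing the published benchmark AUCs requires the external SND /
  Cdataset / LRSSL files (not bundled); the `evaluate` command emits the
  same report schema on them for side-by-side comparison.
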