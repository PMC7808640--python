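# Methods notes

## The TAAF and its calculus

The transformative adaptive activation function wraps an inner activation
`f` (hyperbolic tangent, logistic sigmoid, or identity) as

    g(f, y) = α · f(β·y + γ) + δ,

with the four parameters per neuron, initialized to `(1, 1, 0, 0)` so the
unit starts out identical to `f`, and trained by back-propagation like any
weight.  The analytic partials are the contract the implementation is tested
against:

    ∂g/∂y = αβ·f′(βy+γ),  ∂g/∂α = f(βy+γ),  ∂g/∂β = αy·f′(βy+γ),
    ∂g/∂γ = α·f′(βy+γ),   ∂g/∂δ = 1.

Design choices worth calling out:

- **γ is the bias.**  TAAF units carry no separate additive bias: for a unit
  with incoming weights the input translation γ is algebraically equivalent
  to a bias inside `f`, and a second bias would double-count a parameter.
  Fixed-activation units keep a conventional bias.
- **No clipping.**  α, β, γ, δ are unconstrained during training and
  non-finite values propagate; silently clamping would hide divergence.
- **Redundancy of β.**  For a unit with weights `w`, β can be folded into
  `u = βw`, so β is formally redundant — it is kept because redundant
  reparameterizations change optimization dynamics, and because the
  constrained-variant machinery needs it as a separable switch.  Nothing
  ever stores `u`.
- **Non-uniqueness.**  For odd inner functions (tanh),
  `(α, β, γ, δ)` and `(−α, −β, −γ, δ)` define the same function; recovery
  checks must accept the sign-flipped orbit.
- **Constrained variants** enumerate the 16 subsets of {α, β, γ, δ} ordered
  by subset size then by (α, β, γ, δ) position, so ablation tables have a
  stable layout.  The empty subset is the plain inner activation.

## Network family and training protocol

Networks have 1–3 equally wide, fully connected hidden layers from the
landmark block to the target block; the output layer is linear (one unit
per target) or a TAAF layer.  Weights use normalized initialization
(uniform on ±√(6/(fan_in+fan_out))); dropout (default rate 0.25) is applied
to hidden activations only, with inverted scaling at train time so
evaluation is untouched.  Large target sets can be split into two random
halves served by two half-networks whose predictions are concatenated.

Optimization is mini-batch Nadam: learning rate 5e-4, β₁ = 0.9, β₂ = 0.999,
batch 256, and the momentum schedule ψ(t) = β₁·(1 − 0.5·0.96^(t·η)) with
schedule decay η = 0.004 applied per update step (ε = 1e-8).  The default
epoch budget is 600 but every experiment here runs far fewer because the
synthetic tasks converge quickly.  After each epoch the validation MMAE is
computed with dropout off, and the returned model is the snapshot from the
best epoch (first argmin on ties).

The training loss defaults to mean squared error while all *reported*
metrics are MAE-based; the loss is configurable (`loss_kind`) because the
two conventions are both defensible and the choice measurably matters.
Epoch-level bit determinism holds for a fixed backend and thread count.

The back-propagation engine is written directly in NumPy against the
analytic partials above.  Gradient correctness is enforced by a
finite-difference oracle (central differences, step 1e-5, relative
tolerance 1e-6) over randomized parameter configurations.

## Data handling

Standardization is **global**: one mean and one population standard
deviation for the entire matrix.  Per-gene scaling would equalize all genes
in the error metrics; global scaling keeps highly expressed genes
proportionally larger so absolute-error metrics weight them more and genes
near the noise floor matter less.

Two splitters are provided.  `random_split` uses largest-remainder rounding
of the requested fractions (ties to the earlier split) over lexicographically
sorted, seeded-shuffled sample ids, so splits are functions of ids rather
than row order.  `group_aware_split` keeps every series (experiment group)
inside a single split, eliminating series-level leakage between training
and evaluation; series are placed largest-first, each into the split that
least distorts the target fractions, and a deviation above 5 points (e.g. a
dominant series) produces a warning rather than silent imbalance.

File formats are GCT v1.2 (genes × samples, `#1.2` header) and TSV
(samples × genes); gene roles come from a sidecar landmark-id list.  Series
labels are explicit metadata, never parsed out of sample-id strings.

## The synthetic generator

Each sample has a latent state `z ~ N(0, I_k)` (default k = 8).  Landmarks
are a linear map of the latents plus Gaussian noise — they carry the
signal.  Each target gene is `s_j · f_j(z·w_j) + o_j` plus noise, with
`f_j` tanh or sigmoid, per-gene scales `s_j ~ U(0.5, 3)` and offsets
`o_j ~ U(−2, 2)`.  The per-gene scale/offset mismatch is exactly what a
TAAF's α and δ can absorb while a fixed sigmoidal unit with a linear output
must spend weights on it — the mechanism behind the benchmark comparison.
Samples belong to series with additive block intercepts
(sd `series_effect_sd`), the simplest structure that makes series-aware
splitting measurably different from random splitting.  The phenotype
variant adds a two-class label and shifts `n_de_genes` designated target
genes by `de_effect_size` (default 2.0, several noise sd, so the planted
genes are recoverable exactly on noiseless data) in class B only.

Default sizes — 2,000 samples, 50 landmarks, 200 targets — keep a full
train/evaluate cycle around one second so paired multi-seed comparisons are
cheap.  What the generator does *not* emulate: probe-level noise,
quantile-normalization artifacts, real series composition, and the
continuum of effect sizes in real differential expression.  Passing tests
therefore demonstrate correctness of the machinery and the *direction* of
the TAAF advantage under range mismatch, not absolute error levels on any
real compendium.

## Evaluation and comparison statistics

Samples are treated as independent; all statistics are built from the
samplewise MAE.  MMDAE decomposes exactly as MMAE₁ − MMAE₂ and is
antisymmetric — both identities are asserted in tests.  Bootstrap CIs are
percentile intervals of resampled means over samples (default B = 1,000;
BCa was not needed for mean statistics at these sample counts).  The paired
Wilcoxon signed-rank test drops zero differences, uses the exact null for
n ≤ 25 without ties and the continuity-corrected normal approximation
otherwise.  Degenerate cases are defined, not crashes: all-zero differences
give p = 1 with a warning; nonzero constant differences give a t-test p = 0
with a warning (differences constant to rounding are treated as constant).

## Ensembles

For each target gene the expert is the pool model with the lowest per-gene
MAE on a *selection* half of the validation data (ties to the smallest
model id); candidate pools of up to 4 models are enumerated and ranked by
ensemble MMAE on the disjoint *evaluation* half.  On the selection half the
full-pool ensemble is per-gene minimal by construction — this is asserted —
but on the evaluation half the winner is only guaranteed minimal among the
enumerated candidates.

## Differential-expression impact

The pipeline quantifies how inference error propagates into DE analysis:
call DE genes on ground truth and on inferred expression for the same
samples, score the inferred calls against the truth calls (accuracy, F₀.₅,
F₁, F₂, MCC), and measure the mean absolute rank displacement of the
truth-selected candidates (top-100 and p < 0.05 modes, ranks by ascending
p-value with gene-id tie-break).  The DE backend is pluggable; the default
is Welch's t-test with Benjamini-Hochberg adjustment at adjusted α = 0.01,
chosen because it is assumption-light and dependency-free — a moderated
empirical-Bayes caller can be slotted in without touching the evaluation.
Artificial two-class phenotypes come from Ward/Euclidean hierarchical
clustering of a seeded sample subset, taking the two largest clusters at
the shallowest cut where both exceed a minimum size.

The subsampling experiment draws balanced subsamples (half per class) at
realistic DGE study sizes, repeats a configurable number of times, and
compares methods with paired Wilcoxon tests on per-repetition scores.  One
property of the desk-scale fixture is worth knowing: because the generator
plants a single effect magnitude, truth and both degraded copies saturate
to F₁ = 1 once the per-class count comfortably resolves that effect (around
n ≥ 60 at default settings), which makes median comparisons degenerate
above that point while the paired tests remain informative.  The
monotonicity checks therefore run at sizes 12 and 24, where DE calling is
genuinely uncertain; the unit-test fixture plants graded shifts (0.8–3 sd)
for the same reason.  Real data, with its continuum of effect sizes, does
not saturate this way.

## Problem sizes used in the checks

- Gradient oracle: 1,000 random configurations per inner kind.
- Closed-form identities: 101-point grid on [−5, 5], tolerance 1e-12.
- Parameter recovery: one TAAF unit, 2,000 noiseless points of
  2·tanh(0.5y − 1) + 0.3, tolerance 0.05 on the recovered orbit.
- Benchmark: 10 paired seeds, 1 hidden layer of width 64, 60 epochs,
  sigmoid inner, 2,000 samples (70/15/15 split).
- Split leakage: 200 random fixtures of 15–40 series.
- DGE monotonicity: noise sd 0.1 vs 0.5, sizes {12, 24}, 200 repetitions.
- Type-I control: 5,000 null genes; 1,000 null paired-test simulations.

## Known limitations

- Pure-NumPy training is single-threaded BLAS-bound; it is meant for
  desk-scale studies (thousands of samples, hundreds of genes), not for
  compendium-scale runs.
- Capacity-matched width reduction is defined by the sandwich property on
  the package's own parameter-counting conventions (a TAAF unit costs its
  fan-in plus four parameters, no bias); other conventions give slightly
  different widths.
- The checkpoint archive stores raw arrays keyed by layer; it is not a
  cross-framework interchange format.
- `artificial_phenotypes` fixes Ward linkage with Euclidean distance;
  other linkages would produce different (equally defensible) phenotypes.
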