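# Methods

This note documents the models implemented in `qmpa`, the choices made
where the underlying procedures are underdetermined, and what the
synthetic-data experiments do and do not demonstrate.

## Contrast enhancement

The pipeline operates on intensities normalized to [0, 1] by min–max
scaling; the mean `m` used by the contrast-stretching transform (CST)
is computed on the normalized image.  Normalizing first keeps both
branches informative — the global logistic `e^g/(1+e^g)` saturates
almost completely on 8-bit-range inputs, which would reduce the fusion
to a monotone remap of the CST branch alone.

Numerical conventions:

* CST at `g = 0` is defined as `k = 0`, the continuous `E > 0` limit of
  `1/(1+(m/g)^E)`.
* An all-zero image has no usable mean and raises a degenerate-input
  error from the CST; a constant image cannot be stretched and the
  full pipeline returns a neutral all-0.5 image with a warning instead
  of failing, so batch runs survive blank frames.
* The final stretch is the plain min–max affine map `t = αf − β` with
  `α = 1/(max−min)`, `β = min/(max−min)`.

The slope default is `E = 0.5`.  The enhancement exponent `W` has no
canonical value; the default is `W = 2` (any `W > 1` visibly amplifies
contrast) and it is exposed as a CLI flag.  The `W = 1` case recovers
the un-exponentiated LIP fusion.  Every stage is monotone in pixel
value, so intensity ordering is preserved end to end; the test suite
checks the vectorized pipeline against an independent per-pixel scalar
implementation to 1e-12 relative.

## Sparse autoencoder and augmentation

The named regularizers (L2 weight decay, sparsity regularization,
sparsity proportion) identify the canonical sparse-autoencoder
objective, which is what we implement:

    L = mean((X̂ − X)²) + λ(‖W₁‖² + ‖W₂‖²) + β Σ_h KL(ρ ‖ ρ̂_h)

with logistic activations on both layers, λ = 0.001, β = 4, ρ = 0.15,
hidden size 300 and a 2000-epoch default budget.  The KL term uses mean
hidden activations over the full batch, clamped to [1e−8, 1−1e−8].
Weight decay applies to the weight matrices only, not the biases.

Training is full-batch gradient descent with momentum 0.9 and a fixed
learning rate (default 0.05, chosen for stable convergence of the
logistic/KL objective at these scales; larger rates oscillate on the
sparsity term).  Gradients are analytic and verified against central
finite differences to 1e-5 relative.  Training is deterministic given
the seed (Glorot-uniform initialization from a seeded generator).

Augmentation trains one autoencoder per class by default (a single
global model is available via a flag; which variant the original
augmentation used is not determinable, and we claim neither).  New
observations are produced by encoding a randomly chosen real class
member, adding Gaussian jitter (σ = 0.05) to the code, and decoding —
this yields non-duplicate synthetic images, unlike flips/rotations.
Classes at or above the target pass through unchanged; every output
row carries a real/synthetic provenance flag.  Desk-scale runs resize
images to side 32 and truncate training to ~100 epochs; the count
contract (every class ends at `max(original, target)`) is independent
of either reduction.

## Bayesian optimization

Minimization convention throughout: the incumbent is the lowest
observed value, and expected improvement is measured below it.  The
search space maps each dimension (linear or log scale) to the unit
cube; the demo hyperparameter space uses log scaling for learning rate
(0.01–0.9) and L2 (1e−10–1e−2) and linear for momentum (0.8–0.98).

The surrogate is a zero-prior-mean GP with ARD Matérn-5/2 covariance
plus i.i.d. Gaussian noise and a 1e−10 conditioning jitter.  Kernel
hyperparameters (log length scales, log signal std, log noise std) are
refit each iteration by multi-start Nelder–Mead on the negative log
marginal likelihood; observed values are centered before fitting.
Acquisition maximization scans 2000 uniform candidates and refines the
best with a bounded simplex search; ties resolve to the first maximal
candidate.  EI-per-second fits a second GP to log evaluation seconds
and floors the predicted cost at 1 μs.

The loop spends its budget exactly: `n_seed` uniform points (default
4) then acquisition-driven evaluations up to `max_evals` (default 30).
A raising or non-finite objective is recorded as a failure scored at
the worst finite value so far, and can never become the incumbent.  An
optional improvement threshold (`tol`) provides the early-stopping
criterion; it is off by default, and there is no wall-clock cap.  The
"plus" over-exploitation modifier sometimes attached to EI-per-second
is not specified anywhere we could implement from and is out of scope;
plain `ei` and `eips` are provided.

## Quantum Marine Predators feature selection

The continuous optimizer follows the standard MPA iteration structure;
iterations are indexed 1…maxit with phase gates at thirds.  Brownian
steps are standard normal draws; Lévy steps use the Mantegna algorithm
with exponent 1.5.  After every operator, positions are clipped to
bounds (reflection available via config).  The greedy memory compares
each agent with its previous self and keeps the better; the elite is
the best position ever observed, so the elite-fitness history is
non-increasing by construction.

The quantum update samples `Z = C ± b·|Jbest − Z|·ln(1/u)` with
`C = θ·cBest + (1−θ)·gBest`, `u ~ U(0,1)`, and the sign positive when a
second uniform draw is ≥ 0.5 (the standard quantum-behaved-swarm rule;
the printed branch condition in the source formulation is degenerate).
θ follows the logistic chaotic map `θ ← 4θ(1−θ)` from θ₀ = 0.7,
advanced once per iteration; `b` contracts linearly from b_max = 1.0
to b_min = 0.5 (conventional quantum-swarm endpoints; only the linear
schedule itself is prescribed).  Placement: in phase 2 the exploration
half of the population (the worse half by fitness; the better half
exploits with Lévy prey steps) moves by the quantum sample; in phases
1 and 3 an attractor-driven step `C⊗(E − C⊗P)` scaled by `T·CF` is
blended after the standard move; and each iteration the worst agent is
resampled around the elite.  `quantum=False` disables all three and
recovers the canonical MPA for ablation.

FADs: with probability 0.2 an agent jumps by `CF[Ymin + R(Ymax−Ymin)]`
masked by a binary vector (uniform draws thresholded at 0.2); otherwise
it moves by `[FADs(1−r)+r](P_{r1} − P_{r2})` with distinct random agent
indices (the swap branch requires n ≥ 3; the boundary draw r = 0.2
takes the swap branch).

Feature selection searches [0,1]^d, thresholds at τ = 0.5 (ties
select), and forces the single largest coordinate if a mask comes out
empty.  Fitness is `0.99·err + 0.01·(k/d)` where `err` is the
stratified 3-fold cross-validated error of a 5-nearest-neighbour
classifier on the masked columns; folds are fixed once per run, so the
fitness is deterministic and cacheable by mask.  The fitness function
and the continuous-relaxation encoding are standard
wrapper-selection practice; the original formulation names neither.

## Fusion, classifiers, evaluation

Serial fusion is column-wise concatenation with strict row/label
agreement.  Classifier backends are scikit-learn estimators in a
pipeline whose scaler is fitted on training data only: cubic-kernel
SVC (degree 3, C = 1, scale gamma), 10-NN with squared-inverse
distance weights (a zero-distance neighbour takes all the weight, the
1/d² limit), and ReLU MLPs of sizes (10), (25), (100), (10,10),
(10,10,10) with iteration limit 1000 and no regularization.  These
backends are ordinary model fits, not this package's contribution,
which is why they are delegated to scikit-learn.

Metrics use the conventional one-vs-rest definitions: sensitivity
TP/(TP+FN), precision TP/(TP+FP), FNR = 100 − sensitivity; macro
averages are unweighted over classes.  (Printed formulations of these
metrics sometimes swap sensitivity and precision; the conventional
forms are the ones under which per-class sensitivity + FNR = 100
holds.)  AUC is macro one-vs-rest on class scores (probabilities, or
decision values for the SVM).

## Paired-t validation

The statistic works on absolute per-phase accuracy differences, as the
procedure it reproduces prescribes: `J = |a − b|`, `μ = mean(J)`,
`σ = sd(J)` with divisor I−1, `T = √I·μ/σ`, df = I−1, compared against
the two-sided Student-t quantile (2.776 at df = 4, α = 0.05).  Two
deliberate transparency choices: a `literal` flag reports the
alternative `I·μ/σ` scaling, and σ = 0 yields T = 0 with a degenerate
flag rather than an error.  Absolute differences make μ ≥ 0, so this
is a magnitude test, not a signed paired t-test; the implementation
reports the statistic, interval and boolean and encodes no further
interpretation.

## Synthetic data

Phantoms are geometric, not anatomical: class-specific blob counts,
radii and intensity offsets on a noisy background, with all intensity
squeezed into a narrow band (default 0.35–0.65) so the contrast stage
has work to do.  Background noise is truncated at ±1.5σ, bounding each
image's dynamic range by (band width) + 3σ by construction.  The
default class counts 708/1426/930 reproduce a strongly imbalanced
three-class study population.

Feature matrices emulate sigmoid-activated pooled CNN features: every
value lies strictly in (0, 1); `n_informative` columns are
logistic(class_sep·center + N(0,1)) with per-class unit-normal
centers, the rest logistic(N(0,1)) noise; a recorded permutation hides
the informative columns.  The general-purpose default is
class_sep = 2.0.  Recovery experiments use class_sep = 0.8: with only
three classes the per-class center patterns of five columns are
necessarily correlated, and at stronger separations a strict subset of
the planted columns already achieves zero cross-validated error —
making redundancy, not recovery, the optimal selection.  At 0.8 the
informative-only error sits well away from both zero and chance, so
every planted column carries marginal signal.

**What passing tests do not show:** phantoms carry none of the
anatomy, acquisition physics or inter-patient variability of real
MRI; the feature generator has independent columns, whereas real CNN
features are strongly correlated; and the toy extractor is a fixed
hand-crafted map, not a trained network.  Results on these fixtures
validate the algorithms' contracts (counts, budgets, monotonicity,
recovery of planted signal) — they say nothing about classification
accuracy on real brain-tumor data, which would require the original
imagery and GPU-scale training and is explicitly out of scope.

## Problem sizes

Default experiment scales were chosen for single-CPU runs: SAE
augmentation at image side 32 with 100-epoch training; selector
benchmarks at 30 agents × 100–200 iterations; BO at 4 + 26
evaluations; recovery experiments over 10 seeds.
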