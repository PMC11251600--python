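# Methods

## The optimizer

`bimgo` implements the mountain gazelle optimizer (MGO) and an improved
variant (IMGO) for continuous box-constrained minimization, plus a binary
wrapper (BIMGO) for feature selection. Both optimizers evolve a herd of `N`
positions in `R^D`. Every iteration each gazelle spawns four offspring:

* **TSM** (territorial solitary males): `best − |(ri1·BH − ri2·X_i) ⊙ F| ⊙ Cof`,
  an exploitation move contracting toward the incumbent best;
* **MH** (maternity herds): `(BH + Cof₁) + (ri3·best − ri4·X_rand) ⊙ Cof₂`;
* **BMH** (bachelor male herds): `(X_i − D) + (ri5·best − ri6·BH) ⊙ Cof` with
  the fight vector `D = (|X_i| + |best|)(2r − 1)`;
* **MSF** (migration to search for food): `lb + (ub − lb)·r₇` with one
  scalar `r₇ ~ U[0,1)` shared across coordinates — a restart on the main
  diagonal of the normalized box.

Here `BH = X_ra·⌊r₁⌋ + M_pr·⌈r₂⌉` is the bachelor-herd effect vector (`ra`
uniform over the worse-fitness third of the ascending-sorted herd, `M_pr` the
mean of `⌈N/3⌉` members drawn without replacement; `⌊r₁⌋` with `r₁ ~ U[0,1)`
is implemented literally and vanishes almost surely), `F` is a standard-normal
vector scaled by `exp(2 − 2t/T)`, and the `ri` are scalar draws from {1, 2}.
All 4N offspring join the habitat; the pooled habitat is sorted ascending
(stable, so earlier entries win ties) and the best N survive. The trace of
best-so-far values is therefore monotone non-increasing.

Three structural choices matter enough to state explicitly, because the
dynamics degrade by orders of magnitude without them:

1. **One coefficient matrix per gazelle.** The four-branch coefficient object
   `Cof` — rows `(a+1)+r₃` (a scalar broadcast), `a·N(0,1)^D`, `U[0,1)^D`, and
   `N₃ ⊙ N₄² ⊙ cos(2r₄·N₃)` — is realized once per gazelle per iteration, and
   each of the four `Cof` slots in TSM/MH/BMH samples a row of that matrix
   *with replacement*. The shared realization couples a gazelle's moves at a
   common random scale; with independent redraws per slot the late-stage
   refinement on optima away from the origin stalls around 1e−10 instead of
   reaching the double-precision floor (measured on the 30-D penalized and
   Rosenbrock functions).
2. **Running incumbent.** The "male gazelle" used by TSM/MH/BMH and the spiral
   move is the habitat-wide best-so-far, refreshed after every objective
   evaluation inside the per-gazelle sweep — not the best frozen at the last
   sort. This roughly quadruples the late-stage convergence rate.
3. **Coherent (diagonal) long-range moves.** Both the migration restart (one
   scalar `r₇` shared across coordinates) and the chaotic initialization (one
   chaotic value per gazelle, below) sample the main diagonal of the
   normalized box. Several classical multimodal optima lie on that diagonal
   (Schwefel's `420.97·1`, the integer Shekel foci, the all-ones penalized
   optimum), and the coherent moves find those basins reliably in any
   dimension, whereas independent per-coordinate restarts essentially never
   do for `D ≳ 4` — measured on the Shekel m=5 function the trap rate into
   the second-best basin drops from ~8% to ~0% per run.

Boundary handling clips every candidate elementwise to the box before
evaluation, which preserves the elitism guarantee.

## The four IMGO improvements

* **ICMIC initialization.** The iterative chaotic map with infinite collapses,
  `ω ← sin(0.7π/ω)` on `[−1,0) ∪ (0,1]` (control parameter 0.7; the domain
  excludes 0 because the argument is `0.7π/ω`), generates one orbit value per
  gazelle from a random seed value; gazelle `i` maps its scalar `ω_i` onto
  every coordinate via `x = lb + (ω+1)/2·(ub−lb)`. The initial herd thus lies
  on the main diagonal of the (normalized) box with chaotically spaced,
  bin-filling offsets. The per-gazelle scalar (rather than a fresh chaotic
  value per coordinate) is deliberate: several classical multimodal optima lie
  on or near the diagonal (Schwefel's ±420.97·**1**, Shekel's integer foci,
  the all-ones penalized optimum), and the scalar layout seeds those basins in
  every run — with a per-coordinate chain instead, runs trap in local basins
  on the Schwefel and Shekel functions at several percent per run. A config switch
  (`icmic_multiplicative`) exposes the `sin(0.7π·ω)` reading for comparison.
* **Nonlinear control factor.** `a = −2 + log₂(1 + (1 − t/T)²)` replaces the
  linear `a = −1 − t/T`: both run from −1 to −2, but the nonlinear schedule is
  steepest early (wide exploration) and flattest late (tight exploitation).
* **Spiral perturbation.** After its offspring are spawned, each gazelle is
  moved along a logarithmic spiral around the incumbent,
  `best + e^{c·l}·cos(2πl)·|best − X_i|`, with one scalar `l ~ U[−1,1]` shared
  across dimensions, and the better of old/new is kept. The shape constant `c`
  defaults to 1 (the whale-algorithm convention for the same move; no other
  value is documented for this variant) and is configurable.
* **Neighborhood search.** Once per iteration, after the habitat sort, one
  candidate is drawn per-dimension uniformly from
  `[best − |best − second|, best + |best − second|]`, clipped to the box, and
  greedily accepted into the best slot.

Per iteration IMGO consumes exactly `4N + N + 1` objective evaluations
(baseline MGO: `4N`). Randomness is organized as named substreams (`init`,
`mech`, `spiral`, `neighborhood`, `noise`) spawned from one root seed, so runs
are bit-for-bit reproducible and toggling one component does not shift the
draws of another.

## Why several reproduced values are *exact*

The multimodal reproductions rely on double-precision absorption near the
optimum. Once all coordinates are within ~1e−9 of the Rastrigin/Griewank
optimum, the `−10cos(2πx)+10` and `1 − ∏cos` terms round to exact zeros and
the residual `x²` terms are absorbed, so the value is exactly `0.0`. The
Ackley formula at its optimum evaluates to `4.44e−16` (the `20 + e` additions
cannot cancel exactly), and the penalized function at the all-ones point
leaves `0.1·sin²(3π) = 1.3498e−32`. An optimizer that converges
geometrically deep enough therefore reports these exact floor values — which
is what the elitist herd dynamics achieve within 500 iterations.

## Benchmark registry

The 23 classical test functions carry their standard bounds, default
dimensions (30 for the dimension-generic f1–f13) and documented optima.
Constants not commonly printed (Shekel foci, Hartmann matrices, the foxholes
grid, Kowalik data) are the classical published values, and each
fixed-dimension optimum is verified by a deterministic dense-grid multistart
L-BFGS-B descent (`multistart_minimum`), which doubles as the independent
oracle in the acceptance checks. Notes on individual entries:

* f7 (noisy quartic) adds one `U[0,1)` draw per full-vector evaluation — the
  noise term sits outside the sum — and takes an explicit generator; the
  noise-free part is used when no generator is supplied. Its bounds are the
  classical symmetric `[−1.28, 1.28]`.
* f12 uses the classical `10·sin²(πy₁) … + (y_n−1)²` numerator (the variant
  without the square admits negative values, contradicting the documented
  optimum 0) with penalty `u(x, 5, 100, 4)`; the penalty's middle branch is
  zero on `[−a, a]` inclusive.
* f15 stores the full-precision Kowalik minimum 3.0749e−4 (displays round it
  to 0.00030).
* f19 (Hartmann-3) lives on the unit cube `[0,1]³`, where its documented
  optimum −3.8628 is attainable; the `[1,3]³` range that circulates in older
  comparison tables does not contain the minimizer.
* The four-decimal prints −10.4028/−10.5363 for the Shekel m=7/10 minima are
  historical truncations; the true values are −10.40294/−10.53641 and the
  registry stores the latter.

## Binary feature selection

A feature subset is encoded as a continuous position in `[−5, 5]^D` (the
sigmoid spans ≈ (0.007, 0.993) over that box, keeping both bit states
reachable from the chaotic init; configurable via `fs_bounds`). The transfer
is `S(x) = 1/(1+e^{−x})` thresholded at 0.5, which is exactly `x ≥ 0` with
the boundary assigned to 1. The wrapper fitness of a mask is the held-out
error `1 − (TP+TN)/(TP+TN+FP+FN)`; sensitivity is `TP/(TP+FN)`, computed
one-vs-rest for the declared positive class (default: the minority class) and
reported as missing — not 0 — when the test partition has no positives.
Deliberate choices:

* **No feature-count penalty.** The objective is the raw error rate;
  parsimony must emerge from the search, not the objective. On very separable
  data the search may therefore legitimately return large subsets.
* **Evaluation protocol.** Default is a stratified 80/20 hold-out split fixed
  per run by the run seed; stratified k-fold (counts pooled over folds) is an
  option. The classifier is pluggable: RBF-kernel SVM (default), k-NN (k=5 or
  1) and logistic regression; all are deterministic given the data.
* **All-zero masks** score fitness 1.0 without training (range-preserving
  penalty; no bit repair).
* **Memoization.** Subset evaluations are cached by mask, so the optimizer
  pays only for distinct subsets; memoized and unmemoized runs are identical
  by construction.

Dataset IO: headered CSV (pandas) and ARFF (scipy.io.arff). Numeric columns
pass through; categoricals are integer-encoded by sorted category order;
missing values are imputed by column median (numeric) or deterministic mode
(categorical) with imputation sites recorded in a boolean mask.

## Synthetic data

The generator emulates UCI-style binary-labeled medical tables with known
ground truth: informative columns are class-conditional Gaussians with means
`±effect/2` and unit SD; optional redundant columns are positive mixtures
(weights `U(0.5, 1.5)`) of the informative block plus SD-0.1 noise; the rest
is standard normal noise. Labels use exact class counts in a seeded shuffle;
missing cells are inserted uniformly at the requested rate and
median-imputed, with the sites recorded so fixtures round-trip through CSV
(empty cells) and ARFF (`?`). Defaults — 300 instances, 50 features, 5
informative, effect size 2.0, balanced classes — give a Bayes error near 1%
on the informative block and chance-level error on the noise block, a regime
where wrapper recovery is meaningful but not trivial. What the generator does
*not* emulate: heavy-tailed or discrete clinical measurements, label noise,
class overlap structure beyond a mean shift, and feature counts in the
thousands; passing recovery tests here demonstrates the machinery, not
performance on any particular clinical dataset.

## Experiments and statistics

Per-cell seeds are derived by hashing `(root_seed, algorithm, problem, run)`
(SHA-256, reduced below 2³¹), making experiments replayable and
order-invariant. Cells aggregate mean/std/best of final values; algorithms
are ranked per problem by mean with smaller std breaking ties and exact ties
sharing the better rank. Distributions are compared with a two-sided Wilcoxon
rank-sum test at the 5% level: exact enumeration of the permutation null of
the midrank sum when `min(n, m) ≤ 8`, otherwise the normal approximation with
midrank tie correction and 0.5 continuity correction (which matches the exact
answer to within 0.02 at moderate sizes and scipy's Mann-Whitney
implementation in the large-sample branch). Two identical constant samples
are degenerate: p is NaN and the verdict '='. Verdicts are '+'/'='/'−' from
the perspective of the first (reference) sample, "better" meaning lower mean.

## Problem sizes used in the shipped checks

The continuous reproductions run at the study conditions: population 30, 500
iterations, 20 independent runs per function. The feature-selection recovery
check runs 20 independent wrapper runs of 100 iterations at population 30 on
the default synthetic dataset. The elitism invariant is additionally swept
across all 23 functions with both optimizers at a reduced size (population
10, 40 iterations) — the monotone-trace property is scale-independent. The
registry oracle uses a 400×400 grid for the 2-D six-hump camel and a 5⁴ grid
plus the classical foci for the 4-D Shekel functions.

## Known limitations

* The optimizer is a minimizer; callers maximize by negating.
* No constraint handling beyond box bounds, no parallel/island models, no
  restart strategies.
* The binary layer uses the S-shaped transfer with a fixed 0.5 threshold
  only; V-shaped transfers and time-varying thresholds are out of scope.
* The Wilcoxon exact mode enumerates `C(n+m, n)` assignments and is intended
  for `min(n, m) ≤ 8`.
* On strongly separable datasets the penalty-free wrapper objective admits
  many zero-error subsets, and the returned subset size is then governed by
  search dynamics rather than by any parsimony pressure.
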