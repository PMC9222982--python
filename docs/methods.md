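# Methods

## Model family

All four models are trained by minimising penalised negative log Cox
partial likelihoods. For a cohort {(x_i, t_i, e_i)} with e_i = 1 for an
observed event, the Breslow-form negative log partial likelihood of the
log-relative-hazards h is

    npll(h) = − Σ_{i: e_i = 1} [ h_i − log Σ_{j : t_j ≥ t_i} exp(h_j) ].

Risk sets use t_j ≥ t_i, so each event is a member of its own risk set;
tied event times share one denominator (Breslow convention, the default
of the standard Cox packages). The inner sum is evaluated through a
cumulative log-sum-exp after a global shift, so extreme hazards cannot
overflow, and the analytic gradient is computed in the same sorted pass.

**CPH.** h = Xβ + b; objective npll + λ₁(‖β‖² + b²) with λ₁ = 1e-4,
minimised by L-BFGS-B with the analytic gradient to a gradient-norm
tolerance of 1e-6 (max 2000 iterations). Coefficients start uniform on
[−0.01, 0.01] from a stated seed; the fit is deterministic given seed and
data.

**CPH_ROI.** Two coefficient vectors β₁ (primary) and β₂ (auxiliary)
share one scalar bias b, and the joint objective is the convex
combination (1−λ)·[npll₁ + λ₁(‖β₁‖² + b²)] + λ·[npll₂ + λ₁(‖β₂‖² + b²)]
with λ = 0.2. Prediction for new patients uses β₁ and b only, so the
auxiliary outcome is never consumed at test time.

**CPH_DL / CPH_DL_ROI.** A fully connected extractor F (defaults: widths
100 and 50, dropout 0.5 after each hidden layer, rectified-linear
activations) feeds one or two Cox regression heads; the joint deep
objective mirrors the linear one with both heads reading the same
embedding and sharing the bias. Training is full-batch Adam (step size
1e-3, 200 epochs) — full-batch because the partial likelihood's risk sets
are exact only over the whole cohort, and the cohorts here are a few
hundred patients. Weights use fan-in-scaled uniform initialisation.
Dropout masks come from a dedicated random stream so that a λ = 0 joint
fit follows the bitwise-identical trajectory of a plain deep fit with the
same seed. The deep stack is a compact numpy implementation with
hand-written backpropagation; with a few hundred patients and two hidden
layers, each epoch is a handful of small matrix products.

### The shared bias is inert in the linear model

The bias b cancels between the numerator and the risk-set denominator of
every partial-likelihood term, and its likelihood gradient is identically
zero; with any positive λ₁ the optimum has b = 0 (the test suite asserts
|b| < 1e-3). Consequently the **linear** joint objective is
block-separable in (β₁, β₂): the fitted β₁ of `CPH_ROI` coincides with
the plain `CPH` solution at any mixing weight λ, both at the optimum and
along any gradient trajectory. The shared bias is implemented verbatim
because it is part of the model's definition, but in the linear family
the auxiliary outcome cannot change the primary predictions — only in the
deep family, where the extractor is genuinely shared, does the auxiliary
outcome shape the representation used by the primary head. Benchmark
readers should therefore expect `CPH` ≡ `CPH_ROI` for this package, and
any published gap between the two linear models to reflect implementation
differences (optimizer, convergence, scaling) rather than information
transfer.

## Evaluation

Harrell's concordance index over permissible pairs: a pair is permissible
iff the earlier time belongs to an observed event; among tied times, an
event paired with a censoring is permissible with the event treated as
earlier, and two tied events are not comparable. Higher risk must predict
the earlier event; tied risk scores earn half a pair. When no permissible
pair exists the metric is reported as undefined rather than silently 0.5.

Paired model comparisons across tasks use the one-sided Wilcoxon
signed-rank test (zero differences dropped before ranking; exact null for
≤ 25 non-zero differences, continuity-corrected normal approximation
above).

## Cross-validation protocol

Stratified 10-fold CV on the primary outcome's event status: within each
status class, patients are shuffled and dealt round-robin, so per-class
fold counts differ by at most one. Per fold, features are standardized
(centre/unit variance, population convention; constant columns map to
zero) using **training-fold statistics only** — the leakage-safe default;
a "global" switch standardizes once on the full task for the alternative
reading. ROI models see the auxiliary outcome of training patients only;
held-out folds are scored from features alone and the C-index is computed
within each fold, then summarised by the mean (median also reported)
across folds. A master seed deterministically derives the fold seed and
one seed per model per fold.

## Synthetic-data generator

The generator emulates a high-dimensional prognosis cohort with two
related endpoints: M = 300 patients; p = 150 features x_ij ~ U(−1, 1);
primary coefficients β_j ~ U(−1, 1); auxiliary coefficients
β′_j = β_j + ξ_j with ξ_j ~ U(0, 1), redrawn until Pearson
corr(β, β′) ≥ 0.8 (at p = 150 the first draw almost always satisfies the
floor, realised correlation ≈ 0.9). Latent times follow the exponential
Cox model T_i = E_i / exp(βᵀx_i) with E_i ~ Exponential(mean 3000 days),
drawn independently per outcome. End-of-study censoring places the cutoff
at the 200-th smallest latent time per outcome, so each outcome has
exactly 200 events and 100 patients censored at the cutoff.

Because β′ = β + U(0, 1) noise, the auxiliary coefficient vector has the
*larger* norm in expectation, making the swapped task (auxiliary treated
as primary) slightly easier, not harder.

What the generator does not emulate: real feature correlation structure,
non-linear hazards, informative or random censoring, measurement
missingness, or between-outcome dependence beyond the shared features and
correlated coefficients. Passing benchmarks on this generator show that
the estimation and evaluation machinery is correct under a proportional-
hazards ground truth; they do not certify performance on real cohorts.
Degenerate corner: forcing constant coefficients (e.g. a collapsed
`beta_range`) makes the coefficient correlation undefined; the generator
records it as NaN and skips the floor check.

## Numerical choices and edge cases

- Standardization uses the population variance (divide by n); constant
  columns get unit scale and map to zero.
- MAD feature selection (mean |x − mean|) breaks ties toward the lower
  column index and preserves the original column order among selections.
- E/C cohort QC treats zero censored patients as E/C = +∞ (passes).
- Missingness filtering drops rows above the missing-fraction threshold
  (default 0.2) first, then any column still incomplete; it is idempotent.
- The likelihood raises on zero events instead of returning 0; the
  C-index raises on zero permissible pairs.
- Deep training raises a training error naming the epoch if the loss
  becomes non-finite.
- Linear models serialise to JSON; deep checkpoints to a single npz
  archive that round-trips bitwise.

## Problem sizes in the test and reproduction runs

The repository's benchmark scripts use the generator's full default
cohort (300 × 150) with 10 replicate cohorts per outcome direction and
10-fold CV — the scale at which the simulation study is defined — which
completes in minutes on one CPU core. Unit and property tests use smaller
cohorts (tens of patients, ≤ 10 features) chosen to exercise the same
code paths quickly.

## Known limitations

- Breslow ties only (no Efron correction), no baseline-hazard estimate,
  no survival curves, no competing risks, no time-dependent C-index or
  IPCW correction.
- The linear ROI model cannot, by construction, outperform the plain
  linear model (see "The shared bias is inert" above).
- No hyperparameter search: architecture and weights are fixed at their
  stated defaults.
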