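# Methods

## The scientific question

Delayed-estimation experiments measure how precisely people reproduce an
analog feature (here, bar orientation on the 180°-periodic circle) after
holding K items in memory for T seconds. If the memory substrate is graded
persistent activity in continuous-attractor networks, activity noise makes
the stored value diffuse along the attractor manifold, and two architectures
make sharply different predictions about how recall error should grow with
K and T. This package implements both predictions, a generator of synthetic
delayed-estimation data, and the fitting and model-comparison machinery that
adjudicates between them.

All error quantities are in **normalized units**: orientations live on
[0, Φ] with Φ = 1 standing for 180°, so a mean squared error (MSE) of 0.01
corresponds to an 18° RMS error. `theory.norm_to_deg2`/`deg2_to_norm`
convert. Information rates are in nats (natural logarithm throughout; bits
differ by ln 2 — the pairing of the Gaussian capacity ½ln(1+SNR) with the
e^{−2I} variance bound fixes the base).

## The two storage models

**Direct storage.** K circular variables are written, unencoded, into K
ring-attractor networks. Splitting N resource units K ways leaves each
network diffusivity 𝒟̄ = 𝒟K/N (diffusivity scales inversely with network
size), so while the accrued error is small relative to the squared range,

    D_direct(K, T) = Φ² · 2𝒟 (K/N) · T.

Only the ratio ρ = N/2𝒟 (seconds) is identifiable — it acts as a single
combined resource parameter, proportional to total neuron count.

**Coded storage.** The K variables are first jointly encoded into an
N-dimensional codeword stored across N channels of diffusivity 𝒟 each
(equal total resource). Storage for time T is transmission through an
additive Gaussian channel with noise variance 2𝒟T, i.e. SNR = 1/(2𝒟T).
With power split evenly over items, each item receives total rate
R = (N/2K) ln(1 + SNR) nats over the N uses, and the rate–distortion
function of a uniform source on [0, Φ] bounds the achievable reconstruction
error from below:

    D_coded(K, T) = Φ²/(2πe) · (1 + 1/(2𝒟T))^(−N/K).

This is a lower bound on MSE for *any* encoder/decoder pair; it is evaluated
in the log domain (exp of a sum of logs) so large N/K cannot overflow, and
its T = 0 limit is defined as 0 by continuity. The implementation keeps the
factorization explicit — `per_item_rate` → `rate_distortion_interval` — and
tests assert that the closed form agrees with that composition to 1e−12
relative error over a 1000-point parameter grid. N is treated as a positive
real throughout fitting; integer N is a presentation convention.

The package does not construct encoders or decoders achieving the bound and
makes no finite-N achievability claims; the bound is asymptotic in N and
strict below.

## Diffusion simulator

`diffusion` simulates pure Brownian motion on the circle (no restoring
force: drift along a flat attractor manifold has no mean reversion).
Increments over each step are exact Gaussians with variance 2𝒟·dt, so a
single-step sampler with variance 2𝒟T is statistically identical to a
fine-step path and is used for large ensembles. Displacements are reported
wrapped to (−C/2, C/2]. The simulator validates the two regimes the theory
relies on: linear MSE growth 2𝒟T while 2𝒟T ≪ C², and saturation at the
wrapped-uniform variance C²/12. `estimate_diffusivity` recovers 𝒟 as half
the slope of a through-origin regression of mean squared displacement on
time, valid in the early-time regime. The coding argument treats channel
noise as linear additive Gaussian while the simulator wraps; all
quantitative comparisons are made in the unsaturated regime where the two
coincide.

## Synthetic data generator

The generator emulates the delayed-estimation design it stands in for:
10 subjects; set sizes {1, 2, 4, 6}; delays {0.1, 1, 2, 3} s; 11–15 blocks
per subject (drawn uniformly per subject) of 80 trials, with exactly 5
trials per (K, T) cell per block; targets i.i.d. uniform on [0, 180°);
probed-item colors (8 available) are bookkeeping only. Because per-subject
block counts are random, total trials per cell vary around ~660 per (K, T)
across subjects rather than equalling it exactly; fixing `blocks_min =
blocks_max` gives exact totals when needed.

A trial's response is target + wrapped-normal noise whose **circular** MSE
equals

    baseline(K) + [D_model(K, T) − D_model(K, T₀)],   T₀ = 0.1 s,

so generated data satisfy the fitting stage's anchoring convention by
construction. Two numerical choices matter:

- *Wrap calibration.* The circular MSE of a wrapped normal is below its
  linear variance (by ~5% at the largest cells here), so the linear SD is
  calibrated by inverting the exact piecewise-Gaussian integral of
  E[wrap(X)²] (Brent root find). Targets at or above the circular ceiling
  1/12 are unreachable and fall back to the raw SD with a logged warning.
- *Baselines.* Baseline errors at the shortest delay are additive in
  variance (independence of encoding-stage error from storage-accrued
  error). Defaults correspond to circular SDs of 8°, 12°, 18°, 25° for
  K = 1, 2, 4, 6 — typical magnitudes for delayed orientation estimation,
  chosen once as the package's reference condition.

An optional lognormal per-subject variance scale models subject
heterogeneity (default off; wrap calibration is exact at unit scale and
approximate otherwise). The generator does not simulate misbinding, swap
errors, guessing pedestals, or stimulus rendering — so passing tests
demonstrate correctness of the pipeline under diffusive, well-anchored
noise, not robustness to those real-data phenomena.

## Empirical summaries

`circular_error` returns the signed angular difference on the 180°-periodic
circle in (−90°, 90°], with the measure-zero tie at exactly 90° mapped to
+90° for determinism. Cell statistics are subject-mean-then-average: each
subject contributes one mean normalized squared error per (K, T) cell;
the cell MSE is the unweighted mean of subject means and its SEM is the SD
of subject means over √n_subjects, so the point estimate and its error bar
live on the same decomposition. (A trial-pooled alternative sits behind
`pool_trials=True`.) The pooled variance of per-trial squared errors,
`var_norm`, feeds the comparison likelihood.

## Fitting

Curves are anchored: pred(K, T) = mse(K, T₀) + D_model(K, T) − D_model(K, T₀).
The anchored cells contribute zero residual and are excluded from the
objective. Anchoring uses the curve *difference* rather than a time shift
D(K, T − T₀); the two coincide for the linear direct model and differ
slightly for the coded bound — the difference convention is the default and
`anchor_mode="shifted-time"` exposes the alternative.

The objective is Σ w·(pred − mse)² over cells with T > T₀ with w = 1/SEM
(weights multiply squared residuals). Inverse-SEM weighting — rather than
the conventional inverse-variance 1/SEM² — is the default deliberately;
`weight="inv_var"` selects the alternative. Zero or undefined SEMs are
rejected with a pointer to the `sem_floor` pseudocount option.

- *Direct fit*: the residual is linear in θ = 2𝒟/N, so the WLS solution is
  closed-form; tests cross-check it against a bounded scalar optimizer.
- *Coded fit*: WSSE is evaluated (vectorized, log-domain) on log-spaced
  grids, defaults N ∈ [1, 10³] and 1/2𝒟 ∈ [10⁻², 10³] s with 200 points
  each. The per-N row minima trace the **valley** of near-optimal fits and
  N·(1/2𝒟) along it is the resource curve. The grid argmin (ties break to
  smallest N, then smallest 1/2𝒟; non-finite cells excluded) is refined by
  Nelder–Mead in log-parameters. Because the objective is nearly degenerate
  along the valley, the argmin *location* is ill-conditioned — the refined
  and brute-force optima can sit a few grid cells apart at objective values
  agreeing to well under 1% — so optimizer-agreement checks compare
  objective values, not only locations.
- *Variants*: a 6-item-only OLS direct fit (which over-predicts low-K error
  when the large-K curve is disproportionately steep), and leave-one-subject-
  out jackknife refits with jackknife standard errors.

## Model comparison

The likelihood observable is the per-trial normalized squared error: each
trial in cell (K, T) is scored under a Gaussian with mean equal to the
model's anchored cell prediction and variance equal to the empirical
pooled variance of squared errors in that cell, shared by both models so
the comparison isolates the predicted means. The information criterion is
BIC = −2L̂ + k·ln(2πn) (the `standard` flag gives k·ln n; differences at
equal k are identical). Defaults k = 1 (direct: ρ) and k = 2 (coded: N,
1/2𝒟); counting the four anchored baselines in both models shifts both
penalties equally and provably leaves ΔBIC unchanged. n defaults to the
total number of trials entering the likelihood; a per-cell override exists
for penalty conventions based on observations per (K, T) pair. Pointwise
two-sided Gaussian p-values of each cell mean (z = (mse − pred)/SEM) flag
cells a model cannot explain; baseline cells are excluded since both models
match them exactly.

## Problem sizes and determinism

Monte-Carlo checks use 10⁴–2·10⁴ diffusion paths, 10⁵ trials per cell for
generator-fidelity checks, and 20 seeds of full-design datasets for
recovery and model-selection checks — sizes at which 4-standard-error bands
are discriminating while the whole suite stays fast. All random stages take
explicit integer seeds (NumPy `default_rng`); identical configuration and
seed reproduce outputs bit-for-bit.

## Known limitations

- Headline *empirical* parameter values reported for the original human
  dataset cannot be recomputed here without that dataset; the pipeline
  instead demonstrates recovery of known parameters from its own synthetic
  data at the published operating points (N = 10, 1/2𝒟 = 2.28 s for coded
  storage; ρ = 1215 s for direct). The published literature also contains
  two unreconciled conventions for the direct-storage fit (a dimensionless
  2𝒟/N ≈ 3.24×10⁻⁷ alongside N/2𝒟 ≈ 1215 s, which are not reciprocal
  under a single unit convention); this package works exclusively in
  normalized units and seconds, where ρ = N/2𝒟 is well defined.
- The coded curve is a bound, not an achievable performance model at small
  N; fits interpret human data as operating near the bound.
- Spiking network mechanics, non-diffusive (threshold/catastrophic) error
  regimes, misbinding, and discrete-slot resource allocations are out of
  scope, though the sum-rate machinery (`sum_rate_bound` with arbitrary
  power allocations) admits unequal allocations.
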