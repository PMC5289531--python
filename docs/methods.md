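# Methods

This note documents the models, conventions and design choices behind
`enetbeta`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and standardization

A calibration dataset is an n × p predictor matrix X (spectral channels,
arbitrary physical units) and a single response vector y (concentration
units). Missing values are rejected outright, never imputed. All model
fitting happens on the standardized scale: each channel and y are centred
and scaled to unit *sample* standard deviation. The denominator uses
**ddof = 1** — a convention, not a necessity; the only requirement is
that the same convention is used everywhere (fits, CV folds, inverse
transforms), which it is. Zero-variance channels are rejected with an
error naming the channel.

Standardization statistics are always estimated on training data only and
reused on test data; inside K-fold cross-validation they are re-estimated
on each fold's training part. Anything else leaks held-out information
into the fit. All reported error metrics (RMSEP, NMSE, R²) are computed
on the original concentration scale after de-standardizing predictions.

## Regression engines

**OLS** via `numpy.linalg.lstsq`; rank-deficient or wide designs require
an explicit pseudo-inverse flag, otherwise they are an error.

**PLS** uses the NIPALS recursion with X-deflation, simplified for a
single response. h components yield scores T = XW(PᵀW)⁻¹ and the
regression vector β = W(PᵀW)⁻¹q. With h = min(n−1, p) on a full-rank
tall design, PLS reproduces OLS; score columns are mutually orthogonal
and the X-residual norm is non-increasing in h (both tested). If the
response covariance is numerically exhausted before h components (e.g.
rank-deficient X), the achieved number is returned with a warning.

**Elastic net.** The objective is kept deliberately *unnormalized*,

    f(β) = ‖y − Xβ‖² + λ₁‖β‖₁ + λ₂‖β‖₂²,

with no 1/(2n) factor, so penalty values scale with the unnormalized Gram
matrix (for standardized columns xᵀx = n−1). The reported coefficient is
the minimizer rescaled by (1 + λ₂/n), the standard correction that undoes
the naive estimator's double shrinkage. The solver is cyclic coordinate
descent with covariance (Gram) updates, jit-compiled with numba; a
regularization-path algorithm of the LARS family would find the same
optima with far more machinery and is deliberately not implemented.
Convergence is declared only when the **subgradient KKT residual** is
below 1e−6 (absolute, on this objective's gradient scale): coefficient
sweeps are repeated with a tightening change tolerance (starting at
1e−8, capped at 10⁵ sweeps per stage) until the certificate passes, and
failure raises with the final residual rather than returning an
uncertified solution. On orthonormal designs the solution has the closed
form soft(βOLS, λ₁/2)/(1 + λ₂) · (1 + λ₂/n), which the tests check on a
penalty grid, and the solver is cross-checked coefficient-wise against an
independent implementation (scikit-learn's, under the penalty mapping
α·l1_ratio = λ₁/(2n), α·(1−l1_ratio) = λ₂/n).

**Penalty tuning.** No tuning rule is hard-coded into the estimator;
`enet_grid_search` picks (λ₁, λ₂) by K-fold cross-validated RMSEP (K = 9
by default, matching the component-selection convention used for PLS
here) over user grids. The default grids are λ₁ ∈ {0.5, 0.2, 0.1, 0.05,
0.02}·λ_max with λ_max = 2·max|Xᵀy| (the smallest weight that zeroes
every coefficient) and λ₂ ∈ {1, 10, 100}. CV ties within 1e−12 break
toward smaller λ₁, then smaller λ₂ — deterministic and parsimonious in
shrinkage.

## Evaluation criteria

* RMSEP = √(Σ(yᵢ−ŷᵢ)²/n). Some sources typeset the formula without the
  radical; a `no_sqrt` switch reproduces that literal SSE/n variant for
  comparability, but the root form is the default everywhere.
* NMSE = Σ(yᵢ−ŷᵢ)²/Σyᵢ². A per-term division by yᵢ² would explode at
  yᵢ = 0, so the aggregate form is used. Unlike R², NMSE is *not*
  invariant to a common shift of y and ŷ (tested).
* R² = 1 − SSR/SST.
* AIC/BIC use the Gaussian likelihood with the error variance profiled
  out and constants dropped: AIC = n·ln(SSR/n) + 2k, BIC = n·ln(SSR/n) +
  k·ln(n). Only differences between models fitted to the same data are
  meaningful; values must not be compared across datasets. SSR/n is
  floored at 1e−12 (with a warning) so perfect interpolants do not
  produce −∞.
* K-fold CV partitions are contiguous blocks of a seeded shuffle, with
  per-fold re-standardization.

## Selectors

**PLS-BETA.** Rank channels by |β_PLS| descending (ties by ascending
index) and keep the shortest prefix whose coefficient-norm ratio
‖β_select‖₂/‖β_PLS‖₂ exceeds α. The strict “>” is relaxed to “≥” at the
boundary α = 1 so selection always terminates. The final model is PLS
refit on the selected channels.

**FSS.** Greedy forward stepwise OLS from the intercept-only model,
adding at each step the channel with the largest SSR decrease (ties by
ascending index). The path is computed by progressive Gram–Schmidt
orthogonalization — O(n·p) per step, no matrix inversions — and capped at
min(p, n−2) so the OLS fits stay well-posed with an intercept. The final
size is the BIC argmin along the path, possibly zero (intercept only).

**Enet-BETA.** The six-step procedure described in the README. Design
points that were genuinely open:

* *Candidate sizes.* Prefixes that extend past the elastic-net support
  add only channels the penalty already judged uninformative, so the
  RMSEP curve runs over sizes 1…m with m the support size; a
  `full_path` flag restores the literal 1…p scan.
* *Curve evaluation.* Scoring prefixes on the final test set leaks test
  information into selection, so the default policy is seeded 9-fold CV
  RMSEP on the training set; `eval_policy="holdout"` scores on a
  supplied held-out set for workflows that accept that trade-off. Fold
  partitions are fixed once per selection run, and prefix refits are
  warm-started from the previous prefix (the prefixes are nested), which
  makes the m×K refits cheap.
* *Prefix penalties.* Prefix refits reuse the full-fit (λ₁, λ₂) rather
  than re-tuning per prefix — deterministic, fast, and consistent with
  ranking and refitting being the same estimator.
* *Ties.* The curve argmin takes the smallest size; the relaxation rule
  returns i\* itself when no smaller size qualifies, and a zero RMSEP at
  a smaller size qualifies only when the optimum is also zero.

The relaxation rule is a fixed ratio threshold, not a calibrated test:
no null distribution is specified for it, and the "confidence level"
λ should be read as an accuracy-sacrifice budget (RMSEP within a factor
1/λ of the best).

## Synthetic data generator

`generate_spectra` emulates the structure that makes spectrum calibration
hard, with these defaults as the package's study conditions:

* **Smooth collinear backbone** — 6 latent Gaussian peak profiles
  (centres spread over the channel axis with jitter, widths p/12…p/6),
  mixed with random per-sample loadings; this carries 70% of each
  channel's variance (`PEAK_WEIGHT = 0.7`), chosen so the smooth
  component dominates as in real absorbance spectra.
* **Controlled adjacency** — the remaining 30% is an AR(1) process
  across channels. Its parameter is *calibrated from rho*: since the
  peak component alone correlates near 1 between neighbours, the AR
  parameter φ is solved from rho ≈ w·c_peak + (1−w)·φ so that the
  realized median adjacent-channel correlation tracks the requested
  `rho` (clamped to [0, 1); for very small rho the peaks set a floor).
  At rho = 0.95 and n = 400 the realized median is ≈ 0.95, the regime
  where adjacent channels are near-interchangeable.
* **Planted truth** — k_true channels in up to three contiguous runs
  (with one channel of clearance between runs), coefficients ±uniform
  [0.5, 1.5] with an independent random sign per channel. The truth is
  stored on the raw X scale so y = X·β + const + noise holds exactly.
* **Noise** — i.i.d. Gaussian with variance set from the realized signal
  variance so var(signal)/var(noise) equals the requested SNR (within
  sampling error; tested at 10% for n = 400).
* Channels are dressed with a smooth deterministic baseline and gain so
  the raw data have spectrum-like units; standardization removes both.

What the generator does **not** emulate: physical Beer–Lambert forward
modelling, wavelength-dependent (heteroscedastic) noise, baseline drift
between samples, instrument batch effects, and nonlinearity at high
absorbance. Passing tests therefore demonstrate correct behavior under
controlled collinearity and sparsity, not performance on any particular
real instrument.

A consequence worth stating explicitly, because the tests compute it:
with ± signs drawn independently on contiguous clusters of ~0.95-
correlated channels, an opposite-sign near-duplicate pair carries only
≈ 2(1−ρ) of the signal variance a same-sign pair would, so part of the
planted support can be statistically almost invisible at finite SNR.
Exact-support sensitivity of *any* selector is bounded in this regime,
and the relaxation step — whose whole purpose is to drop channels that
do not change RMSEP — prunes near-duplicates of already-selected
channels first. The support-recovery study in the acceptance test
reflects this: Enet-BETA selects essentially no false positives and is
never larger than the elastic-net support, while its sensitivity sits
well below 1 at the default confidence level.

## Problem sizes

The test suite and the acceptance script run the recovery study at
n = 400, p = 100, k_true = 10, rho = 0.95, SNR = 50 over 20 seeds, and
module tests use problems from 4×1 up to 400×100 — sizes at which every
oracle (exhaustive CV re-evaluation, per-step exhaustive forward
selection, closed-form orthonormal solutions) can be recomputed exactly.

## Known limitations

* Single response only; the multi-response extensions of PLS are not
  exposed.
* No spectral preprocessing (SNV, MSC, derivatives, baseline
  correction); inputs are modelled as-is.
* The coordinate-descent solver certifies optima but does not compute
  regularization paths; grid search refits each penalty pair (with warm
  starts inside a selection run only).
* BIC values are comparable only within one dataset (profiled-likelihood
  constants are dropped).
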