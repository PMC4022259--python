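# Methods

This note records the models dissolvekit implements, the defaults it ships
with and why, the numerical choices, and what the synthetic-data studies do
and do not demonstrate.

## Sampling-volume correction

An autosampler that withdraws an aliquot V_s at each time point removes
both medium and dissolved drug. Two correction conventions are implemented
behind `mode`:

- **as-printed** (default): the multiplicative form common in the
  dissolution literature, F_i = C_i·V_i / (Dose − Σ_{j<i} C_j·V_s), with
  vessel volume V_i = V_or − (i−1)·V_s without replacement and V_i = V_or
  with replacement. The (i−1) counts aliquots withdrawn *before* the
  current draw — the only reading under which the first time point needs no
  correction. The running sum covers draws 1..i−1 and is empty at i = 1.
- **mass-balance**: the additive accounting
  F_i = [C_i·V_i + Σ_{j<i} C_j·V_s] / Dose.

The two coincide at the first time point, whenever V_s = 0, and as
dissolution completes; they differ mid-profile. Both are kept because both
appear in practice; the as-printed form is the default for fidelity with
the published convention. A denominator that reaches zero (drug carried
away by sampling equals the dose) raises an error rather than clipping —
silent repair would fabricate data. `generate_raw_concentrations` inverts
either recurrence exactly, which yields a machine-precision roundtrip test
of the whole pathway (observed worst case ≈ 3e−14 over random doses,
volumes and curves).

t = 0 rows in input CSVs are dropped with a logged notice: every downstream
rule (minimum three points, f2 itself) excludes t = 0.

## f2 and its applicability rules

f2 = 50·log10{[1 + MSD]^(−1/2)·100} with MSD the mean squared difference
of the two mean profiles over the points used. The statistic is computed on
mean profiles only (its definition averages over units); per-unit variants
are out of scope. No clamp is applied: MSD > 9999 drives f2 below zero and
the value is returned as computed with a warning, since the formula has
none.

Time-point selection honors the one-point-over-85% rule: all points up to
and including the first at which the policy-selected profile(s) exceed 85%
are kept. The default policy `either` truncates at the first crossing by
either product; `both`, `reference` and `all_points` are provided because
published comparisons report both truncated and all-points results, and the
package deliberately reports whichever the caller asks for without
inventing a verdict hierarchy between them.

The rule engine reports rather than raises. "Early" time points for the
CV rule (≤ 20% early, ≤ 10% later) are the first half of included points,
at least the first — the guideline phrase is not defined precisely, so the
cutoff is configurable (`early_fraction`). CV uses the sample SD (n−1
denominator, the regulatory convention). A zero mean with zero SD gives
CV = 0; CV is never reported as infinity. Any CV above 15% triggers a
warning recommending multivariate (confidence-region) comparison, which
this package does not implement.

## Bootstrap f2

Units are resampled with replacement independently within each batch
(resample size = original unit count), the two mean profiles and their f2
recomputed per replicate; the interval is the equal-tailed percentile of
the replicate distribution by default (B = 1000, level 0.90), with BCa
available (bias correction from the replicate CDF at the point estimate;
acceleration from a delete-one-unit jackknife pooled over both batches)
because the literature on bootstrap f2 favors bias-corrected intervals.
Everything is deterministic given the seed. When both batches have zero
within-batch variance every resample is mathematically the original batch,
so the replicates are set identically to the point estimate and the
interval has width zero.

**Calibration study.** The coverage simulation uses two distinct power-law
products (k = 12, n = 0.35 vs k = 7, n = 0.40 over 10–60 min; population
f2 ≈ 46, i.e. near the similarity boundary where the statistic actually
decides something), 12 units, within-unit SD 3%, between-unit SD 2%
(CV ≈ 5–12%, consistent with profiles that pass the CV rules), B = 500,
200 simulated studies. Observed coverage of the nominal 90% percentile
interval is ≈ 82–88% depending on seed — the familiar mild undercoverage
of percentile intervals at n = 12.

**Known limitation:** for *nearly identical* products (true MSD of a few
%²), the plug-in f2 is biased low — sampling noise inflates the MSD by
the variance of the mean difference (here ≈ 2·(3² + 2²)/12 ≈ 2.2 %²),
which is material only when the true MSD is comparable. In that regime the
percentile interval undercovers the population f2 (≈ 76% observed at
population f2 ≈ 81 under the same noise). This is a property of the
statistic, not of the resampling; users comparing near-identical profiles
should read the interval as describing the *plug-in* f2.

## Kinetic models

Forward predictors map parameters and minutes to percent dissolved.
Choices worth recording:

- **Lag variant**: F clamps to 0 for t ≤ T_lag (no release before onset; a
  negative base under a real exponent is undefined). The *fitting*
  parameterization leaves T_lag unbounded so the optimizer can explore;
  a fitted negative lag is caught by the plausibility screen instead.
- **Burst variant**: F₀ is unbounded during fitting for the same reason —
  a grossly negative fitted burst is exactly the pathology the
  plausibility-aware ranking exists to demote.
- **Baker–Lonsdale** is defined implicitly, LHS(F) = (3/2)[1−(1−F/100)^(2/3)]
  − F/100 = k_BL·t; the physical constants it condenses are not modelled
  separately — only k_BL is exposed. LHS is strictly increasing from 0 to
  1/2 on [0, 100], so prediction inverts it with 80 vectorized bisection
  steps on the bracket (interval 100·2⁻⁸⁰, far below any tolerance; no
  convergence failures possible). F = 100 wherever k_BL·t ≥ 1/2. Fitting
  uses F-space residuals so all models share one objective.
- **Higuchi / Hixson–Crowell** use their standard closed forms
  (k_H·√t and 100·[1−(1−k_HC·t)³] on k_HC·t ≤ 1): adopted from the general
  literature, as is conventional.
- **Mechanism classification**: exponent at the lower cutoff labels Fickian
  (the cutoff is listed in the Fickian row of the standard table); at the
  upper cutoff, case II; above the upper cutoff the case-II label is kept
  with a boundary note — no "super case II" category is invented.
- **Power-law truncation** (F < 60%) is a separate operation, applied by
  the CLI for power-law-family fits unless `--no-truncate`; `fit_model`
  itself never truncates, since the early-portion rule is general practice
  rather than absolute.

## Fitting

Unweighted least squares (a weighted hook exists but is off by default,
matching the additive-noise generator so recovery tests are internally
consistent), minimized by Nelder–Mead: the simplex is robust to the strong
log-scale coupling between k and n. Defaults: 8 jittered restarts on top of
deterministic starting points, xatol = fatol = 1e−10, 5000 iterations per
restart, seed 0. Starting points: k from the first positive observation
(at n = 0.5), n = 0.5, T_lag = 0, F₀ = first observation; plus the log-log
linearized estimate when all F > 0; plus, for the lag/burst variants, a
warm start at the plain power-law optimum with the extra parameter at 0 —
Nelder–Mead never worsens its best vertex, so the nested models provably
fit at least as well as the plain one. Jitter is multiplicative
(log-normal, σ = 0.4) for positive-scale parameters and additive for
T_lag/F₀. Bounds are enforced by an additive quadratic penalty (10⁸ ×
violation²), keeping the simplex unconstrained. Fits are bit-reproducible
given the seed.

The log-log alternative (`fit_kp_linearized`) is ordinary least squares of
log10 F on log10 t. On additive noise its exponent differs systematically
from the nonlinear estimate because the log transform distorts the error
structure; the test suite demonstrates the gap as seed-stable rather than
asserting its sign.

Goodness of fit: R² = 1 − SSres/SStot, R²adj = 1 − (n−1)/(n−p)(1−R²),
AIC = n·ln(SSres) + 2p, MSC = ln(SStot/SSres) − 2p/n — the standard
unweighted-SS forms used across dissolution software. MSC ≡ ln(SStot) −
AIC/n, so AIC and MSC orderings coincide on shared data; the suite checks
this numerically. Degenerate inputs are flagged, not raised: constant
observations leave the R² family NaN; a perfect fit reports AIC/MSC as
∓∞ sentinels.

Ranking demotes implausible fits (k ≤ 0, n ≤ 0, F₀ ∉ [0, 100),
T_lag ∉ [0, max t)) below every plausible fit regardless of criterion,
recording each violation. Standard errors or intervals on kinetic
parameters are not provided.

## Synthetic data

The generators emulate a multi-unit dissolution run: a smooth kinetic mean
curve, a per-unit Gaussian offset (content uniformity / unit-to-unit
variability) and independent Gaussian observation noise (assay scatter).
Defaults used across the simulation studies: 12 units, six time points in
the 5–60 min window, within-unit SD 1–3%, between-unit SD 0–2% — a
well-behaved immediate/modified-release profile with CVs comfortably under
the 15% regulatory attention threshold. Clipping to [0, 100] is off in
recovery studies (it biases estimates near the extremes) and available for
realism demonstrations.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: correlated residuals along the time
axis, heteroscedastic assay error, non-Gaussian outliers (capsule rupture,
coning), inter-vessel hydrodynamic differences, and model misspecification
(real profiles rarely follow any single kinetic law exactly). Parameter
recovery at the stated noise levels (median |n̂ − 0.43| ≈ 0.02 at 1%
noise) should be read as "the estimator adds little error on top of the
data's own", not as an accuracy claim for arbitrary formulations.

## Problem sizes

Simulation studies ship at: 200 replicates for parameter recovery, 50
datasets for the nested-dominance and ranking-identity checks, 25 for the
optimizer-versus-grid oracle (two-stage 200×200 grid), 200 studies × 500
resamples for bootstrap coverage, 100 random cases for the correction
roundtrip. These sizes give stable medians/rates while keeping the full
verification run around a minute on one CPU.
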