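"""f2 similarity, regulatory applicability rules and bootstrap intervals.

The similarity factor f2 compares the mean dissolution profiles of a
reference and a test product over a shared time grid:

    f2 = 50 * log10{ [1 + (1/n) * sum_t (R_t - T_t)^2]^(-1/2) * 100 }

where ``R_t`` and ``T_t`` are mean percent dissolved at time ``t`` and
``n`` is the number of time points used.  Identical profiles give 100;
values of 50 or more declare the profiles similar (a mean squared
difference of 99, about 10% average offset, sits exactly at 50).  The
formula has no clamp: a mean squared difference above 9999 drives f2 below
zero, and such values are returned as computed with a warning flag.

Regulatory guidance restricts when f2 may be used; `check_applicability`
evaluates those conditions as a rule engine (at least 3 time points
excluding t=0, 12 units per product, at most one point above 85% dissolved,
identical grids, CV limits, the very-rapidly-dissolving shortcut, and a
recommendation to use multivariate methods when CV exceeds 15% — the
multivariate procedure itself is out of scope here).

f2 has no closed-form sampling distribution, so `bootstrap_f2` resamples
dosage units with replacement within each batch to attach a confidence
interval (percentile or BCa) to the point estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dissolution_data import DissolutionBatch, summarize

__all__ = [
    "RuleOutcome",
    "F2Result",
    "BootstrapF2Result",
    "f2",
    "select_timepoints",
    "check_applicability",
    "bootstrap_f2",
    "compare_profiles",
    "TIMEPOINT_POLICIES",
]

TIMEPOINT_POLICIES = ("either", "both", "reference", "all_points")

#: Mean percent dissolved above which a time point counts as "over 85%".
RELEASE_CAP = 85.0
#: Minutes within which both products >= 85% makes f2 unnecessary.
RAPID_WINDOW_MIN = 15.0


@dataclass(frozen=True)
class RuleOutcome:
    """One applicability rule's verdict: pass, fail, warn or info."""

    rule: str
    status: str
    message: str


@dataclass
class F2Result:
    """f2 similarity statistic with the applicability audit trail."""

    value: float
    n_points: int
    times_used: np.ndarray
    similar: bool
    applicability: list[RuleOutcome] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class BootstrapF2Result:
    """Bootstrap distribution and confidence interval for f2."""

    point: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    b: int
    seed: int
    method: str
    ci_level: float = 0.90


def _f2_from_msd(msd) -> np.ndarray:
    return 50.0 * np.log10(100.0 / np.sqrt(1.0 + np.asarray(msd, dtype=float)))


def f2(ref_mean, test_mean) -> float:
    """Similarity factor between two aligned mean percent-dissolved series.

    Returns the statistic as computed, uncapped; a value below 0 (possible
    only for mean squared differences above 9999) triggers a RuntimeWarning.
    """
    r = np.asarray(ref_mean, dtype=float)
    t = np.asarray(test_mean, dtype=float)
    if r.shape != t.shape or r.ndim != 1 or r.size < 1:
        raise ValueError("ref and test series must be 1-D and the same length")
    value = float(_f2_from_msd(np.mean((r - t) ** 2)))
    if value < 0:
        warnings.warn(
            f"f2 = {value:.2f} is below 0 (mean squared difference > 9999); "
            "reported uncapped", RuntimeWarning, stacklevel=2,
        )
    return value


def select_timepoints(ref_mean, test_mean, times, policy: str = "either") -> np.ndarray:
    """Indices of the time points an f2 comparison should use.

    Guidance allows at most one point after a profile passes 85% dissolved,
    so all points up to and including the first such point are kept.  The
    `policy` decides whose crossing truncates the grid: ``"either"`` product
    (default), ``"both"`` products jointly, the ``"reference"`` alone, or
    ``"all_points"`` to keep every collected point.
    """
    if policy not in TIMEPOINT_POLICIES:
        raise ValueError(f"policy must be one of {TIMEPOINT_POLICIES}")
    r = np.asarray(ref_mean, dtype=float)
    t = np.asarray(test_mean, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (r.shape == t.shape == times.shape):
        raise ValueError("ref, test and times must be aligned")
    if policy == "all_points":
        return np.arange(times.size)
    if policy == "either":
        over = (r > RELEASE_CAP) | (t > RELEASE_CAP)
    elif policy == "both":
        over = (r > RELEASE_CAP) & (t > RELEASE_CAP)
    else:
        over = r > RELEASE_CAP
    if not over.any():
        return np.arange(times.size)
    first = int(np.argmax(over))
    return np.arange(first + 1)


def check_applicability(
    ref: DissolutionBatch,
    test: DissolutionBatch,
    *,
    times_idx: np.ndarray | None = None,
    early_fraction: float = 0.5,
) -> list[RuleOutcome]:
    """Evaluate the f2 applicability conditions; rules report, never raise.

    `times_idx` restricts the audit to the time points actually entering the
    comparison (defaults to every shared point).  "Early" time points for
    the CV rule are the first `early_fraction` of included points, at least
    the first one.
    """
    outcomes: list[RuleOutcome] = []
    same_grid = ref.times.size == test.times.size and np.allclose(ref.times, test.times)
    outcomes.append(
        RuleOutcome(
            "identical_time_grids", "pass" if same_grid else "fail",
            "sampling times match" if same_grid
            else "the two products were sampled on different time grids",
        )
    )
    if not same_grid:
        return outcomes
    times = ref.times if times_idx is None else ref.times[np.asarray(times_idx)]
    idx = np.arange(ref.times.size) if times_idx is None else np.asarray(times_idx)

    n_pts = times.size
    outcomes.append(
        RuleOutcome(
            "min_three_timepoints", "pass" if n_pts >= 3 else "fail",
            f"{n_pts} shared time point(s) excluding t=0 (minimum 3)",
        )
    )
    for batch in (ref, test):
        if batch.n_units == 12:
            status, msg = "pass", f"{batch.label}: 12 dosage units"
        elif batch.n_units < 12:
            status = "fail"
            msg = f"{batch.label}: only {batch.n_units} dosage units (guidance requires 12)"
        else:
            status = "warn"
            msg = f"{batch.label}: {batch.n_units} dosage units (guidance expects 12)"
        outcomes.append(RuleOutcome("twelve_units", status, msg))

    sums = {b.label: summarize(b) for b in (ref, test)}
    for batch in (ref, test):
        mean = sums[batch.label].mean_pct[idx]
        n_over = int((mean > RELEASE_CAP).sum())
        outcomes.append(
            RuleOutcome(
                "one_point_over_85", "pass" if n_over <= 1 else "fail",
                f"{batch.label}: {n_over} included point(s) above {RELEASE_CAP:g}% "
                "(at most one allowed)",
            )
        )

    n_early = max(1, int(math.floor(n_pts * early_fraction)))
    cv_ok, cv_known = True, True
    for batch in (ref, test):
        cv = sums[batch.label].cv_pct[idx]
        if np.isnan(cv).any():
            cv_known = False
            continue
        if np.any(cv[:n_early] > 20.0) or np.any(cv[n_early:] > 10.0):
            cv_ok = False
    if not cv_known:
        outcomes.append(
            RuleOutcome("cv_limits", "warn",
                        "CV undefined (single-unit batch); rule not assessable")
        )
    else:
        outcomes.append(
            RuleOutcome(
                "cv_limits", "pass" if cv_ok else "fail",
                f"CV <= 20% over the first {n_early} point(s) and <= 10% after"
                if cv_ok else
                f"CV exceeds 20% in the first {n_early} point(s) or 10% later",
            )
        )

    early = ref.times <= RAPID_WINDOW_MIN
    rapid = bool(early.any()) and all(
        bool((sums[b.label].mean_pct[early] >= RELEASE_CAP).any()) for b in (ref, test)
    )
    if rapid:
        outcomes.append(
            RuleOutcome(
                "very_rapidly_dissolving", "info",
                f"both products >= {RELEASE_CAP:g}% dissolved within "
                f"{RAPID_WINDOW_MIN:g} min: very rapidly dissolving; similar without f2",
            )
        )
    if cv_known:
        any_high_cv = any(
            bool((sums[b.label].cv_pct[idx] > 15.0).any()) for b in (ref, test)
        )
        if any_high_cv:
            outcomes.append(
                RuleOutcome(
                    "cv_over_15_multivariate", "warn",
                    "within-batch CV exceeds 15%: a multivariate confidence-region "
                    "comparison is recommended over f2 (not implemented here)",
                )
            )
    return outcomes


def compare_profiles(
    ref: DissolutionBatch,
    test: DissolutionBatch,
    policy: str = "either",
) -> F2Result:
    """Full f2 comparison: select time points, compute f2, audit the rules."""
    for b in (ref, test):
        if b.value_kind != "percent_dissolved":
            raise ValueError(f"{b.label}: correct to percent_dissolved before comparing")
    if ref.times.size != test.times.size or not np.allclose(ref.times, test.times):
        raise ValueError("products must share a time grid for f2")
    r_mean, t_mean = ref.mean_profile(), test.mean_profile()
    idx = select_timepoints(r_mean, t_mean, ref.times, policy=policy)
    notes: list[str] = []
    if idx.size < 3:
        notes.append(f"only {idx.size} time point(s) selected; below the minimum of 3")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        value = f2(r_mean[idx], t_mean[idx])
    notes.extend(str(w.message) for w in caught)
    rules = check_applicability(ref, test, times_idx=idx)
    return F2Result(
        value=value,
        n_points=int(idx.size),
        times_used=ref.times[idx].copy(),
        similar=bool(50.0 <= value <= 100.0),
        applicability=rules,
        warnings=notes,
    )


def _bca_interval(reps: np.ndarray, point: float, jack: np.ndarray, level: float):
    b = reps.size
    p0 = float(np.clip(np.mean(reps < point), 0.5 / b, 1.0 - 0.5 / b))
    z0 = norm.ppf(p0)
    u = jack.mean() - jack
    denom = float(np.sum(u**2)) ** 1.5
    a = float(np.sum(u**3)) / (6.0 * denom) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for z_alpha in (norm.ppf(alpha), norm.ppf(1.0 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(reps, norm.cdf(adj))))
    return lo_hi[0], lo_hi[1]


def bootstrap_f2(
    ref: DissolutionBatch,
    test: DissolutionBatch,
    b: int = 1000,
    seed: int = 0,
    method: str = "percentile",
    ci_level: float = 0.90,
    times_idx: np.ndarray | None = None,
) -> BootstrapF2Result:
    """Unit-level bootstrap confidence interval for f2.

    Each replicate draws dosage units with replacement, independently within
    the reference and test batches (resample size equal to the original unit
    count), recomputes the two mean profiles and their f2.  The interval is
    taken from the replicate distribution: equal-tailed percentile by
    default, or bias-corrected-and-accelerated (``"bca"``) with a delete-one
    unit jackknife for the acceleration.  Deterministic given `seed`.
    """
    if method not in ("percentile", "bca"):
        raise ValueError("method must be 'percentile' or 'bca'")
    for batch in (ref, test):
        if batch.value_kind != "percent_dissolved":
            raise ValueError(f"{batch.label}: percent_dissolved data required")
        if batch.n_units < 3:
            raise ValueError(f"{batch.label}: at least 3 units needed to bootstrap")
    if ref.times.size != test.times.size or not np.allclose(ref.times, test.times):
        raise ValueError("products must share a time grid")
    if b < 100:
        warnings.warn(f"b = {b} resamples is too few for a stable interval",
                      UserWarning, stacklevel=2)

    cols = np.arange(ref.times.size) if times_idx is None else np.asarray(times_idx)
    r_data = ref.units[:, cols]
    t_data = test.units[:, cols]
    point = float(_f2_from_msd(np.mean((r_data.mean(0) - t_data.mean(0)) ** 2)))

    rng = np.random.default_rng(seed)
    nr, nt = r_data.shape[0], t_data.shape[0]
    if np.ptp(r_data, axis=0).max() == 0 and np.ptp(t_data, axis=0).max() == 0:
        # zero within-batch variance: every resample is the original batch
        reps = np.full(b, point)
    else:
        r_means = r_data[rng.integers(0, nr, size=(b, nr))].mean(axis=1)
        t_means = t_data[rng.integers(0, nt, size=(b, nt))].mean(axis=1)
        reps = _f2_from_msd(np.mean((r_means - t_means) ** 2, axis=1))

    if float(np.ptp(reps)) == 0.0:
        lo = hi = float(reps[0])
    elif method == "percentile":
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = (float(q) for q in np.quantile(reps, [alpha, 1.0 - alpha]))
    else:
        jack = []
        for i in range(nr):
            m = np.delete(r_data, i, axis=0).mean(0)
            jack.append(float(_f2_from_msd(np.mean((m - t_data.mean(0)) ** 2))))
        for i in range(nt):
            m = np.delete(t_data, i, axis=0).mean(0)
            jack.append(float(_f2_from_msd(np.mean((r_data.mean(0) - m) ** 2))))
        lo, hi = _bca_interval(reps, point, np.asarray(jack), ci_level)
    return BootstrapF2Result(
        point=point, replicates=reps, ci_low=lo, ci_high=hi,
        b=b, seed=seed, method=method, ci_level=ci_level,
    )
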