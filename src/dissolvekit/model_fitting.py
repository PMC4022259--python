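"""Nonlinear least-squares fitting of release models and model selection.

Parameters are estimated by minimizing the unweighted residual sum of
squares between observed and predicted percent dissolved with the
Nelder-Mead simplex — robust for the power-law family, whose rate and
exponent are strongly coupled on the log scale — restarted from several
jittered heuristic initial points (seeded, hence deterministic).  Parameter
bounds are enforced by an additive quadratic penalty so the simplex itself
stays unconstrained.  The classical log-log linearization (ordinary least
squares of log10 F on log10 t) is provided as the historical alternative;
on noisy data its exponent estimate differs systematically from the
nonlinear one because the log transform distorts the error structure.

Goodness of fit follows dissolution-software convention, all built on the
residual sum of squares SSres and total sum of squares SStot (about the
observation mean), with n observations and p parameters:

    R^2      = 1 - SSres / SStot
    R^2_adj  = 1 - (n - 1) / (n - p) * (1 - R^2)
    AIC      = n * ln(SSres) + 2 p
    MSC      = ln(SStot / SSres) - 2 p / n

MSC equals ln(SStot) - AIC / n identically, so AIC and MSC always rank a
set of fits to the same data identically.

Ranking is plausibility-aware: a fit whose parameters are physically
impossible (negative rate or exponent, burst fraction outside [0, 100),
lag beyond the observed window) is demoted below every plausible fit no
matter how good its criterion value — a large negative fitted burst, for
instance, can produce the best adjusted R^2 of a candidate set while being
physically meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .release_models import ModelSpec, bl_lhs, get_model

__all__ = [
    "FitResult",
    "GofStats",
    "KineticCurveFit",
    "fit_model",
    "fit_kp_linearized",
    "goodness_of_fit",
    "check_plausibility",
    "rank_models",
    "RANK_CRITERIA",
]

RANK_CRITERIA = ("r2_adj", "aic", "msc")

_PENALTY = 1e8
_BIG = 1e12


@dataclass(frozen=True)
class GofStats:
    """Goodness-of-fit criteria for one fitted model.

    `flags` carries degeneracy notes: constant observations leave the R^2
    family undefined (NaN); a perfect fit sends AIC/MSC to -inf/+inf.
    """

    r2: float
    r2_adj: float
    aic: float
    msc: float
    ss_res: float
    ss_tot: float
    flags: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.r2, self.r2_adj, self.aic, self.msc))


@dataclass
class FitResult:
    """A kinetic model fit: estimates, fit quality and plausibility."""

    model: str
    params: dict[str, float]
    ss_res: float
    r2: float
    r2_adj: float
    aic: float
    msc: float
    n_obs: int
    n_params: int
    converged: bool
    n_restarts_used: int
    plausible: bool
    plausibility_notes: tuple[str, ...]
    gof_flags: tuple[str, ...] = ()
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    f_obs: np.ndarray = field(default_factory=lambda: np.empty(0))


def goodness_of_fit(f_obs, f_pred, n_params: int) -> GofStats:
    """R^2, adjusted R^2, AIC and MSC for predictions against observations.

    Degenerate cases are flagged rather than raised: SStot = 0 (constant
    observations) leaves the R^2 family NaN; SSres = 0 (perfect fit) yields
    AIC = -inf and MSC = +inf sentinels.
    """
    y = np.asarray(f_obs, dtype=float)
    yhat = np.asarray(f_pred, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("f_obs and f_pred must be aligned 1-D series")
    n = y.size
    if n <= n_params:
        raise ValueError(f"need more observations ({n}) than parameters ({n_params})")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    flags: list[str] = []
    if ss_tot == 0.0:
        r2 = r2_adj = float("nan")
        flags.append("constant observations: R^2 family undefined")
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (n - 1) / (n - n_params) * (1.0 - r2)
    if ss_res == 0.0:
        aic, msc = float("-inf"), float("inf")
        flags.append("perfect fit: AIC/MSC at infinite sentinels")
    else:
        aic = n * np.log(ss_res) + 2.0 * n_params
        msc = (np.log(ss_tot / ss_res) if ss_tot > 0 else float("nan")) - 2.0 * n_params / n
    return GofStats(r2=r2, r2_adj=r2_adj, aic=float(aic), msc=float(msc),
                    ss_res=ss_res, ss_tot=ss_tot, flags=tuple(flags))


def fit_kp_linearized(times, f_obs) -> tuple[float, float, float]:
    """Power-law fit by log-log linear regression.

    Ordinary least squares of log10(F) on log10(t): the slope estimates the
    release exponent n, ``10**intercept`` the rate constant k.  Returns
    ``(k, n, r2_loglog)`` with R^2 taken in log space.  Requires strictly
    positive F and t.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(f_obs, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("need aligned 1-D series with at least 2 points")
    if np.any(t <= 0) or np.any(y <= 0):
        raise ValueError("log-log fit requires strictly positive times and F")
    lx, ly = np.log10(t), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(10.0**intercept), float(slope), float(r2)


def check_plausibility(
    spec: ModelSpec, params: Sequence[float], times
) -> tuple[bool, tuple[str, ...]]:
    """Physical-plausibility screen for fitted kinetic parameters.

    Rate constants and the release exponent must be positive; a burst
    fraction must lie in [0, 100); a lag time must be non-negative and
    shorter than the observed window.
    """
    notes: list[str] = []
    t_max = float(np.max(np.asarray(times, dtype=float)))
    for name, value in zip(spec.param_names, params):
        if name.startswith("k") and value <= 0:
            notes.append(f"{name} = {value:.4g} is not positive")
        elif name == "n" and value <= 0:
            notes.append(f"n = {value:.4g} is not positive")
        elif name == "f0" and not (0.0 <= value < 100.0):
            notes.append(f"F0 = {value:.4g} outside [0, 100)")
        elif name == "t_lag" and not (0.0 <= value < t_max):
            notes.append(f"T_lag = {value:.4g} outside [0, max time)")
    return (len(notes) == 0), tuple(notes)


def _heuristic_init(spec: ModelSpec, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Data-driven starting point: k from the first positive observation."""
    pos = y > 0
    t1, f1 = (t[pos][0], y[pos][0]) if pos.any() else (t[0], max(y[0], 1.0))
    t_last, f_last = t[-1], max(min(y[-1], 99.9), 1e-3)
    name = spec.name
    if name == "korsmeyer_peppas":
        return np.array([max(f1, 1e-3) / np.sqrt(t1), 0.5])
    if name == "kp_tlag":
        return np.array([max(f1, 1e-3) / np.sqrt(t1), 0.5, 0.0])
    if name == "kp_f0":
        return np.array([max(f1, 1e-3) / np.sqrt(t1), 0.5, y[0]])
    if name == "higuchi":
        return np.array([max(f1, 1e-3) / np.sqrt(t1)])
    if name == "hixson_crowell":
        k = (1.0 - (1.0 - f_last / 100.0) ** (1.0 / 3.0)) / t_last
        return np.array([max(k, 1e-6)])
    if name == "baker_lonsdale":
        return np.array([max(float(bl_lhs(f_last)) / t_last, 1e-8)])
    raise ValueError(f"no initialization heuristic for {name}")  # pragma: no cover


def _candidate_inits(
    spec: ModelSpec, t: np.ndarray, y: np.ndarray,
    user_init: Sequence[float] | None,
    max_iter: int, xatol: float, fatol: float,
) -> list[np.ndarray]:
    """Unjittered starting points: heuristic, log-log, nested warm starts."""
    inits = [_heuristic_init(spec, t, y)]
    if user_init is not None:
        user_init = np.asarray(user_init, dtype=float)
        if user_init.size != spec.n_params:
            raise ValueError("init length does not match the model's parameter count")
        inits.insert(0, user_init)
    kp_family = spec.name in ("korsmeyer_peppas", "kp_tlag", "kp_f0")
    if kp_family and np.all(y > 0) and np.all(t > 0) and t.size >= 2:
        k_lin, n_lin, _ = fit_kp_linearized(t, y)
        if np.isfinite(k_lin) and np.isfinite(n_lin) and k_lin > 0 and n_lin > 0:
            extra = [0.0] * (spec.n_params - 2)
            inits.append(np.array([k_lin, n_lin, *extra]))
    if spec.name in ("kp_tlag", "kp_f0"):
        # warm-start at the plain power-law optimum with the extra term at 0:
        # Nelder-Mead never worsens its best vertex, so the nested fit is
        # guaranteed to do at least as well as the 2-parameter model.
        kp = get_model("korsmeyer_peppas")
        best = None
        for x0 in _candidate_inits(kp, t, y, None, max_iter, xatol, fatol):
            res = minimize(
                lambda p: _penalized_ss(kp, p, t, y), x0, method="Nelder-Mead",
                options={"maxiter": max_iter, "xatol": xatol, "fatol": fatol},
            )
            if best is None or res.fun < best.fun:
                best = res
        inits.append(np.array([*best.x, 0.0]))
    return inits


def _penalized_ss(
    spec: ModelSpec, params: np.ndarray, t: np.ndarray, y: np.ndarray,
    w: np.ndarray | None = None,
) -> float:
    """(Weighted) residual sum of squares plus quadratic out-of-bounds penalty."""
    penalty = 0.0
    clipped = np.array(params, dtype=float)
    for j, (lo, hi) in enumerate(spec.bounds):
        if lo is not None and params[j] < lo:
            penalty += _PENALTY * (lo - params[j]) ** 2
            clipped[j] = lo
        if hi is not None and params[j] > hi:
            penalty += _PENALTY * (params[j] - hi) ** 2
            clipped[j] = hi
    # evaluate strictly inside open bounds to keep the predictor defined
    for j, (lo, hi) in enumerate(spec.bounds):
        if lo is not None and clipped[j] <= lo:
            clipped[j] = lo + 1e-12
    with np.errstate(all="ignore"):
        try:
            pred = spec.predict(t, *clipped)
        except (ValueError, FloatingPointError):
            return _BIG + penalty
    if not np.all(np.isfinite(pred)):
        return _BIG + penalty
    resid2 = (y - pred) ** 2
    if w is not None:
        resid2 = w * resid2
    return float(np.sum(resid2)) + penalty


def _safe_predict(spec: ModelSpec, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the predictor, nudging params off open lower bounds."""
    p = np.array(params, dtype=float)
    for j, (lo, _) in enumerate(spec.bounds):
        if lo is not None and p[j] <= lo:
            p[j] = lo + 1e-12
    with np.errstate(all="ignore"):
        return np.asarray(spec.predict(t, *p), dtype=float)


class KineticCurveFit(BaseEstimator, RegressorMixin):
    """Fit one kinetic release model to a dissolution profile.

    A scikit-learn style regressor over time: ``fit(t, f_obs)`` estimates
    the model's parameters by multi-start Nelder-Mead on the residual sum
    of squares, ``predict(t)`` evaluates the fitted release curve.

    Parameters
    ----------
    model : str, default "korsmeyer_peppas"
        Registry name (or alias) of the kinetic model.
    n_restarts : int, default 8
        Number of jittered restarts beyond the deterministic starting
        points (heuristic, log-log, nested warm start).
    random_state : int, default 0
        Seed for the restart jitter; fits are bit-reproducible given the
        seed and inputs.
    max_iter : int, default 5000
        Nelder-Mead iteration cap per restart.
    xatol, fatol : float, default 1e-10
        Simplex-size and objective-change convergence tolerances.
    init : sequence of float, optional
        User-supplied starting point, tried first (unjittered).

    Attributes
    ----------
    params_ : ndarray
        Estimates, ordered as the model's ``param_names``.
    result_ : FitResult
        Full record: goodness of fit, convergence, plausibility.
    n_features_in_ : int
        Always 1 (time).
    """

    def __init__(
        self,
        model: str = "korsmeyer_peppas",
        n_restarts: int = 8,
        random_state: int = 0,
        max_iter: int = 5000,
        xatol: float = 1e-10,
        fatol: float = 1e-10,
        init: Sequence[float] | None = None,
    ):
        self.model = model
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.max_iter = max_iter
        self.xatol = xatol
        self.fatol = fatol
        self.init = init

    @staticmethod
    def _as_times(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be a 1-D array of times (or a single column)")
        return t

    def fit(self, X, y, sample_weight=None):
        spec = get_model(self.model)
        t = self._as_times(X)
        f_obs = np.asarray(y, dtype=float)
        weights = None
        if sample_weight is not None:
            weights = np.asarray(sample_weight, dtype=float)
            if weights.shape != f_obs.shape or np.any(weights < 0):
                raise ValueError("sample_weight must be non-negative and aligned")
        if t.shape != f_obs.shape:
            raise ValueError("times and observations must be aligned")
        if np.any(t <= 0):
            raise ValueError("all times must be positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t.size <= spec.n_params:
            raise ValueError(
                f"{t.size} observation(s) cannot identify {spec.n_params} parameter(s)"
            )

        rng = np.random.default_rng(self.random_state)
        bases = _candidate_inits(spec, t, f_obs, self.init,
                                 self.max_iter, self.xatol, self.fatol)
        starts = list(bases)
        t_span = float(t[-1] - t[0])
        for r in range(self.n_restarts):
            base = bases[r % len(bases)]
            jit = np.array(base, dtype=float)
            for j, name in enumerate(spec.param_names):
                if name == "t_lag":
                    jit[j] = abs(jit[j] + rng.normal(0.0, 0.15 * max(t_span, 1.0)))
                elif name == "f0":
                    jit[j] = jit[j] + rng.normal(0.0, 5.0)
                else:  # positive scale parameters: multiplicative jitter
                    jit[j] = max(abs(jit[j]), 1e-8) * np.exp(rng.normal(0.0, 0.4))
            starts.append(jit)

        best = None
        options = {"maxiter": self.max_iter, "xatol": self.xatol, "fatol": self.fatol}
        for x0 in starts:
            res = minimize(lambda p: _penalized_ss(spec, p, t, f_obs, weights), x0,
                           method="Nelder-Mead", options=options)
            if best is None or res.fun < best.fun:
                best = res

        params = np.asarray(best.x, dtype=float)
        pred = _safe_predict(spec, params, t)
        gof = goodness_of_fit(f_obs, pred, spec.n_params)
        plausible, notes = check_plausibility(spec, params, t)
        self.spec_ = spec
        self.params_ = params
        self.n_features_in_ = 1
        self.result_ = FitResult(
            model=spec.name,
            params={n: float(v) for n, v in zip(spec.param_names, params)},
            ss_res=gof.ss_res,
            r2=gof.r2, r2_adj=gof.r2_adj, aic=gof.aic, msc=gof.msc,
            n_obs=int(t.size), n_params=spec.n_params,
            converged=bool(best.success),
            n_restarts_used=len(starts),
            plausible=plausible, plausibility_notes=notes,
            gof_flags=gof.flags,
            times=t.copy(), f_obs=f_obs.copy(),
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("this KineticCurveFit instance is not fitted yet")
        return _safe_predict(self.spec_, self.params_, self._as_times(X))


def fit_model(
    model: str | ModelSpec,
    times,
    f_obs,
    init: Sequence[float] | None = None,
    *,
    n_restarts: int = 8,
    seed: int = 0,
    max_iter: int = 5000,
    xatol: float = 1e-10,
    fatol: float = 1e-10,
) -> FitResult:
    """Fit a kinetic model by multi-start Nelder-Mead; see `KineticCurveFit`."""
    name = model.name if isinstance(model, ModelSpec) else model
    est = KineticCurveFit(
        model=name, n_restarts=n_restarts, random_state=seed,
        max_iter=max_iter, xatol=xatol, fatol=fatol, init=init,
    )
    est.fit(times, f_obs)
    return est.result_


def _criterion_key(fit: FitResult, criterion: str) -> float:
    value = getattr(fit, criterion)
    sign = 1.0 if criterion == "aic" else -1.0  # aic ascending, others descending
    if np.isnan(value):
        return float("inf")
    return sign * value


def rank_models(fits: Sequence[FitResult], criterion: str = "r2_adj") -> list[FitResult]:
    """Order candidate fits, demoting implausible ones below all plausible.

    All fits must be on the same data.  Plausible fits are sorted by the
    criterion (adjusted R^2 and MSC descending, AIC ascending); implausible
    fits follow in the same criterion order, each carrying its
    `plausibility_notes`.
    """
    if criterion not in RANK_CRITERIA:
        raise ValueError(f"criterion must be one of {RANK_CRITERIA}")
    fits = list(fits)
    if not fits:
        return []
    ref_t, ref_y = fits[0].times, fits[0].f_obs
    for fit in fits[1:]:
        if not (np.array_equal(fit.times, ref_t) and np.array_equal(fit.f_obs, ref_y)):
            raise ValueError("rank_models requires fits on identical (times, f_obs)")
    return sorted(
        fits, key=lambda f: (0 if f.plausible else 1, _criterion_key(f, criterion))
    )
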