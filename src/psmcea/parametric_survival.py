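"""Censored maximum-likelihood survival fitting and curve contracts.

Fits each of the seven candidate families to (time, event) records by
maximizing the right-censored log likelihood

    l(theta) = sum_events ln f(t_i; theta) + sum_censored ln S(t_i; theta),

ranks converged fits by AIC (2k - 2 ln L) or BIC (k ln n - 2 ln L), and
exposes evaluable survival curves: fully parametric, KM step, or the
hybrid used for extrapolation — the KM estimate within follow-up spliced
at its last time to a fitted parametric tail, rescaled so the curve is
continuous at the splice.

The exponential fit is closed form (rate = events / total follow-up);
other families use multi-start quasi-Newton optimization on
log-transformed positive parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import distributions as dist
from .synthetic_trial import KMPoints

__all__ = [
    "FitResult",
    "SurvivalCurve",
    "ParametricCurve",
    "KMCurve",
    "HybridCurve",
    "log_likelihood",
    "fit_mle",
    "fit_all",
    "select_best",
    "survival_at",
    "median_survival",
    "fits_to_frame",
]

_GTOL = 1e-8


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def log_likelihood(family: str, params, ipd: pd.DataFrame) -> float:
    """Right-censored log likelihood; -inf if any point has zero likelihood."""
    p = dist.validate_params(family, params)
    if len(ipd) == 0:
        raise ValueError("ipd must be non-empty")
    time = ipd["time"].to_numpy(float)
    event = ipd["event"].to_numpy(int) == 1
    ll = 0.0
    if event.any():
        ll += float(np.sum(dist.logpdf(family, p, time[event])))
    if (~event).any():
        ll += float(np.sum(dist.logsf(family, p, time[~event])))
    return ll if np.isfinite(ll) else -np.inf


@dataclass(frozen=True)
class FitResult:
    family: str
    params: tuple[float, ...]
    loglik: float
    n: int
    aic: float
    bic: float
    converged: bool

    @classmethod
    def from_fit(cls, family, params, loglik, n, converged):
        k = dist.n_params(family)
        return cls(family=family, params=tuple(float(x) for x in params),
                   loglik=loglik, n=n,
                   aic=2 * k - 2 * loglik, bic=k * np.log(n) - 2 * loglik,
                   converged=converged)


def _log_moments(ipd):
    lt = np.log(ipd.loc[ipd["event"] == 1, "time"].to_numpy(float))
    if lt.size == 0:
        lt = np.log(ipd["time"].to_numpy(float))
    mu = float(np.mean(lt))
    sd = float(np.std(lt)) or 0.5
    return mu, sd


def _starts(family: str, ipd: pd.DataFrame) -> list[np.ndarray]:
    """Method-of-moments and exponential-equivalent starting points."""
    time = ipd["time"].to_numpy(float)
    d = max(int(ipd["event"].sum()), 1)
    rate = d / float(time.sum())
    scale = 1.0 / rate
    mu, sd = _log_moments(ipd)
    ev = ipd.loc[ipd["event"] == 1, "time"].to_numpy(float)
    if ev.size >= 2:
        m, v = float(np.mean(ev)), float(np.var(ev)) or 1.0
    else:
        m, v = scale, scale ** 2
    if family == "exponential":
        return [np.array([rate])]
    if family == "weibull":
        return [np.array([1.0, scale]), np.array([0.8, scale]), np.array([1.5, scale])]
    if family == "gamma":
        return [np.array([1.0, scale]), np.array([m * m / v, v / m])]
    if family == "gompertz":
        return [np.array([1e-3, rate]), np.array([0.05, rate]),
                np.array([-0.02, rate]), np.array([0.15, rate])]
    if family == "loglogistic":
        med = float(np.median(time))
        return [np.array([1.0, med]), np.array([1.5, med]), np.array([2.5, med])]
    if family == "lognormal":
        return [np.array([mu, sd]), np.array([np.log(scale), 1.0])]
    # generalized_gamma
    return [np.array([mu, sd, 0.5]), np.array([mu, sd, 1.0]),
            np.array([np.log(scale), 1.0, 1.0]), np.array([mu, sd, -0.5])]


def _pack(family, params):
    _, domains = dist.FAMILIES[family]
    return np.array([np.log(v) if d == "pos" else v for v, d in zip(params, domains)])


def _unpack(family, x):
    _, domains = dist.FAMILIES[family]
    return np.array([np.exp(v) if d == "pos" else v for v, d in zip(x, domains)])


def fit_mle(family: str, ipd: pd.DataFrame, init: Sequence[float] | None = None) -> FitResult:
    """Maximum-likelihood fit of one family.

    Uses the analytic MLE for the exponential; multi-start L-BFGS-B on
    transformed parameters otherwise.  ``converged`` is False if no start
    produced a finite optimum that passed the optimizer's own test.
    """
    if len(ipd) == 0:
        raise ValueError("ipd must be non-empty")
    n = len(ipd)
    if family == "exponential":
        d = int(ipd["event"].sum())
        total = float(ipd["time"].sum())
        if d == 0:
            return FitResult.from_fit(family, (np.nan,), -np.inf, n, False)
        rate = d / total
        return FitResult.from_fit(family, (rate,), log_likelihood(family, (rate,), ipd), n, True)

    starts = [np.asarray(init, float)] if init is not None else _starts(family, ipd)

    def nll(x):
        p = _unpack(family, x)
        try:
            return -log_likelihood(family, p, ipd)
        except dist.InvalidParameterError:
            return np.inf

    best, best_val, ok = None, np.inf, False
    for s0 in starts:
        try:
            x0 = _pack(family, s0)
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(x0)) or not np.isfinite(nll(x0)):
            continue
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"gtol": _GTOL, "maxiter": 500})
        if np.isfinite(res.fun) and res.fun < best_val:
            best, best_val, ok = res.x, float(res.fun), bool(res.success)
    if best is None:
        k = dist.n_params(family)
        return FitResult.from_fit(family, (np.nan,) * k, -np.inf, n, False)
    params = _unpack(family, best)
    return FitResult.from_fit(family, params, -best_val, n, ok)


def fit_all(ipd: pd.DataFrame, families: Sequence[str] | None = None) -> list[FitResult]:
    """Fit every requested family (default: all seven)."""
    families = list(families) if families is not None else sorted(dist.FAMILIES)
    return [fit_mle(f, ipd) for f in families]


def select_best(fits: Sequence[FitResult], criterion: str = "aic") -> str:
    """Family with the minimal information criterion among converged fits.

    Ties break toward fewer parameters, then lexicographic family name.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    ranked = [f for f in fits if f.converged]
    if not ranked:
        raise ValueError("no converged fits to select from")
    key = lambda f: (getattr(f, criterion), dist.n_params(f.family), f.family)
    return min(ranked, key=key).family


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Fit-comparison table (one row per family, AIC/BIC columns)."""
    return pd.DataFrame([
        {"family": f.family, "params": ";".join(f"{p:.6g}" for p in f.params),
         "loglik": f.loglik, "n": f.n, "aic": f.aic, "bic": f.bic,
         "converged": f.converged}
        for f in fits
    ])


# ---------------------------------------------------------------------------
# survival-curve contracts
# ---------------------------------------------------------------------------

class SurvivalCurve:
    """Evaluable S(t) for t >= 0 with S(0) = 1, non-increasing, in [0, 1]."""

    kind = "abstract"

    def survival(self, t) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ParametricCurve(SurvivalCurve):
    family: str
    params: tuple[float, ...]
    kind = "parametric"

    def survival(self, t):
        return dist.sf(self.family, self.params, t)

    @classmethod
    def from_fit(cls, fit: FitResult) -> "ParametricCurve":
        return cls(fit.family, fit.params)


@dataclass(frozen=True)
class KMCurve(SurvivalCurve):
    km: KMPoints
    kind = "km_step"

    def survival(self, t):
        return self.km.evaluate(t)


@dataclass(frozen=True)
class HybridCurve(SurvivalCurve):
    """KM step within follow-up, parametric tail beyond.

    For t <= t_max the KM value is returned; beyond, the parametric tail is
    scaled by KM(t_max)/S_param(t_max) so the spliced curve is continuous.
    """

    km: KMPoints
    tail: ParametricCurve
    t_max: float | None = None
    kind = "hybrid"

    def __post_init__(self):
        tm = self.t_max if self.t_max is not None else float(self.km.times[-1])
        object.__setattr__(self, "t_max", float(tm))
        s_tail = float(self.tail.survival(np.array([tm]))[0])
        s_km = float(self.km.evaluate(np.array([tm]))[0])
        scale = s_km / s_tail if s_tail > 0 else 0.0
        object.__setattr__(self, "_scale", scale)

    @property
    def continuity_scale(self) -> float:
        return self._scale

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape)
        head = t <= self.t_max
        if head.any():
            out[head] = self.km.evaluate(t[head])
        if (~head).any():
            out[~head] = np.clip(self._scale * self.tail.survival(t[~head]), 0.0, 1.0)
        return out


def survival_at(curve: SurvivalCurve, t) -> np.ndarray:
    """S(t) for t >= 0; scalar in, scalar-shaped array out."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return np.clip(curve.survival(t), 0.0, 1.0)


def median_survival(curve: SurvivalCurve, horizon: float = 5000.0, tol: float = 1e-6) -> float:
    """Time at which S(t) crosses 0.5, by bisection to *tol* months."""
    lo, hi = 0.0, 1.0
    while float(survival_at(curve, hi)) > 0.5:
        hi *= 2.0
        if hi > horizon:
            raise ValueError(f"survival stays above 0.5 out to {horizon} months")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if float(survival_at(curve, mid)) > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
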