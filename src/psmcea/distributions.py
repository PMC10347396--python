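"""Parametric survival distribution families.

Seven candidate families commonly used to extrapolate oncology trial
survival curves: exponential, gamma, generalized gamma, Gompertz, Weibull,
log-logistic and log-normal.  Each family exposes a log-density, a
log-survival function, a survival function and an inverse-transform
sampler, all parameterized on the time scale of months.

Parameter conventions
---------------------
exponential        (rate,)              S(t) = exp(-rate*t)
weibull            (shape, scale)       S(t) = exp(-(t/scale)^shape)
gamma              (shape, scale)       S(t) = Q(shape, t/scale)  (upper reg. gamma)
gompertz           (shape, rate)        S(t) = exp(-(rate/shape)*(e^{shape*t}-1))
loglogistic        (shape, scale)       S(t) = 1/(1+(t/scale)^shape)
lognormal          (mu, sigma)          S(t) = 1 - Phi((ln t - mu)/sigma)
generalized_gamma  (mu, sigma, Q)       Prentice parameterization (see below)

The generalized gamma uses the Prentice (mu, sigma, Q) form for numerical
stability: with z = (ln t - mu)/sigma and gam = Q^-2,

    f(t) = |Q| gam^gam / (sigma * t * Gamma(gam)) * exp(gam*(Q*z - e^{Q*z}))
    S(t) = 1 - I(gam, gam*e^{Q*z})   if Q > 0
         = I(gam, gam*e^{Q*z})       if Q < 0
         = 1 - Phi(z)                if Q = 0  (log-normal limit)

where I is the regularized lower incomplete gamma function.  Q = 1
recovers the Weibull family, Q = sigma the gamma family and Q = 0 the
log-normal, which the tests assert numerically.

The Gompertz shape may be negative, giving a bounded "cure fraction"
exp(rate/shape); samples falling in that fraction never fail and are
returned as ``inf`` (administrative censoring truncates them downstream).
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "n_params",
    "validate_params",
    "logpdf",
    "logsf",
    "sf",
    "sample",
    "prentice_to_stacy",
    "stacy_to_prentice",
]

#: family name -> (number of parameters, per-parameter domain)
#: domain code: "pos" = strictly positive, "real" = unconstrained
FAMILIES: dict[str, tuple[int, tuple[str, ...]]] = {
    "exponential": (1, ("pos",)),
    "gamma": (2, ("pos", "pos")),
    "generalized_gamma": (3, ("real", "pos", "real")),
    "gompertz": (2, ("real", "pos")),
    "weibull": (2, ("pos", "pos")),
    "loglogistic": (2, ("pos", "pos")),
    "lognormal": (2, ("real", "pos")),
}

_NEG_INF = -np.inf
_GG_Q_EPS = 1e-8  # below this |Q| the Prentice family is evaluated as log-normal


class UnknownFamilyError(ValueError):
    """Raised when a distribution family name is not one of the seven."""


class InvalidParameterError(ValueError):
    """Raised when a parameter vector violates its family's domain."""


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise UnknownFamilyError(
            f"unknown distribution family {family!r}; expected one of {sorted(FAMILIES)}"
        )


def n_params(family: str) -> int:
    """Number of free parameters of *family* (1, 2 or 3)."""
    _check_family(family)
    return FAMILIES[family][0]


def validate_params(family: str, params) -> np.ndarray:
    """Validate and return *params* as a float array, else raise."""
    _check_family(family)
    k, domains = FAMILIES[family]
    p = np.asarray(params, dtype=float).ravel()
    if p.size != k:
        raise InvalidParameterError(
            f"{family} expects {k} parameter(s), got {p.size}"
        )
    if not np.all(np.isfinite(p)):
        raise InvalidParameterError(f"{family} parameters must be finite, got {p}")
    for value, dom in zip(p, domains):
        if dom == "pos" and value <= 0:
            raise InvalidParameterError(
                f"{family} requires strictly positive parameters where "
                f"applicable, got {p}"
            )
    return p


# ---------------------------------------------------------------------------
# log-density and log-survival per family
# ---------------------------------------------------------------------------

def _gompertz_cumhaz(t, shape, rate):
    # H(t) = (rate/shape)*(e^{shape t} - 1); -> rate*t as shape -> 0
    t = np.asarray(t, dtype=float)
    if abs(shape) < 1e-12:
        return rate * t
    return (rate / shape) * np.expm1(shape * t)


def _gg_split(params):
    mu, sigma, q = params
    return mu, sigma, q


def logpdf(family: str, params, t) -> np.ndarray:
    """Log density f(t); ``-inf`` where the density vanishes (incl. t <= 0)."""
    p = validate_params(family, params)
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, _NEG_INF)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if family == "exponential":
            (rate,) = p
            val = np.log(rate) - rate * tp
        elif family == "weibull":
            shape, scale = p
            val = stats.weibull_min.logpdf(tp, shape, scale=scale)
        elif family == "gamma":
            shape, scale = p
            val = stats.gamma.logpdf(tp, shape, scale=scale)
        elif family == "gompertz":
            shape, rate = p
            val = np.log(rate) + shape * tp - _gompertz_cumhaz(tp, shape, rate)
        elif family == "loglogistic":
            shape, scale = p
            val = stats.fisk.logpdf(tp, shape, scale=scale)
        elif family == "lognormal":
            mu, sigma = p
            val = stats.lognorm.logpdf(tp, sigma, scale=np.exp(mu))
        else:  # generalized_gamma, Prentice
            mu, sigma, q = _gg_split(p)
            z = (np.log(tp) - mu) / sigma
            if abs(q) < _GG_Q_EPS:
                val = stats.lognorm.logpdf(tp, sigma, scale=np.exp(mu))
            else:
                gam = q ** -2
                val = (
                    np.log(abs(q))
                    + gam * np.log(gam)
                    - special.gammaln(gam)
                    - np.log(sigma)
                    - np.log(tp)
                    + gam * (q * z - np.exp(q * z))
                )
    val = np.where(np.isnan(val), _NEG_INF, val)
    out[pos] = val
    return out


def logsf(family: str, params, t) -> np.ndarray:
    """Log survival ln S(t); 0 for t <= 0."""
    p = validate_params(family, params)
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if family == "exponential":
            (rate,) = p
            val = -rate * tp
        elif family == "weibull":
            shape, scale = p
            val = -((tp / scale) ** shape)
        elif family == "gamma":
            shape, scale = p
            val = np.log(special.gammaincc(shape, tp / scale))
        elif family == "gompertz":
            shape, rate = p
            val = -_gompertz_cumhaz(tp, shape, rate)
        elif family == "loglogistic":
            shape, scale = p
            val = -np.log1p((tp / scale) ** shape)
        elif family == "lognormal":
            mu, sigma = p
            val = stats.norm.logsf((np.log(tp) - mu) / sigma)
        else:  # generalized_gamma
            mu, sigma, q = _gg_split(p)
            z = (np.log(tp) - mu) / sigma
            if abs(q) < _GG_Q_EPS:
                val = stats.norm.logsf(z)
            else:
                gam = q ** -2
                u = gam * np.exp(q * z)
                if q > 0:
                    val = np.log(special.gammaincc(gam, u))
                else:
                    val = np.log(special.gammainc(gam, u))
    val = np.where(np.isnan(val), _NEG_INF, val)
    out[pos] = val
    return out


def sf(family: str, params, t) -> np.ndarray:
    """Survival S(t) in [0, 1]."""
    with np.errstate(over="ignore"):
        return np.exp(logsf(family, params, t))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample(family: str, params, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw event times from *family*; may contain ``inf`` for defective
    (negative-shape Gompertz) distributions."""
    p = validate_params(family, params)
    if family == "exponential":
        (rate,) = p
        return rng.exponential(1.0 / rate, size)
    if family == "weibull":
        shape, scale = p
        return scale * rng.weibull(shape, size)
    if family == "gamma":
        shape, scale = p
        return rng.gamma(shape, scale, size)
    if family == "gompertz":
        shape, rate = p
        u = rng.uniform(size=size)
        if abs(shape) < 1e-12:
            return -np.log(u) / rate
        arg = 1.0 - (shape / rate) * np.log(u)
        out = np.full(size, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / shape
        return out
    if family == "loglogistic":
        shape, scale = p
        u = rng.uniform(size=size)
        return scale * (u / (1.0 - u)) ** (1.0 / shape)
    if family == "lognormal":
        mu, sigma = p
        return rng.lognormal(mu, sigma, size)
    # generalized_gamma
    mu, sigma, q = _gg_split(p)
    if abs(q) < _GG_Q_EPS:
        return rng.lognormal(mu, sigma, size)
    gam = q ** -2
    g = rng.gamma(gam, 1.0, size)
    return np.exp(mu + sigma * np.log(q * q * g) / q)


# ---------------------------------------------------------------------------
# Prentice <-> Stacy conversion for the generalized gamma
# ---------------------------------------------------------------------------

def prentice_to_stacy(mu: float, sigma: float, q: float) -> tuple[float, float, float]:
    """Convert Prentice (mu, sigma, Q), Q > 0, to Stacy (k, c, scale) where
    f(t) ∝ t^{k*c-1} exp(-(t/scale)^c)."""
    if q <= 0:
        raise InvalidParameterError("Stacy form exists only for Q > 0")
    k = q ** -2
    c = q / sigma
    scale = np.exp(mu) * (q * q) ** (sigma / q)
    return k, c, scale


def stacy_to_prentice(k: float, c: float, scale: float) -> tuple[float, float, float]:
    """Inverse of :func:`prentice_to_stacy`."""
    if min(k, c, scale) <= 0:
        raise InvalidParameterError("Stacy parameters must be positive")
    q = k ** -0.5
    sigma = q / c
    mu = np.log(scale) - sigma * np.log(q * q) / q
    return mu, sigma, q
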