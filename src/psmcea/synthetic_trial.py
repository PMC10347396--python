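"""Synthetic two-arm trial generator.

Simulates per-subject event/censoring times from a known parametric
distribution, reduces them to the published form of a trial readout — a
Kaplan–Meier step curve plus a numbers-at-risk table — and optionally
perturbs the curve the way manual digitization of a printed figure would.
This is the test harness for the reconstruction → fitting → economic-model
pipeline when the underlying trial data are not available.

Censoring model: independent exponential drop-out plus an administrative
cutoff at the end of follow-up; the observed time is the minimum of event,
drop-out and cutoff times.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import distributions as dist

__all__ = [
    "ArmSpec",
    "KMPoints",
    "RiskTable",
    "simulate_arm",
    "km_estimate",
    "digitize",
    "read_ipd",
    "write_ipd",
]


@dataclass(frozen=True)
class ArmSpec:
    """One trial arm / endpoint: the generating distribution and censoring.

    Parameters are on the month scale.  ``censor_rate`` is the exponential
    drop-out rate per month (0 disables drop-out); ``admin_cutoff`` is the
    administrative end of follow-up in months.
    """

    label: str
    family: str
    params: tuple[float, ...]
    n_subjects: int
    censor_rate: float = 0.0
    admin_cutoff: float = np.inf

    def __post_init__(self):
        dist.validate_params(self.family, self.params)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not self.admin_cutoff > 0:
            raise ValueError("admin_cutoff must be > 0")


@dataclass(frozen=True)
class KMPoints:
    """A survival step curve as ordered (time, survival) coordinates.

    Times start at 0 with survival 1 and are strictly increasing; survival
    is non-increasing in [0, 1].  The curve is right-continuous: S(t) is
    the survival at the last coordinate time <= t.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.size != s.size or t.size == 0:
            raise ValueError("times and survival must be equal-length, non-empty")
        if t[0] != 0 or s[0] != 1:
            raise ValueError("curve must start at (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if s.min() < -1e-12 or s.max() > 1 + 1e-12:
            raise ValueError("survival must lie in [0, 1]")

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous step evaluation S(t) for t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.times) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KMPoints":
        return cls(df["time"].to_numpy(float), df["survival"].to_numpy(float))


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk on a time grid, as printed under a KM figure."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.size != n.size or t.size == 0:
            raise ValueError("times and n_at_risk must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(n) > 0):
            raise ValueError("n_at_risk must be non-increasing")
        if np.any(n < 0):
            raise ValueError("n_at_risk must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "n_at_risk": self.n_at_risk})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskTable":
        return cls(df["time"].to_numpy(float), df["n_at_risk"].to_numpy(int))


def simulate_arm(spec: ArmSpec, seed: int) -> pd.DataFrame:
    """Simulate one arm; returns a frame with columns ``time`` and ``event``.

    ``time`` is min(event time, drop-out time, administrative cutoff);
    ``event`` is 1 iff the event time attained the minimum.  Deterministic
    for a fixed (spec, seed).
    """
    rng = np.random.default_rng(seed)
    t_event = dist.sample(spec.family, spec.params, spec.n_subjects, rng)
    if spec.censor_rate > 0:
        t_drop = rng.exponential(1.0 / spec.censor_rate, spec.n_subjects)
    else:
        t_drop = np.full(spec.n_subjects, np.inf)
    t_cens = np.minimum(t_drop, spec.admin_cutoff)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # degenerate guard: simulated times of exactly 0 are nudged to stay positive
    time = np.maximum(time, np.finfo(float).tiny)
    return pd.DataFrame({"time": time, "event": event})


def km_estimate(
    records: pd.DataFrame, risk_grid=None
) -> tuple[KMPoints, RiskTable]:
    """Product-limit estimate with steps at event times, plus a risk table.

    ``risk_grid`` defaults to every 3 months from 0 through the last
    observed time, matching the cadence of published KM figures.
    """
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    time = records["time"].to_numpy(float)
    event = records["event"].to_numpy(int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    # product-limit over distinct event times; events precede censorings at ties
    uniq = np.unique(time[event == 1])
    surv = 1.0
    km_t, km_s = [0.0], [1.0]
    for t in uniq:
        n_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        surv *= 1.0 - d / n_risk
        km_t.append(t)
        km_s.append(surv)
    # extend flat to the end of follow-up, as published curves are drawn
    last_obs = float(time.max())
    if last_obs > km_t[-1]:
        km_t.append(last_obs)
        km_s.append(surv)
    km = KMPoints(np.array(km_t), np.clip(np.array(km_s), 0.0, 1.0))

    if risk_grid is None:
        last = time.max()
        risk_grid = np.arange(0.0, last + 1e-9, 3.0)
    risk_grid = np.asarray(risk_grid, dtype=float)
    n_at_risk = np.array([np.sum(time >= g) for g in risk_grid])
    return km, RiskTable(risk_grid, n_at_risk)


def digitize(
    km: KMPoints, grid, jitter_sd: float = 0.0, seed: int = 0
) -> KMPoints:
    """Read the KM curve off a grid, emulating manual figure digitization.

    Evaluates the step curve at the grid times, optionally perturbs the
    survival ordinates with truncated Gaussian noise (vertical error, as in
    hand digitization), then restores monotonicity by a running minimum and
    clips to [0, 1].  The (0, 1) anchor is always preserved; ``jitter_sd=0``
    returns the exact step values.
    """
    grid = np.asarray(grid, dtype=float)
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if np.any(grid > km.times[-1] + 1e-9):
        raise ValueError("grid extends beyond the last KM time")
    if grid[0] != 0:
        grid = np.concatenate([[0.0], grid])
    s = km.evaluate(grid)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.clip(rng.normal(0.0, jitter_sd, s.shape), -3 * jitter_sd, 3 * jitter_sd)
        s = s + noise
        s[0] = 1.0
    s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    s[0] = 1.0
    return KMPoints(grid, s)


def write_ipd(records: pd.DataFrame, path) -> None:
    records[["time", "event"]].to_csv(path, index=False)


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if not {"time", "event"} <= set(df.columns):
        raise ValueError("IPD file must have 'time' and 'event' columns")
    return df[["time", "event"]]
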