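"""One-way and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the full partitioned-survival model at
the low and high bound of one parameter at a time, holding everything
else at base case, and ranks parameters by the absolute ICER span.
Default ranges are base +/-20%, except the discount rate (0 to 8%) and
the trastuzumab-deruxtecan price, whose lower bound is a 50% decrement
in anticipation of reimbursement-negotiation price cuts.

The probabilistic analysis draws unit costs from Gamma and utilities
from Beta distributions, both moment-matched to (mean, sd) with sd
defaulting to 20% of the mean, runs the model once per draw (1,000
iterations by convention), and summarizes the draws as a
cost-effectiveness acceptability curve (CEAC) and an incremental
cost-effectiveness scatter.  Each parameter owns an independent random
substream keyed by its name, so adding a parameter does not perturb the
draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parametric_survival import SurvivalCurve
from .psm_engine import (AEProfile, AgentCost, CostInputs, EconResult,
                         EconomicSettings, ICERResult, UtilityInputs,
                         compute_icer, run_arm)

__all__ = [
    "EconModel",
    "ParamRange",
    "default_ranges",
    "one_way",
    "draw_psa_params",
    "run_psa",
    "ceac",
    "ce_plane_export",
    "plot_tornado",
    "plot_ceac",
    "plot_ce_plane",
]


@dataclass(frozen=True)
class EconModel:
    """A fully specified two-strategy model: curves plus economic inputs.

    ``evaluate`` applies named parameter overrides (see PARAM_HANDLES) and
    returns (intervention result, comparator result, ICER record).
    """

    os_tdxd: SurvivalCurve
    pfs_tdxd: SurvivalCurve
    os_chemo: SurvivalCurve
    pfs_chemo: SurvivalCurve
    settings: EconomicSettings = field(default_factory=EconomicSettings)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    ae: AEProfile = field(default_factory=AEProfile)

    def evaluate(self, overrides: dict[str, float] | None = None
                 ) -> tuple[EconResult, EconResult, ICERResult]:
        settings, costs, utilities, ae = _apply_overrides(
            self.settings, self.costs, self.utilities, self.ae, overrides or {})
        r_tdxd = run_arm(self.os_tdxd, self.pfs_tdxd, "tdxd",
                         settings, costs, utilities, ae)
        r_chemo = run_arm(self.os_chemo, self.pfs_chemo, "chemo",
                          settings, costs, utilities, ae)
        return r_tdxd, r_chemo, compute_icer(r_tdxd, r_chemo)


#: named parameter handles usable in overrides, OWSA ranges and PSA draws.
#: kind 'cost' -> Gamma draw, 'utility' -> Beta draw, 'rate' -> OWSA only,
#: 'multiplier' -> dimensionless scale factor with base 1.0
PARAM_HANDLES: dict[str, str] = {
    "tdxd_cost_per_100mg": "cost",
    "cost_capecitabine": "cost",
    "cost_eribulin": "cost",
    "cost_gemcitabine": "cost",
    "cost_paclitaxel": "cost",
    "cost_nab-paclitaxel": "cost",
    "chemo_drug_cost": "multiplier",
    "hospitalization_per_cycle": "cost",
    "followup_per_cycle": "cost",
    "pd_cost_per_cycle": "cost",
    "ae_cost": "multiplier",
    "utility_pfs": "utility",
    "utility_pd": "utility",
    "discount_rate": "rate",
}
PARAM_HANDLES.update({f"ae_cost_{e}": "cost" for e in
                      ("neutropenia", "anemia", "thrombocytopenia", "leukopenia",
                       "nausea", "vomiting", "diarrhea",
                       "increased_aminotransferase", "fatigue",
                       "decreased_appetite")})


def _apply_overrides(settings, costs, utilities, ae, overrides):
    unknown = set(overrides) - set(PARAM_HANDLES)
    if unknown:
        raise KeyError(f"unknown model parameter(s): {sorted(unknown)}")
    agents = dict(costs.agents)
    ae_costs = dict(ae.costs)
    cost_kw: dict[str, float] = {}
    u_pfs, u_pd = utilities.u_pfs, utilities.u_pd
    for name, value in overrides.items():
        if name == "tdxd_cost_per_100mg":
            cost_kw["tdxd_per_100mg"] = value
        elif name.startswith("cost_"):
            agent = name[len("cost_"):]
            agents[agent] = replace(agents[agent], unit_cost=value)
        elif name == "chemo_drug_cost":
            for a, spec in agents.items():
                if spec.unit_cost is not None:
                    agents[a] = replace(spec, unit_cost=spec.unit_cost * value)
        elif name in ("hospitalization_per_cycle", "followup_per_cycle",
                      "pd_cost_per_cycle"):
            cost_kw[name] = value
        elif name == "ae_cost":
            ae_costs = {e: c * value for e, c in ae_costs.items()}
        elif name.startswith("ae_cost_"):
            ae_costs[name[len("ae_cost_"):]] = value
        elif name == "utility_pfs":
            u_pfs = value
        elif name == "utility_pd":
            u_pd = value
        elif name == "discount_rate":
            settings = replace(settings, annual_discount=value)
    # independent utility draws can cross; enforce the state ordering
    u_pd = min(u_pd, u_pfs)
    return (settings,
            replace(costs, agents=agents, **cost_kw),
            UtilityInputs(u_pfs=u_pfs, u_pd=u_pd),
            replace(ae, costs=ae_costs))


@dataclass(frozen=True)
class ParamRange:
    name: str
    base: float
    low: float
    high: float

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")


def default_ranges(model: EconModel) -> list[ParamRange]:
    """Tornado ranges: +/-20%, discount 0-8%, half-price drug lower bound."""
    c, u, s = model.costs, model.utilities, model.settings
    ranges = [
        ParamRange("tdxd_cost_per_100mg", c.tdxd_per_100mg,
                   0.5 * c.tdxd_per_100mg, 1.2 * c.tdxd_per_100mg),
        ParamRange("chemo_drug_cost", 1.0, 0.8, 1.2),
        ParamRange("utility_pfs", u.u_pfs, 0.8 * u.u_pfs, min(1.0, 1.2 * u.u_pfs)),
        ParamRange("utility_pd", u.u_pd, 0.8 * u.u_pd, min(1.0, 1.2 * u.u_pd)),
        ParamRange("discount_rate", s.annual_discount, 0.0, 0.08),
        ParamRange("pd_cost_per_cycle", c.pd_cost_per_cycle,
                   0.8 * c.pd_cost_per_cycle, 1.2 * c.pd_cost_per_cycle),
        ParamRange("ae_cost", 1.0, 0.8, 1.2),
        ParamRange("hospitalization_per_cycle", c.hospitalization_per_cycle,
                   0.8 * c.hospitalization_per_cycle, 1.2 * c.hospitalization_per_cycle),
        ParamRange("followup_per_cycle", c.followup_per_cycle,
                   0.8 * c.followup_per_cycle, 1.2 * c.followup_per_cycle),
    ]
    return ranges


def one_way(model: EconModel, ranges: list[ParamRange] | None = None) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's bounds, sorted by span."""
    if ranges is None:
        ranges = default_ranges(model)
    rows = []
    for r in ranges:
        if r.name not in PARAM_HANDLES:
            raise KeyError(f"unknown model parameter: {r.name}")
        icer_lo = model.evaluate({r.name: r.low})[2].icer
        icer_hi = model.evaluate({r.name: r.high})[2].icer
        rows.append({"parameter": r.name, "base": r.base, "low": r.low,
                     "high": r.high, "icer_at_low": icer_lo,
                     "icer_at_high": icer_hi,
                     "span": abs(icer_hi - icer_lo)})
    out = pd.DataFrame(rows).sort_values("span", ascending=False, kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _param_rng(root_seed: int, name: str) -> np.random.Generator:
    # stable per-parameter substream: adding a parameter leaves others intact
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())]))


def _gamma_draws(mean, sd, n, rng):
    if sd == 0 or mean == 0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, n)


def _beta_draws(mean, sd, n, rng):
    if sd == 0:
        return np.full(n, mean)
    v = sd * sd
    if v >= mean * (1 - mean):
        raise ValueError(
            f"Beta moment matching infeasible: sd {sd} too large for mean {mean}")
    nu = mean * (1 - mean) / v - 1.0
    return rng.beta(mean * nu, (1 - mean) * nu, n)


def _psa_means(model: EconModel) -> dict[str, tuple[float, str]]:
    """Parameters varied in PSA: every unit cost plus both utilities."""
    c, u = model.costs, model.utilities
    means: dict[str, tuple[float, str]] = {
        "tdxd_cost_per_100mg": (c.tdxd_per_100mg, "cost"),
        "hospitalization_per_cycle": (c.hospitalization_per_cycle, "cost"),
        "followup_per_cycle": (c.followup_per_cycle, "cost"),
        "pd_cost_per_cycle": (c.pd_cost_per_cycle, "cost"),
        "utility_pfs": (u.u_pfs, "utility"),
        "utility_pd": (u.u_pd, "utility"),
    }
    for name, agent in c.agents.items():
        if agent.unit_cost is not None:
            means[f"cost_{name}"] = (agent.unit_cost, "cost")
    for event, cost in model.ae.costs.items():
        means[f"ae_cost_{event}"] = (cost, "cost")
    return means


def draw_psa_params(model: EconModel, n_iter: int = 1000, seed: int = 0,
                    sigma_frac: float = 0.2) -> pd.DataFrame:
    """Moment-matched Gamma (costs) / Beta (utilities) parameter draws.

    ``sigma_frac`` sets each parameter's sd as a fraction of its mean;
    0 degenerates to the base case exactly.
    """
    draws = {}
    for name, (mean, kind) in sorted(_psa_means(model).items()):
        rng = _param_rng(seed, name)
        sd = sigma_frac * mean
        if kind == "utility":
            draws[name] = _beta_draws(mean, sd, n_iter, rng)
        else:
            draws[name] = _gamma_draws(mean, sd, n_iter, rng)
    out = pd.DataFrame(draws)
    out.insert(0, "iteration", np.arange(n_iter))
    return out


def run_psa(model: EconModel, n_iter: int = 1000, seed: int = 0,
            sigma_frac: float = 0.2) -> pd.DataFrame:
    """One full model evaluation per parameter draw, for both strategies."""
    params = draw_psa_params(model, n_iter, seed, sigma_frac)
    names = [c for c in params.columns if c != "iteration"]
    rows = []
    for i in range(n_iter):
        overrides = {n: float(params.iloc[i][n]) for n in names}
        try:
            r_t, r_c, _ = model.evaluate(overrides)
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        rows.append({"cost_tdxd": r_t.cost_total, "qaly_tdxd": r_t.qaly_total,
                     "cost_chemo": r_c.cost_total, "qaly_chemo": r_c.qaly_total})
    res = pd.DataFrame(rows)
    res["delta_cost"] = res["cost_tdxd"] - res["cost_chemo"]
    res["delta_qaly"] = res["qaly_tdxd"] - res["qaly_chemo"]
    return pd.concat([params, res], axis=1)


def ceac(samples: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """P(intervention cost-effective) at each willingness-to-pay threshold.

    Cost-effective means strictly positive incremental net monetary
    benefit, lambda * dQALY - dCost > 0; ties count as not cost-effective.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    dq = samples["delta_qaly"].to_numpy(float)
    dc = samples["delta_cost"].to_numpy(float)
    prob = [(lam * dq - dc > 0).mean() for lam in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})


def _quadrant(dq: float, dc: float) -> str:
    if dq == 0 and dc == 0:
        return "indeterminate"
    if dq > 0:
        return "NE" if dc > 0 else "SE"
    if dq < 0:
        return "NW" if dc > 0 else "SW"
    return "N" if dc > 0 else "S"


def ce_plane_export(samples: pd.DataFrame) -> pd.DataFrame:
    """Incremental (dQALY, dCost) pairs with cost-effectiveness-plane
    quadrant labels, ready for scatter plotting or CSV export."""
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    out = samples[["delta_qaly", "delta_cost"]].copy()
    out["quadrant"] = [_quadrant(q, c) for q, c in
                       zip(out["delta_qaly"], out["delta_cost"])]
    return out


# ---------------------------------------------------------------------------
# optional figure rendering
# ---------------------------------------------------------------------------

def _axes():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_tornado(tornado: pd.DataFrame, base_icer: float, path) -> None:
    """Horizontal-bar tornado of ICER spans, widest at the top."""
    plt = _axes()
    t = tornado.iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(t) + 1.5))
    lo = np.minimum(t["icer_at_low"], t["icer_at_high"])
    hi = np.maximum(t["icer_at_low"], t["icer_at_high"])
    ax.barh(t["parameter"], hi - lo, left=lo, color="#4477aa")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_xlabel("ICER (USD/QALY)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(table: pd.DataFrame, wtp: float, path) -> None:
    """Acceptability curve with the willingness-to-pay threshold marked."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["wtp"], table["probability"], color="#4477aa")
    ax.axvline(wtp, color="k", lw=1, ls="--", label="WTP threshold")
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("P(intervention cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(plane: pd.DataFrame, wtp: float, path) -> None:
    """Incremental cost-effectiveness scatter with the WTP line."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane["delta_qaly"], plane["delta_cost"], s=8, alpha=0.4,
               color="#4477aa")
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q, color="k", lw=1, ls="--", label="WTP threshold")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
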