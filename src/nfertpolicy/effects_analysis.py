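"""Headline analyses: cost-efficiency, sub-level targeting, elasticity,
field-level effect regressions, the N-balance diagnostic and welfare/ROI.

Field-level effects (one OLS per policy, field values averaged over years):

* income effect — income after policy (profits + compensation) regressed on
  base-level income; a slope near 1 means the policy leaves the income
  distribution intact.
* point source reduction effect — leaching after policy on base leaching;
  a slope below 1 means reductions concentrate in high-leaching fields
  (hotspot control).
* internalization effect — profit change (after - base, before
  compensation) on base leaching; a negative slope means fields with larger
  externalities bear larger profit losses.

Welfare: with an externality cost of 16.1 US$ per kg N leached to
groundwater and a state maize area of 4.4 Mha, the welfare gain of a policy
is its externality reduction minus its policy cost (taxes, fees and
compensations are transfers and cancel out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import policy_engine as pe
from .evaluation import STATE
from .synthetic_fields import Dataset, N_GRID


class EffectsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cost-efficiency and sub-level selection
# ---------------------------------------------------------------------------

def cost_efficiency_curve(sweep_summaries: pd.DataFrame) -> pd.DataFrame:
    """State-scope (leaching reduction %, policy cost) pairs along a sweep.

    ``sweep_summaries`` must stack :func:`evaluation.aggregate` outputs for a
    single policy over its sub-levels, including the base run, and carry an
    ``excluded_flag`` column if the yield guard was applied (flagged
    sub-levels are dropped).
    """
    state = sweep_summaries.loc[sweep_summaries.index == STATE].copy()
    if state.empty:
        raise EffectsError("sweep summaries contain no state-scope rows")
    base = state.loc[state["policy"] == "base"]
    if base.empty:
        raise EffectsError("sweep must include the base run")
    base_leach = float(base["leach2"].iloc[0])
    if "excluded_flag" in state.columns:
        state = state.loc[(state["policy"] == "base") | ~state["excluded_flag"]]
    state = state.sort_values("sublevel", kind="stable")
    reduction = 100.0 * (base_leach - state["leach2"]) / base_leach
    cost = state["policy_cost"].fillna(0.0) if "policy_cost" in state.columns else 0.0
    curve = pd.DataFrame(
        {
            "policy": state["policy"].to_numpy(),
            "sublevel": state["sublevel"].to_numpy(),
            "leach_reduction_pct": reduction.to_numpy(),
            "policy_cost": np.asarray(cost, dtype=float),
        }
    ).reset_index(drop=True)
    return curve


def select_sublevel(curve: pd.DataFrame, target_reduction: float) -> dict:
    """Smallest swept sub-level reaching a state leaching-reduction target.

    Returns the achieving grid sub-level plus a linear interpolation between
    the bracketing sub-levels.  Raises if the sweep never reaches the target.
    """
    pts = curve.loc[curve["policy"] != "base"].sort_values("sublevel")
    base = curve.loc[curve["policy"] == "base"]
    if not base.empty:
        pts = pd.concat([base, pts]).sort_values("sublevel")
    red = pts["leach_reduction_pct"].to_numpy()
    sub = pts["sublevel"].to_numpy()
    reach = np.flatnonzero(red >= target_reduction)
    if reach.size == 0:
        raise EffectsError(
            f"target {target_reduction}% unreachable; max achieved "
            f"{red.max():.2f}% at sublevel {sub[red.argmax()]}"
        )
    i = int(reach[0])
    if i == 0 or red[i] == target_reduction:
        interp = float(sub[i])
    else:
        lo, hi = i - 1, i
        interp = float(
            sub[lo]
            + (target_reduction - red[lo]) * (sub[hi] - sub[lo]) / (red[hi] - red[lo])
        )
    return {
        "sublevel": float(sub[i]),
        "sublevel_interp": interp,
        "achieved_reduction_pct": float(red[i]),
    }


def own_price_elasticity(
    p_low: float, n_low: float, p_high: float, n_high: float
) -> float:
    """Arc (midpoint) own-price elasticity of N demand, unitless magnitude.

    ``|%dN / %dp|`` with both percentage changes taken against midpoints.
    """
    if p_low == p_high:
        raise EffectsError("price points must differ")
    dn = (n_high - n_low) / ((n_high + n_low) / 2.0) if (n_high + n_low) else 0.0
    dp = (p_high - p_low) / ((p_high + p_low) / 2.0)
    return abs(dn / dp)


# ---------------------------------------------------------------------------
# Field-level effect regressions
# ---------------------------------------------------------------------------

@dataclass
class EffectRegression:
    effect: str
    slope: float
    slope_p_value: float
    r2: float
    n_fields: int

    @property
    def stars(self) -> str:
        p = self.slope_p_value
        return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else "ns"


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return float(fit.params[1]), float(fit.pvalues[1]), float(fit.rsquared)


def field_effects(
    outcomes_with_comp: pd.DataFrame,
    base_outcomes_with_comp: pd.DataFrame,
) -> list[EffectRegression]:
    """The three field-level effect regressions for one policy run.

    Both inputs must carry the compensation columns from
    :func:`evaluation.compensate` (for the base run income == profit_after).
    Values are averaged per field across years before regression.
    """
    cols = ["income", "profit_after", "leach2"]
    pol = outcomes_with_comp.groupby("field_id")[cols].mean()
    base = base_outcomes_with_comp.groupby("field_id")[cols].mean()
    common = pol.index.intersection(base.index)
    if len(common) < 3:
        raise EffectsError("need at least 3 matched fields")
    pol, base = pol.loc[common], base.loc[common]
    out = []
    for effect, x, y in (
        ("income", base["income"], pol["income"]),
        ("point_source", base["leach2"], pol["leach2"]),
        ("internalization", base["leach2"], pol["profit_after"] - base["profit_after"]),
    ):
        slope, p, r2 = _ols(x.to_numpy(), y.to_numpy())
        out.append(EffectRegression(effect, slope, p, r2, len(common)))
    return out


def effects_table(regs: dict[str, list[EffectRegression]]) -> pd.DataFrame:
    rows = [
        {
            "policy": pol,
            "effect": r.effect,
            "slope": r.slope,
            "p_value": r.slope_p_value,
            "r2": r.r2,
            "stars": r.stars,
            "n_fields": r.n_fields,
        }
        for pol, lst in regs.items()
        for r in lst
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# N-balance diagnostic
# ---------------------------------------------------------------------------

def n_balance_diagnostic(
    dataset: Dataset,
    base_outcomes: pd.DataFrame,
    seed: int = 0,
    fixed_rates: Sequence[float] = (40.0, 120.0, 200.0, 280.0),
    common_rate: float = 180.0,
    n_small: int = 45,
    n_large: int = 5000,
    params: pe.BalanceParams = pe.BalanceParams(),
) -> pd.DataFrame:
    """How well the N-balance surplus tracks leaching as data complexity grows.

    Five scenarios, each an OLS of 2-yr leaching on N balance:

    A. one location (field-year), four fixed N rates — within-location,
       rate-driven variation;
    B. ``n_small`` locations x four fixed rates;
    C. many locations, one common fixed rate — variation purely from soil
       and weather;
    D. ``n_small`` locations at the base-policy recommended rates;
    E. ``n_large`` (or all available) locations at recommended rates.

    Scenario sizes shrink automatically on small datasets.  A scenario with
    fewer than 3 points (or no between-location variance) yields NaNs with a
    warning.
    """
    rng = np.random.default_rng(seed)
    n_rows = len(dataset.curves)
    rows = []

    def balance_leach_at(rate: float, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        step = N_GRID[1] - N_GRID[0]
        j = int(round(rate / step))
        y = dataset.yields[idx, j]
        l2 = dataset.leach2[idx, j]
        return pe.n_balance(rate, y, params), l2

    def fit(tag: str, bal: np.ndarray, l2: np.ndarray, n_loc: int):
        bal, l2 = np.asarray(bal, float), np.asarray(l2, float)
        if len(bal) < 3 or np.std(bal) == 0:
            warnings.warn(f"scenario {tag}: degenerate data, reporting NaNs")
            rows.append({"scenario": tag, "slope": np.nan, "p_value": np.nan,
                         "r2": np.nan, "n_locations": n_loc, "n_points": len(bal)})
            return
        slope, p, r2 = _ols(bal, l2)
        rows.append({"scenario": tag, "slope": slope, "p_value": p, "r2": r2,
                     "n_locations": n_loc, "n_points": len(bal)})

    # A: one location, four fixed rates
    loc = int(rng.integers(n_rows))
    bals, l2s = [], []
    for rate in fixed_rates:
        b, l2 = balance_leach_at(rate, np.asarray([loc]))
        bals.append(b[0]); l2s.append(l2[0])
    fit("A", np.asarray(bals), np.asarray(l2s), 1)

    # B: n_small locations x four fixed rates
    nb = min(n_small, n_rows)
    locs = rng.choice(n_rows, size=nb, replace=False)
    bals, l2s = [], []
    for rate in fixed_rates:
        b, l2 = balance_leach_at(rate, locs)
        bals.append(b); l2s.append(l2)
    fit("B", np.concatenate(bals), np.concatenate(l2s), nb)

    # C: many locations, one common rate
    nc = min(n_large, n_rows)
    locs = rng.choice(n_rows, size=nc, replace=False)
    b, l2 = balance_leach_at(common_rate, locs)
    fit("C", b, l2, nc)

    # D/E: locations at the base-policy recommended rate
    base = base_outcomes
    nd = min(n_small, len(base))
    pick = rng.choice(len(base), size=nd, replace=False)
    fit("D", base["n_balance"].to_numpy()[pick], base["leach2"].to_numpy()[pick], nd)
    ne = min(n_large, len(base))
    pick = rng.choice(len(base), size=ne, replace=False)
    fit("E", base["n_balance"].to_numpy()[pick], base["leach2"].to_numpy()[pick], ne)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Welfare
# ---------------------------------------------------------------------------

@dataclass
class WelfareParams:
    externality_cost_per_kg: float = 16.1  # US$ per kg N leached (groundwater)
    state_area: float = 4.4e6              # ha of maize in the state


@dataclass
class WelfareReport:
    externality_cost_per_kg: float
    state_area: float
    load_reduction: float        # kg N/yr
    externality_reduction: float  # US$/yr
    policy_cost_total: float     # US$/yr
    welfare_gain: float          # US$/yr
    roi: float | None            # %, None when policy cost is 0

    def as_dict(self) -> dict:
        return {
            "externality_cost_per_kg": self.externality_cost_per_kg,
            "state_area": self.state_area,
            "load_reduction": self.load_reduction,
            "externality_reduction": self.externality_reduction,
            "policy_cost_total": self.policy_cost_total,
            "welfare_gain": self.welfare_gain,
            "roi": self.roi,
        }


def welfare(
    delta_leach_per_ha: float,
    policy_cost_per_ha: float | None = None,
    params: WelfareParams = WelfareParams(),
    policy_cost_total: float | None = None,
) -> WelfareReport:
    """State-scale welfare arithmetic for one policy at one sub-level.

    ``delta_leach_per_ha`` is the base-minus-policy leaching (kg N/ha/yr);
    the policy cost may be given per ha or as a state total (US$/yr).
    """
    if policy_cost_total is None:
        if policy_cost_per_ha is None:
            raise EffectsError("provide policy_cost_per_ha or policy_cost_total")
        policy_cost_total = policy_cost_per_ha * params.state_area
    load = delta_leach_per_ha * params.state_area
    ext = load * params.externality_cost_per_kg
    gain = ext - policy_cost_total
    roi = 100.0 * gain / policy_cost_total if policy_cost_total > 0 else None
    return WelfareReport(
        externality_cost_per_kg=params.externality_cost_per_kg,
        state_area=params.state_area,
        load_reduction=load,
        externality_reduction=ext,
        policy_cost_total=policy_cost_total,
        welfare_gain=gain,
        roi=roi,
    )


def welfare_from_summaries(
    base_summary: pd.DataFrame,
    policy_summary: pd.DataFrame,
    params: WelfareParams = WelfareParams(),
) -> WelfareReport:
    """Welfare report from state-scope aggregate summaries."""
    b = base_summary.loc[base_summary.index == STATE].iloc[0]
    p = policy_summary.loc[policy_summary.index == STATE].iloc[0]
    return welfare(
        delta_leach_per_ha=float(b["leach2"] - p["leach2"]),
        policy_cost_per_ha=float(p["policy_cost"]),
        params=params,
    )
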