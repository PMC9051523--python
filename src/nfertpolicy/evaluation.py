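"""Stage 3: field outcomes, collections, lump-sum compensation, aggregation.

Every field represents 1 ha, so per-ha and per-field quantities coincide.
Aggregation follows a two-stage rule: first the mean across years within
each field (each year weighted equally), then the unweighted mean across
fields for a region; the state is the unweighted mean across all fields.

Compensation is a lump sum per ha, identical for all fields of a region in
a given year, with two components: (1) a return of the government
collections of that region-year, and (2) a payment covering the policy cost
(the residual income loss after collections are returned — the deadweight
loss).  Component 1 is zero under the base and voluntary policies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import policy_engine as pe
from .synthetic_fields import N_GRID, Dataset

STATE = "state"


class EvaluationError(ValueError):
    pass


def evaluate_fields(
    eval_subset: Dataset,
    rates: np.ndarray,
    policy: pe.Policy,
    prices: pe.Prices = pe.Prices(),
) -> pd.DataFrame:
    """Realized outcomes for evaluation field-years at the recommended rates.

    Returns one row per field-year with yield, 2-yr leaching, revenue,
    fertilizer cost (tax-inclusive), fee paid, after-fee profit and the
    N-balance surplus.
    """
    rates = np.asarray(rates, dtype=float)
    curves = eval_subset.curves
    if len(rates) != len(curves):
        raise EvaluationError("one recommended rate per field-year required")
    step = N_GRID[1] - N_GRID[0]
    idx_f = rates / step
    idx = np.rint(idx_f).astype(int)
    if not np.allclose(idx_f, idx) or idx.min() < 0 or idx.max() >= len(N_GRID):
        raise EvaluationError("recommended rates must lie on the N grid")
    rows = np.arange(len(curves))
    yields = eval_subset.yields[rows, idx]
    leach2 = eval_subset.leach2[rows, idx]
    p_n = policy.effective_p_n(prices)
    gross = prices.p_maize * yields
    fert_cost = p_n * rates
    bal = pe.n_balance(rates, yields, policy.balance_params)
    if policy.kind == "leaching_fee":
        thr = pe._threshold_vector(policy.leach_thresholds, curves["region"].tolist())
        fee = policy.sublevel * np.maximum(0.0, leach2 - thr)
    elif policy.kind == "balance_fee":
        thr = pe._threshold_vector(policy.balance_thresholds, curves["region"].tolist())
        fee = policy.sublevel * np.maximum(0.0, bal - thr)
    else:
        fee = np.zeros(len(curves))
    out = pd.DataFrame(
        {
            "field_id": curves["field_id"].to_numpy(),
            "year": curves["year"].to_numpy(),
            "region": curves["region"].to_numpy(),
            "n_rate": rates,
            "yield": yields,
            "leach2": leach2,
            "gross_revenue": gross,
            "fert_cost": fert_cost,
            "fee_paid": fee,
            "profit_after": gross - fert_cost - fee,
            "n_balance": bal,
        }
    )
    return out


def evaluate_field(
    curve: Mapping,
    recommended_rate: float,
    policy: pe.Policy,
    prices: pe.Prices = pe.Prices(),
    region: str | None = None,
) -> dict:
    """Single-curve convenience wrapper around the vectorized evaluation."""
    region = region or curve.get("region")
    grid = np.asarray(curve["n_grid"], dtype=float)
    i = np.flatnonzero(np.isclose(grid, recommended_rate))
    if i.size == 0:
        raise EvaluationError(f"rate {recommended_rate} not on the curve grid")
    i = int(i[0])
    yields = float(np.asarray(curve["yield_at"], dtype=float)[i])
    leach2 = float(np.asarray(curve["leach2_at"], dtype=float)[i])
    p_n = policy.effective_p_n(prices)
    gross = prices.p_maize * yields
    fert_cost = p_n * recommended_rate
    bal = float(pe.n_balance(recommended_rate, yields, policy.balance_params))
    if policy.kind == "leaching_fee":
        fee = policy.sublevel * max(0.0, leach2 - policy.leach_thresholds[region])
    elif policy.kind == "balance_fee":
        fee = policy.sublevel * max(0.0, bal - policy.balance_thresholds[region])
    else:
        fee = 0.0
    return {
        "field_id": curve.get("field_id"),
        "year": curve.get("year"),
        "region": region,
        "n_rate": recommended_rate,
        "yield": yields,
        "leach2": leach2,
        "gross_revenue": gross,
        "fert_cost": fert_cost,
        "fee_paid": fee,
        "profit_after": gross - fert_cost - fee,
        "n_balance": bal,
    }


def collections_per_fieldyear(
    outcomes: pd.DataFrame, policy: pe.Policy, prices: pe.Prices = pe.Prices()
) -> pd.Series:
    """Government take per field-year (US$/ha).

    Price-ratio policy: the tax wedge (p_n' - p_n_base) x N (the base
    fertilizer cost is a market transaction, not a collection).  Fee
    policies: the fee paid.  Base and voluntary: zero.
    """
    if policy.kind == "price_ratio":
        wedge = policy.effective_p_n(prices) - prices.p_n
        return wedge * outcomes["n_rate"]
    if policy.kind in ("leaching_fee", "balance_fee"):
        return outcomes["fee_paid"].copy()
    return pd.Series(0.0, index=outcomes.index)


def two_stage_mean(outcomes: pd.DataFrame, col: str) -> pd.Series:
    """Regional + state means: per-field mean over years, then over fields."""
    per_field = outcomes.groupby(["region", "field_id"], sort=True)[col].mean()
    regional = per_field.groupby("region").mean()
    regional[STATE] = per_field.mean()
    return regional


def government_collections(
    outcomes: pd.DataFrame, policy: pe.Policy, prices: pe.Prices = pe.Prices()
) -> pd.Series:
    """Regional (+ state) government collections, US$/ha, two-stage mean."""
    out = outcomes.copy()
    out["_coll"] = collections_per_fieldyear(outcomes, policy, prices)
    return two_stage_mean(out, "_coll")


@dataclass
class CompensationPlan:
    """Per-region lump-sum compensation (US$/ha/yr, aggregated)."""

    region: str
    collections_per_ha: float
    policy_cost_per_ha: float

    @property
    def total_per_ha(self) -> float:
        return self.collections_per_ha + self.policy_cost_per_ha


def compensate(
    outcomes: pd.DataFrame,
    base_outcomes: pd.DataFrame,
    policy: pe.Policy,
    prices: pe.Prices = pe.Prices(),
) -> tuple[pd.DataFrame, dict[str, CompensationPlan]]:
    """Attach lump-sum compensation to outcomes and summarize per region.

    Component 1 is paid per region-year (total collections of the
    region-year divided by its area, i.e. the mean since fields are 1 ha
    each), so collections are conserved exactly within every region-year.
    Component 2 is the regional policy cost: mean base profit minus mean
    (after-fee profit + component 1); it restores the regional mean income
    to the base level by construction.

    Returns ``(outcomes_with_compensation, plans)`` where outcomes gain
    ``comp_collections``, ``comp_policy_cost`` and ``income`` columns.
    """
    if base_outcomes is None or base_outcomes.empty:
        raise EvaluationError("matching base-level outcomes are required")
    out = outcomes.copy()
    coll = collections_per_fieldyear(outcomes, policy, prices)
    out["_coll"] = coll
    # component 1: region-year mean of collections (area = field count, 1 ha each)
    out["comp_collections"] = out.groupby(["region", "year"])["_coll"].transform("mean")
    if policy.kind in ("base", "voluntary"):
        out["comp_collections"] = 0.0

    base_mean = two_stage_mean(base_outcomes, "profit_after")
    out["_after_c1"] = out["profit_after"] + out["comp_collections"]
    after_mean = two_stage_mean(out, "_after_c1")
    plans: dict[str, CompensationPlan] = {}
    comp2 = {}
    for region in out["region"].unique():
        if region not in base_mean.index:
            raise EvaluationError(f"no base outcomes for region {region!r}")
        cost = float(base_mean[region] - after_mean[region])
        comp2[region] = cost
        plans[region] = CompensationPlan(
            region=region,
            collections_per_ha=float(two_stage_mean(out, "comp_collections")[region]),
            policy_cost_per_ha=cost,
        )
    out["comp_policy_cost"] = out["region"].map(comp2)
    out["income"] = out["profit_after"] + out["comp_collections"] + out["comp_policy_cost"]
    out = out.drop(columns=["_coll", "_after_c1"])
    return out, plans


def aggregate(
    outcomes: pd.DataFrame,
    policy: pe.Policy,
    prices: pe.Prices = pe.Prices(),
    base_outcomes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Indicator summary per region and state for one (policy, sublevel) run.

    Columns: yield (t/ha), leach2 (kg/ha), n_fert (kg/ha), profits (US$/ha,
    after fees), gov_collections (US$/ha), and — when a base run is supplied
    — policy_cost (US$/ha) and abatement_cost (US$ per kg leaching avoided,
    NaN when no leaching is avoided).
    """
    if outcomes.empty:
        raise EvaluationError("no outcomes to aggregate")
    out = outcomes.copy()
    out["_coll"] = collections_per_fieldyear(outcomes, policy, prices)
    agg = pd.DataFrame(
        {
            "yield": two_stage_mean(out, "yield") / 1000.0,
            "leach2": two_stage_mean(out, "leach2"),
            "n_fert": two_stage_mean(out, "n_rate"),
            "profits": two_stage_mean(out, "profit_after"),
            "gov_collections": two_stage_mean(out, "_coll"),
        }
    )
    agg.index.name = "scope"
    agg.insert(0, "policy", policy.kind)
    agg.insert(1, "sublevel", policy.sublevel)
    if base_outcomes is not None:
        base_profit = two_stage_mean(base_outcomes, "profit_after")
        base_leach = two_stage_mean(base_outcomes, "leach2")
        agg["policy_cost"] = base_profit - (agg["profits"] + agg["gov_collections"])
        agg["abatement_cost"] = abatement_cost(
            agg["policy_cost"], base_leach, agg["leach2"]
        )
    return agg


def abatement_cost(policy_cost, base_leach2, policy_leach2):
    """Policy cost per kg of N leaching avoided; NaN when nothing is avoided."""
    delta = np.asarray(base_leach2, dtype=float) - np.asarray(policy_leach2, dtype=float)
    cost = np.asarray(policy_cost, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = np.where(delta > 0, cost / np.where(delta > 0, delta, np.nan), np.nan)
    if np.isscalar(policy_cost) or np.ndim(policy_cost) == 0:
        return float(ac)
    return pd.Series(ac, index=getattr(policy_cost, "index", None))


def yield_guard(
    summaries: pd.DataFrame, base_summaries: pd.DataFrame, tol: float = 0.05
) -> pd.DataFrame:
    """Flag (policy, sublevel) combinations losing > 5% regional yield.

    A run is excluded if regional yield drops strictly below (1 - tol) x the
    base regional yield in ANY region (a 95%-of-base regional yield is kept).
    """
    base_regional = base_summaries.loc[base_summaries.index != STATE, "yield"]
    flagged = summaries.copy()
    flags = []
    for (pol, sub), grp in summaries.groupby(["policy", "sublevel"], sort=False):
        regional = grp.loc[grp.index != STATE, "yield"]
        bad = bool((regional < (1.0 - tol) * base_regional.reindex(regional.index) - 1e-12).any())
        flags.append(((pol, sub), bad))
    flag_map = dict(flags)
    flagged["excluded_flag"] = [
        flag_map[(p, s)] for p, s in zip(flagged["policy"], flagged["sublevel"])
    ]
    return flagged


def round_indicators(summary: pd.DataFrame) -> pd.DataFrame:
    """Reporting-layer rounding: yield 1 decimal (t/ha), money to integer
    US$/ha, abatement cost 1 decimal."""
    out = summary.copy()
    out["yield"] = out["yield"].round(1)
    out["leach2"] = out["leach2"].round(1)
    out["n_fert"] = out["n_fert"].round(0)
    for col in ("profits", "gov_collections", "policy_cost"):
        if col in out.columns:
            out[col] = out[col].round(0)
    if "abatement_cost" in out.columns:
        out["abatement_cost"] = out["abatement_cost"].round(1)
    return out
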