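"""Policy instruments and economically optimal N rate (EONR) selection.

Five policy variants are modeled:

* ``base`` — current market conditions (no intervention): maize at 0.158
  US$/kg, fertilizer N at 0.79 US$/kg, i.e. an N:maize price ratio of 5 kg
  maize per kg N.
* ``price_ratio`` — a fertilizer tax that raises the N:maize price ratio to
  a target level while the maize price stays fixed.
* ``leaching_fee`` — a fee per kg of 2-yr N leaching above a per-region
  threshold (60% of the regional base-level mean leaching).
* ``balance_fee`` — a fee per kg of N-balance surplus (fertilizer N minus
  grain N removal) above a per-region threshold (regional base-level mean
  balance minus 60 kg/ha).
* ``voluntary`` — farmers reduce the base-level EONR by a fixed fraction;
  no transfer of funds to the government.

The EONR under a policy is the grid N rate maximizing after-fee profit on a
field-year response curve; ties break toward the lowest N rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_fields import N_GRID

POLICY_KINDS = ("base", "price_ratio", "leaching_fee", "balance_fee", "voluntary")

#: Inclusive sub-level ranges per policy kind (units in the class docstring).
SUBLEVEL_RANGES = {
    "base": (0.0, 0.0),
    "price_ratio": (5.0, 20.0),
    "leaching_fee": (0.0, 40.0),
    "balance_fee": (0.0, 4.0),
    "voluntary": (0.0, 0.30),
}

#: Default sub-level sweep grids for cost-efficiency curves.
DEFAULT_SWEEPS = {
    "price_ratio": tuple(np.arange(5.0, 20.01, 1.0)),
    "leaching_fee": tuple(np.arange(0.0, 40.01, 2.0)),
    "balance_fee": tuple(np.arange(0.0, 4.001, 0.25)),
    "voluntary": tuple(np.round(np.arange(0.0, 0.3001, 0.02), 2)),
}


class PolicyError(ValueError):
    pass


@dataclass(frozen=True)
class Prices:
    """Market prices; the base N:maize price ratio is 0.79/0.158 = 5."""

    p_maize: float = 0.158  # US$/kg grain
    p_n: float = 0.79       # US$/kg N

    def __post_init__(self):
        if self.p_maize <= 0 or self.p_n <= 0:
            raise PolicyError("prices must be positive")

    @property
    def ratio(self) -> float:
        return self.p_n / self.p_maize


def price_ratio(prices: Prices) -> float:
    """N:maize price ratio, kg maize per kg N."""
    return prices.ratio


@dataclass(frozen=True)
class BalanceParams:
    """N-balance bookkeeping: grain N concentration, kg N per kg grain."""

    grain_n_conc: float = 0.0115

    def __post_init__(self):
        if not 0 < self.grain_n_conc < 0.05:
            raise PolicyError("grain_n_conc must lie in (0, 0.05)")


def n_balance(n_fert, yield_, params: BalanceParams = BalanceParams()):
    """N-balance surplus: fertilizer N minus grain N removal (may be < 0)."""
    return np.asarray(n_fert, dtype=float) - np.asarray(yield_, dtype=float) * params.grain_n_conc


@dataclass(frozen=True)
class Policy:
    """One policy variant with its scalar sub-level and regional thresholds.

    ``sublevel`` units: target price ratio (kg maize/kg N) for
    ``price_ratio``; US$/kg N leached for ``leaching_fee``; US$/kg N balance
    for ``balance_fee``; reduction fraction for ``voluntary``; ignored for
    ``base``.
    """

    kind: str = "base"
    sublevel: float = 0.0
    leach_thresholds: Mapping[str, float] | None = None
    balance_thresholds: Mapping[str, float] | None = None
    balance_params: BalanceParams = BalanceParams()

    def __post_init__(self):
        if self.kind not in POLICY_KINDS:
            raise PolicyError(f"unknown policy kind {self.kind!r}")
        lo, hi = SUBLEVEL_RANGES[self.kind]
        if self.kind != "base" and not lo <= self.sublevel <= hi:
            raise PolicyError(
                f"{self.kind} sublevel {self.sublevel} outside [{lo}, {hi}]"
            )
        if self.kind == "leaching_fee" and self.leach_thresholds is None:
            raise PolicyError("leaching_fee policy requires leach_thresholds")
        if self.kind == "balance_fee" and self.balance_thresholds is None:
            raise PolicyError("balance_fee policy requires balance_thresholds")

    def effective_p_n(self, prices: Prices) -> float:
        """Fertilizer price farmers face (tax-inclusive for price_ratio)."""
        if self.kind == "price_ratio":
            return self.sublevel * prices.p_maize
        return prices.p_n


def profit_matrix(
    yields: np.ndarray,
    leach2: np.ndarray,
    regions: Sequence[str],
    policy: Policy,
    prices: Prices = Prices(),
    n_grid: np.ndarray = N_GRID,
) -> np.ndarray:
    """After-fee profit (US$/ha) for every curve (rows) at every grid rate.

    base/voluntary: p_maize*Y - p_n*N.  price_ratio: p_maize*Y - p_n'*N with
    p_n' = sublevel*p_maize.  leaching_fee: base profit minus
    fee*max(0, leach2 - threshold[region]).  balance_fee: base profit minus
    fee*max(0, n_balance - threshold[region]).
    """
    yields = np.atleast_2d(np.asarray(yields, dtype=float))
    leach2 = np.atleast_2d(np.asarray(leach2, dtype=float))
    n = np.asarray(n_grid, dtype=float)
    p_n = policy.effective_p_n(prices)
    prof = prices.p_maize * yields - p_n * n[None, :]
    if policy.kind == "leaching_fee":
        thr = _threshold_vector(policy.leach_thresholds, regions)
        prof = prof - policy.sublevel * np.maximum(0.0, leach2 - thr[:, None])
    elif policy.kind == "balance_fee":
        thr = _threshold_vector(policy.balance_thresholds, regions)
        bal = n_balance(n[None, :], yields, policy.balance_params)
        prof = prof - policy.sublevel * np.maximum(0.0, bal - thr[:, None])
    return prof


def _threshold_vector(thresholds: Mapping[str, float], regions: Sequence[str]) -> np.ndarray:
    try:
        return np.asarray([thresholds[r] for r in regions], dtype=float)
    except KeyError as exc:
        raise PolicyError(f"missing threshold for region {exc.args[0]!r}") from None


def profit(curve: Mapping, n_rate: float, policy: Policy,
           prices: Prices = Prices(), region: str | None = None) -> float:
    """After-fee profit at one grid N rate on one response curve."""
    grid = np.asarray(curve["n_grid"], dtype=float)
    idx = np.flatnonzero(np.isclose(grid, n_rate))
    if idx.size == 0:
        raise PolicyError(f"N rate {n_rate} not on the curve grid")
    region = region or curve.get("region")
    prof = profit_matrix(
        curve["yield_at"], curve["leach2_at"], [region], policy, prices, n_grid=grid
    )
    return float(prof[0, idx[0]])


def snap_down(rate, n_grid: np.ndarray = N_GRID):
    """Largest grid rate <= rate (clipped into the grid)."""
    step = n_grid[1] - n_grid[0]
    snapped = np.floor(np.asarray(rate, dtype=float) / step + 1e-9) * step
    return np.clip(snapped, n_grid[0], n_grid[-1])


def snap_nearest(rate, n_grid: np.ndarray = N_GRID):
    """Nearest grid rate; exact midpoints snap toward the lower rate."""
    step = n_grid[1] - n_grid[0]
    x = np.asarray(rate, dtype=float) / step
    lower = np.floor(x)
    frac = x - lower
    snapped = np.where(frac <= 0.5 + 1e-12, lower, lower + 1) * step
    return np.clip(snapped, n_grid[0], n_grid[-1])


def eonr_vector(
    yields: np.ndarray,
    leach2: np.ndarray,
    regions: Sequence[str],
    policy: Policy,
    prices: Prices = Prices(),
    n_grid: np.ndarray = N_GRID,
) -> np.ndarray:
    """Policy-conditional EONR for every curve (kg N/ha, on the grid).

    Argmax of after-fee profit over the grid, ties toward the lowest rate.
    The voluntary policy scales the base-policy EONR by (1 - sublevel) and
    snaps down to the grid.
    """
    if policy.kind == "voluntary":
        base = eonr_vector(yields, leach2, regions, Policy("base"), prices, n_grid)
        return snap_down(base * (1.0 - policy.sublevel), n_grid)
    prof = profit_matrix(yields, leach2, regions, policy, prices, n_grid)
    # exact-tie tolerance: treat profits within 1e-9 of the max as ties and
    # pick the lowest N among them
    maxp = prof.max(axis=1, keepdims=True)
    is_max = prof >= maxp - 1e-9
    idx = is_max.argmax(axis=1)
    return np.asarray(n_grid, dtype=float)[idx]


def eonr(curve: Mapping, policy: Policy, prices: Prices = Prices(),
         region: str | None = None) -> float:
    """Policy-conditional EONR on one response curve."""
    region = region or curve.get("region")
    grid = np.asarray(curve["n_grid"], dtype=float)
    return float(
        eonr_vector(curve["yield_at"], curve["leach2_at"], [region], policy,
                    prices, n_grid=grid)[0]
    )


def compute_thresholds(base_outcomes: pd.DataFrame) -> tuple[dict, dict]:
    """Regional fee thresholds from realized base-level outcomes.

    leach threshold = 0.6 x regional mean base leaching; balance threshold =
    regional mean base N balance - 60 kg/ha.  ``base_outcomes`` needs columns
    ``region``, ``leach2`` and ``n_balance`` (one row per field-year).
    """
    for col in ("region", "leach2", "n_balance"):
        if col not in base_outcomes.columns:
            raise PolicyError(f"base outcomes missing column {col!r}")
    leach_thr, bal_thr = {}, {}
    grouped = base_outcomes.groupby("region")
    for region in sorted(base_outcomes["region"].unique()):
        grp = grouped.get_group(region)
        if grp.empty:
            raise PolicyError(f"no base outcomes for region {region!r}")
        leach_thr[region] = 0.6 * float(grp["leach2"].mean())
        bal_thr[region] = float(grp["n_balance"].mean()) - 60.0
    if not leach_thr:
        raise PolicyError("base outcomes contain no regions")
    return leach_thr, bal_thr
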