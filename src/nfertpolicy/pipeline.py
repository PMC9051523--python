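"""End-to-end orchestration: leave-one-year-out base run, policy runs,
sub-level sweeps and the full report.

For every held-out year a recommender is trained on the trial curves of the
remaining years under the policy's conditions, then applied ex-ante to the
evaluation fields in maize that year.  Fee thresholds are derived once from
the realized base-level outcomes (0.6 x regional mean leaching; regional
mean balance - 60) and shared by all fee sub-levels, mirroring how a
regulator would publish fixed thresholds.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import effects_analysis as ea
from . import evaluation as ev
from . import policy_engine as pe
from . import recommendation as rec
from .synthetic_fields import Dataset, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


def _fold_seed(seed: int, kind: str, sublevel: float, year: int) -> int:
    """Stable per-(policy, sublevel, fold) training seed below 2**31."""
    key = f"{kind}:{round(float(sublevel), 6)}:{int(year)}".encode()
    h = zlib.crc32(key) & 0x7FFFFFF
    return (seed * 1009 + h) % (2**31 - 1)


@dataclass
class BaseRun:
    outcomes: pd.DataFrame                  # realized base-level field-years
    models: dict[int, rec.Recommender]      # per held-out year
    leach_thresholds: dict[str, float]
    balance_thresholds: dict[str, float]
    summary: pd.DataFrame


@dataclass
class PolicyRun:
    policy: pe.Policy
    outcomes: pd.DataFrame                  # with compensation columns
    summary: pd.DataFrame
    plans: dict[str, ev.CompensationPlan]


def _run_folds(
    dataset: Dataset,
    policy: pe.Policy,
    prices: pe.Prices,
    seed: int,
    base_models: dict[int, rec.Recommender] | None = None,
) -> tuple[pd.DataFrame, dict[int, rec.Recommender]]:
    """Train per-fold recommenders and evaluate the held-out year's fields."""
    years = sorted(dataset.curves["year"].unique())
    all_out = []
    models: dict[int, rec.Recommender] = {}
    for year in years:
        t0 = time.perf_counter()
        if policy.kind == "voluntary":
            if base_models is None or year not in base_models:
                raise ev.EvaluationError("voluntary policy requires base-run models")
            model = base_models[year]
        else:
            table = rec.build_training_table(dataset, policy, prices, held_out_year=year)
            model = rec.train(
                table,
                seed=_fold_seed(seed, policy.kind, policy.sublevel, year),
                policy=policy,
                held_out_year=year,
            )
        models[year] = model
        eval_sub = dataset.eval_curves(year)
        if len(eval_sub.curves) == 0:
            continue
        rates = rec.recommend(model, eval_sub.curves, policy)
        out = ev.evaluate_fields(eval_sub, rates, policy, prices)
        all_out.append(out)
        logger.info(
            "policy=%s sublevel=%s fold=%d fields=%d %.2fs",
            policy.kind, policy.sublevel, year, len(out), time.perf_counter() - t0,
        )
    return pd.concat(all_out, ignore_index=True), models


def run_base(dataset: Dataset, prices: pe.Prices = pe.Prices(), seed: int = 0) -> BaseRun:
    """Base-level leave-one-year-out run; derives the regional fee thresholds."""
    policy = pe.Policy("base")
    outcomes, models = _run_folds(dataset, policy, prices, seed)
    leach_thr, bal_thr = pe.compute_thresholds(outcomes)
    summary = ev.aggregate(outcomes, policy, prices)
    return BaseRun(outcomes, models, leach_thr, bal_thr, summary)


def make_policy(kind: str, sublevel: float, base_run: BaseRun) -> pe.Policy:
    """Instantiate a policy with the base run's thresholds attached."""
    return pe.Policy(
        kind=kind,
        sublevel=sublevel,
        leach_thresholds=base_run.leach_thresholds if kind == "leaching_fee" else None,
        balance_thresholds=base_run.balance_thresholds if kind == "balance_fee" else None,
    )


def run_policy(
    dataset: Dataset,
    policy: pe.Policy,
    base_run: BaseRun,
    prices: pe.Prices = pe.Prices(),
    seed: int = 0,
) -> PolicyRun:
    """One (policy, sublevel) leave-one-year-out run with compensation."""
    outcomes, _ = _run_folds(
        dataset, policy, prices, seed,
        base_models=base_run.models if policy.kind == "voluntary" else None,
    )
    outcomes, plans = ev.compensate(outcomes, base_run.outcomes, policy, prices)
    summary = ev.aggregate(outcomes, policy, prices, base_outcomes=base_run.outcomes)
    return PolicyRun(policy, outcomes, summary, plans)


def sweep(
    dataset: Dataset,
    kind: str,
    sublevels: Sequence[float],
    base_run: BaseRun,
    prices: pe.Prices = pe.Prices(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[float, PolicyRun]]:
    """Run one policy across sub-levels; returns stacked summaries + runs.

    The stacked summary includes the base run (as policy "base") and the
    yield-guard exclusion flag.
    """
    runs: dict[float, PolicyRun] = {}
    frames = [base_run.summary.assign(policy_cost=0.0, abatement_cost=np.nan)]
    for sub in sublevels:
        policy = make_policy(kind, float(sub), base_run)
        run = run_policy(dataset, policy, base_run, prices, seed)
        runs[float(sub)] = run
        frames.append(run.summary)
    stacked = pd.concat(frames)
    stacked = ev.yield_guard(stacked, base_run.summary)
    return stacked, runs


# ---------------------------------------------------------------------------
# Run configuration and the full report
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    synthetic: SyntheticConfig = dc_field(default_factory=SyntheticConfig)
    p_maize: float = 0.158
    p_n: float = 0.79
    sweeps: dict = dc_field(default_factory=lambda: {
        "price_ratio": [6, 7, 8, 9, 10, 12, 14, 17, 20],
        "leaching_fee": [0.5, 1, 1.5, 2, 3, 4, 6, 9, 13, 20],
        "balance_fee": [0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4],
        "voluntary": [0.03, 0.06, 0.09, 0.12, 0.15, 0.18, 0.21, 0.25, 0.30],
    })
    target_reduction: float = 20.0  # % state leaching reduction
    externality_cost_per_kg: float = 16.1
    state_area: float = 4.4e6
    seed: int = 0

    @property
    def prices(self) -> pe.Prices:
        return pe.Prices(self.p_maize, self.p_n)

    @property
    def welfare_params(self) -> ea.WelfareParams:
        return ea.WelfareParams(self.externality_cost_per_kg, self.state_area)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["region_props"] = list(d["synthetic"]["region_props"])
        for k in ("som_mean", "ymax_mean"):
            d["synthetic"][k] = list(d["synthetic"][k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        for k in ("region_props", "som_mean", "ymax_mean"):
            if k in syn:
                syn[k] = tuple(syn[k])
        try:
            cfg = cls(synthetic=SyntheticConfig(**syn), **d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        cfg.synthetic.validate()
        return cfg


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class Report:
    base_summary: pd.DataFrame
    selected: dict                      # policy -> select_sublevel record
    table: pd.DataFrame                 # indicator rows at selected sub-levels
    curves: dict[str, pd.DataFrame]     # policy -> cost-efficiency curve
    effects: pd.DataFrame
    balance_diagnostic: pd.DataFrame
    welfare: dict[str, ea.WelfareReport]
    elasticity: float


def full_report(config: RunConfig, dataset: Dataset | None = None) -> Report:
    """Run the complete analysis: sweeps, 20%-target selection, Table-style
    indicators, field effects, N-balance diagnostic and welfare."""
    if dataset is None:
        dataset = generate_dataset(config.synthetic)
    prices = config.prices
    base = run_base(dataset, prices, config.seed)
    base_comp, _ = ev.compensate(base.outcomes, base.outcomes, pe.Policy("base"), prices)

    curves: dict[str, pd.DataFrame] = {}
    selected: dict[str, dict] = {}
    rows = [base.summary.assign(policy_cost=np.nan, abatement_cost=np.nan,
                                excluded_flag=False)]
    effects: dict[str, list[ea.EffectRegression]] = {}
    welfare_reports: dict[str, ea.WelfareReport] = {}
    ratio_runs: dict[float, PolicyRun] = {}

    for kind, sublevels in config.sweeps.items():
        stacked, runs = sweep(dataset, kind, sublevels, base, prices, config.seed)
        if kind == "price_ratio":
            ratio_runs = runs
        curve = ea.cost_efficiency_curve(stacked)
        curves[kind] = curve
        sel = ea.select_sublevel(curve, config.target_reduction)
        selected[kind] = sel
        run = runs[sel["sublevel"]]
        rows.append(ev.yield_guard(run.summary, base.summary))
        effects[kind] = ea.field_effects(run.outcomes, base_comp)
        welfare_reports[kind] = ea.welfare_from_summaries(
            base.summary, run.summary, config.welfare_params
        )

    # own-price elasticity at the base point, from the two lowest ratio levels
    ratio_levels = sorted(ratio_runs)
    base_ratio = prices.ratio
    first = ratio_levels[0]
    n_base = float(base.summary.loc[ev.STATE, "n_fert"])
    n_first = float(ratio_runs[first].summary.loc[ev.STATE, "n_fert"])
    elasticity = ea.own_price_elasticity(
        prices.p_n, n_base, first * prices.p_maize, n_first
    )

    diag = ea.n_balance_diagnostic(dataset, base.outcomes, seed=config.seed)
    table = pd.concat(rows)
    return Report(
        base_summary=base.summary,
        selected=selected,
        table=table,
        curves=curves,
        effects=ea.effects_table(effects),
        balance_diagnostic=diag,
        welfare=welfare_reports,
        elasticity=elasticity,
    )


def write_report(report: Report, config: RunConfig, outdir: str | Path) -> None:
    """Persist the report: summary.csv, effects.csv, balance_diagnostic.csv,
    welfare.json, cost_efficiency.csv and the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev.round_indicators(report.table).to_csv(outdir / "summary.csv")
    report.effects.to_csv(outdir / "effects.csv", index=False)
    report.balance_diagnostic.to_csv(outdir / "balance_diagnostic.csv", index=False)
    pd.concat(
        [c.assign(policy=k) for k, c in report.curves.items()], ignore_index=True
    ).to_csv(outdir / "cost_efficiency.csv", index=False)
    payload = {
        "elasticity": report.elasticity,
        "selected_sublevels": report.selected,
        "welfare": {k: w.as_dict() for k, w in report.welfare.items()},
    }
    (outdir / "welfare.json").write_text(json.dumps(payload, indent=2))
    dump_config(config, outdir / "config.yaml")
    from . import __version__
    (outdir / "VERSION").write_text(__version__ + "\n")
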