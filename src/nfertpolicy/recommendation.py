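"""Ex-ante N-rate recommendation: the stage-2 learner of the pipeline.

For each policy sub-level and each held-out year, a regressor is trained on
trial field-years (predictors = v5 soil/weather/crop covariates, response =
the policy-conditional EONR computed on the trial response curves) and used
to issue ex-ante recommendations for evaluation fields in the held-out year.

The default model family is a random forest (bagged trees); any regressor
implementing ``fit(X, y)`` / ``predict(X)`` can be injected.  Predictions
are clipped to the N-rate grid range and snapped to the grid (nearest, ties
toward the lower rate) before use.  The voluntary policy reuses the
base-policy model and scales its recommendation by (1 - reduction), snapped
down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import policy_engine as pe
from .synthetic_fields import COVARIATE_NAMES, N_GRID, Dataset

#: Default random-forest hyperparameters (config-overridable).
DEFAULT_RF_PARAMS = {"n_estimators": 300, "n_jobs": 1}


class RecommendationError(ValueError):
    pass


def build_training_table(
    dataset: Dataset,
    policy: pe.Policy,
    prices: pe.Prices = pe.Prices(),
    held_out_year: int | None = None,
) -> pd.DataFrame:
    """One row per trial field-year with its policy-conditional EONR.

    Rows from ``held_out_year`` are excluded (leave-one-year-out); pass
    ``None`` to use every trial year.
    """
    years = set(dataset.curves["year"].unique())
    if held_out_year is not None and held_out_year not in range(dataset.config.n_years):
        raise RecommendationError(f"held-out year {held_out_year} outside the dataset")
    sub = dataset.trial_curves(exclude_year=held_out_year)
    eonrs = pe.eonr_vector(
        sub.yields, sub.leach2, sub.curves["region"].tolist(), policy, prices
    )
    table = sub.curves[["field_id", "year", "region", *COVARIATE_NAMES]].copy()
    table["eonr"] = eonrs
    return table


@dataclass
class Recommender:
    """A fitted EONR predictor plus its training metadata."""

    model: object
    policy_kind: str
    sublevel: float
    held_out_year: int | None
    seed: int
    family: str = "random_forest"

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """Continuous N-rate predictions, clipped to the grid range."""
        missing = [c for c in COVARIATE_NAMES if c not in covariates.columns]
        if missing:
            raise RecommendationError(f"missing covariate {missing[0]!r}")
        X = covariates[list(COVARIATE_NAMES)].to_numpy(dtype=float)
        pred = np.asarray(self.model.predict(X), dtype=float)
        return np.clip(pred, N_GRID[0], N_GRID[-1])


def train(
    table: pd.DataFrame,
    seed: int = 0,
    policy: pe.Policy | None = None,
    held_out_year: int | None = None,
    model_factory: Callable[[int], object] | None = None,
) -> Recommender:
    """Fit a recommender on a training table (needs >= 10 rows).

    ``model_factory(seed)`` may supply any fit/predict regressor; the default
    is a 300-tree random forest seeded deterministically.
    """
    if len(table) < 10:
        raise RecommendationError(
            f"training table has {len(table)} rows; at least 10 required"
        )
    if model_factory is None:
        model = RandomForestRegressor(random_state=seed, **DEFAULT_RF_PARAMS)
        family = "random_forest"
    else:
        model = model_factory(seed)
        family = type(model).__name__
    X = table[list(COVARIATE_NAMES)].to_numpy(dtype=float)
    y = table["eonr"].to_numpy(dtype=float)
    model.fit(X, y)
    policy = policy or pe.Policy("base")
    return Recommender(
        model=model,
        policy_kind=policy.kind,
        sublevel=policy.sublevel,
        held_out_year=held_out_year,
        seed=seed,
        family=family,
    )


def recommend(
    recommender: Recommender,
    covariates: pd.DataFrame,
    policy: pe.Policy,
) -> np.ndarray:
    """Grid N-rate recommendations for evaluation field-years.

    Non-voluntary policies snap the (clipped) prediction to the nearest grid
    rate, ties toward the lower rate.  The voluntary policy scales the
    base-policy prediction by (1 - reduction) and snaps down.
    """
    pred = recommender.predict(covariates)
    if policy.kind == "voluntary":
        if recommender.policy_kind != "base":
            raise RecommendationError(
                "voluntary recommendations require a base-policy recommender"
            )
        return pe.snap_down(pred * (1.0 - policy.sublevel))
    return pe.snap_nearest(pred)
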