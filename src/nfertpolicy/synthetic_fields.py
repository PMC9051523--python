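"""Seeded synthetic populations of maize fields and N-response curves.

This module generates field-level yield and 2-year nitrate-leaching response
curves over a discrete N-rate grid (0–320 kg N/ha in 10 kg steps), together
with early-season (crop stage v5) soil/weather/crop covariates, for a state
divided into three latitudinal regions.  The generated population reproduces
the qualitative spatial structure the downstream policy analysis relies on:
moving south -> north, soil organic matter, attainable yield and baseline
leaching all rise while the economically optimal N rate (EONR) falls.

Curve families
--------------
* Yield: quadratic-plateau, ``Y(N) = Ymax - dY * (1 - N/Nc)^2`` for
  ``N < Nc`` and ``Ymax`` beyond, i.e. concave with a hard plateau at the
  agronomic critical rate ``Nc``.  ``dY = Ymax - Y(0)`` is the total yield
  response to fertilizer; high-organic-matter soils mineralize more N and
  therefore have a smaller ``dY``.
* Leaching (2-yr total: maize year + following soybean year):
  ``L(N) = Lbase + slope * resp * sc * softplus((N - knee*Nc)/sc)``.
  ``Lbase`` is fertilizer-independent background leaching from soil organic
  matter mineralization over the rotation cycle (rising with SOM and with
  early-season rain); the softplus term is the convex fertilizer-driven
  loss — including the soybean-year residual of unrecovered fertilizer N —
  that accelerates once N exceeds crop demand.  ``resp`` couples the
  fertilizer responsiveness of leaching to the field's baseline leaching
  propensity (soils that leach more at N=0 also retain fertilizer N worse).

Both forms are strictly monotone where the analysis requires it: yield is
non-decreasing in N and the 2-yr leaching strictly increasing.

Determinism: one root seed; sites, weather years and every field-year curve
draw from counter-derived child streams (``SeedSequence`` spawn keys), so
changing the number of fields or years does not reshuffle existing draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("south", "central", "north")

#: Discrete N-rate grid shared by every response curve (kg N/ha).
N_GRID = np.arange(0, 321, 10)
GRID_STEP = 10

#: Covariates observable at crop stage v5, in training-table order.
COVARIATE_NAMES = (
    "surface_residue",
    "soil_n_v5",
    "esw_v5",
    "whc",
    "som",
    "sand",
    "clay",
    "rain_to_v5",
    "temp_to_v5",
    "rad_to_v5",
    "long_term_yield",
    "lai_v5",
)


class ConfigurationError(ValueError):
    """Invalid synthetic-population configuration; names the offending field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic field population.

    Defaults are a scaled-down test population (24 trial + 120 evaluation
    fields, 10 weather years); :meth:`paper_scale` returns the full-size
    population (240 trial + 4,030 evaluation fields, 30 years).
    """

    n_trial_fields: int = 24
    n_eval_fields: int = 120
    n_years: int = 10
    region_props: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    # Soil organic matter (%) by region, south -> north rising.
    som_mean: tuple[float, float, float] = (2.0, 2.8, 3.6)
    som_cv: float = 0.15

    # Attainable (plateau) yield level by region, kg grain/ha.
    ymax_mean: tuple[float, float, float] = (12150.0, 12400.0, 13100.0)
    ymax_cv: float = 0.11
    season_quality_sd: float = 0.05  # lognormal sd of the shared year effect
    ymax_noise_sd: float = 0.12      # residual field-year yield noise

    # Yield response magnitude dY = Ymax - Y0 (kg/ha) and its SOM link.
    dyield_mean: float = 2600.0
    dyield_cv: float = 0.18
    dyield_som_slope: float = 0.05   # fractional dY decrease per % SOM above state mean

    # Latent EONR model (kg N/ha); regional gradient emerges from SOM.
    eonr_base: float = 175.0
    eonr_som_slope: float = 18.0     # kg N/ha decrease per % SOM
    eonr_soiln_slope: float = 0.45   # kg N/ha decrease per kg soil N at v5
    eonr_rain_slope: float = 0.06    # kg N/ha per mm early rain (losses)
    eonr_noise_sd: float = 12.0

    # Baseline 2-yr leaching Lbase = lbase_coef * som**lbase_exp * wet * noise.
    lbase_coef: float = 12.1
    lbase_exp: float = 0.51
    lbase_noise_sd: float = 0.42
    wet_exponent: float = 0.6        # rain sensitivity of background leaching

    # Fertilizer-driven leaching (2-yr total: the soybean-year residual of
    # fertilizer N is folded into this convex term).
    leach_slope: float = 0.43        # kg leach per kg N at full marginal response
    leach_scale: float = 40.0        # softplus smoothing scale, kg N/ha
    leach_knee_frac: float = 0.70    # knee position as a fraction of Nc
    leach_resp_exp: float = 0.25     # coupling of responsiveness to Lbase
    grain_n_conc: float = 0.0115     # kg N removed per kg grain

    # Early-season weather (to v5).
    rain_mean: float = 330.0
    rain_sd: float = 80.0
    temp_mean: float = 290.0
    temp_sd: float = 25.0
    rad_mean: float = 950.0
    rad_sd: float = 80.0

    seed: int = 2022

    @classmethod
    def paper_scale(cls, seed: int = 2022) -> "SyntheticConfig":
        """Full-size population: 240 trial + 4,030 evaluation fields, 30 years."""
        return cls(n_trial_fields=240, n_eval_fields=4030, n_years=30, seed=seed)

    def validate(self) -> None:
        if self.n_trial_fields < 2:
            raise ConfigurationError("n_trial_fields must be >= 2")
        if self.n_trial_fields % 2 != 0:
            raise ConfigurationError(
                "n_trial_fields must be even (maize-soy rotation halves must be equal)"
            )
        if self.n_eval_fields < 2:
            raise ConfigurationError("n_eval_fields must be >= 2")
        if self.n_years < 2:
            raise ConfigurationError("n_years must be >= 2")
        if len(self.region_props) != 3 or any(p < 0 for p in self.region_props):
            raise ConfigurationError("region_props must be three non-negative weights")
        if not np.isclose(sum(self.region_props), 1.0):
            raise ConfigurationError("region_props must sum to 1")
        if any(m <= 0 for m in self.som_mean):
            raise ConfigurationError("som_mean entries must be positive")
        if not 0 < self.grain_n_conc < 0.05:
            raise ConfigurationError("grain_n_conc must lie in (0, 0.05)")


def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    """Counter-derived child stream: stable under changing field/year counts."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    )


def _region_counts(n: int, props: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n fields over the three regions."""
    raw = np.asarray(props, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def generate_sites(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the static field population (one row per field).

    Trial fields get ids 0..n_trial-1, evaluation fields follow; within each
    role, regions are assigned by the configured proportions so the two roles
    are spatially interleaved (same regional mix).
    """
    config.validate()
    rows = []
    for role, n_fields, id0 in (
        ("trial", config.n_trial_fields, 0),
        ("evaluation", config.n_eval_fields, config.n_trial_fields),
    ):
        counts = _region_counts(n_fields, config.region_props)
        region_seq = [r for r, c in zip(REGIONS, counts) for _ in range(c)]
        for i, region in enumerate(region_seq):
            fid = id0 + i
            r = REGIONS.index(region)
            rng = _rng(config, 0, fid)
            som = config.som_mean[r] * rng.lognormal(0.0, config.som_cv)
            sand = float(np.clip(rng.normal(28 - 4 * r, 8), 5, 70))
            clay = float(np.clip(rng.normal(26 + 3 * r, 7), 5, min(60, 95 - sand)))
            whc = float(np.clip(rng.normal(165 + 12 * som, 20), 80, 300))
            lty = config.ymax_mean[r] * rng.lognormal(0.0, config.ymax_cv)
            rows.append(
                {
                    "field_id": fid,
                    "region": region,
                    "som": som,
                    "sand": sand,
                    "clay": clay,
                    "whc": whc,
                    "long_term_yield": lty,
                    "role": role,
                }
            )
    sites = pd.DataFrame(rows)
    return sites


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """One shared weather year per calendar year (the leave-one-year-out block)."""
    config.validate()
    rows = []
    for year in range(config.n_years):
        rng = _rng(config, 2, year)
        rows.append(
            {
                "year": year,
                "rain_to_v5": float(np.clip(rng.normal(config.rain_mean, config.rain_sd), 60, None)),
                "temp_to_v5": float(rng.normal(config.temp_mean, config.temp_sd)),
                "rad_to_v5": float(rng.normal(config.rad_mean, config.rad_sd)),
                "season_quality": float(rng.lognormal(0.0, config.season_quality_sd)),
            }
        )
    return pd.DataFrame(rows)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _curve_latents(site: Mapping, season: Mapping, config: SyntheticConfig,
                   rng: np.random.Generator) -> dict:
    """Draw the per-field-year latent parameters and v5 covariates."""
    som = float(site["som"])
    region = site["region"]
    r = REGIONS.index(region)
    rain = float(season["rain_to_v5"])
    wet = (rain / config.rain_mean) ** config.wet_exponent

    # Mineralization proxy observable at v5 (kg N/ha, 0-60 cm).
    soil_n_latent = 12.0 * som * wet ** 0.3 + rng.normal(0.0, 4.0)
    soil_n_latent = max(soil_n_latent, 2.0)

    som_state_mean = float(np.mean(config.som_mean))
    eonr_target = (
        config.eonr_base
        - config.eonr_som_slope * (som - som_state_mean)
        - config.eonr_soiln_slope * (soil_n_latent - 12.0 * som_state_mean)
        + config.eonr_rain_slope * (rain - config.rain_mean)
        + rng.normal(0.0, config.eonr_noise_sd)
    )
    eonr_target = float(np.clip(eonr_target, 30.0, 300.0))

    ymax = (
        float(site["long_term_yield"])
        * float(season["season_quality"])
        * rng.lognormal(0.0, config.ymax_noise_sd)
    )
    dyield = (
        config.dyield_mean
        * (1.0 - config.dyield_som_slope * (som - som_state_mean))
        * rng.lognormal(0.0, config.dyield_cv)
    )
    # The base-price EONR exists on the response only if the marginal yield at
    # N=0 exceeds the price ratio; clamp dY (and below Nc) accordingly.
    r0 = 5.0  # base price ratio used to anchor the curvature
    dyield = float(np.clip(dyield, 2.0 * r0 * eonr_target / 0.95, max(ymax - 300.0, 500.0)))
    arg = 1.0 - 2.0 * r0 * eonr_target / dyield
    nc = dyield / r0 * (1.0 - np.sqrt(max(arg, 1e-9)))
    clamped = nc > N_GRID[-1]
    nc = float(np.clip(nc, 40.0, N_GRID[-1]))

    lbase = (
        config.lbase_coef
        * som ** config.lbase_exp
        * wet
        * rng.lognormal(0.0, config.lbase_noise_sd)
    )
    lbase_typ = config.lbase_coef * som_state_mean ** config.lbase_exp
    resp = (lbase / (lbase_typ * wet)) ** config.leach_resp_exp * wet

    covariates = {
        "surface_residue": float(site["long_term_yield"]) / 2500.0 + rng.normal(0.0, 0.4),
        "soil_n_v5": soil_n_latent + rng.normal(0.0, 2.0),
        "esw_v5": float(site["whc"]) * min(wet ** 0.5, 1.3) * 0.6 + rng.normal(0.0, 8.0),
        "whc": float(site["whc"]),
        "som": som,
        "sand": float(site["sand"]),
        "clay": float(site["clay"]),
        "rain_to_v5": rain,
        "temp_to_v5": float(season["temp_to_v5"]),
        "rad_to_v5": float(season["rad_to_v5"]),
        "long_term_yield": float(site["long_term_yield"]),
        "lai_v5": 2.2 * ymax / 12500.0 + rng.normal(0.0, 0.15),
    }
    return {
        "ymax": ymax,
        "dyield": dyield,
        "nc": nc,
        "lbase": lbase,
        "resp": resp,
        "clamped": bool(clamped),
        "region_idx": r,
        "covariates": covariates,
    }


def _curve_arrays(lat: dict, config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate yield and 2-yr leaching on the N grid from latent parameters."""
    n = N_GRID.astype(float)
    ymax, dy, nc = lat["ymax"], lat["dyield"], lat["nc"]
    yields = np.where(n < nc, ymax - dy * (1.0 - n / nc) ** 2, ymax)
    yields = np.maximum(yields, 0.0)
    knee = config.leach_knee_frac * nc
    fert = (
        config.leach_slope
        * lat["resp"]
        * config.leach_scale
        * _softplus((n - knee) / config.leach_scale)
    )
    leach2 = lat["lbase"] + fert
    return yields, leach2


def generate_response_curve(site: Mapping, season: Mapping,
                            config: SyntheticConfig) -> dict:
    """Generate one field-year response curve.

    Returns a dict with ``n_grid``, ``yield_at``, ``leach2_at`` arrays and the
    ``covariates_v5`` mapping.  Latent parameters outside valid ranges are
    clamped (logged at debug level).
    """
    rng = _rng(config, 1, int(site["field_id"]), int(season["year"]))
    lat = _curve_latents(site, season, config, rng)
    if lat["clamped"]:
        logger.debug(
            "field %s year %s: critical rate clamped to grid maximum",
            site["field_id"], season["year"],
        )
    yields, leach2 = _curve_arrays(lat, config)
    return {
        "field_id": int(site["field_id"]),
        "year": int(season["year"]),
        "region": site["region"],
        "n_grid": N_GRID.copy(),
        "yield_at": yields,
        "leach2_at": leach2,
        "covariates_v5": lat["covariates"],
    }


@dataclass
class Dataset:
    """A generated population: sites, weather, and all maize-year curves.

    ``curves`` holds one row per field-year in maize (rotation parity), with
    region/role and the v5 covariates; ``yields`` and ``leach2`` are aligned
    (n_rows, len(N_GRID)) arrays.
    """

    config: SyntheticConfig
    sites: pd.DataFrame
    weather: pd.DataFrame
    curves: pd.DataFrame
    yields: np.ndarray
    leach2: np.ndarray

    @property
    def n_grid(self) -> np.ndarray:
        return N_GRID

    def subset(self, mask: np.ndarray) -> "Dataset":
        idx = np.flatnonzero(np.asarray(mask))
        return Dataset(
            config=self.config,
            sites=self.sites,
            weather=self.weather,
            curves=self.curves.iloc[idx].reset_index(drop=True),
            yields=self.yields[idx],
            leach2=self.leach2[idx],
        )

    def trial_curves(self, exclude_year: int | None = None) -> "Dataset":
        mask = self.curves["role"].to_numpy() == "trial"
        if exclude_year is not None:
            mask &= self.curves["year"].to_numpy() != exclude_year
        return self.subset(mask)

    def eval_curves(self, year: int) -> "Dataset":
        mask = (self.curves["role"].to_numpy() == "evaluation") & (
            self.curves["year"].to_numpy() == year
        )
        return self.subset(mask)


def rotation_parity(sites: pd.DataFrame) -> pd.Series:
    """Maize-year parity per field: within each role, alternate halves grow
    maize on even vs odd years (maize-soy rotation)."""
    parity = pd.Series(index=sites.index, dtype=int)
    for role in ("trial", "evaluation"):
        sel = sites["role"] == role
        ids = sites.loc[sel, "field_id"].rank(method="first").astype(int) - 1
        parity.loc[sel] = (ids % 2).to_numpy()
    return parity


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate the full dataset: sites, weather and all maize-year curves."""
    config.validate()
    sites = generate_sites(config)
    weather = generate_weather(config)
    parity = rotation_parity(sites)

    rows = []
    ylist, llist = [], []
    n_clamped = 0
    site_records = sites.to_dict("records")
    weather_records = weather.to_dict("records")
    for site, par in zip(site_records, parity):
        for season in weather_records:
            if season["year"] % 2 != par:
                continue
            rng = _rng(config, 1, int(site["field_id"]), int(season["year"]))
            lat = _curve_latents(site, season, config, rng)
            n_clamped += lat["clamped"]
            yields, leach2 = _curve_arrays(lat, config)
            row = {
                "field_id": site["field_id"],
                "year": season["year"],
                "region": site["region"],
                "role": site["role"],
            }
            row.update(lat["covariates"])
            rows.append(row)
            ylist.append(yields)
            llist.append(leach2)
    if n_clamped:
        logger.warning("%d curves had their critical N rate clamped to the grid maximum",
                       n_clamped)
    curves = pd.DataFrame(rows)
    return Dataset(
        config=config,
        sites=sites,
        weather=weather,
        curves=curves,
        yields=np.vstack(ylist),
        leach2=np.vstack(llist),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

DATA_DICTIONARY = """\
# Data dictionary

## sites.csv (one row per field)
- field_id: integer field identifier
- region: south | central | north
- som: soil organic matter, %
- sand, clay: texture, % (sand + clay <= 100)
- whc: water holding capacity, mm
- long_term_yield: attainable yield level, kg grain/ha
- role: trial | evaluation

## curves.csv (long format, one row per field x year x N rate)
- field_id, year, region, role: keys
- n_rate: fertilizer N, kg N/ha (0..320 step 10)
- yield: maize grain yield at n_rate, kg/ha
- leach2: 2-year N leaching (maize + following soybean year), kg N/ha
- covariates observable at v5 (identical across n_rate within a field-year):
  surface_residue (t/ha), soil_n_v5 (kg N/ha 0-60 cm), esw_v5 (mm),
  whc (mm), som (%), sand (%), clay (%), rain_to_v5 (mm),
  temp_to_v5 (degree-days), rad_to_v5 (MJ/m2), long_term_yield (kg/ha),
  lai_v5 (m2/m2)
"""


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Write sites.csv, curves.csv (long format) and the data dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.sites.to_csv(outdir / "sites.csv", index=False)
    n_rows, n_pts = dataset.yields.shape
    long = dataset.curves.loc[dataset.curves.index.repeat(n_pts)].reset_index(drop=True)
    long.insert(4, "n_rate", np.tile(N_GRID, n_rows))
    long.insert(5, "yield", dataset.yields.ravel())
    long.insert(6, "leach2", dataset.leach2.ravel())
    long.to_csv(outdir / "curves.csv", index=False)
    (outdir / "data_dictionary.md").write_text(DATA_DICTIONARY)


def read_dataset(indir: str | Path, config: SyntheticConfig | None = None) -> Dataset:
    """Load a dataset written by :func:`write_dataset` (or user-supplied CSVs
    with the same columns)."""
    indir = Path(indir)
    sites = pd.read_csv(indir / "sites.csv")
    long = pd.read_csv(indir / "curves.csv")
    key = ["field_id", "year"]
    meta_cols = [c for c in long.columns if c not in ("n_rate", "yield", "leach2")]
    curves = long[meta_cols].drop_duplicates(subset=key).reset_index(drop=True)
    n_pts = long.groupby(key, sort=False).size().iloc[0]
    if not (long.groupby(key, sort=False).size() == n_pts).all():
        raise ValueError("curves.csv: unequal grid lengths across field-years")
    order = long.sort_values(key + ["n_rate"], kind="stable")
    grid = np.sort(order["n_rate"].unique())
    if len(grid) != n_pts:
        raise ValueError("curves.csv: inconsistent N grid")
    yields = order["yield"].to_numpy().reshape(-1, n_pts)
    leach2 = order["leach2"].to_numpy().reshape(-1, n_pts)
    curves_sorted = order[meta_cols].drop_duplicates(subset=key).reset_index(drop=True)
    return Dataset(
        config=config or SyntheticConfig(),
        sites=sites,
        weather=pd.DataFrame({"year": sorted(curves_sorted["year"].unique())}),
        curves=curves_sorted,
        yields=yields,
        leach2=leach2,
    )
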