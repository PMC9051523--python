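# Methods

`nfertpolicy` simulates how economic policy instruments change nitrogen (N)
fertilizer decisions on maize fields, and what that implies for nitrate
leaching, yields, farm income, government budgets and social welfare. It is
a desk-scale re-implementation of a three-stage bio-economic pipeline:
synthetic field-level N-response data stand in for a process-based crop
model, a statistical learner issues ex-ante N-rate recommendations, and an
accounting layer aggregates field outcomes into regional and state
indicators.

## The decision model

A field-year is described by two curves over the N-rate grid
N ∈ {0, 10, …, 320} kg N/ha:

* grain yield Y(N), concave and plateauing (quadratic-plateau:
  Y(N) = Ymax − dY·(1 − N/Nc)² for N < Nc, else Ymax);
* two-year N leaching L(N) (maize year plus the following soybean year),
  strictly increasing and convex in N, positive at N = 0.

Profit under each policy, with maize price p_m (0.158 US$/kg) and
fertilizer price p_n (0.79 US$/kg, price ratio p_n/p_m = 5):

| policy | after-fee profit at rate N |
|---|---|
| base, voluntary | p_m·Y(N) − p_n·N |
| price ratio r | p_m·Y(N) − (r·p_m)·N |
| leaching fee f | base profit − f·max(0, L(N) − T_L(region)) |
| balance fee f | base profit − f·max(0, B(N) − T_B(region)) |

where the N balance is B(N) = N − c·Y(N) with grain N concentration
c = 0.0115 kg N/kg grain. The economically optimal N rate (EONR) is the
grid argmax of after-fee profit; ties break toward the lowest rate
(environmentally conservative; the choice only matters on exactly flat
profit segments). The voluntary policy takes the base EONR scaled by
(1 − reduction), snapped down to the grid.

Fee thresholds are regional and derived from the realized base-level run:
T_L = 0.6 × regional mean base leaching; T_B = regional mean base balance
− 60 kg/ha. They are computed once from the base run and shared by every
fee sub-level, as a regulator publishing fixed thresholds would do.

Sub-level ranges: price ratio 5–20 kg maize/kg N; leaching fee 0–40 US$/kg;
balance fee 0–4 US$/kg; voluntary reduction 0–30%.

## The three-stage pipeline

For each held-out year (leave-one-year-out over all simulated years):

1. **Trial data** — the trial fields' response curves from all other years.
   With 240 trial fields on a maize–soy rotation (half in maize each year)
   and 30 years this is 120 × 29 = 3,480 curves per fold.
2. **Optimization** — per policy sub-level, the policy-conditional EONR is
   computed on every trial curve and a random forest (300 trees,
   scikit-learn defaults otherwise, deterministic seed per fold) is trained
   to predict it from twelve covariates observable at crop stage v5:
   surface residue, soil N 0–60 cm, extractable soil water, water holding
   capacity, soil organic matter, sand, clay, rain/temperature/radiation to
   v5, long-term yield and LAI at v5. The voluntary policy reuses the base
   model. The model family is injectable (any `fit`/`predict` regressor).
3. **Evaluation** — recommendations (clipped to [0, 320], snapped to the
   nearest grid rate, ties down) are applied to the evaluation fields in
   maize that year; yield and leaching are read off their curves; revenue,
   tax-inclusive fertilizer cost, fees, profit and N balance are recorded.

Aggregation is two-stage: mean over years within each field (years weighted
equally), then an unweighted mean over fields for the region; the state is
the unweighted mean over all fields. Every field represents 1 ha.

**Compensation** is a lump sum per ha, equal for all fields of a region:
component 1 returns the region-year's government collections (fee revenue,
or the tax wedge (p_n′ − p_n)·N under the price-ratio policy; zero under
base and voluntary); component 2 covers the policy cost — the regional mean
base profit minus the regional mean of (after-fee profit + component 1) —
i.e. the deadweight loss. By construction component 1 is conserved exactly
within each region-year and compensation restores regional mean income to
the base level; both identities are asserted in tests.

Sub-levels whose regional yield falls strictly below 95% of the base
regional yield in any region are excluded (a stand-in for price feedbacks
that are out of scope).

**Welfare**: with an externality cost of 16.1 US$/kg N leached and a state
maize area of 4.4 Mha, welfare gain = leaching reduction × area × 16.1 −
policy cost; transfers (taxes, fees, compensation) cancel. The ROI is the
welfare gain over the policy cost, reported to the nearest percent as
computed (published figures derived from the same inputs round to ~257%;
a printed headline of 260% is not reproduced by the arithmetic and is not
matched).

**Own-price elasticity** of N demand is an arc (midpoint) elasticity
between the base point and the first swept price-ratio level; the midpoint
convention is a documented choice (the quantity is reported, not targeted).
On default synthetic data it is ≈ 0.2–0.3 — inelastic, which is why large
price movements are needed for modest N reductions.

## The synthetic population

The generator emulates the structure of a crop-model dataset for an
Illinois-like state: three latitudinal regions (south/central/north, equal
shares by default) with rising soil organic matter (SOM: 2.0/2.8/3.6%),
rising attainable yield (12.15/12.4/13.1 t/ha) and rising baseline leaching
south → north, and falling EONR (≈195/175/155 kg N/ha). Defaults were
calibrated once so the base-level regional indicators match the published
regional structure of the system being modeled (state means ≈ 176 kg N/ha,
12.6 t/ha, 38.8 kg leached/ha, 1,850 US$/ha profit); they are study
conditions, not free dials.

Per field-year, a latent EONR target is drawn as a linear function of SOM,
a mineralization proxy (soil N at v5) and early rain plus noise; the yield
curve's critical rate Nc is solved so the base-price EONR equals that
target. Covariates are noisy observations of the underlying latents, which
makes them genuinely informative: a tree ensemble predicts base EONR with
out-of-fold RMSE at least 20% below the constant-mean predictor (asserted).

Two-year leaching is L(N) = Lbase + slope·resp·sc·softplus((N − knee·Nc)/sc):

* Lbase = 12.1·SOM^0.51·(rain/330)^0.6·lognormal(σ=0.42) — background
  leaching from mineralization over the rotation cycle, independent of N;
* the softplus term is the fertilizer-driven loss (slope 0.43 kg/kg, scale
  40 kg/ha, knee at 0.70·Nc), which accelerates once N outruns crop demand;
* resp = (field's SOM/noise factor)^0.25 couples fertilizer responsiveness
  to baseline leaching propensity, so soils that leach more also retain
  fertilizer N worse — this is what concentrates policy-induced reductions
  in high-leaching fields (point-source slopes < 1).

The soybean-year residual of fertilizer N is folded into the convex term
and Lbase rather than modeled as an explicit fraction of the maize-year N
surplus. An explicit surplus term would hard-wire a cross-field correlation
between the N-balance indicator and leaching at a fixed N rate, and the
weakness of exactly that correlation — leaching driven by soil and weather,
not by the balance — is a qualitative property of the system this package
must reproduce (see the N-balance diagnostic below).

Determinism: one root seed; sites, weather years and each field-year curve
use counter-derived child streams (`SeedSequence` spawn keys), so extending
the simulated period does not reshuffle earlier draws. Regions are assigned
by largest-remainder apportionment within each role, so trial and
evaluation fields share the same regional mix.

What the generator does **not** emulate: process-based soil dynamics, daily
weather, spatial autocorrelation, manure N, management practices other than
the N rate, or real geography. Passing tests therefore demonstrate that the
pipeline's economics and accounting behave correctly under the assumed
response structure — not that the absolute indicator values transfer to
real fields.

## The N-balance diagnostic

Five regressions of 2-yr leaching on the N balance, with growing data
complexity: (A) one location × four fixed rates; (B) 45 locations × four
rates; (C) many locations at one common rate; (D) 45 locations at
recommended base rates; (E) all available locations at recommended rates.
Rate-driven variation (A, B) produces positive, significant slopes; with a
common rate (C) the relationship collapses (r² < 0.02 at the default seed)
because leaching variation then comes from SOM, weather and soil noise that
the balance bookkeeping does not see. Scenario sizes shrink automatically
on small datasets; degenerate scenarios return NaNs with a warning.

## Problem sizes and numerical choices

* Default population: 24 trial + 120 evaluation fields × 10 years (720
  maize field-years), the package's standard desk-scale study size; the
  full-size population (240 + 4,030 × 30) is available via
  `SyntheticConfig.paper_scale()`.
* Default sub-level sweeps (configurable) cover ratio 6–20, leaching fee
  0.5–20, balance fee 0.25–4, voluntary 3–30%; the 20% target selection
  reports both the first achieving grid sub-level and a linear
  interpolation between the bracketing levels — re-running at the
  interpolated level lands within ±2 percentage points of the target.
* EONR ties: profits within 1e-9 US$/ha are treated as tied; the lowest
  rate wins.
* Latent curve parameters are clamped to valid ranges (Nc to the grid
  maximum, dY to keep a positive-EONR interior solution); clamping is
  logged. About 2–4% of curves hit the Nc clamp at default settings.
* Monotonicity checks of pipeline trajectories (N use, leaching, profits
  vs sub-level) allow a 0.5% relative tolerance for random-forest refit
  noise; per-curve EONR monotonicity is exact and asserted without
  tolerance.
* Reporting-layer rounding (yield 0.1 t/ha, money 1 US$/ha, abatement cost
  0.1 US$/kg) is applied only when writing `summary.csv`.

## Known limitations

* Policy cost levels at desk scale (≈ 10–16 US$/ha at the 20% reduction)
  are below the full-scale published range (30–37 US$/ha): deadweight loss
  depends on the curvature heterogeneity of thousands of real response
  surfaces, which a 144-field synthetic population compresses. Relative
  orderings (leaching fee cheapest per kg abated; costs rising convexly
  with the reduction target) are reproduced.
* Profits cover the maize year only; leaching covers the 2-year rotation
  cycle (the soybean year carries no revenue term).
* Farmers are risk-neutral profit maximizers who apply exactly the
  recommended rate; no behavioral response, transaction costs, land-use
  change or price feedback beyond the 5% yield guard.
* The scenario-C r² fluctuates with the seed (≈ 0.002–0.05 across seeds at
  the default population size) because only ~144 distinct fields inform
  the cross-field correlation; the default-seed value is 0.002.
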