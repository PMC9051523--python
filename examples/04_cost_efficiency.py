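"""Cost-efficiency curves and selection of the 20%-reduction sub-level.

Sweeps the leaching fee and voluntary reduction across sub-levels, prints
(leaching reduction %, policy cost) pairs, and selects the sub-level that
reaches a 20% state-wide leaching reduction.
"""

from nfertpolicy import effects_analysis as ea
from nfertpolicy import pipeline as pl
from nfertpolicy.synthetic_fields import generate_dataset

cfg = pl.RunConfig()
ds = generate_dataset(cfg.synthetic)
base = pl.run_base(ds, cfg.prices, seed=0)

for kind, subs in [("leaching_fee", [1, 2, 3, 4, 6, 9]),
                   ("voluntary", [0.05, 0.10, 0.15, 0.20, 0.25])]:
    stacked, _ = pl.sweep(ds, kind, subs, base, cfg.prices, seed=0)
    curve = ea.cost_efficiency_curve(stacked)
    print(f"\n{kind}:")
    print(curve.round(2).to_string(index=False))
    sel = ea.select_sublevel(curve, 20.0)
    print(f"  20% target -> sub-level {sel['sublevel']} "
          f"(interpolated {sel['sublevel_interp']:.2f}), "
          f"achieved {sel['achieved_reduction_pct']:.1f}%")

print(
    "\nPolicy cost rises convexly with the reduction target: early kilograms\n"
    "of abated leaching are cheap, deeper cuts increasingly hurt profits."
)
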