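"""Outcome accounting, compensation conservation and aggregation rules."""

import numpy as np
import pandas as pd
import pytest

from nfertpolicy import evaluation as ev
from nfertpolicy import policy_engine as pe

from conftest import hand_curve


class TestEvaluateField:
    def test_base_profit_arithmetic(self):
        curve = hand_curve([0, 100, 200], [5000, 9000, 9500])
        out = ev.evaluate_field(curve, 100, pe.Policy("base"))
        assert out["profit_after"] == pytest.approx(0.158 * 9000 - 0.79 * 100)
        assert out["fee_paid"] == 0.0
        assert out["n_balance"] == pytest.approx(100 - 0.0115 * 9000)

    def test_linear_leaching_fee(self):
        curve = hand_curve([0, 100], [5000, 9000], leach2=[10.0, 25.0])
        pol = pe.Policy("leaching_fee", 10.0, leach_thresholds={"central": 23.0})
        out = ev.evaluate_field(curve, 100, pol)
        assert out["fee_paid"] == pytest.approx(20.0)  # 10 $/kg x 2 kg over threshold
        assert out["profit_after"] == pytest.approx(0.158 * 9000 - 0.79 * 100 - 20.0)

    def test_voluntary_pays_no_fee(self):
        curve = hand_curve([0, 100], [5000, 9000], leach2=[10.0, 25.0])
        out = ev.evaluate_field(curve, 100, pe.Policy("voluntary", 0.2))
        assert out["fee_paid"] == 0.0

    def test_price_ratio_tax_in_fert_cost(self):
        curve = hand_curve([0, 100], [5000, 9000])
        out = ev.evaluate_field(curve, 100, pe.Policy("price_ratio", 10.0))
        assert out["fert_cost"] == pytest.approx(10.0 * 0.158 * 100)

    def test_off_grid_rate_errors(self):
        curve = hand_curve([0, 100], [5000, 9000])
        with pytest.raises(ev.EvaluationError):
            ev.evaluate_field(curve, 55, pe.Policy("base"))

    def test_identity_profit_decomposition(self, default_dataset, base_run):
        out = base_run.outcomes
        np.testing.assert_allclose(
            out["profit_after"],
            out["gross_revenue"] - out["fert_cost"] - out["fee_paid"],
            rtol=1e-12,
        )
        assert (out["fee_paid"] >= 0).all()
        assert (out["fee_paid"] == 0).all()  # base policy charges nothing


def _toy_outcomes():
    """Two regions; one field with 1 year, one with 3 years in the south."""
    return pd.DataFrame(
        {
            "field_id": [1, 2, 2, 2, 3],
            "year": [0, 0, 1, 2, 0],
            "region": ["south", "south", "south", "south", "north"],
            "n_rate": [100.0, 200.0, 200.0, 200.0, 150.0],
            "yield": [9000.0, 10000.0, 10000.0, 10000.0, 11000.0],
            "leach2": [30.0, 40.0, 40.0, 40.0, 50.0],
            "gross_revenue": [1422.0, 1580.0, 1580.0, 1580.0, 1738.0],
            "fert_cost": [79.0, 158.0, 158.0, 158.0, 118.5],
            "fee_paid": [10.0, 30.0, 30.0, 30.0, 0.0],
            "profit_after": [1333.0, 1392.0, 1392.0, 1392.0, 1619.5],
            "n_balance": [-3.5, 85.0, 85.0, 85.0, 23.5],
        }
    )


class TestAggregation:
    def test_single_field_year_equals_outcome(self):
        out = _toy_outcomes().iloc[[4]]
        agg = ev.aggregate(out, pe.Policy("base"))
        assert agg.loc["north", "yield"] == pytest.approx(11.0)
        assert agg.loc[ev.STATE, "profits"] == pytest.approx(1619.5)

    def test_fields_weighted_equally_regardless_of_year_count(self):
        out = _toy_outcomes()
        agg = ev.aggregate(out, pe.Policy("base"))
        # south: field 1 (one year) and field 2 (three years) each weigh 1/2
        assert agg.loc["south", "n_rate" if "n_rate" in agg else "n_fert"] == pytest.approx(150.0)
        assert agg.loc["south", "profits"] == pytest.approx((1333.0 + 1392.0) / 2)
        # state: three fields, equal weights
        assert agg.loc[ev.STATE, "leach2"] == pytest.approx((30 + 40 + 50) / 3)

    def test_two_stage_mean_helper(self):
        out = _toy_outcomes()
        m = ev.two_stage_mean(out, "fee_paid")
        assert m["south"] == pytest.approx((10 + 30) / 2)
        assert m[ev.STATE] == pytest.approx((10 + 30 + 0) / 3)

    def test_empty_errors(self):
        with pytest.raises(ev.EvaluationError):
            ev.aggregate(_toy_outcomes().iloc[:0], pe.Policy("base"))


class TestCollections:
    def test_base_collects_nothing(self):
        coll = ev.government_collections(_toy_outcomes(), pe.Policy("base"))
        assert (coll == 0).all()

    def test_voluntary_collects_nothing(self):
        coll = ev.government_collections(_toy_outcomes(), pe.Policy("voluntary", 0.1))
        assert (coll == 0).all()

    def test_fee_mean(self):
        pol = pe.Policy("leaching_fee", 1.0, leach_thresholds={"south": 0, "north": 0})
        coll = ev.government_collections(_toy_outcomes(), pol)
        assert coll["south"] == pytest.approx(20.0)  # fields pay 10 and 30

    def test_price_ratio_wedge(self):
        pol = pe.Policy("price_ratio", 10.0)
        coll = ev.government_collections(_toy_outcomes().iloc[[0]], pol)
        wedge = (10.0 * 0.158 - 0.79) * 100.0
        assert coll["south"] == pytest.approx(wedge)


class TestCompensation:
    def test_base_vs_base_zero(self):
        out = _toy_outcomes()
        comp, plans = ev.compensate(out, out, pe.Policy("base"))
        for plan in plans.values():
            assert plan.collections_per_ha == pytest.approx(0.0)
            assert plan.policy_cost_per_ha == pytest.approx(0.0, abs=1e-9)

    def test_missing_base_errors(self):
        with pytest.raises(ev.EvaluationError):
            ev.compensate(_toy_outcomes(), _toy_outcomes().iloc[:0], pe.Policy("base"))

    def test_voluntary_total_is_policy_cost(self, default_dataset, base_run):
        from nfertpolicy import pipeline as pl

        pol = pe.Policy("voluntary", 0.15)
        run = pl.run_policy(default_dataset, pol, base_run, seed=0)
        for plan in run.plans.values():
            assert plan.collections_per_ha == 0.0
            assert plan.total_per_ha == pytest.approx(plan.policy_cost_per_ha)

    def test_conservation_and_restoration(self, default_dataset, base_run):
        """Component 1 returns exactly what was collected, per region-year;
        compensation restores the regional mean income to the base level."""
        from nfertpolicy import pipeline as pl

        pol = pl.make_policy("leaching_fee", 8.0, base_run)
        run = pl.run_policy(default_dataset, pol, base_run, seed=0)
        out = run.outcomes.copy()
        out["_coll"] = ev.collections_per_fieldyear(out, pol)
        for (_r, _y), grp in out.groupby(["region", "year"]):
            np.testing.assert_allclose(
                grp["comp_collections"].sum(), grp["_coll"].sum(), rtol=1e-9
            )
        base_mean = ev.two_stage_mean(base_run.outcomes, "profit_after")
        income_mean = ev.two_stage_mean(out, "income")
        for region in ("south", "central", "north"):
            assert income_mean[region] == pytest.approx(base_mean[region], rel=1e-9)


class TestYieldGuard:
    def _summaries(self, factor):
        base = pd.DataFrame(
            {"policy": "base", "sublevel": 0.0, "yield": [10.0, 12.0, 10.9]},
            index=pd.Index(["south", "central", ev.STATE], name="scope"),
        )
        pol = base.copy()
        pol["policy"] = "leaching_fee"
        pol["sublevel"] = 9.9
        pol.loc["south", "yield"] = 10.0 * factor
        return base, pol

    def test_base_never_flagged(self):
        base, _ = self._summaries(1.0)
        flagged = ev.yield_guard(base, base)
        assert not flagged["excluded_flag"].any()

    def test_six_percent_loss_flagged(self):
        base, pol = self._summaries(0.94)
        flagged = ev.yield_guard(pol, base)
        assert flagged["excluded_flag"].all()

    def test_exactly_five_percent_not_flagged(self):
        base, pol = self._summaries(0.95)
        flagged = ev.yield_guard(pol, base)
        assert not flagged["excluded_flag"].any()


class TestAbatement:
    def test_ratio(self):
        assert ev.abatement_cost(33.0, 38.8, 31.4) == pytest.approx(33 / 7.4)

    def test_undefined_when_no_reduction(self):
        assert np.isnan(ev.abatement_cost(10.0, 30.0, 30.0))
        assert np.isnan(ev.abatement_cost(10.0, 30.0, 31.0))
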