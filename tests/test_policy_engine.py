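"""Policy arithmetic, EONR selection and its brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfertpolicy import policy_engine as pe
from nfertpolicy.synthetic_fields import N_GRID

from conftest import hand_curve


class TestPriceRatio:
    def test_base_prices_give_ratio_five(self):
        assert pe.price_ratio(pe.Prices(0.158, 0.79)) == pytest.approx(5.0)

    def test_identity(self):
        assert pe.price_ratio(pe.Prices(1.0, 1.0)) == pytest.approx(1.0)

    def test_target_sublevel_arithmetic(self):
        # fertilizer at 2.0527 US$/kg against 0.158 maize: ratio ~= 12.99
        assert pe.price_ratio(pe.Prices(0.158, 2.0527)) == pytest.approx(12.9918, abs=1e-3)

    @pytest.mark.parametrize("p_maize,p_n", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_invalid_prices(self, p_maize, p_n):
        with pytest.raises(pe.PolicyError):
            pe.Prices(p_maize, p_n)


class TestNBalance:
    def test_surplus_arithmetic(self):
        # 176 kg N applied, 12,600 kg grain removed at 11.5 g N/kg
        assert pe.n_balance(176, 12600) == pytest.approx(31.1)

    def test_zero(self):
        assert pe.n_balance(0, 0) == 0.0

    def test_no_removal(self):
        assert pe.n_balance(100, 10000, pe.BalanceParams(1e-9)) == pytest.approx(100, abs=1e-4)

    @given(n=st.floats(0, 320), y=st.floats(0, 20000))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_inputs(self, n, y):
        assert pe.n_balance(n, y) == pytest.approx(n - 0.0115 * y, abs=1e-9)


class TestProfit:
    def test_hand_curve_profits(self):
        curve = hand_curve([0, 100, 200], [5000, 9000, 9500])
        pol = pe.Policy("base")
        assert pe.profit(curve, 0, pol) == pytest.approx(790.0)
        assert pe.profit(curve, 100, pol) == pytest.approx(1343.0)
        assert pe.profit(curve, 200, pol) == pytest.approx(1343.0)

    def test_off_grid_rate_errors(self):
        curve = hand_curve([0, 100, 200], [5000, 9000, 9500])
        with pytest.raises(pe.PolicyError, match="not on the curve grid"):
            pe.profit(curve, 50, pe.Policy("base"))

    def test_zero_fee_equals_base(self):
        curve = hand_curve([0, 100, 200], [5000, 9000, 9500], leach2=[10, 30, 60])
        base = pe.Policy("base")
        for pol in (
            pe.Policy("leaching_fee", 0.0, leach_thresholds={"central": 0.0}),
            pe.Policy("balance_fee", 0.0, balance_thresholds={"central": 0.0}),
        ):
            for n in (0, 100, 200):
                assert pe.profit(curve, n, pol) == pytest.approx(pe.profit(curve, n, base))

    def test_fee_never_binds_equals_base(self):
        curve = hand_curve([0, 100, 200], [5000, 9000, 9500], leach2=[10, 30, 60])
        pol = pe.Policy("leaching_fee", 25.0, leach_thresholds={"central": 1e4})
        base = pe.Policy("base")
        for n in (0, 100, 200):
            assert pe.profit(curve, n, pol) == pytest.approx(pe.profit(curve, n, base))

    def test_missing_threshold_errors(self):
        curve = hand_curve([0, 100], [5000, 9000], leach2=[10, 30], region="north")
        pol = pe.Policy("leaching_fee", 5.0, leach_thresholds={"south": 10.0})
        with pytest.raises(pe.PolicyError, match="north"):
            pe.profit(curve, 100, pol)


def brute_force_eonr(yields, leach2, region, policy, prices=pe.Prices()):
    """Independent oracle: evaluate profit at every grid point one by one."""
    best_n, best_p = None, -np.inf
    for j, n in enumerate(N_GRID):
        y = float(yields[j])
        l2 = float(leach2[j])
        p_n = policy.sublevel * prices.p_maize if policy.kind == "price_ratio" else prices.p_n
        p = prices.p_maize * y - p_n * n
        if policy.kind == "leaching_fee":
            p -= policy.sublevel * max(0.0, l2 - policy.leach_thresholds[region])
        elif policy.kind == "balance_fee":
            p -= policy.sublevel * max(0.0, (n - 0.0115 * y) - policy.balance_thresholds[region])
        if p > best_p + 1e-9:
            best_p, best_n = p, float(n)
    return best_n


@pytest.fixture(scope="module")
def random_curve_pool(default_dataset):
    ds = default_dataset
    rng = np.random.default_rng(42)
    idx = rng.choice(len(ds.curves), size=200, replace=False)
    return ds.subset(np.isin(np.arange(len(ds.curves)), idx))


THRESH = {"south": 18.0, "central": 23.0, "north": 29.0}
BAL_THRESH = {"south": 11.0, "central": -23.0, "north": -55.0}


def _policies_for(sub_scale):
    return [
        pe.Policy("base"),
        pe.Policy("price_ratio", 5 + 15 * sub_scale),
        pe.Policy("leaching_fee", 40 * sub_scale, leach_thresholds=THRESH),
        pe.Policy("balance_fee", 4 * sub_scale, balance_thresholds=BAL_THRESH),
    ]


class TestEONR:
    def test_flat_curve_gives_zero(self):
        curve = hand_curve(N_GRID, np.full(len(N_GRID), 8000.0),
                           leach2=np.linspace(10, 40, len(N_GRID)))
        assert pe.eonr(curve, pe.Policy("base")) == 0.0

    def test_voluntary_zero_is_identity(self, random_curve_pool):
        ds = random_curve_pool
        regions = ds.curves["region"].tolist()
        base = pe.eonr_vector(ds.yields, ds.leach2, regions, pe.Policy("base"))
        vol = pe.eonr_vector(ds.yields, ds.leach2, regions, pe.Policy("voluntary", 0.0))
        np.testing.assert_array_equal(base, vol)

    def test_zero_sublevel_identities(self, random_curve_pool):
        ds = random_curve_pool
        regions = ds.curves["region"].tolist()
        base = pe.eonr_vector(ds.yields, ds.leach2, regions, pe.Policy("base"))
        for pol in _policies_for(0.0)[1:]:
            got = pe.eonr_vector(ds.yields, ds.leach2, regions, pol)
            np.testing.assert_array_equal(base, got)

    @pytest.mark.parametrize("sub_scale", [0.1, 0.35, 0.7, 1.0])
    def test_matches_brute_force(self, random_curve_pool, sub_scale):
        ds = random_curve_pool
        regions = ds.curves["region"].tolist()
        for pol in _policies_for(sub_scale):
            fast = pe.eonr_vector(ds.yields, ds.leach2, regions, pol)
            for i in range(len(ds.curves)):
                slow = brute_force_eonr(ds.yields[i], ds.leach2[i], regions[i], pol)
                assert fast[i] == slow, (pol.kind, pol.sublevel, i)

    def test_tie_breaks_to_lowest_rate(self):
        # plateau from N=100 onward with free fertilizer: profits tie
        yields = np.where(N_GRID < 100, 5000 + 40 * N_GRID, 9000).astype(float)
        curve = hand_curve(N_GRID, yields, leach2=np.linspace(5, 50, len(N_GRID)))
        free_n = pe.Prices(0.158, 1e-12)
        assert pe.eonr(curve, pe.Policy("base"), prices=free_n) == 100.0

    def test_monotone_policy_pressure(self, random_curve_pool):
        """EONR is non-increasing in sublevel for every policy kind."""
        ds = random_curve_pool
        regions = ds.curves["region"].tolist()
        grids = {
            "price_ratio": [5, 8, 11, 15, 20],
            "leaching_fee": [0, 5, 15, 28, 40],
            "balance_fee": [0, 0.5, 1.5, 2.5, 4.0],
            "voluntary": [0, 0.08, 0.16, 0.24, 0.30],
        }
        for kind, subs in grids.items():
            prev = None
            for sub in subs:
                pol = pe.Policy(
                    kind, sub,
                    leach_thresholds=THRESH if kind == "leaching_fee" else None,
                    balance_thresholds=BAL_THRESH if kind == "balance_fee" else None,
                )
                e = pe.eonr_vector(ds.yields, ds.leach2, regions, pol)
                if prev is not None:
                    assert (e <= prev + 1e-9).all(), (kind, sub)
                prev = e

    def test_profit_dominance_at_eonr(self, random_curve_pool):
        ds = random_curve_pool
        regions = ds.curves["region"].tolist()
        pol = pe.Policy("leaching_fee", 12.0, leach_thresholds=THRESH)
        prof = pe.profit_matrix(ds.yields, ds.leach2, regions, pol)
        e = pe.eonr_vector(ds.yields, ds.leach2, regions, pol)
        at = prof[np.arange(len(e)), (e / 10).astype(int)]
        assert (at >= prof.max(axis=1) - 1e-9).all()


class TestSnap:
    @given(x=st.floats(-50, 400))
    @settings(max_examples=100, deadline=None)
    def test_snap_nearest_properties(self, x):
        s = float(pe.snap_nearest(x))
        assert s in N_GRID
        if 0 <= x <= 320:
            assert abs(s - x) <= 5.0

    def test_snap_examples(self):
        assert pe.snap_nearest(104.9) == 100.0
        assert pe.snap_nearest(105.0) == 100.0  # midpoint ties go down
        assert pe.snap_nearest(105.1) == 110.0
        assert pe.snap_nearest(327.0) == 320.0
        assert pe.snap_down(199.99) == 190.0
        assert pe.snap_down(200.0) == 200.0


class TestThresholds:
    def test_threshold_formulas(self):
        out = pd.DataFrame(
            {
                "region": ["south"] * 2 + ["north"] * 2,
                "leach2": [20.0, 40.0, 0.0, 0.0],
                "n_balance": [61.0, 81.0, 10.0, 10.0],
            }
        )
        leach_thr, bal_thr = pe.compute_thresholds(out)
        assert leach_thr["south"] == pytest.approx(18.0)  # 0.6 x 30
        assert bal_thr["south"] == pytest.approx(11.0)    # 71 - 60
        assert leach_thr["north"] == pytest.approx(0.0)
        assert bal_thr["north"] == pytest.approx(-50.0)

    def test_missing_columns_error(self):
        with pytest.raises(pe.PolicyError, match="n_balance"):
            pe.compute_thresholds(pd.DataFrame({"region": ["south"], "leach2": [1.0]}))


class TestPolicyValidation:
    @pytest.mark.parametrize(
        "kind,sub",
        [("price_ratio", 4.0), ("price_ratio", 21.0), ("leaching_fee", -1.0),
         ("leaching_fee", 41.0), ("balance_fee", 5.0), ("voluntary", 0.4)],
    )
    def test_sublevel_ranges(self, kind, sub):
        with pytest.raises(pe.PolicyError):
            pe.Policy(kind, sub, leach_thresholds=THRESH, balance_thresholds=BAL_THRESH)

    def test_fee_policies_require_thresholds(self):
        with pytest.raises(pe.PolicyError, match="thresholds"):
            pe.Policy("leaching_fee", 5.0)
        with pytest.raises(pe.PolicyError, match="thresholds"):
            pe.Policy("balance_fee", 1.0)
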