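import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kidneywait.engine import make_initial_occupancy, run_model
from kidneywait.errors import ValidationError
from kidneywait.waittime import (
    KMCurve,
    RiskSetTable,
    km_product_limit,
    percentile,
    risk_set_from_trace,
    summarize,
)
from helpers import params_with, toy_spec


class TestRiskSetTable:
    def test_ledger_invariant_enforced(self):
        with pytest.raises(ValidationError, match="consistent"):
            RiskSetTable(n=[100, 95], d=[10, 0], c=[5, 0])

    def test_events_cannot_exceed_at_risk(self):
        with pytest.raises(ValidationError, match="exceed"):
            RiskSetTable(n=[10, 5], d=[11, 0], c=[0, 0])


class TestProductLimit:
    def test_hand_computed_three_rows(self):
        table = RiskSetTable(n=[10.0, 7.0], d=[2.0, 1.0], c=[1.0, 0.0])
        curve = km_product_limit(table)
        np.testing.assert_allclose(curve.survival, [1.0, 0.8, 0.8 * 6 / 7])
        assert curve.survival[2] == pytest.approx(0.6857, abs=5e-5)

    def test_no_events_flat_curve(self):
        table = RiskSetTable(n=[10.0, 8.0], d=[0.0, 0.0], c=[2.0, 8.0])
        curve = km_product_limit(table)
        assert np.all(curve.survival == 1.0)

    def test_empty_risk_months_contribute_factor_one(self):
        table = RiskSetTable(n=[10.0, 0.0, 0.0], d=[10.0, 0.0, 0.0], c=[0.0, 0.0, 0.0])
        curve = km_product_limit(table)
        np.testing.assert_allclose(curve.survival, [1.0, 0.0, 0.0, 0.0])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=0.9), min_size=1, max_size=12)
    )
    @settings(deadline=None)
    def test_no_censoring_equals_surviving_fraction(self, hazards):
        # with c == 0 the product-limit curve telescopes to n_{t+1}/n_0
        n0 = 1_000.0
        n, d = [], []
        cur = n0
        for h in hazards:
            n.append(cur)
            d.append(cur * h)
            cur -= cur * h
        table = RiskSetTable(n=n, d=d, c=np.zeros(len(n)))
        curve = km_product_limit(table)
        frac = np.concatenate([[n0], n0 - np.cumsum(d)]) / n0
        np.testing.assert_allclose(curve.survival, frac, rtol=1e-9, atol=1e-12)


class TestPercentile:
    def make_curve(self):
        return KMCurve(
            months=np.arange(4.0), survival=np.array([1.0, 0.8, 0.6857, 0.3429])
        )

    def test_median_first_crossing(self):
        assert percentile(self.make_curve(), 0.5) == 3.0

    def test_never_crossing_returns_none(self):
        flat = KMCurve(months=np.arange(3.0), survival=np.ones(3))
        assert percentile(flat, 0.5) is None

    def test_iqr_bounds(self):
        s = summarize(self.make_curve())
        assert s.q25 == 2.0    # first month with S <= 0.75
        assert s.median == 3.0  # first month with S <= 0.50
        assert s.q75 is None    # the curve never reaches 0.25

    def test_out_of_range_quantile(self):
        with pytest.raises(ValidationError):
            percentile(self.make_curve(), 1.5)

    def test_interpolated_median_between_grid_points(self):
        curve = KMCurve(months=np.arange(3.0), survival=np.array([1.0, 0.6, 0.4]))
        assert percentile(curve, 0.5) == 2.0
        assert percentile(curve, 0.5, interpolate=True) == pytest.approx(1.5)


class TestRiskSetFromTrace:
    def test_no_listings_empty_table(self):
        spec = toy_spec(dialysis_unlisted=1_000)
        trace = run_model(make_initial_occupancy(spec, 1.0), params_with(), horizon=6)
        table = risk_set_from_trace(trace)
        assert len(table) == 0

    def test_single_cohort_bookkeeping(self):
        # 1,000 listed; month 1 sees 10 transplants and 5 censorings
        spec = toy_spec(dialysis_listed=1_000, horizon=2)
        params = params_with(p_ddt_listed=0.01, p_death_listed=0.003, p_removal=0.002)
        trace = run_model(make_initial_occupancy(spec, 1.0), params, horizon=2)
        table = risk_set_from_trace(trace)
        assert table.n[0] == pytest.approx(1_000)
        assert table.d[0] == pytest.approx(10)
        assert table.c[0] == pytest.approx(5)
        assert table.n[1] == pytest.approx(985)

    def test_pooled_cohorts_match_hand_recursion(self):
        # steady listing inflow creates staggered entry cohorts; pool them by
        # an independent per-cohort recursion and compare
        spec = toy_spec(dialysis_listed=1_000, dialysis_unlisted=10_000, horizon=4)
        p_list, p_tx, p_cen = 0.02, 0.05, 0.01
        params = params_with(
            p_list_dialysis=p_list, p_ddt_listed=p_tx, p_death_listed=p_cen
        )
        H = 4
        trace = run_model(make_initial_occupancy(spec, 1.0), params, horizon=H)
        # oracle: track each entry cohort separately
        unlisted = 10_000.0
        entries = {0: 1_000.0}  # entry cycle -> cohort size
        n = np.zeros(H)
        d = np.zeros(H)
        c = np.zeros(H)
        survivors = {0: 1_000.0}
        for cycle in range(1, H + 1):
            for entry, alive in list(survivors.items()):
                dur = cycle - entry  # month of wait experienced this cycle
                n[dur - 1] += alive
                d[dur - 1] += alive * p_tx
                c[dur - 1] += alive * p_cen
                survivors[entry] = alive * (1 - p_tx - p_cen)
            newly = unlisted * p_list
            unlisted -= newly
            if cycle < H:  # listed at end of cycle, at risk from the next one
                survivors[cycle] = newly
        # administrative censoring of everyone still waiting at the horizon
        for entry, alive in survivors.items():
            if entry < H:
                c[H - entry - 1] += alive
        table = risk_set_from_trace(trace)
        np.testing.assert_allclose(table.n, n[: len(table)], rtol=1e-12)
        np.testing.assert_allclose(table.d, d[: len(table)], rtol=1e-12)
        np.testing.assert_allclose(table.c, c[: len(table)], rtol=1e-12)

    def test_time_homogeneous_hazard_gives_geometric_curve(self):
        # equal transplant hazard in every cell: pooling cannot distort the
        # curve, which must equal (1 - p)^t exactly
        spec = toy_spec(dialysis_listed=5_000, dialysis_unlisted=50_000, horizon=24)
        p = 0.03
        params = params_with(p_ddt_listed=p, p_list_dialysis=0.01, p_death_listed=0.005)
        trace = run_model(make_initial_occupancy(spec, 1.0), params, horizon=24)
        curve = km_product_limit(risk_set_from_trace(trace))
        expected = (1 - p) ** curve.months
        np.testing.assert_allclose(curve.survival, expected, rtol=1e-10)


class TestMonotonicity:
    def test_median_non_increasing_in_transplant_hazard(self):
        spec = toy_spec(dialysis_listed=10_000, horizon=120)
        medians = []
        for p_tx in (0.01, 0.02, 0.05, 0.10):
            params = params_with(p_ddt_listed=p_tx, p_death_listed=0.004)
            trace = run_model(make_initial_occupancy(spec, 1.0), params, horizon=120)
            curve = km_product_limit(risk_set_from_trace(trace))
            medians.append(percentile(curve, 0.5, interpolate=True))
        assert all(m is not None for m in medians)
        assert all(a >= b for a, b in zip(medians, medians[1:]))
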