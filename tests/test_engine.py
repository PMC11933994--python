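import numpy as np
import pytest

from kidneywait.engine import (
    CohortTrace,
    EventCounts,
    annual_counts,
    make_initial_occupancy,
    run_model,
    step_cycle,
)
from kidneywait.errors import EngineError, ValidationError
from kidneywait.parameters import STRATA, CohortSpec, HealthState

from helpers import params_with, toy_spec

H = HealthState


class TestInitialOccupancy:
    def test_identity_at_factor_one(self, cohort_spec):
        occ = make_initial_occupancy(cohort_spec, 1.0)
        assert occ.total == pytest.approx(cohort_spec.total_count, rel=1e-12)
        for (stratum, state), count in cohort_spec.counts().items():
            if state in (H.CKD_LISTED, H.DIALYSIS_LISTED):
                i = STRATA.index(stratum)
                k = 0 if state is H.CKD_LISTED else 1
                assert occ.listed[i, k, 0] == pytest.approx(count)
                assert occ.listed[i, k, 1:].sum() == 0.0

    def test_proportional_expansion_arithmetic(self):
        spec = toy_spec(
            ckd_listed=10_000,
            dialysis_listed=80_000,
            ckd_unlisted=100_000,
            dialysis_unlisted=300_000,
        )
        occ = make_initial_occupancy(spec, 1.1)
        assert occ.state_total(H.CKD_LISTED) == pytest.approx(11_000)
        assert occ.state_total(H.DIALYSIS_LISTED) == pytest.approx(88_000)
        assert occ.total == pytest.approx(490_000)

    def test_conservation_under_expansion(self, cohort_spec):
        base = make_initial_occupancy(cohort_spec, 1.0)
        expanded = make_initial_occupancy(cohort_spec, 1.5)
        assert expanded.total == pytest.approx(base.total, rel=1e-12)
        assert expanded.listed.sum() == pytest.approx(1.5 * base.listed.sum(), rel=1e-12)
        # every initially listed person starts the wait-time clock at 0
        assert expanded.listed[:, :, 1:].sum() == 0.0

    def test_factor_below_one_rejected(self, cohort_spec):
        with pytest.raises(ValidationError):
            make_initial_occupancy(cohort_spec, 0.9)

    def test_insufficient_unlisted_pool_rejected(self):
        spec = toy_spec(ckd_listed=100, ckd_unlisted=10, dialysis_unlisted=1000)
        with pytest.raises(ValidationError, match="not enough"):
            make_initial_occupancy(spec, 1.5)


class TestStepCycle:
    def test_null_dynamics(self):
        spec = toy_spec(dialysis_listed=5_000, dialysis_unlisted=20_000)
        occ = make_initial_occupancy(spec, 1.0)
        nxt, ev, tx, cens = step_cycle(occ, params_with())
        assert nxt.unlisted.sum() == occ.unlisted.sum()
        assert nxt.listed.sum() == occ.listed.sum()
        assert all(v == 0.0 for v in ev.as_dict().values())
        # listed mass still advances along the duration axis
        assert nxt.listed[:, 1, 1].sum() == pytest.approx(5_000)

    def test_absorbing_death_sweep(self):
        spec = toy_spec(
            ckd_unlisted=100, dialysis_unlisted=200, dialysis_listed=50, ckd_listed=25
        )
        params = params_with(
            p_death_ckd=1.0,
            p_death_dialysis=1.0,
            p_death_listed=1.0,
            p_death_removed=1.0,
            p_death_posttx=1.0,
        )
        nxt, ev, _, _ = step_cycle(make_initial_occupancy(spec, 1.0), params)
        assert nxt.state_total(H.DEAD) == pytest.approx(375)
        assert nxt.total == pytest.approx(375)

    def test_single_transition_arithmetic(self):
        spec = toy_spec(dialysis_listed=100_000)
        params = params_with(p_ddt_listed=0.01)
        nxt, ev, tx, _ = step_cycle(make_initial_occupancy(spec, 1.0), params)
        assert ev.ddt == pytest.approx(1_000)
        assert nxt.listed[:, :, 1].sum() == pytest.approx(99_000)
        assert tx[0] == pytest.approx(1_000)  # transplants at duration 0 -> month 1
        # no perioperative mortality configured: all survive to graft function
        assert nxt.state_total(H.GRAFT_FUNCTIONING) == pytest.approx(1_000)

    def test_periop_split_counts_as_transplant_and_death(self):
        spec = toy_spec(dialysis_listed=10_000)
        params = params_with(p_ddt_listed=0.1, p_periop_death=0.05)
        nxt, ev, _, _ = step_cycle(make_initial_occupancy(spec, 1.0), params)
        assert ev.ddt == pytest.approx(1_000)
        assert ev.periop_deaths == pytest.approx(50)
        assert nxt.state_total(H.GRAFT_FUNCTIONING) == pytest.approx(950)
        assert nxt.state_total(H.DEAD) == pytest.approx(50)

    def test_graft_failure_returns_to_dialysis_unlisted(self):
        spec = toy_spec(dialysis_listed=1_000, dialysis_unlisted=1_000)
        params = params_with(p_graft_failure=0.5)
        occ = make_initial_occupancy(spec, 1.0)
        occ.unlisted[1, 3] = 100.0  # seed graft-functioning mass
        nxt, ev, _, _ = step_cycle(occ, params)
        assert ev.graft_failures == pytest.approx(50)
        assert nxt.state_total(H.DIALYSIS_UNLISTED) == pytest.approx(1_050)

    def test_listed_ckd_progression_keeps_wait_clock(self):
        spec = toy_spec(ckd_listed=1_000)
        params = params_with(p_progress=0.2)
        nxt, ev, _, cens = step_cycle(make_initial_occupancy(spec, 1.0), params)
        # progression is a lateral move, not an exit from the list
        assert nxt.listed[:, 1, 1].sum() == pytest.approx(200)
        assert nxt.listed[:, 0, 1].sum() == pytest.approx(800)
        assert cens.sum() == 0.0


class TestRunModel:
    def test_zero_horizon_returns_only_initial(self, cohort_spec, registry_params):
        occ0 = make_initial_occupancy(cohort_spec, 1.0)
        trace = run_model(occ0, registry_params, horizon=0)
        assert trace.horizon == 0
        assert len(trace.occupancies) == 1

    def test_conservation_every_cycle(self, cohort_spec, status_quo_trace):
        total = cohort_spec.total_count
        for occ in status_quo_trace.occupancies:
            assert abs(occ.total - total) <= 1e-9 * total

    def test_dead_occupancy_monotone(self, status_quo_trace):
        dead = [occ.state_total(H.DEAD) for occ in status_quo_trace.occupancies]
        assert np.all(np.diff(dead) >= -1e-9)

    def test_linearity_under_cohort_scaling(self, cohort_spec, registry_params):
        occ0 = make_initial_occupancy(cohort_spec, 1.0)
        doubled = CohortSpec(
            total_count=2 * cohort_spec.total_count,
            state_split=cohort_spec.state_split,
            horizon=cohort_spec.horizon,
        )
        occ0x2 = make_initial_occupancy(doubled, 1.0)
        t1 = run_model(occ0, registry_params, horizon=24)
        t2 = run_model(occ0x2, registry_params, horizon=24)
        for a, b in zip(t1.occupancies, t2.occupancies):
            np.testing.assert_allclose(2 * a.unlisted, b.unlisted, rtol=1e-12)
            np.testing.assert_allclose(2 * a.listed, b.listed, rtol=1e-12, atol=1e-9)
        for ea, eb in zip(t1.events, t2.events):
            for name, v in ea.as_dict().items():
                assert 2 * v == pytest.approx(getattr_ev(eb, name), rel=1e-12, abs=1e-9)

    def test_determinism(self, cohort_spec, registry_params):
        occ0 = make_initial_occupancy(cohort_spec, 1.0)
        t1 = run_model(occ0, registry_params, horizon=6)
        t2 = run_model(occ0, registry_params, horizon=6)
        for a, b in zip(t1.occupancies, t2.occupancies):
            np.testing.assert_array_equal(a.listed, b.listed)
            np.testing.assert_array_equal(a.unlisted, b.unlisted)

    def test_list_expansion_overflow_rejected_not_renormalised(self):
        from kidneywait.errors import ProbabilityOverflowError
        from kidneywait.scenarios import ScenarioSpec

        spec = toy_spec(ckd_unlisted=10_000, dialysis_unlisted=10_000)
        params = params_with(
            p_list_dialysis=0.4, p_death_dialysis=0.3, p_death_removed=0.3
        )
        occ0 = make_initial_occupancy(spec, 1.0)
        wide = ScenarioSpec("wl_huge", list_factor=3.0)
        with pytest.raises(ProbabilityOverflowError):
            run_model(occ0, params, wide, horizon=1)


class TestAnnualCounts:
    def _trace_with_events(self, events):
        return CohortTrace([], events, np.zeros((len(events), 1)), np.zeros((len(events), 1)))

    def test_constant_rate_arithmetic(self):
        trace = self._trace_with_events([EventCounts(ddt=100.0)] * 24)
        assert annual_counts(trace, 1).ddt == pytest.approx(1_200)
        assert annual_counts(trace, 2).ddt == pytest.approx(1_200)

    def test_zero_events(self):
        trace = self._trace_with_events([EventCounts()] * 12)
        assert annual_counts(trace, 1).ldt == 0.0

    def test_year_out_of_range(self):
        trace = self._trace_with_events([EventCounts()] * 12)
        with pytest.raises(ValidationError):
            annual_counts(trace, 2)


def getattr_ev(ev, name):
    return ev.as_dict()[name]
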