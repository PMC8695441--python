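"""Markov cohort engine: discounting, half-cycle correction, accruals."""
import numpy as np
import pytest

import nsclc_cea as m
from conftest import random_schedule


def _const_strategy(schedule, u_pf=1.0, u_pd=1.0, c_pf=0.0, c_pd=0.0, entry=0.0):
    return m.StrategySpec(
        name="test", schedule=schedule, u_pf=u_pf, u_pd=u_pd,
        pf_cost=lambda k: c_pf, pd_cost=lambda k: c_pd, entry_cost=entry,
    )


class TestDiscountFactor:
    def test_unity_at_time_zero(self):
        assert m.discount_factor(0.0, 0.03) == 1.0

    def test_unity_at_zero_rate(self):
        assert m.discount_factor(500.0, 0.0) == 1.0

    def test_one_year(self):
        assert m.discount_factor(m.WEEKS_PER_YEAR, 0.03) == pytest.approx(1 / 1.03)


class TestHalfCycleCorrect:
    def test_constant_membership_loses_half_cycle_each_end(self):
        raw = np.full(10, 2.0)
        corrected = m.half_cycle_correct(raw)
        assert corrected.sum() == pytest.approx(raw.sum() - 2.0)

    def test_single_cycle_halved(self):
        assert m.half_cycle_correct(np.array([4.0])).sum() == pytest.approx(2.0)

    def test_between_riemann_sums_for_decreasing_occupancy(self):
        f = 0.9 ** np.arange(30)  # smooth decreasing occupancy
        corrected = m.half_cycle_correct(f).sum()
        left = f[:-1].sum()
        right = f[1:].sum()
        assert right < corrected < left


class TestRunCohort:
    def test_immortal_healthy_cohort_accrues_exactly_horizon(self):
        # cycle length chosen to divide one year into 10 cycles exactly
        settings = m.RunSettings(
            cycle_length_weeks=m.WEEKS_PER_YEAR / 10, discount_rate=0.0,
            horizon_years=1.0, half_cycle_correction=False,
        )
        schedule = m.TransitionSchedule(np.zeros(10), np.zeros(10))
        trace = m.run_cohort(_const_strategy(schedule), settings)
        assert trace.total_ly == pytest.approx(1.0)
        assert trace.total_qaly == pytest.approx(1.0)

    def test_deterministic_two_cycle_path(self):
        # everyone progresses in cycle 0 and dies in cycle 1: two cycles lived
        settings = m.RunSettings(discount_rate=0.0, half_cycle_correction=False)
        p_prog = np.zeros(5); p_prog[0] = 1.0
        p_death = np.zeros(5); p_death[1] = 1.0
        schedule = m.TransitionSchedule(p_prog, p_death)
        trace = m.run_cohort(_const_strategy(schedule), settings)
        assert trace.n_cycles == 2
        assert trace.total_ly == pytest.approx(2 * 6.0 / m.WEEKS_PER_YEAR)

    def test_matches_microsimulation(self):
        """Cohort expectation vs an independent per-patient simulation."""
        schedule = random_schedule(42)
        u_pf, u_pd, c_pf, c_pd = 0.85, 0.6, 1000.0, 3000.0
        settings = m.RunSettings(horizon_years=6.9)
        strat = _const_strategy(schedule, u_pf, u_pd, c_pf, c_pd, entry=500.0)
        trace = m.run_cohort(strat, settings)

        rng = np.random.default_rng(3)
        n = 20_000
        k_cycles = trace.n_cycles
        state = np.zeros(n, dtype=np.int8)
        occ_pf = np.zeros((k_cycles, n), dtype=bool)
        occ_pd = np.zeros((k_cycles, n), dtype=bool)
        for k in range(k_cycles):
            occ_pf[k] = state == 0
            occ_pd[k] = state == 1
            prog = occ_pf[k] & (rng.random(n) < schedule.p_pf_to_pd[k])
            die = occ_pd[k] & (rng.random(n) < schedule.p_pd_to_death[k])
            state[die] = 2
            state[prog] = 1
        w = np.ones(k_cycles); w[0] = 0.5; w[-1] = 0.5
        disc = (1.03) ** (-(np.arange(k_cycles) * 6.0) / m.WEEKS_PER_YEAR)
        dt_y = 6.0 / m.WEEKS_PER_YEAR
        coef = w * disc
        ly_i = coef @ (occ_pf.astype(float) + occ_pd) * dt_y
        qaly_i = coef @ (occ_pf * u_pf + occ_pd * u_pd) * dt_y
        cost_i = coef @ (occ_pf * c_pf + occ_pd * c_pd) + 500.0
        for total, samples in [
            (trace.total_disc_ly, ly_i),
            (trace.total_disc_qaly, qaly_i),
            (trace.total_disc_cost, cost_i),
        ]:
            se = samples.std(ddof=1) / np.sqrt(n)
            assert abs(total - samples.mean()) < 3 * se + 1e-12

    def test_schedule_too_short_errors(self):
        schedule = m.TransitionSchedule(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError, match="schedule"):
            m.run_cohort(_const_strategy(schedule), m.RunSettings())

    def test_outcome_invariants(self, base_result):
        for arm, trace in base_result.traces.items():
            assert np.all(trace.pf + trace.pd + trace.death == pytest.approx(1.0, abs=1e-12))
            assert np.all(np.diff(trace.death) >= -1e-15)
            assert trace.total_qaly <= trace.total_ly + 1e-12
            assert trace.total_disc_cost <= trace.total_cost + 1e-9
            assert trace.total_disc_qaly <= trace.total_qaly + 1e-12
            ratio = trace.total_disc_qaly / trace.total_disc_ly
            lo = 0.72
            hi = 0.79 if arm == "chemotherapy" else 0.88
            assert lo - 1e-9 <= ratio <= hi + 1e-9

    def test_results_invariant_to_cohort_size(self, base_cfg, exact_trial):
        res_small = m.run_base_case(
            base_cfg, exact_trial,
            m.settings_from_config(base_cfg),
        )
        settings_big = m.RunSettings(cohort_size=1)
        res_big = m.run_base_case(base_cfg, exact_trial, settings_big)
        for arm in res_small.outcomes:
            assert res_small.outcomes[arm].cost == pytest.approx(res_big.outcomes[arm].cost)
            assert res_small.outcomes[arm].qaly == pytest.approx(res_big.outcomes[arm].qaly)
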