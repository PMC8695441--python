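"""Weibull curves, hazard-ratio transforms, interval probabilities, KM fits."""
import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import nsclc_cea as m


class TestWeibullSurvival:
    @pytest.mark.parametrize(
        "shape,scale,t,expected",
        [
            (1.0, 10.0, 0.0, 1.0),
            (1.0, 10.0, 10.0, np.exp(-1)),
            (2.0, 20.0, 20.0, np.exp(-1)),  # t = scale forces unit exponent
        ],
    )
    def test_survival_values(self, shape, scale, t, expected):
        assert m.survival_at(m.WeibullSurvival(shape, scale), t) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            m.WeibullSurvival(1.0, 10.0).at(-1.0)

    @pytest.mark.parametrize("shape,scale", [(0.0, 10.0), (-1.0, 10.0), (1.0, 0.0)])
    def test_invalid_parameters_rejected(self, shape, scale):
        with pytest.raises(ValueError):
            m.WeibullSurvival(shape, scale)


class TestHazardRatio:
    def test_identity(self):
        ref = m.WeibullSurvival(1.3, 50.0)
        out = m.apply_hazard_ratio(ref, 1.0)
        assert out.shape == ref.shape and out.scale == pytest.approx(ref.scale)

    def test_exponential_halved_hazard_doubles_scale(self):
        out = m.apply_hazard_ratio(m.WeibullSurvival(1.0, 10.0), 0.5)
        assert out.scale == pytest.approx(20.0)

    def test_power_relation_on_grid(self):
        ref = m.WeibullSurvival(1.5, 40.0)
        out = m.apply_hazard_ratio(ref, 0.66)
        for t in np.arange(6.0, 121.0, 6.0):
            assert out.at(t) == pytest.approx(ref.at(t) ** 0.66, abs=1e-12)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            m.apply_hazard_ratio(m.WeibullSurvival(1.0, 10.0), 0.0)

    @hyp_settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        shape=st.floats(0.5, 3.0),
        scale=st.floats(10.0, 200.0),
        hr=st.floats(0.2, 2.0),
        t=st.floats(0.0, 300.0),
    )
    def test_proportional_hazards_everywhere(self, shape, scale, hr, t):
        ref = m.WeibullSurvival(shape, scale)
        assert m.apply_hazard_ratio(ref, hr).at(t) == pytest.approx(
            ref.at(t) ** hr, abs=1e-12
        )

    def test_hr_then_interval_prob_is_survival_ratio_power(self):
        ref = m.WeibullSurvival(1.2, 60.0)
        hr = 0.66
        out = m.apply_hazard_ratio(ref, hr)
        for t in (0.0, 12.0, 60.0, 150.0):
            p = m.interval_event_prob(out, t, 6.0)
            ratio = ref.at(t + 6.0) / ref.at(t)
            assert 1.0 - p == pytest.approx(ratio**hr, abs=1e-12)


class TestIntervalEventProb:
    def test_exponential_is_memoryless(self):
        scale = -6.0 / np.log(0.9)  # per-6-week survival 0.9
        curve = m.WeibullSurvival(1.0, scale)
        for t in (0.0, 6.0, 60.0, 300.0):
            assert m.interval_event_prob(curve, t, 6.0) == pytest.approx(0.1)

    def test_closed_form(self):
        curve = m.WeibullSurvival(2.0, 52.0)
        expected = 1.0 - np.exp(-((58.0 / 52.0) ** 2 - 1.0))
        assert m.interval_event_prob(curve, 52.0, 6.0) == pytest.approx(expected)

    def test_vanishes_as_dt_shrinks(self):
        curve = m.WeibullSurvival(1.7, 30.0)
        assert m.interval_event_prob(curve, 20.0, 1e-9) < 1e-9

    def test_exhausted_support_returns_one(self):
        assert m.interval_event_prob(m.WeibullSurvival(3.0, 1.0), 1e6, 6.0) == 1.0

    def test_domain_errors(self):
        curve = m.WeibullSurvival(1.0, 10.0)
        with pytest.raises(ValueError):
            m.interval_event_prob(curve, -1.0, 6.0)
        with pytest.raises(ValueError):
            m.interval_event_prob(curve, 1.0, 0.0)

    def test_product_of_complements_telescopes(self):
        curve = m.WeibullSurvival(1.3, 45.0)
        probs = [m.interval_event_prob(curve, 6.0 * k, 6.0) for k in range(20)]
        assert np.prod(1.0 - np.array(probs)) == pytest.approx(curve.at(120.0), abs=1e-10)


class TestDigitizedKM:
    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            m.DigitizedKM("PFS", [0.0, 6.0, 12.0], [1.0, 0.8, 0.9])

    def test_must_start_at_full_survival(self):
        with pytest.raises(ValueError):
            m.DigitizedKM("PFS", [0.0, 6.0], [0.9, 0.8])

    def test_step_lookup_and_range(self):
        km = m.DigitizedKM("OS", [0.0, 6.0, 12.0], [1.0, 0.8, 0.5])
        assert km.at(7.0) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            km.at(13.0)


class TestFitWeibullKM:
    @pytest.mark.parametrize("shape", [1.2, 0.7])
    def test_roundtrip_recovery(self, shape):
        grid = np.arange(0.0, 73.0, 6.0)
        truth = m.WeibullSurvival(shape, 60.0)
        surv = truth.at(grid)
        km = m.DigitizedKM("PFS", grid, surv, np.round(1000 * surv))
        fit = m.fit_weibull_km(km)
        assert fit.shape == pytest.approx(shape, abs=0.01)
        assert fit.scale == pytest.approx(60.0, abs=0.5)

    def test_exponential_special_case(self):
        grid = np.arange(0.0, 73.0, 6.0)
        truth = m.WeibullSurvival(1.0, 40.0)
        surv = truth.at(grid)
        km = m.DigitizedKM("OS", grid, surv, np.round(1000 * surv))
        assert m.fit_weibull_km(km).shape == pytest.approx(1.0, abs=0.02)

    def test_two_point_curve_rejected(self):
        km = m.DigitizedKM("PFS", [0.0, 6.0], [1.0, 0.8])
        with pytest.raises(ValueError):
            m.fit_weibull_km(km)

    def test_flat_curve_rejected(self):
        km = m.DigitizedKM("PFS", [0.0, 6.0, 12.0, 18.0], [1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            m.fit_weibull_km(km)

    def test_wls_fallback_without_at_risk_is_exact_on_clean_data(self):
        grid = np.arange(0.0, 73.0, 6.0)
        truth = m.WeibullSurvival(1.2, 60.0)
        fit = m.fit_weibull_km(m.DigitizedKM("PFS", grid, truth.at(grid)))
        assert fit.shape == pytest.approx(1.2, abs=1e-9)
        assert fit.scale == pytest.approx(60.0, abs=1e-6)

    def test_agrees_with_lifelines_on_individual_data(self):
        """Dual route: interval fit on the digitized curve vs a parametric fit
        on the underlying individual event times."""
        from lifelines import WeibullFitter

        rng = np.random.default_rng(3)
        truth = m.WeibullSurvival(1.4, 55.0)
        times = truth.scale * rng.weibull(truth.shape, size=4000)
        wf = WeibullFitter().fit(times, event_observed=np.ones_like(times))

        grid = np.arange(0.0, 121.0, 6.0)
        surv = truth.at(grid)
        mine = m.fit_weibull_km(m.DigitizedKM("OS", grid, surv, np.round(4000 * surv)))
        assert mine.shape == pytest.approx(wf.rho_, rel=0.05)
        assert mine.scale == pytest.approx(wf.lambda_, rel=0.05)


class TestPiecewiseExtrapolated:
    def test_continuous_at_switch_and_weibull_beyond(self):
        grid = np.arange(0.0, 73.0, 6.0)
        truth = m.WeibullSurvival(1.2, 60.0)
        km = m.DigitizedKM("PFS", grid, truth.at(grid))
        pw = m.PiecewiseExtrapolatedSurvival(km, m.fit_weibull_km(km))
        assert pw.at(72.0) == pytest.approx(pw.at(72.0 + 1e-9), abs=1e-6)
        # inside: step curve values; outside: close to ground truth
        assert pw.at(30.0) == pytest.approx(km.at(30.0))
        assert pw.at(150.0) == pytest.approx(truth.at(150.0), rel=1e-3)
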