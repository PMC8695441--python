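"""Distribution parameterization, PSA, CEAC, scatter and tornado analyses."""
import numpy as np
import pandas as pd
import pytest

import nsclc_cea as m
from nsclc_cea.parameters import ParamDistribution, get_by_path
from nsclc_cea.sensitivity import PSAResult


class TestDistributions:
    def test_beta_utility_sample_mean(self):
        d = ParamDistribution("u", "parameters.utilities.pf_ni", 0.88, "beta", (11.0, 1.5))
        rng = np.random.default_rng(0)
        draws = np.array([d.sample(rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.88, abs=0.003)

    def test_gamma_drug_cost_mean(self):
        d = ParamDistribution("c", "x", 29_890.0, "gamma", (100.0, 298.90))
        rng = np.random.default_rng(1)
        draws = np.array([d.sample(rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(29_890.0, rel=0.005)

    def test_fixed_always_base(self):
        d = ParamDistribution("f", "x", 0.68, "fixed")
        rng = np.random.default_rng(2)
        assert all(d.sample(rng) == 0.68 for _ in range(10))

    def test_every_table_distribution_sample_mean_near_analytic(self, distributions):
        rng = np.random.default_rng(123)
        for d in distributions:
            if d.family == "fixed":
                continue
            draws = np.array([d.sample(rng) for _ in range(100_000)])
            assert draws.mean() == pytest.approx(d.mean(), rel=0.01), d.name

    def test_baselines_consistent_with_family_means_where_table_is(self):
        """Most printed baselines equal their family means to 0.5% relative;
        the standardized combination-arm rows are known exceptions and are
        surfaced, not silently accepted."""
        report = m.check_param_means()
        inconsistent = set(report.loc[~report["ok"], "name"])
        assert all("N+I+chemotherapy" in name for name in inconsistent)
        assert (~report["ok"]).sum() <= 6

    def test_dirichlet_two_counts_behaves_as_beta(self):
        d = ParamDistribution("sq", "x", 0.28, "dirichlet", (163, 419))
        rng = np.random.default_rng(3)
        draws = np.array([d.sample(rng) for _ in range(50_000)])
        assert draws.mean() == pytest.approx(163 / 582, abs=0.002)
        assert np.all((draws > 0) & (draws < 1))

    def test_invalid_family_params_rejected(self):
        with pytest.raises(ValueError):
            ParamDistribution("bad", "x", 0.5, "beta", (-1.0, 2.0))


class TestSampleParams:
    def test_all_fixed_leaves_config_unchanged(self, base_cfg):
        dists = [ParamDistribution("hr", "parameters.hazard_ratios.pfs", 0.68, "fixed")]
        cfg = m.sample_params(base_cfg, dists, np.random.default_rng(0))
        assert cfg == base_cfg

    def test_sampled_values_land_on_their_paths(self, base_cfg, distributions):
        cfg = m.sample_params(base_cfg, distributions, np.random.default_rng(5))
        moved = sum(
            get_by_path(cfg, d.path) != get_by_path(base_cfg, d.path)
            for d in distributions if d.family != "fixed"
        )
        assert moved == sum(d.family != "fixed" for d in distributions)


class TestRunPSA:
    def test_zero_variance_reproduces_base_case(self, fixed_runner, base_cfg):
        dists = [ParamDistribution("hr", "parameters.hazard_ratios.pfs", 0.68, "fixed")]
        base = fixed_runner(base_cfg)
        psa = m.run_psa(fixed_runner, base_cfg, dists, iterations=3, seed=0)
        for _, row in psa.data.iterrows():
            assert row["cost"] == pytest.approx(base[row["strategy"]].cost)
            assert row["qaly"] == pytest.approx(base[row["strategy"]].qaly)

    def test_same_seed_reproducible(self, fixed_runner, base_cfg, distributions):
        a = m.run_psa(fixed_runner, base_cfg, distributions, iterations=10, seed=7)
        b = m.run_psa(fixed_runner, base_cfg, distributions, iterations=10, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_mean_incremental_cost_near_base_case(self, fixed_runner, base_cfg, distributions):
        """Incremental cost is linear in the sampled inputs, so the PSA mean
        converges on the base-case increment."""
        base = fixed_runner(base_cfg)
        base_inc = base["nivolumab_ipilimumab"].cost - base["chemotherapy"].cost
        psa = m.run_psa(fixed_runner, base_cfg, distributions, iterations=200, seed=11)
        cost = psa.pivot("cost")
        inc = cost["nivolumab_ipilimumab"] - cost["chemotherapy"]
        se = inc.std(ddof=1) / np.sqrt(len(inc))
        assert abs(inc.mean() - base_inc) < 3 * se


def _toy_psa(n=400, seed=0):
    """Two-strategy PSA cloud with positive incremental cost and QALYs."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append({"iteration": i, "strategy": "ref",
                     "cost": 100_000 + rng.normal(0, 5_000), "ly": 1.6, "qaly": 1.2})
        rows.append({"iteration": i, "strategy": "new",
                     "cost": 180_000 + rng.normal(0, 10_000), "ly": 2.1,
                     "qaly": 1.2 + rng.uniform(0.2, 0.8)})
    return PSAResult(pd.DataFrame(rows), seed=seed, iterations=n, failures=[])


class TestCEAC:
    def test_single_strategy_probability_one(self):
        df = pd.DataFrame(
            [{"iteration": i, "strategy": "only", "cost": 1.0, "ly": 1.0, "qaly": 1.0}
             for i in range(5)]
        )
        psa = PSAResult(df, seed=0, iterations=5, failures=[])
        curves = m.ceac(psa, [0.0, 50_000.0, 150_000.0])
        assert np.allclose(curves["probability"], 1.0)

    def test_zero_threshold_rewards_cheapest(self):
        psa = _toy_psa()
        curves = m.ceac(psa, [0.0])
        ref = curves[curves["strategy"] == "ref"]["probability"].iloc[0]
        assert ref == 1.0

    def test_probabilities_sum_to_one_with_ties(self):
        df = pd.DataFrame(
            [{"iteration": i, "strategy": s, "cost": 100.0, "ly": 1.0, "qaly": 1.0}
             for i in range(4) for s in ("a", "b")]
        )
        psa = PSAResult(df, seed=0, iterations=4, failures=[])
        curves = m.ceac(psa, [0.0, 100.0])
        sums = curves.groupby("threshold")["probability"].sum()
        assert np.allclose(sums, 1.0)
        assert np.allclose(curves["probability"], 0.5)  # ties split equally

    def test_crossing_equals_icer_quantile_two_strategies(self):
        psa = _toy_psa()
        cost, qaly = psa.pivot("cost"), psa.pivot("qaly")
        icers = (cost["new"] - cost["ref"]) / (qaly["new"] - qaly["ref"])
        for lam in (120_003.0, 200_007.0, 350_001.0):  # off the ICER atoms
            curves = m.ceac(psa, [lam])
            p_new = curves[curves["strategy"] == "new"]["probability"].iloc[0]
            assert p_new == pytest.approx((icers < lam).mean())

    def test_empty_psa_rejected(self):
        psa = PSAResult(pd.DataFrame(columns=["iteration", "strategy", "cost", "ly", "qaly"]),
                        seed=0, iterations=0, failures=[])
        with pytest.raises(ValueError):
            m.ceac(psa, [0.0])


class TestCEScatter:
    def test_reference_points_at_origin(self):
        psa = _toy_psa()
        scatter = m.ce_scatter(psa, "ref")
        ref_rows = scatter[scatter["strategy"] == "ref"]
        assert np.allclose(ref_rows[["d_qaly", "d_cost"]], 0.0)

    def test_fraction_at_infinite_wtp_is_positive_dqaly_share(self):
        psa = _toy_psa()
        scatter = m.ce_scatter(psa, "ref")
        frac = m.fraction_cost_effective(scatter, "new", 1e12)
        sub = scatter[scatter["strategy"] == "new"]
        assert frac == pytest.approx((sub["d_qaly"] > 0).mean())

    def test_fraction_matches_direct_nmb_count(self):
        psa = _toy_psa()
        scatter = m.ce_scatter(psa, "ref")
        frac = m.fraction_cost_effective(scatter, "new", 150_000.0)
        cost, qaly = psa.pivot("cost"), psa.pivot("qaly")
        nmb_new = 150_000.0 * qaly["new"] - cost["new"]
        nmb_ref = 150_000.0 * qaly["ref"] - cost["ref"]
        assert frac == pytest.approx((nmb_new > nmb_ref).mean())


@pytest.fixture(scope="module")
def tornado(fixed_runner, base_cfg, distributions):
    return m.one_way_dsa(fixed_runner, base_cfg, distributions)


class TestOneWayDSA:
    def test_degenerate_range_zero_swing(self, fixed_runner, base_cfg):
        d = ParamDistribution(
            "BSC cost per 6 weeks ($)", "parameters.bsc_cost_per_cycle",
            4894.0, "gamma", (100.0, 48.94), range=(4894.0, 4894.0),
        )
        df = m.one_way_dsa(fixed_runner, base_cfg, [d])
        assert df["swing"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_ni_drug_cost_minimum_gives_lowest_icer(self, tornado):
        row = tornado[tornado["parameter"] == "Drug cost per 6 weeks ($): Nivolumab plus ipilimumab"]
        lowest = np.nanmin(
            np.concatenate([tornado["low_icer"].astype(float),
                            tornado["high_icer"].astype(float)])
        )
        assert row["low_icer"].iloc[0] == pytest.approx(lowest)
        assert row.index[0] == 0  # largest swing sits on top of the tornado

    def test_increasing_ni_cost_never_decreases_icer(self, tornado):
        row = tornado[tornado["parameter"] == "Drug cost per 6 weeks ($): Nivolumab plus ipilimumab"]
        assert row["low_icer"].iloc[0] <= row["high_icer"].iloc[0]
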