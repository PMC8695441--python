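import numpy as np
import pytest

import nsclc_cea as m


@pytest.fixture(scope="session")
def base_cfg():
    cfg, _ = m.gen_param_set()
    return cfg


@pytest.fixture(scope="session")
def distributions():
    return m.table_distributions()


@pytest.fixture(scope="session")
def exact_trial():
    """Perfectly digitized synthetic trial from the default ground truth."""
    spec = m.SyntheticTrialSpec(
        arms=m.scenario_curves(), enrollment=1000, mode="exact", seed=11
    )
    return m.gen_trial(spec)


@pytest.fixture(scope="session")
def base_result(base_cfg, exact_trial):
    """Full deterministic base case on the synthetic trial."""
    return m.run_base_case(base_cfg, exact_trial)


@pytest.fixture(scope="session")
def fixed_runner(base_cfg, exact_trial):
    """Sensitivity-analysis runner with schedules frozen at base case."""
    settings = m.settings_from_config(base_cfg)
    surv = m.build_arm_survival(exact_trial, base_cfg)
    schedules, _ = m.build_schedules(surv, settings)
    return m.make_runner(schedules, settings)


def random_schedule(seed: int, cycles: int = 60):
    """A random but extinction-reaching transition schedule."""
    rng = np.random.default_rng(seed)
    p_prog = rng.uniform(0.05, 0.35, cycles)
    p_death = rng.uniform(0.05, 0.30, cycles)
    return m.TransitionSchedule(p_prog, p_death)
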