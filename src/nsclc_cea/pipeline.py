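"""End-to-end assembly: curves -> schedules -> strategies -> comparison.

The pipeline mirrors the study design: the chemotherapy and
nivolumab+ipilimumab arms are informed by their own (digitized) PFS/OS
curves; the combination arm is derived from the chemotherapy reference via
published hazard ratios.  In-trial transition probabilities come from the
digitized step curves, the fitted Weibull tail takes over beyond follow-up,
and per-cycle death probabilities are calibrated so modeled overall
survival reproduces each arm's OS curve.
"""
from __future__ import annotations

from dataclasses import dataclass

from .calibration import (
    CalibrationReport,
    TransitionSchedule,
    calibrate_death_probs,
    pfs_to_progression_probs,
    validate_calibration,
)
from .cohort import CohortTrace, RunSettings, StrategySpec, run_cohort
from .costing import ARMS, expected_ae_cost, pd_state_cost, pf_state_cost
from .economics import ComparisonResult, StrategyOutcome, dominance_frontier
from .survival import (
    DigitizedKM,
    HRTransformedSurvival,
    PiecewiseExtrapolatedSurvival,
    fit_weibull_km,
)

__all__ = [
    "ArmSurvival",
    "BaseCaseResult",
    "build_arm_survival",
    "build_schedules",
    "build_strategy",
    "run_base_case",
    "make_runner",
    "settings_from_config",
]


@dataclass
class ArmSurvival:
    """Lifetime PFS and OS representations for one strategy arm."""

    pfs: object  # anything with .at(t)
    os: object


def settings_from_config(config: dict, seed: int | None = None) -> RunSettings:
    s = config.get("settings", {})
    kwargs = {k: s[k] for k in (
        "cycle_length_weeks", "discount_rate", "horizon_years", "cohort_size",
        "wtp", "half_cycle_correction", "extinction_threshold",
    ) if k in s}
    if seed is not None:
        kwargs["seed"] = seed
    return RunSettings(**kwargs)


def build_arm_survival(
    trial: dict[str, dict[str, DigitizedKM]], config: dict
) -> dict[str, ArmSurvival]:
    """Lifetime survival per arm from digitized curves plus hazard ratios.

    Arms with digitized curves get a piecewise representation (step curve
    within follow-up, fitted Weibull tail beyond).  The combination arm is
    the proportional-hazards transform of the chemotherapy reference,
    applied to whichever representation is active at time t.
    """
    out: dict[str, ArmSurvival] = {}
    for arm, endpoints in trial.items():
        reprs = {}
        for endpoint in ("PFS", "OS"):
            km = endpoints[endpoint]
            fitted = fit_weibull_km(km)
            reprs[endpoint] = PiecewiseExtrapolatedSurvival(km, fitted)
        out[arm] = ArmSurvival(pfs=reprs["PFS"], os=reprs["OS"])

    hr = config["parameters"].get("hazard_ratios")
    if hr and "nivolumab_ipilimumab_chemo" not in out and "chemotherapy" in out:
        ref = out["chemotherapy"]
        out["nivolumab_ipilimumab_chemo"] = ArmSurvival(
            pfs=HRTransformedSurvival(ref.pfs, float(hr["pfs"])),
            os=HRTransformedSurvival(ref.os, float(hr["os"])),
        )
    return out


def build_schedules(
    arm_survival: dict[str, ArmSurvival], settings: RunSettings
) -> tuple[dict[str, TransitionSchedule], dict[str, CalibrationReport]]:
    """Calibrated per-cycle transition schedules for every arm."""
    schedules: dict[str, TransitionSchedule] = {}
    reports: dict[str, CalibrationReport] = {}
    cycles = settings.max_cycles
    dt = settings.cycle_length_weeks
    for arm, surv in arm_survival.items():
        p_prog = pfs_to_progression_probs(surv.pfs, cycles, dt)
        schedule = calibrate_death_probs(p_prog, surv.os, cycles, dt)
        schedules[arm] = schedule
        reports[arm] = validate_calibration(schedule, surv.os, dt)
    return schedules, reports


def build_strategy(arm: str, config: dict, schedule: TransitionSchedule) -> StrategySpec:
    """Assemble a runnable strategy from the parameter block."""
    p = config["parameters"]
    u_pf = p["utilities"]["pf_chemo" if arm == "chemotherapy" else "pf_ni"]
    entry = expected_ae_cost(p["ae_incidence"][arm], p["ae_costs"])
    pd_cost = pd_state_cost(arm, p)
    return StrategySpec(
        name=arm,
        schedule=schedule,
        u_pf=float(u_pf),
        u_pd=float(p["utilities"]["pd"]),
        pf_cost=lambda k, _arm=arm, _p=p: pf_state_cost(_arm, k, _p),
        pd_cost=lambda k, _c=pd_cost: _c,
        entry_cost=entry,
    )


@dataclass
class BaseCaseResult:
    """Traces, outcomes and frontier comparison for one scenario."""

    traces: dict[str, CohortTrace]
    outcomes: dict[str, StrategyOutcome]
    comparison: ComparisonResult
    calibration: dict[str, CalibrationReport]


def _run_outcomes(
    config: dict, schedules: dict[str, TransitionSchedule], settings: RunSettings
) -> dict[str, CohortTrace]:
    traces = {}
    for arm in ARMS:
        if arm not in schedules:
            continue
        strategy = build_strategy(arm, config, schedules[arm])
        traces[arm] = run_cohort(strategy, settings)
    return traces


def run_base_case(
    config: dict,
    trial: dict[str, dict[str, DigitizedKM]],
    settings: RunSettings | None = None,
) -> BaseCaseResult:
    """Full deterministic analysis: fit, calibrate, simulate, compare."""
    settings = settings_from_config(config) if settings is None else settings
    arm_survival = build_arm_survival(trial, config)
    schedules, reports = build_schedules(arm_survival, settings)
    traces = _run_outcomes(config, schedules, settings)
    outcomes = {arm: t.outcome() for arm, t in traces.items()}
    if len(outcomes) >= 2:
        comparison = dominance_frontier(list(outcomes.values()))
    else:
        only = next(iter(outcomes.values()))
        comparison = ComparisonResult(
            outcomes=[only], frontier=[only.name], labels={only.name: "on frontier"}
        )
    return BaseCaseResult(traces, outcomes, comparison, reports)


def make_runner(schedules: dict[str, TransitionSchedule], settings: RunSettings):
    """A sensitivity-analysis runner with survival schedules held fixed.

    Returns ``runner(config) -> {arm: StrategyOutcome}`` suitable for
    ``run_psa`` and ``one_way_dsa``: each call rebuilds costs, utilities,
    adverse-event and second-line parameters from the configuration and
    reruns every arm on the fixed transition schedules.
    """

    def runner(config: dict) -> dict[str, StrategyOutcome]:
        traces = _run_outcomes(config, schedules, settings)
        return {arm: t.outcome() for arm, t in traces.items()}

    return runner
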