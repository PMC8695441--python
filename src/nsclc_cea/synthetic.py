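"""Synthetic trial inputs with the statistical structure the model assumes.

The original analysis ran on survival curves digitized from published
figures, which have no machine-readable accession.  This module generates
drop-in stand-ins: per-arm Weibull ground truth evaluated (or
Kaplan-Meier-estimated from simulated patients) on a digitization grid,
with optional digitization noise and numbers-at-risk tables, plus complete
baseline parameter configurations.  Ground truth is returned alongside the
curves so fitting and calibration can be tested by round-trip recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import WEEKS_PER_YEAR
from .parameters import base_config, perturbed_config, table_distributions
from .survival import DigitizedKM, WeibullSurvival

__all__ = [
    "ArmCurves",
    "SyntheticTrialSpec",
    "gen_trial",
    "gen_param_set",
    "scenario_curves",
    "SUBGROUPS",
    "REFERENCE_TRIALS",
]

SUBGROUPS = ("all", "pdl1_high", "pdl1_low")
REFERENCE_TRIALS = ("checkmate227", "checkmate9la")


@dataclass(frozen=True)
class ArmCurves:
    """Ground-truth Weibull PFS and OS for one trial arm."""

    pfs: WeibullSurvival
    os: WeibullSurvival


#: Default ground-truth scenarios.  Shapes and scales are chosen so that
#: median OS lands around 14-17 months, median PFS around 5 months, and the
#: immunotherapy arm has the flatter late hazard (shape < 1) characteristic
#: of checkpoint-inhibitor survival curves.  Qualitative emulation only; no
#: quantitative claim about the source trials is attached.
_SCENARIOS: dict[tuple[str, str], dict[str, ArmCurves]] = {
    ("all", "checkmate227"): {
        "chemotherapy": ArmCurves(WeibullSurvival(1.25, 30.0), WeibullSurvival(1.15, 85.0)),
        "nivolumab_ipilimumab": ArmCurves(WeibullSurvival(0.85, 35.0), WeibullSurvival(0.95, 105.0)),
    },
    ("pdl1_high", "checkmate227"): {
        "chemotherapy": ArmCurves(WeibullSurvival(1.25, 32.0), WeibullSurvival(1.15, 92.0)),
        "nivolumab_ipilimumab": ArmCurves(WeibullSurvival(0.85, 38.0), WeibullSurvival(0.95, 120.0)),
    },
    ("pdl1_low", "checkmate227"): {
        "chemotherapy": ArmCurves(WeibullSurvival(1.25, 26.0), WeibullSurvival(1.15, 70.0)),
        "nivolumab_ipilimumab": ArmCurves(WeibullSurvival(0.85, 40.0), WeibullSurvival(0.95, 130.0)),
    },
}
# alternative reference: chemotherapy-arm survival as observed in the
# later combination trial (slightly better OS than the 227-style arm)
for _sub in SUBGROUPS:
    _src = _SCENARIOS[(_sub, "checkmate227")]
    _SCENARIOS[(_sub, "checkmate9la")] = {
        "chemotherapy": ArmCurves(
            WeibullSurvival(_src["chemotherapy"].pfs.shape, _src["chemotherapy"].pfs.scale * 1.05),
            WeibullSurvival(1.10, _src["chemotherapy"].os.scale * 1.06),
        ),
        "nivolumab_ipilimumab": _src["nivolumab_ipilimumab"],
    }


def scenario_curves(subgroup: str = "all", reference_trial: str = "checkmate227"):
    """Ground-truth arm curves for a named subgroup / reference-trial pair."""
    try:
        return dict(_SCENARIOS[(subgroup, reference_trial)])
    except KeyError as exc:
        raise KeyError(
            f"no scenario for subgroup={subgroup!r}, reference_trial={reference_trial!r}"
        ) from exc


@dataclass
class SyntheticTrialSpec:
    """Specification of a synthetic digitized trial.

    ``mode`` "exact" evaluates ground truth on the grid (a perfectly
    digitized arbitrarily large trial); "sampled" simulates individual
    event and censoring times and digitizes the resulting Kaplan-Meier
    estimate.  ``noise_sd`` adds truncated Gaussian digitization error to
    the survival values, re-monotonized by cumulative minimum.  The OS
    curve is kept above PFS at every grid point by construction.
    """

    arms: dict[str, ArmCurves]
    enrollment: int = 583
    annual_censor_rate: float = 0.05
    grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 205.0, 6.0))
    noise_sd: float = 0.0
    mode: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.mode not in ("exact", "sampled"):
            raise ValueError("mode must be 'exact' or 'sampled'")
        if self.enrollment < 1:
            raise ValueError("enrollment must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.annual_censor_rate < 0:
            raise ValueError("censoring rate must be non-negative")
        for name, arm in self.arms.items():
            s_pfs = arm.pfs.at(self.grid)
            s_os = arm.os.at(self.grid)
            if np.any(s_os < s_pfs - 1e-9):
                raise ValueError(
                    f"arm {name!r}: ground-truth OS falls below PFS on the grid; "
                    "every death must be preceded by progression"
                )


def _digitize_exact(curve: WeibullSurvival, grid, enrollment: int):
    surv = curve.at(grid)
    at_risk = np.round(enrollment * surv)
    return surv, at_risk


def _km_on_grid(event_times, observed, grid):
    """Kaplan-Meier estimate evaluated at grid times, with at-risk counts."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(event_times, event_observed=observed)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = np.array([(event_times >= t - 1e-9).sum() for t in grid], dtype=float)
    return surv, at_risk


def _digitize_sampled(curve, grid, enrollment, annual_censor_rate, rng):
    true_times = curve.scale * rng.weibull(curve.shape, size=enrollment)
    t_max = grid[-1]
    if annual_censor_rate > 0:
        censor = rng.exponential(WEEKS_PER_YEAR / annual_censor_rate, size=enrollment)
        censor = np.minimum(censor, t_max)
    else:
        censor = np.full(enrollment, t_max)
    observed_times = np.minimum(true_times, censor)
    events = true_times <= censor
    return _km_on_grid(observed_times, events, grid)


def _apply_noise(surv, noise_sd, rng):
    eps = np.clip(rng.normal(0.0, noise_sd, size=len(surv)), -3 * noise_sd, 3 * noise_sd)
    noisy = np.clip(surv + eps, 0.0, 1.0)
    noisy[0] = 1.0
    return np.minimum.accumulate(noisy)


def _validate_informative(surv) -> None:
    if np.sum(np.diff(surv) < -1e-12) < 2:
        raise ValueError(
            "degenerate synthetic curve: fewer than three distinct decreasing "
            "survival values (censoring too heavy or grid too short)"
        )


def gen_trial(spec: SyntheticTrialSpec) -> dict[str, dict[str, DigitizedKM]]:
    """Generate digitized KM curves per arm and endpoint from ground truth.

    Returns ``{arm: {"PFS": DigitizedKM, "OS": DigitizedKM}}``.  Determinism:
    the same spec (including seed) always yields identical output.  Ground
    truth remains available on ``spec.arms`` for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, dict[str, DigitizedKM]] = {}
    for arm_name in sorted(spec.arms):
        arm = spec.arms[arm_name]
        curves = {}
        surv_by_endpoint = {}
        for endpoint, truth in (("PFS", arm.pfs), ("OS", arm.os)):
            if spec.mode == "exact":
                surv, at_risk = _digitize_exact(truth, spec.grid, spec.enrollment)
            else:
                surv, at_risk = _digitize_sampled(
                    truth, spec.grid, spec.enrollment, spec.annual_censor_rate, rng
                )
            if spec.noise_sd > 0:
                surv = _apply_noise(surv, spec.noise_sd, rng)
            surv_by_endpoint[endpoint] = surv
            curves[endpoint] = at_risk
        # keep OS on or above PFS at every grid point
        surv_by_endpoint["OS"] = np.maximum(surv_by_endpoint["OS"], surv_by_endpoint["PFS"])
        for endpoint in ("PFS", "OS"):
            surv = surv_by_endpoint[endpoint]
            _validate_informative(surv)
            curves[endpoint] = DigitizedKM(
                endpoint=endpoint,
                times=spec.grid.copy(),
                survival=surv,
                at_risk=curves[endpoint],
            )
        out[arm_name] = curves
    return out


def gen_param_set(seed: int | None = None, perturb: bool = False):
    """A complete, validated model configuration plus its distributions.

    By default returns the baseline configuration (every field at its
    published value).  With ``perturb=True`` and a seed, every uncertain
    parameter is redrawn from its distribution and clipped to its published
    range, yielding a plausible alternative parameter set.
    """
    if perturb:
        if seed is None:
            raise ValueError("perturbation requires a seed")
        cfg = perturbed_config(seed)
    else:
        cfg = base_config()
    return cfg, table_distributions()
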