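"""Transition-probability calibration for the three-state Markov model.

The model has states progression-free (PF), progressive disease (PD) and
death, with no death allowed directly from PF: every patient progresses
before dying.  Per-cycle PF->PD probabilities come straight from the
progression-free survival curve; the PD->death probabilities are then
back-solved cycle by cycle so that modeled overall survival (PF + PD)
reproduces the target OS curve exactly wherever that is feasible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import interval_event_prob

__all__ = [
    "TransitionSchedule",
    "CalibrationReport",
    "pfs_to_progression_probs",
    "calibrate_death_probs",
    "simulate_memberships",
    "validate_calibration",
]

log = logging.getLogger(__name__)

#: PD membership below which a required OS drop is deferred to the next cycle
#: (early cycles where nobody has progressed yet cannot absorb deaths).
PD_EPSILON = 1e-9


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities driving the cohort model."""

    p_pf_to_pd: np.ndarray
    p_pd_to_death: np.ndarray
    clamped_cycles: list[int] = field(default_factory=list)
    deferred_cycles: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.p_pf_to_pd = np.asarray(self.p_pf_to_pd, dtype=float)
        self.p_pd_to_death = np.asarray(self.p_pd_to_death, dtype=float)
        if self.p_pf_to_pd.shape != self.p_pd_to_death.shape:
            raise ValueError("probability sequences must have equal length")
        for name, arr in (("p_pf_to_pd", self.p_pf_to_pd), ("p_pd_to_death", self.p_pd_to_death)):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} must lie in [0, 1]")
        self.p_pf_to_pd = np.clip(self.p_pf_to_pd, 0.0, 1.0)
        self.p_pd_to_death = np.clip(self.p_pd_to_death, 0.0, 1.0)

    @property
    def n_cycles(self) -> int:
        return len(self.p_pf_to_pd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "p_pf_to_pd": self.p_pf_to_pd,
                "p_pd_to_death": self.p_pd_to_death,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionSchedule":
        df = df.sort_values("cycle")
        return cls(df["p_pf_to_pd"].to_numpy(), df["p_pd_to_death"].to_numpy())


def pfs_to_progression_probs(pfs, cycles: int, dt: float) -> np.ndarray:
    """Per-cycle PF->PD probabilities from a PFS curve.

    Element k is the conditional progression probability over cycle k,
    1 - S_pfs((k+1) dt) / S_pfs(k dt).  Under the no-death-in-PF assumption
    the product of complements reconstructs the PFS curve exactly.
    """
    if cycles < 1:
        raise ValueError("need at least one cycle")
    return np.array([interval_event_prob(pfs, k * dt, dt) for k in range(cycles)])


def simulate_memberships(p_pf_to_pd, p_pd_to_death, cycles: int | None = None):
    """Forward-iterate state occupancies from a full PF cohort.

    Transitions are ordered so patients progressing in cycle k become
    eligible for death from cycle k+1 onward.  Returns arrays of length
    cycles+1 with occupancies at cycle boundaries (index k = start of
    cycle k); death occupancy is 1 - pf - pd.
    """
    p_prog = np.asarray(p_pf_to_pd, dtype=float)
    p_death = np.asarray(p_pd_to_death, dtype=float)
    n = len(p_prog) if cycles is None else int(cycles)
    if n > len(p_prog) or n > len(p_death):
        raise ValueError("schedule shorter than requested number of cycles")
    pf = np.empty(n + 1)
    pd_ = np.empty(n + 1)
    pf[0], pd_[0] = 1.0, 0.0
    for k in range(n):
        prog = pf[k] * p_prog[k]
        deaths = pd_[k] * p_death[k]
        pf[k + 1] = pf[k] - prog
        pd_[k + 1] = pd_[k] - deaths + prog
    return pf, pd_


def calibrate_death_probs(
    pfs_probs, os_curve, cycles: int, dt: float, eps: float = PD_EPSILON
) -> TransitionSchedule:
    """Back-solve per-cycle PD->death probabilities against a target OS curve.

    At each cycle the death probability is the OS drop required over the
    cycle divided by current PD membership, with the membership evolved by
    forward simulation.  Requirements that exceed [0, 1] are clamped and the
    cycle recorded; drops demanded while PD membership is still essentially
    zero are deferred to later cycles (the unmet deficit carries forward
    automatically because the next requirement is measured from modeled,
    not target, survival).
    """
    p_prog = np.asarray(pfs_probs, dtype=float)
    if cycles > len(p_prog):
        raise ValueError("progression schedule shorter than requested cycles")
    grid = np.arange(cycles + 1) * dt
    os_target = np.array([os_curve.at(t) for t in grid])

    s_pfs = np.concatenate([[1.0], np.cumprod(1.0 - p_prog[:cycles])])
    if np.any(os_target < s_pfs - 1e-9):
        worst = int(np.argmax(s_pfs - os_target))
        raise ValueError(
            "target OS falls below PFS at cycle "
            f"{worst} (OS={os_target[worst]:.6f} < PFS={s_pfs[worst]:.6f}); "
            "every death must be preceded by progression"
        )

    p_death = np.zeros(cycles)
    clamped: list[int] = []
    deferred: list[int] = []
    pf, pd_ = 1.0, 0.0
    for k in range(cycles):
        drop_needed = (pf + pd_) - os_target[k + 1]
        if pd_ > eps:
            p = drop_needed / pd_
            if p < 0.0:
                p = 0.0
                clamped.append(k)
            elif p > 1.0:
                p = 1.0
                clamped.append(k)
        else:
            p = 0.0
            if drop_needed > 1e-12:
                deferred.append(k)
        prog = pf * p_prog[k]
        deaths = pd_ * p
        pf, pd_ = pf - prog, pd_ - deaths + prog
        p_death[k] = p

    if clamped:
        log.warning("calibration clamped PD->death probability at %d cycle(s): %s",
                    len(clamped), clamped[:10])
    if deferred:
        log.info("calibration deferred OS drops at %d early cycle(s)", len(deferred))
    return TransitionSchedule(p_prog[:cycles], p_death, clamped, deferred)


@dataclass(frozen=True)
class CalibrationReport:
    """Fit of a forward-simulated schedule against a target OS curve.

    ``max_abs_deviation`` covers every cycle boundary;
    ``unclamped_max_abs_deviation`` excludes boundaries directly downstream
    of a clamped or deferred cycle, where an exact match is structurally
    impossible (e.g. the target OS drops before anyone has progressed).
    """

    max_abs_deviation: float
    unclamped_max_abs_deviation: float
    residuals: np.ndarray  # OS_model - OS_target at each cycle boundary
    tolerance: float
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cycle": np.arange(len(self.residuals)), "residual": self.residuals}
        )


def validate_calibration(
    schedule: TransitionSchedule, os_target, dt: float, tolerance: float = 1e-6
) -> CalibrationReport:
    """Compare forward-simulated OS against the target at every cycle boundary."""
    n = schedule.n_cycles
    if n < 1:
        raise ValueError("empty schedule: no overlap with target")
    pf, pd_ = simulate_memberships(schedule.p_pf_to_pd, schedule.p_pd_to_death)
    grid = np.arange(n + 1) * dt
    target = np.array([os_target.at(t) for t in grid])
    residuals = (pf + pd_) - target
    max_dev = float(np.max(np.abs(residuals)))
    mask = np.ones(n + 1, dtype=bool)
    mask[0] = False  # boundary 0 is exact by construction
    for k in schedule.clamped_cycles + schedule.deferred_cycles:
        if k + 1 <= n:
            mask[k + 1] = False
    unclamped = float(np.max(np.abs(residuals[mask]))) if mask.any() else 0.0
    return CalibrationReport(max_dev, unclamped, residuals, tolerance,
                             unclamped <= tolerance)
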