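"""Survival curves for the cost-effectiveness model.

Trial evidence enters the model as digitized Kaplan-Meier step curves
(survival probabilities read off a published figure at grid times, with
numbers-at-risk annotations).  Within the trial follow-up the curve is used
directly; beyond follow-up a Weibull function fitted to the digitized points
extrapolates survival to lifetime.  Comparator arms without their own curves
are derived through proportional-hazards transforms, S'(t) = S(t)**hr.

Times are in weeks throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "DigitizedKM",
    "WeibullSurvival",
    "HazardRatioPair",
    "PiecewiseExtrapolatedSurvival",
    "HRTransformedSurvival",
    "survival_at",
    "fit_weibull_km",
    "apply_hazard_ratio",
    "interval_event_prob",
]


@dataclass(frozen=True)
class WeibullSurvival:
    """Two-parameter Weibull survival function S(t) = exp(-(t/scale)**shape).

    Parameters
    ----------
    shape : float
        Dimensionless shape; shape < 1 means decreasing hazard, 1 is
        exponential, > 1 increasing hazard.
    scale : float
        Characteristic life in weeks; S(scale) = exp(-1) regardless of shape.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be a positive finite number, got {self.shape}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be a positive finite number, got {self.scale}")

    def at(self, t):
        """Survival probability at time ``t`` (weeks); scalar or array."""
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise ValueError("time must be non-negative")
        s = np.exp(-((arr / self.scale) ** self.shape))
        return float(s) if arr.ndim == 0 else s

    def median(self) -> float:
        return self.scale * np.log(2.0) ** (1.0 / self.shape)

    def mean(self) -> float:
        from scipy.special import gamma as gamma_fn

        return self.scale * gamma_fn(1.0 + 1.0 / self.shape)


@dataclass(frozen=True)
class HazardRatioPair:
    """Hazard ratios of an intervention arm versus a reference arm."""

    hr_pfs: float
    hr_os: float

    def __post_init__(self) -> None:
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValueError("hazard ratios must be positive")


@dataclass
class DigitizedKM:
    """A digitized Kaplan-Meier step curve for one arm and endpoint.

    ``times`` must be strictly increasing and start at 0 with survival 1;
    ``survival`` is non-increasing in [0, 1].  ``at_risk`` optionally carries
    numbers-at-risk aligned to ``times`` (non-increasing, non-negative).
    """

    endpoint: str  # "PFS" or "OS"
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError(f"endpoint must be 'PFS' or 'OS', got {self.endpoint!r}")
        if self.times.ndim != 1 or self.times.shape != self.survival.shape:
            raise ValueError("times and survival must be 1-d arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.times[0]) > 1e-12 or abs(self.survival[0] - 1.0) > 1e-9:
            raise ValueError("curve must start at t=0 with survival 1")
        if np.any(self.survival < -1e-12) or np.any(self.survival > 1.0 + 1e-9):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        self.survival = np.clip(self.survival, 0.0, 1.0)
        if self.at_risk is not None:
            self.at_risk = np.asarray(self.at_risk, dtype=float)
            if self.at_risk.shape != self.times.shape:
                raise ValueError("at_risk must align with times")
            if np.any(self.at_risk < 0):
                raise ValueError("at_risk counts must be non-negative")
            if np.any(np.diff(self.at_risk) > 1e-9):
                raise ValueError("at_risk counts must be non-increasing")
            if np.any(np.abs(self.at_risk - np.round(self.at_risk)) > 1e-6):
                raise ValueError("at_risk counts must be integers")

    @property
    def last_time(self) -> float:
        return float(self.times[-1])

    def at(self, t):
        """Step-function survival at ``t`` (right-continuous, previous value).

        Raises for ``t`` outside the digitized range: the step curve carries
        no information beyond its last observed time.
        """
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise ValueError("time must be non-negative")
        if np.any(arr > self.times[-1] + 1e-9):
            raise ValueError(
                f"curve undefined beyond t={self.times[-1]:g} weeks; requested later time"
            )
        idx = np.searchsorted(self.times, arr + 1e-12, side="right") - 1
        s = self.survival[np.clip(idx, 0, len(self.times) - 1)]
        return float(s) if arr.ndim == 0 else s


@dataclass(frozen=True)
class PiecewiseExtrapolatedSurvival:
    """Digitized step curve within follow-up, Weibull tail beyond.

    The tail is rescaled so the composite curve is continuous at the switch
    time: S(t) = S_km(t_s) * S_w(t) / S_w(t_s) for t > t_s.  In-trial values
    are taken directly from the digitized curve; the fitted function only
    governs extrapolation.
    """

    km: DigitizedKM
    tail: WeibullSurvival
    switch_time: float | None = None

    def __post_init__(self) -> None:
        st = self.km.last_time if self.switch_time is None else float(self.switch_time)
        if st < 0 or st > self.km.last_time + 1e-9:
            raise ValueError("switch_time must lie within the digitized range")
        object.__setattr__(self, "switch_time", st)

    def at(self, t):
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise ValueError("time must be non-negative")
        out = np.empty(arr.shape if arr.ndim else (1,), dtype=float)
        flat_t = np.atleast_1d(arr)
        inside = flat_t <= self.switch_time + 1e-12
        if np.any(inside):
            out[inside] = np.atleast_1d(self.km.at(flat_t[inside]))
        if np.any(~inside):
            anchor = self.km.at(self.switch_time)
            denom = self.tail.at(self.switch_time)
            out[~inside] = anchor * self.tail.at(flat_t[~inside]) / denom
        return float(out[0]) if arr.ndim == 0 else out


@dataclass(frozen=True)
class HRTransformedSurvival:
    """Proportional-hazards transform of any survival curve: S(t)**hr."""

    base: object  # anything with .at(t)
    hr: float

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")

    def at(self, t):
        s = self.base.at(t)
        return np.power(s, self.hr) if isinstance(s, np.ndarray) else float(s) ** self.hr


def survival_at(curve, t):
    """Evaluate a survival representation at time ``t`` (weeks)."""
    return curve.at(t)


def apply_hazard_ratio(ref: WeibullSurvival, hr: float) -> WeibullSurvival:
    """Transform a Weibull curve by a proportional hazard ratio.

    With a shared shape, multiplying the hazard by ``hr`` rescales the scale
    parameter: scale' = scale * hr**(-1/shape), so S'(t) = S(t)**hr exactly.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return WeibullSurvival(shape=ref.shape, scale=ref.scale * hr ** (-1.0 / ref.shape))


def interval_event_prob(curve, t: float, dt: float) -> float:
    """Conditional probability of the event within (t, t+dt] given alive at t.

    Returns 1 - S(t+dt)/S(t).  When S(t) has decayed to numerical zero the
    probability is 1 by convention (the cohort there is absorbed anyway).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if dt <= 0:
        raise ValueError("cycle length must be positive")
    s0 = curve.at(t)
    if s0 <= 1e-300:
        return 1.0
    s1 = curve.at(t + dt)
    return float(np.clip(1.0 - s1 / s0, 0.0, 1.0))


def _wls_loglog_fit(times, survival, weights=None) -> WeibullSurvival:
    """Weighted least squares on log(-log S) vs log t (Weibull linearization)."""
    t = np.asarray(times, dtype=float)
    s = np.asarray(survival, dtype=float)
    mask = (t > 0) & (s > 0) & (s < 1)
    if mask.sum() < 2:
        raise ValueError("need at least two points with 0 < S < 1 at t > 0 to fit")
    x = np.log(t[mask])
    y = np.log(-np.log(s[mask]))
    w = np.ones(mask.sum()) if weights is None else np.asarray(weights, dtype=float)[mask]
    w = np.maximum(w, 1e-12)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    if slope <= 0:
        raise ValueError("degenerate curve: fitted shape is non-positive")
    return WeibullSurvival(shape=float(slope), scale=float(np.exp(-intercept / slope)))


def _reconstructed_counts(times, survival, at_risk):
    """Per-interval event and censoring counts implied by curve + at-risk table.

    Deaths in [t_k, t_{k+1}) follow from the at-risk count and the survival
    drop, d_k = n_k (1 - S_{k+1}/S_k); the remainder of the at-risk decline is
    censoring.  Counts may be fractional; intervals with nobody at risk are
    excluded.
    """
    n = np.asarray(at_risk, dtype=float)
    s = np.asarray(survival, dtype=float)
    k = len(times) - 1
    deaths = np.zeros(k)
    censored = np.zeros(k)
    for i in range(k):
        if n[i] <= 0 or s[i] <= 0:
            continue
        deaths[i] = n[i] * (1.0 - s[i + 1] / s[i])
        censored[i] = max(n[i] - deaths[i] - n[i + 1], 0.0)
    return deaths, censored


def fit_weibull_km(km: DigitizedKM) -> WeibullSurvival:
    """Fit a Weibull survival function to a digitized Kaplan-Meier curve.

    When numbers-at-risk are available the fit maximizes an
    interval-censored likelihood over the event structure reconstructed from
    the curve and the at-risk table (events interval-censored within each
    digitization interval, losses censored at the interval midpoint, the
    final at-risk count right-censored at the last time).  Without an
    at-risk table the fit falls back to weighted least squares on the
    log(-log S) linearization.
    """
    if len(km.times) < 3:
        raise ValueError("need at least three digitized time points to fit")
    decreasing = np.sum(np.diff(km.survival) < -1e-12)
    if decreasing < 2:
        raise ValueError("degenerate curve: need at least three distinct decreasing survival values")

    init = _wls_loglog_fit(km.times, km.survival, km.at_risk)
    if km.at_risk is None:
        return init

    times = km.times
    deaths, censored = _reconstructed_counts(times, km.survival, km.at_risk)
    mids = 0.5 * (times[:-1] + times[1:])
    n_tail = float(km.at_risk[-1])
    t_last = times[-1]

    def nll(p):
        shape, scale = np.exp(p)
        cum_haz = (times / scale) ** shape
        surv = np.exp(-cum_haz)
        p_int = np.clip(surv[:-1] - surv[1:], 1e-300, None)
        ll = np.sum(deaths * np.log(p_int))
        ll -= np.sum(censored * (mids / scale) ** shape)
        ll -= n_tail * (t_last / scale) ** shape
        return -ll

    x0 = np.log([init.shape, init.scale])
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000, "maxfev": 4000},
    )
    if not np.all(np.isfinite(res.x)):
        return init
    shape, scale = np.exp(res.x)
    return WeibullSurvival(shape=float(shape), scale=float(scale))
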