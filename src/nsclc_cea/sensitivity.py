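"""Probabilistic and one-way deterministic sensitivity analysis.

PSA redraws every uncertain parameter from its assigned distribution each
iteration, reruns all strategies, and summarizes the resulting cloud of
outcomes as cost-effectiveness acceptability curves (CEAC) and incremental
cost-effectiveness scatter data.  One-way DSA sweeps each parameter across
its published range and reports the ICER swing (tornado table).

Survival transition probabilities stay fixed at base case during PSA: they
are time-dependent curve-derived quantities without an assigned sampling
distribution in the input table.
"""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .economics import StrategyOutcome, icer
from .parameters import ParamDistribution, set_by_path

__all__ = [
    "PSAResult",
    "sample_params",
    "run_psa",
    "ceac",
    "ce_scatter",
    "fraction_cost_effective",
    "one_way_dsa",
]

log = logging.getLogger(__name__)

Runner = Callable[[dict], Mapping[str, StrategyOutcome]]


def sample_params(
    config: dict, distributions: list[ParamDistribution], rng: np.random.Generator
) -> dict:
    """One sampled configuration: each distributed parameter redrawn.

    Parameters are drawn independently; a parameter shared between arms
    (e.g. the progression-free utility of both immunotherapy-containing
    strategies) occupies a single configuration slot and is therefore drawn
    once, keeping the arms correlated.
    """
    cfg = copy.deepcopy(config)
    for d in distributions:
        if d.family == "fixed":
            continue
        set_by_path(cfg, d.path, d.sample(rng))
    return cfg


@dataclass
class PSAResult:
    """Per-iteration strategy outcomes from probabilistic analysis."""

    data: pd.DataFrame  # columns: iteration, strategy, cost, ly, qaly
    seed: int
    iterations: int
    failures: list[int]

    def strategies(self) -> list[str]:
        return sorted(self.data["strategy"].unique())

    def pivot(self, column: str) -> pd.DataFrame:
        return self.data.pivot(index="iteration", columns="strategy", values=column)


def run_psa(
    runner: Runner,
    config: dict,
    distributions: list[ParamDistribution],
    iterations: int = 500,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo PSA: sample, rebuild, rerun every strategy per iteration.

    Each iteration uses an independent substream derived from (seed,
    iteration index), so results are reproducible and order-independent.
    Failed iterations are logged and skipped, not fatal.
    """
    if iterations < 1:
        raise ValueError("need at least one iteration")
    rows = []
    failures: list[int] = []
    for i in range(iterations):
        rng = np.random.default_rng([seed, i])
        cfg = sample_params(config, distributions, rng)
        try:
            outcomes = runner(cfg)
        except Exception:  # noqa: BLE001 - record and continue
            log.exception("PSA iteration %d failed; skipping", i)
            failures.append(i)
            continue
        for name, o in outcomes.items():
            rows.append({"iteration": i, "strategy": name,
                         "cost": o.cost, "ly": o.ly, "qaly": o.qaly})
    if not rows:
        raise RuntimeError("every PSA iteration failed")
    return PSAResult(pd.DataFrame(rows), seed=seed, iterations=iterations, failures=failures)


def ceac(psa: PSAResult, thresholds) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each willingness-to-pay threshold, the probability a strategy is
    optimal is the fraction of iterations in which it attains the maximum
    net monetary benefit; exact ties share the count equally, so the
    probabilities sum to one at every threshold.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if len(psa.data) == 0:
        raise ValueError("empty PSA result")
    cost = psa.pivot("cost")
    qaly = psa.pivot("qaly")
    n_iter = len(cost)
    rows = []
    for lam in thresholds:
        nmb = lam * qaly - cost
        best = nmb.max(axis=1)
        is_best = nmb.eq(best, axis=0)
        share = is_best.div(is_best.sum(axis=1), axis=0)
        probs = share.sum(axis=0) / n_iter
        for name, p in probs.items():
            rows.append({"threshold": lam, "strategy": name, "probability": p})
    return pd.DataFrame(rows)


def ce_scatter(psa: PSAResult, reference: str) -> pd.DataFrame:
    """Per-iteration incremental (dQALY, dCost) pairs versus a reference arm."""
    if reference not in psa.strategies():
        raise ValueError(f"reference strategy {reference!r} not in PSA result")
    cost = psa.pivot("cost")
    qaly = psa.pivot("qaly")
    rows = []
    for name in psa.strategies():
        d_cost = cost[name] - cost[reference]
        d_qaly = qaly[name] - qaly[reference]
        for it, (dq, dc) in enumerate(zip(d_qaly.to_numpy(), d_cost.to_numpy())):
            rows.append({"iteration": cost.index[it], "strategy": name,
                         "d_qaly": dq, "d_cost": dc})
    return pd.DataFrame(rows)


def fraction_cost_effective(scatter: pd.DataFrame, strategy: str, wtp: float) -> float:
    """Fraction of iterations falling below the WTP ray (positive NMB vs
    the reference): wtp * dQALY - dCost > 0."""
    sub = scatter[scatter["strategy"] == strategy]
    if len(sub) == 0:
        raise ValueError(f"strategy {strategy!r} not present in scatter data")
    nmb = wtp * sub["d_qaly"] - sub["d_cost"]
    return float((nmb > 0).mean())


def one_way_dsa(
    runner: Runner,
    config: dict,
    distributions: list[ParamDistribution],
    strategy: str = "nivolumab_ipilimumab",
    comparator: str = "chemotherapy",
) -> pd.DataFrame:
    """Tornado table: rerun the base case at each parameter's range ends.

    For every parameter with a published range, the configuration is rerun
    with the parameter at its minimum and at its maximum (everything else
    at base), and the resulting ICER of ``strategy`` versus ``comparator``
    recorded.  Rows are sorted by the ICER swing.
    """
    base_outcomes = runner(config)
    base_icer = icer(base_outcomes[strategy], base_outcomes[comparator]).per_qaly
    rows = []
    for d in distributions:
        if d.range is None or d.family == "fixed":
            continue
        lo, hi = d.range
        icers = {}
        for label, value in (("low", lo), ("high", hi)):
            cfg = copy.deepcopy(config)
            set_by_path(cfg, d.path, value)
            outcomes = runner(cfg)
            icers[label] = icer(outcomes[strategy], outcomes[comparator]).per_qaly
        swing = (
            abs(icers["high"] - icers["low"])
            if icers["low"] is not None and icers["high"] is not None
            else np.nan
        )
        rows.append({
            "parameter": d.name, "base_value": d.base,
            "low_value": lo, "high_value": hi,
            "low_icer": icers["low"], "high_icer": icers["high"],
            "base_icer": base_icer, "swing": swing,
        })
    df = pd.DataFrame(rows)
    return df.sort_values("swing", ascending=False, kind="stable").reset_index(drop=True)
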