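"""Baseline model parameters and their uncertainty distributions.

The default configuration encodes the published input table of the analysis:
per-6-week drug acquisition costs, administration cost, grade 3/4
adverse-event incidences and management costs, second-line therapy mixes,
health-state utilities, histology mix, and the hazard ratios linking the
combination arm to the chemotherapy reference.  Each uncertain parameter
carries its distribution family (Beta / Gamma / Dirichlet) and plausible
range for probabilistic and one-way deterministic sensitivity analysis.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParamDistribution",
    "base_config",
    "table_distributions",
    "check_param_means",
    "get_by_path",
    "set_by_path",
    "validate_config",
]


@dataclass(frozen=True)
class ParamDistribution:
    """A PSA-sampleable description of one input parameter.

    ``path`` is a dot-path into the run configuration; ``family`` is one of
    "beta", "gamma", "dirichlet" or "fixed"; ``params`` are the family
    parameters (alpha/beta, shape/scale, or Dirichlet counts); ``range``
    is the plausible (min, max) used by one-way sensitivity analysis, or
    ``None`` when no range is published.
    """

    name: str
    path: str
    base: float
    family: str
    params: tuple = ()
    range: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "dirichlet", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma") and (
            len(self.params) != 2 or any(p <= 0 for p in self.params)
        ):
            raise ValueError(f"{self.name}: {self.family} needs two positive parameters")
        if self.family == "dirichlet" and (
            len(self.params) < 2 or any(p <= 0 for p in self.params)
        ):
            raise ValueError(f"{self.name}: dirichlet needs >=2 positive counts")
        if self.range is not None and self.range[0] > self.range[1]:
            raise ValueError(f"{self.name}: range min exceeds max")

    def mean(self) -> float:
        """Analytic mean of the assigned family (the base value for fixed)."""
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "dirichlet":
            return self.params[0] / sum(self.params)
        return self.base

    def sample(self, rng: np.random.Generator) -> float:
        """One draw; a two-count Dirichlet reduces to its first component
        (equivalent to a Beta draw)."""
        if self.family == "beta":
            return float(rng.beta(*self.params))
        if self.family == "gamma":
            shape, scale = self.params
            return float(rng.gamma(shape, scale))
        if self.family == "dirichlet":
            return float(rng.dirichlet(self.params)[0])
        return self.base


def get_by_path(config: dict, path: str):
    node = config
    for key in path.split("."):
        node = node[key]
    return node


def set_by_path(config: dict, path: str, value) -> None:
    keys = path.split(".")
    node = config
    for key in keys[:-1]:
        node = node[key]
    node[keys[-1]] = value


def base_config() -> dict:
    """Baseline run configuration (all costs in 2020 USD, times in weeks)."""
    return {
        "settings": {
            "cycle_length_weeks": 6.0,
            "discount_rate": 0.03,
            "horizon_years": 40.0,
            "cohort_size": 10_000,
            "wtp": 150_000.0,
            "half_cycle_correction": True,
            "extinction_threshold": 1e-4,
        },
        "parameters": {
            "squamous_fraction": 0.28,
            "utilities": {"pf_chemo": 0.79, "pf_ni": 0.88, "pd": 0.72},
            "admin_cost_per_visit": 149.0,
            "drug_cost_per_cycle": {
                "nivolumab_ipilimumab": 29_890.0,
                "gemcitabine_carboplatin": 2_528.0,
                "paclitaxel_carboplatin": 502.0,
                "pemetrexed_carboplatin": 13_791.0,
                "docetaxel": 834.0,
                "nivolumab": 18_756.0,
                "erlotinib": 14_350.0,
            },
            "bsc_cost_per_cycle": 4_894.0,
            "bsc_in_pf": False,
            "ae_costs": {
                "diarrhea": 17_668.0,
                "rash": 16_811.0,
                "fatigue": 17_320.0,
                "decreased_appetite": 24_814.0,
                "nausea": 20_698.0,
                "anemia": 21_681.0,
                "neutropenia": 18_386.0,
            },
            "ae_incidence": {
                "chemotherapy": {
                    "diarrhea": 0.007,
                    "fatigue": 0.014,
                    "decreased_appetite": 0.012,
                    "nausea": 0.021,
                    "anemia": 0.116,
                    "neutropenia": 0.095,
                },
                "nivolumab_ipilimumab": {
                    "diarrhea": 0.017,
                    "rash": 0.016,
                    "fatigue": 0.017,
                    "decreased_appetite": 0.007,
                    "nausea": 0.005,
                    "anemia": 0.014,
                },
                "nivolumab_ipilimumab_chemo": {
                    "diarrhea": 0.048,
                    "rash": 0.017,
                    "fatigue": 0.055,
                    "decreased_appetite": 0.012,
                    "nausea": 0.034,
                    "anemia": 0.048,
                    "neutropenia": 0.070,
                },
            },
            "second_line": {
                "chemotherapy": {"chemo": 0.297, "immuno": 0.408, "targeted": 0.058},
                "nivolumab_ipilimumab": {"chemo": 0.350, "immuno": 0.055, "targeted": 0.057},
                "nivolumab_ipilimumab_chemo": {"chemo": 0.387, "immuno": 0.071, "targeted": 0.065},
            },
            "hazard_ratios": {"pfs": 0.68, "os": 0.66},
            "first_line_caps": {"chemotherapy": 2, "nivolumab_ipilimumab": 17},
        },
    }


def _beta_rows():
    # (table row name, path, base, (alpha, beta), (min, max))
    p = "parameters"
    rows = []
    ae = [
        # N+I + chemotherapy arm
        ("N+I+chemotherapy", "nivolumab_ipilimumab_chemo", [
            ("Diarrhea", "diarrhea", 0.048, (17, 341), (0.038, 0.057)),
            ("Rash", "rash", 0.017, (6, 352), (0.013, 0.020)),
            ("Fatigue", "fatigue", 0.055, (20, 338), (0.044, 0.066)),
            ("Decreased appetite", "decreased_appetite", 0.012, (4, 354), (0.009, 0.014)),
            ("Nausea", "nausea", 0.034, (12, 346), (0.027, 0.041)),
            ("Anemia", "anemia", 0.048, (17, 341), (0.038, 0.057)),
            ("Neutropenia", "neutropenia", 0.070, (25, 333), (0.056, 0.083)),
        ]),
        ("N+I", "nivolumab_ipilimumab", [
            ("Diarrhea", "diarrhea", 0.017, (10, 566), (0.014, 0.020)),
            ("Rash", "rash", 0.016, (9, 567), (0.013, 0.019)),
            ("Fatigue", "fatigue", 0.017, (10, 566), (0.014, 0.020)),
            ("Decreased appetite", "decreased_appetite", 0.007, (4, 572), (0.006, 0.008)),
            ("Nausea", "nausea", 0.005, (3, 573), (0.004, 0.006)),
            ("Anemia", "anemia", 0.014, (8, 568), (0.011, 0.017)),
        ]),
        ("chemotherapy", "chemotherapy", [
            ("Diarrhea", "diarrhea", 0.007, (4, 566), (0.006, 0.008)),
            ("Fatigue", "fatigue", 0.014, (8, 562), (0.011, 0.017)),
            ("Decreased appetite", "decreased_appetite", 0.012, (7, 563), (0.010, 0.014)),
            ("Nausea", "nausea", 0.021, (12, 558), (0.017, 0.025)),
            ("Anemia", "anemia", 0.116, (66, 504), (0.093, 0.139)),
            ("Neutropenia", "neutropenia", 0.095, (54, 516), (0.076, 0.114)),
        ]),
    ]
    for arm_label, arm_key, events in ae:
        for label, key, base, ab, rng in events:
            rows.append(ParamDistribution(
                name=f"Grade 3/4 AEs incidence, {arm_label}: {label}",
                path=f"{p}.ae_incidence.{arm_key}.{key}",
                base=base, family="beta", params=ab, range=rng,
            ))
    second = [
        ("N+I+chemotherapy", "nivolumab_ipilimumab_chemo", [
            ("Chemotherapy", "chemo", 0.387, (140, 221), (0.310, 0.464)),
            ("Immunotherapy", "immuno", 0.071, (26, 335), (0.057, 0.085)),
            ("Targeted therapy", "targeted", 0.065, (23, 338), (0.052, 0.078)),
        ]),
        ("N+I", "nivolumab_ipilimumab", [
            ("Chemotherapy", "chemo", 0.350, (204, 379), (0.280, 0.420)),
            ("Immunotherapy", "immuno", 0.055, (32, 551), (0.044, 0.066)),
            ("Targeted therapy", "targeted", 0.057, (33, 550), (0.046, 0.068)),
        ]),
        ("chemotherapy", "chemotherapy", [
            ("Chemotherapy", "chemo", 0.297, (173, 410), (0.238, 0.356)),
            ("Immunotherapy", "immuno", 0.408, (238, 345), (0.326, 0.490)),
            ("Targeted therapy", "targeted", 0.058, (34, 549), (0.046, 0.070)),
        ]),
    ]
    for arm_label, arm_key, entries in second:
        for label, key, base, ab, rng in entries:
            rows.append(ParamDistribution(
                name=f"Second-line therapy proportion, {arm_label}: {label}",
                path=f"{p}.second_line.{arm_key}.{key}",
                base=base, family="beta", params=ab, range=rng,
            ))
    rows += [
        ParamDistribution(
            name="Health utility: N+I with/without chemotherapy",
            path=f"{p}.utilities.pf_ni",
            base=0.88, family="beta", params=(11.0, 1.5), range=(0.79, 0.97),
        ),
        ParamDistribution(
            name="Health utility: Chemotherapy",
            path=f"{p}.utilities.pf_chemo",
            base=0.79, family="beta", params=(20.2, 5.4), range=(0.71, 0.87),
        ),
        ParamDistribution(
            name="Health utility: Progressive disease",
            path=f"{p}.utilities.pd",
            base=0.72, family="beta", params=(27.3, 10.6), range=(0.65, 0.79),
        ),
    ]
    return rows


def _gamma_rows():
    p = "parameters"
    rows = [
        ParamDistribution(
            name="Administration cost ($)",
            path=f"{p}.admin_cost_per_visit",
            base=149.0, family="gamma", params=(100.0, 1.49), range=(120.0, 179.0),
        ),
        ParamDistribution(
            name="BSC cost per 6 weeks ($)",
            path=f"{p}.bsc_cost_per_cycle",
            base=4894.0, family="gamma", params=(100.0, 48.94), range=(3915.0, 5873.0),
        ),
    ]
    drugs = [
        ("Nivolumab plus ipilimumab", "nivolumab_ipilimumab", 29_890.0, 298.90, (23_912.0, 35_868.0)),
        ("Gemcitabine plus carboplatin", "gemcitabine_carboplatin", 2_528.0, 25.28, (2_022.0, 3_034.0)),
        ("Paclitaxel plus carboplatin", "paclitaxel_carboplatin", 502.0, 5.02, (401.0, 602.0)),
        ("Pemetrexed plus carboplatin", "pemetrexed_carboplatin", 13_791.0, 137.91, (11_033.0, 16_550.0)),
        ("Docetaxel", "docetaxel", 834.0, 8.34, (667.0, 1_001.0)),
        ("Nivolumab", "nivolumab", 18_756.0, 187.56, (15_005.0, 22_507.0)),
        ("Erlotinib", "erlotinib", 14_350.0, 143.50, (11_480.0, 17_220.0)),
    ]
    for label, key, base, scale, rng in drugs:
        rows.append(ParamDistribution(
            name=f"Drug cost per 6 weeks ($): {label}",
            path=f"{p}.drug_cost_per_cycle.{key}",
            base=base, family="gamma", params=(100.0, scale), range=rng,
        ))
    ae_costs = [
        ("Diarrhea", "diarrhea", 17_668.0, 176.68, (14_135.0, 21_202.0)),
        ("Rash", "rash", 16_811.0, 168.11, (13_449.0, 20_173.0)),
        ("Fatigue", "fatigue", 17_320.0, 173.20, (13_856.0, 20_784.0)),
        ("Decrease appetite", "decreased_appetite", 24_814.0, 248.14, (19_851.0, 29_776.0)),
        ("Nausea", "nausea", 20_698.0, 206.98, (16_558.0, 24_837.0)),
        ("Anemia", "anemia", 21_681.0, 216.81, (17_345.0, 26_017.0)),
        ("Neutropenia", "neutropenia", 18_386.0, 183.86, (14_709.0, 22_063.0)),
    ]
    for label, key, base, scale, rng in ae_costs:
        rows.append(ParamDistribution(
            name=f"Grade 3/4 AEs cost ($): {label}",
            path=f"{p}.ae_costs.{key}",
            base=base, family="gamma", params=(100.0, scale), range=rng,
        ))
    return rows


def table_distributions() -> list[ParamDistribution]:
    """All uncertain input parameters with their assigned distributions.

    The histology share carries a two-count Dirichlet (equivalent to a
    Beta); the hazard ratios are published without a distribution or range
    and enter as fixed values.
    """
    rows = [
        ParamDistribution(
            name="Squamous in tumor histology",
            path="parameters.squamous_fraction",
            base=0.28, family="dirichlet", params=(163, 419), range=None,
        ),
    ]
    rows += _beta_rows()
    rows += _gamma_rows()
    rows += [
        ParamDistribution(
            name="Hazard ratio N+I+chemotherapy vs chemotherapy: PFS",
            path="parameters.hazard_ratios.pfs", base=0.68, family="fixed",
        ),
        ParamDistribution(
            name="Hazard ratio N+I+chemotherapy vs chemotherapy: OS",
            path="parameters.hazard_ratios.os", base=0.66, family="fixed",
        ),
    ]
    return rows


def _printed_tolerance(base: float) -> float:
    """Half a unit in the last printed decimal place of the baseline."""
    text = f"{base!r}"
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 0.5 * 10.0 ** (-decimals)


def check_param_means(
    distributions: list[ParamDistribution] | None = None, rtol: float = 0.005
):
    """Consistency of each printed baseline with its family's analytic mean.

    A baseline counts as consistent when it matches the analytic mean either
    to ``rtol`` relative or to the precision it was printed at (half a unit
    in its last decimal).  A handful of published rows — the combination
    arm's standardized adverse-event incidences and second-line proportions
    — fail both and are surfaced, not silently accepted.
    """
    import pandas as pd

    dists = table_distributions() if distributions is None else distributions
    rows = []
    for d in dists:
        if d.family == "fixed":
            continue
        mean = d.mean()
        rel = abs(mean - d.base) / abs(d.base) if d.base else abs(mean)
        ok = rel <= rtol or abs(mean - d.base) <= _printed_tolerance(d.base)
        rows.append({"name": d.name, "base": d.base, "analytic_mean": mean,
                     "rel_deviation": rel, "ok": ok})
    return pd.DataFrame(rows)


def validate_config(config: dict) -> list[str]:
    """Collect configuration problems; empty list means valid."""
    errors: list[str] = []
    try:
        p = config["parameters"]
    except KeyError:
        return ["missing 'parameters' block"]
    if not 0.0 <= p.get("squamous_fraction", -1) <= 1.0:
        errors.append("squamous_fraction must lie in [0, 1]")
    for key, u in p.get("utilities", {}).items():
        if not 0.0 <= u <= 1.0:
            errors.append(f"utility {key} out of [0, 1]: {u}")
    for block in ("drug_cost_per_cycle", "ae_costs"):
        for key, v in p.get(block, {}).items():
            if v < 0:
                errors.append(f"{block}.{key} negative: {v}")
    for scalar in ("admin_cost_per_visit", "bsc_cost_per_cycle"):
        if p.get(scalar, 0) < 0:
            errors.append(f"{scalar} negative")
    for arm, mix in p.get("second_line", {}).items():
        total = 0.0
        for key, v in mix.items():
            if not 0.0 <= v <= 1.0:
                errors.append(f"second_line.{arm}.{key} out of [0, 1]: {v}")
            total += v
        if total > 1.0 + 1e-9:
            errors.append(f"second_line.{arm} proportions sum to {total:.3f} > 1")
    for arm, profile in p.get("ae_incidence", {}).items():
        for key, v in profile.items():
            if not 0.0 <= v <= 1.0:
                errors.append(f"ae_incidence.{arm}.{key} out of [0, 1]: {v}")
    for key, v in p.get("hazard_ratios", {}).items():
        if v <= 0:
            errors.append(f"hazard_ratios.{key} must be positive: {v}")
    return errors


def perturbed_config(seed: int) -> dict:
    """A configuration with every uncertain parameter redrawn from its
    distribution and clipped to its published range (where one exists)."""
    cfg = copy.deepcopy(base_config())
    rng = np.random.default_rng(seed)
    for d in table_distributions():
        if d.family == "fixed":
            continue
        value = d.sample(rng)
        if d.range is not None:
            value = float(np.clip(value, d.range[0], d.range[1]))
        set_by_path(cfg, d.path, value)
    return cfg
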