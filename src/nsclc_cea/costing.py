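"""Per-cycle state costs per strategy, plus dosing helpers.

Costs (2020 USD) are assembled from first-line drug acquisition,
administration per infusion cycle, one-time adverse-event management at
model entry, second-line therapy weighted by the observed treatment mix,
and best supportive care.  Drug costs are taken as per-6-week inputs; the
dosing helpers (Calvert formula, body-metric scaling) document how such
per-cycle prices arise from unit prices and are available for extensions.
"""
from __future__ import annotations

from typing import Mapping

__all__ = [
    "ARMS",
    "carboplatin_dose",
    "body_metric_dose",
    "histology_blend",
    "first_line_drug_cost",
    "pf_state_cost",
    "pd_state_cost",
    "expected_ae_cost",
    "validate_second_line_mix",
]

#: canonical strategy keys, in comparison order
ARMS = ("chemotherapy", "nivolumab_ipilimumab", "nivolumab_ipilimumab_chemo")

#: first-line chemotherapy regimen by histology and trial design:
#: pemetrexed+carboplatin for non-squamous tumors in both source trials;
#: gemcitabine+carboplatin (227-style arms) or paclitaxel+carboplatin
#: (combination arm) for squamous tumors.
_FIRST_LINE_SQUAMOUS = {
    "chemotherapy": "gemcitabine_carboplatin",
    "nivolumab_ipilimumab_chemo": "paclitaxel_carboplatin",
}

#: second-line chemotherapy: docetaxel after first-line chemotherapy
#: (either histology); platinum doublet by histology after the
#: immunotherapy-containing arms.
_SECOND_LINE_IV_ADMIN = {"chemo": True, "immuno": True, "targeted": False}


def carboplatin_dose(target_auc: float, gfr: float) -> float:
    """Carboplatin dose in mg by the Calvert formula: AUC x (GFR + 25).

    ``target_auc`` in mg/mL-min, ``gfr`` (glomerular filtration rate) in
    mL/min.  A zero AUC is a valid degenerate request; negative inputs or a
    non-positive GFR are domain errors.
    """
    if target_auc < 0:
        raise ValueError("target AUC must be non-negative")
    if gfr <= 0:
        raise ValueError("GFR must be positive")
    return target_auc * (gfr + 25.0)


def body_metric_dose(rate: float, metric: float) -> float:
    """Absolute dose from a per-kg or per-m2 rate and the body metric.

    E.g. nivolumab 3 mg/kg x 70 kg, or 500 mg/m2 x 1.84 m2.
    """
    if rate < 0:
        raise ValueError("dose rate must be non-negative")
    if metric <= 0:
        raise ValueError("body metric must be positive")
    return rate * metric


def histology_blend(p_squamous: float, squamous_value: float, nonsquamous_value: float) -> float:
    """Linear mix of a squamous / non-squamous quantity by histology share."""
    if not 0.0 <= p_squamous <= 1.0:
        raise ValueError("squamous fraction must lie in [0, 1]")
    return p_squamous * squamous_value + (1.0 - p_squamous) * nonsquamous_value


def _drug(params: Mapping, key: str) -> float:
    try:
        return float(params["drug_cost_per_cycle"][key])
    except KeyError as exc:
        raise KeyError(f"unknown regimen {key!r} in drug cost table") from exc


def first_line_drug_cost(arm: str, cycle: int, params: Mapping) -> float:
    """First-line drug acquisition cost charged in a given cycle (USD).

    Respects the per-regimen duration caps: platinum-doublet chemotherapy
    for at most 12 weeks (2 cycles), nivolumab+ipilimumab for at most 2
    years; the combination arm's two 3-week chemotherapy cycles fall
    entirely within model cycle 0.
    """
    if arm not in ARMS:
        raise KeyError(f"unknown strategy {arm!r}")
    caps = params["first_line_caps"]
    p_sq = float(params["squamous_fraction"])
    cost = 0.0
    if arm == "chemotherapy":
        if cycle < int(caps["chemotherapy"]):
            cost += histology_blend(
                p_sq,
                _drug(params, _FIRST_LINE_SQUAMOUS[arm]),
                _drug(params, "pemetrexed_carboplatin"),
            )
    else:
        if cycle < int(caps["nivolumab_ipilimumab"]):
            cost += _drug(params, "nivolumab_ipilimumab")
        if arm == "nivolumab_ipilimumab_chemo" and cycle < 1:
            cost += histology_blend(
                p_sq,
                _drug(params, _FIRST_LINE_SQUAMOUS[arm]),
                _drug(params, "pemetrexed_carboplatin"),
            )
    return cost


def _on_first_line(arm: str, cycle: int, params: Mapping) -> bool:
    caps = params["first_line_caps"]
    if arm == "chemotherapy":
        return cycle < int(caps["chemotherapy"])
    return cycle < int(caps["nivolumab_ipilimumab"])


def pf_state_cost(arm: str, cycle: int, params: Mapping) -> float:
    """Progression-free state cost per cycle: drug + administration (+ BSC
    if configured for the PF state; off by default)."""
    if cycle < 0:
        raise ValueError("cycle index must be non-negative")
    cost = first_line_drug_cost(arm, cycle, params)
    if _on_first_line(arm, cycle, params):
        cost += float(params["admin_cost_per_visit"])
    if params.get("bsc_in_pf", False):
        cost += float(params["bsc_cost_per_cycle"])
    return cost


def validate_second_line_mix(mix: Mapping) -> None:
    total = 0.0
    for key in ("chemo", "immuno", "targeted"):
        p = float(mix[key])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"second-line proportion {key} out of [0, 1]: {p}")
        total += p
    if total > 1.0 + 1e-9:
        raise ValueError(f"second-line proportions sum to {total:.3f} > 1")


def pd_state_cost(arm: str, params: Mapping) -> float:
    """Progressive-disease state cost per cycle (USD).

    Expected second-line drug + administration cost weighted by the
    arm-specific treatment mix and histology, plus best supportive care for
    everyone in PD.  The remainder of the mix (1 - sum) receives BSC only.
    Second-line therapy is modeled as continuing through PD occupancy.
    """
    if arm not in ARMS:
        raise KeyError(f"unknown strategy {arm!r}")
    mix = params["second_line"][arm]
    validate_second_line_mix(mix)
    admin = float(params["admin_cost_per_visit"])
    p_sq = float(params["squamous_fraction"])

    if arm == "chemotherapy":
        chemo_drug = _drug(params, "docetaxel")
    else:
        chemo_drug = histology_blend(
            p_sq,
            _drug(params, "gemcitabine_carboplatin"),
            _drug(params, "pemetrexed_carboplatin"),
        )
    component = {
        "chemo": chemo_drug,
        "immuno": _drug(params, "nivolumab"),
        "targeted": _drug(params, "erlotinib"),
    }
    cost = float(params["bsc_cost_per_cycle"])
    for key, drug_cost in component.items():
        p = float(mix[key])
        cost += p * (drug_cost + (admin if _SECOND_LINE_IV_ADMIN[key] else 0.0))
    return cost


def expected_ae_cost(profile: Mapping, ae_costs: Mapping) -> float:
    """Expected one-time grade 3/4 adverse-event management cost at entry.

    Sum over events of incidence x management cost; every event in the
    profile must have a cost entry.
    """
    total = 0.0
    for event, incidence in profile.items():
        if not 0.0 <= float(incidence) <= 1.0:
            raise ValueError(f"incidence for {event!r} out of [0, 1]")
        if event not in ae_costs:
            raise KeyError(f"no management cost for adverse event {event!r}")
        total += float(incidence) * float(ae_costs[event])
    return total
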