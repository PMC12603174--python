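"""Default parameter set ("fixture") for the extensive-stage SCLC model.

The trial IPD behind the transition hazards and the claims data behind
the cost inputs are both access-restricted, so the package ships a
synthetic parameter set chosen once from clinical anchors for first-line ES-SCLC without baseline brain metastases
(median progression-free survival around 5 months, median overall survival
around 12 months, grade>=3 haematological AE frequencies of the
atezolizumab + carboplatin/etoposide regimen).  The set deliberately lands
the base case in the northeast quadrant of the cost-effectiveness plane
near the willingness-to-pay threshold, which is where this decision
problem lives; it is *not* a reconstruction of the unpublished trial
curves.
"""

from __future__ import annotations

import numpy as np

from .cohort import CostParams, ModelConfig
from .survival import ParametricSurvivalModel, get_family
from .utilities import AE_CATEGORIES, TimeVaryingCurves, UtilityParams

__all__ = [
    "default_survival_truth",
    "default_cost_params",
    "default_utility_params",
    "default_curves",
    "default_model",
]

#: standard error attached to each unconstrained coefficient of the
#: synthetic truth models (stands in for a fit covariance in DSA/PSA)
_TRUTH_SE = 0.05


def _model(family: str, arm: str, tp: str, **natural) -> ParametricSurvivalModel:
    fam = get_family(family)
    if family == "exponential":
        params = [np.log(natural["rate"])]
    elif family in ("weibull", "loglogistic"):
        params = [np.log(natural["shape"]), np.log(natural["scale"])]
    elif family == "gompertz":
        params = [natural["shape"], np.log(natural["rate"])]
    elif family == "lognormal":
        params = [natural["mu"], np.log(natural["sigma"])]
    else:  # gengamma
        params = [natural["mu"], np.log(natural["sigma"]), natural["q"]]
    params = np.asarray(params, dtype=float)
    return ParametricSurvivalModel(
        family=fam,
        params=params,
        vcov=np.eye(len(params)) * _TRUTH_SE**2,
        loglik=0.0,
        n_events=200,
        n_obs=200,
        transition_id=tp,
        arm=arm,
    )


def default_survival_truth() -> dict[str, dict[str, ParametricSurvivalModel]]:
    """True transition hazards per arm (times in years since state entry).

    The intervention arm progresses and dies more slowly on every pathway
    into death, with the largest gap on the progression-free exits —
    matching the qualitative pattern that motivates the comparison.
    """
    return {
        "intervention": {
            "TP1": _model("weibull", "intervention", "TP1", shape=1.30, scale=0.55),
            "TP2": _model("weibull", "intervention", "TP2", shape=1.30, scale=1.80),
            "TP3": _model("exponential", "intervention", "TP3", rate=0.18),
            "TP4": _model("exponential", "intervention", "TP4", rate=0.45),
            "TP5": _model("weibull", "intervention", "TP5", shape=1.10, scale=0.95),
            "TP6": _model("weibull", "intervention", "TP6", shape=1.10, scale=0.60),
        },
        "comparator": {
            "TP1": _model("weibull", "comparator", "TP1", shape=1.30, scale=0.45),
            "TP2": _model("weibull", "comparator", "TP2", shape=1.30, scale=1.55),
            "TP3": _model("exponential", "comparator", "TP3", rate=0.28),
            "TP4": _model("exponential", "comparator", "TP4", rate=0.50),
            "TP5": _model("weibull", "comparator", "TP5", shape=1.10, scale=0.70),
            "TP6": _model("weibull", "comparator", "TP6", shape=1.10, scale=0.52),
        },
    }


def default_cost_params() -> CostParams:
    return CostParams()


def default_utility_params() -> UtilityParams:
    return UtilityParams()


def default_curves(n_cycles: int, cycle_len: float = 21.0 / 365.25) -> TimeVaryingCurves:
    """Deterministic fixture curves consistent with the truth hazards.

    The on-treatment proportion is the survivor function of time to
    treatment stop implied by the truth: progression-free exit hazards
    plus an intolerance rate of 0.3/yr (intervention continues until
    progression or intolerance; the comparator receives drug only during
    the four induction cycles, so its curve is truncated there).  The
    response proportion saturates near the arm's overall response rate;
    AE prevalence scales with the on-treatment proportion.
    """
    truth = default_survival_truth()
    t = np.arange(n_cycles) * cycle_len
    resp = {}
    treat = {}
    ae = {}
    resp_max = {"intervention": 0.60, "comparator": 0.64}
    ae_base = {
        "intervention": {"leukocyte": 0.090, "anemia": 0.055, "platelet": 0.030},
        "comparator": {"leukocyte": 0.080, "anemia": 0.050, "platelet": 0.025},
    }
    for arm in ("intervention", "comparator"):
        H_pf = sum(truth[arm][tp].cumhaz(t) for tp in ("TP1", "TP2", "TP3"))
        on = np.exp(-(H_pf + 0.30 * t))
        if arm == "comparator":
            on = np.where(np.arange(n_cycles) < 4, on, 0.0)
        treat[arm] = np.minimum.accumulate(on)
        resp[arm] = resp_max[arm] * (1.0 - np.exp(-np.arange(n_cycles) / 2.0))
        for cat in AE_CATEGORIES:
            ae[(arm, cat)] = ae_base[arm][cat] * np.exp(-(H_pf + 0.30 * t))
    return TimeVaryingCurves(resp=resp, ae=ae, treat=treat).validate()


def default_model(config: ModelConfig | None = None):
    """Assembled base-case model ready to run (the package's fixture)."""
    from .model import CEAModel

    config = config or ModelConfig()
    n = config.n_cycles
    return CEAModel(
        config=config,
        survival_models=default_survival_truth(),
        utility_params=default_utility_params(),
        curves=default_curves(n, config.cycle_len),
        cost_params=default_cost_params(),
    )
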