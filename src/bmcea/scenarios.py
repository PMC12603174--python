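"""Nine-scenario framework: survival-model choice, horizon, PD utility.

Scenario 1 swaps every transition's survival model for its second-best
fit by AIC/BIC; Scenarios 2 and 3 pick, from each transition's three
lowest-criterion candidates, the family with the most (optimistic) or
least (pessimistic) favourable long-term survival, operationalised as the
largest / smallest model survival at the analysis horizon, applied per
transition and per arm independently.  Scenarios 4-7 change the time
horizon (5, 10, 20, 40 years).  Scenarios 8 and 9 fix both progressed-
disease utilities at a single value (0.7511, the all-participant trial
estimate, and 0.473, the value used by earlier economic evaluations).

Scenario application is a pure transformation: the base model instance is
never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ARMS, CEAModel
from .survival import ModelSelection
from .transitions import TRANSITION_MAP
from .uncertainty import (
    default_parameter_specs,
    evpi,
    prob_cost_effective,
    run_psa,
)

__all__ = ["ScenarioSpec", "default_scenarios", "apply_scenario", "run_all"]


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One alternative-assumption run."""

    id: int
    kind: str  # survival_choice | horizon | pd_utility
    payload: object

    def __post_init__(self):
        if self.kind == "survival_choice" and self.payload not in (
            "second_best",
            "optimistic",
            "pessimistic",
        ):
            raise ScenarioError(f"scenario {self.id}: bad survival_choice payload {self.payload!r}")
        if self.kind == "horizon" and float(self.payload) <= 0:
            raise ScenarioError(f"scenario {self.id}: horizon must be positive")
        if self.kind == "pd_utility" and not -1.0 <= float(self.payload) <= 1.0:
            raise ScenarioError(f"scenario {self.id}: PD utility outside [-1, 1]")
        if self.kind not in ("survival_choice", "horizon", "pd_utility"):
            raise ScenarioError(f"scenario {self.id}: unknown kind {self.kind!r}")


def default_scenarios(horizons=(5.0, 10.0, 20.0, 40.0)) -> list[ScenarioSpec]:
    return [
        ScenarioSpec(1, "survival_choice", "second_best"),
        ScenarioSpec(2, "survival_choice", "optimistic"),
        ScenarioSpec(3, "survival_choice", "pessimistic"),
        *[ScenarioSpec(4 + i, "horizon", h) for i, h in enumerate(horizons)],
        ScenarioSpec(8, "pd_utility", 0.7511),
        ScenarioSpec(9, "pd_utility", 0.473),
    ]


def _pick_by_long_term_survival(selection: ModelSelection, horizon_years: float, best: bool):
    candidates = selection.top3
    s_end = [float(m.sf(horizon_years)) for m in candidates]
    idx = int(np.argmax(s_end)) if best else int(np.argmin(s_end))
    return candidates[idx]


def apply_scenario(
    model: CEAModel,
    spec: ScenarioSpec,
    selections: dict[tuple[str, str], ModelSelection] | None = None,
) -> CEAModel:
    """Return a new model with the scenario's assumption applied.

    ``selections`` maps (arm, transition) to the ranked candidate fits and
    is required for the survival-choice scenarios.
    """
    if spec.kind == "horizon":
        return model.replace(config=model.config.with_horizon(float(spec.payload)))

    if spec.kind == "pd_utility":
        import copy

        util = copy.deepcopy(model.utility_params)
        util.u_pd_nobm = float(spec.payload)
        util.u_pd_bm = float(spec.payload)
        return model.replace(utility_params=util)

    # survival_choice
    if selections is None:
        raise ScenarioError(f"scenario {spec.id} needs ranked fits per (arm, transition)")
    new_models = {}
    for arm in ARMS:
        new_models[arm] = {}
        for tp in TRANSITION_MAP:
            key = (arm, tp)
            if key not in selections:
                raise ScenarioError(f"scenario {spec.id}: no ranked fits for {key}")
            sel = selections[key]
            if spec.payload == "second_best":
                chosen = sel.second_best
            else:
                chosen = _pick_by_long_term_survival(
                    sel, model.config.horizon_years, best=(spec.payload == "optimistic")
                )
            new_models[arm][tp] = chosen
    return model.replace(survival_models=new_models)


def run_all(
    model: CEAModel,
    scenarios: list[ScenarioSpec] | None = None,
    selections: dict[tuple[str, str], ModelSelection] | None = None,
    n_draws: int = 5000,
    seed: int = 1,
    include_base: bool = True,
) -> pd.DataFrame:
    """Complete CEA (deterministic + PSA summary) per scenario.

    Emits one row per scenario with ICER, INMB, P(cost-effective at the
    base WTP) and per-person EVPI.  An empty scenario list yields an
    empty (or base-only) report without error.
    """
    scenarios = default_scenarios() if scenarios is None else scenarios
    rows = []

    def one(label, m: CEAModel):
        res = m.run()
        specs = default_parameter_specs(m)
        matrix = run_psa(m, specs, n_draws=n_draws, seed=seed)
        wtp = m.config.wtp_per_qaly
        ic = res.cea_qaly.icer
        return {
            "scenario": label,
            "delta_cost": res.delta_cost,
            "delta_qaly": res.delta_qaly,
            "ICER": ic if not isinstance(ic, str) else np.nan,
            "dominance": ic if isinstance(ic, str) else "",
            "INMB": res.cea_qaly.inmb,
            "p_cost_effective": prob_cost_effective(matrix, wtp),
            "EVPI": evpi(matrix, wtp),
        }

    if include_base:
        rows.append(one("base", model))
    for spec in scenarios:
        m = apply_scenario(model, spec, selections=selections)
        rows.append(one(f"S{spec.id}", m))
    return pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "delta_cost",
            "delta_qaly",
            "ICER",
            "dominance",
            "INMB",
            "p_cost_effective",
            "EVPI",
        ],
    )
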