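"""Assembled two-strategy cost-effectiveness model.

``CEAModel`` bundles everything one deterministic evaluation needs —
global settings, the six fitted transition models per arm, utility
parameters, time-varying curves, and cost inputs — and exposes a single
``run()`` that builds the transition schedule, assembles rewards, runs the
cohort for both arms and returns the incremental comparison.  Sensitivity
analyses perturb it through a flat named-parameter override interface, so
one-way and probabilistic analyses share the exact same model path as the
base case.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (
    CostParams,
    ModelConfig,
    RewardSchedule,
    build_reward_schedule,
    compare_arms,
    run_cohort,
)
from .metrics import CEAResult, cea_result
from .survival import ParametricSurvivalModel
from .transitions import TRANSITION_MAP, build_schedule, exit_sets_from_models
from .utilities import AE_CATEGORIES, TimeVaryingCurves, UtilityParams

__all__ = ["CEAModel", "ModelRun"]

ARMS = ("intervention", "comparator")


class OverrideError(KeyError):
    """An override key the model does not recognise (no silent typos)."""


@dataclass
class ModelRun:
    """One deterministic evaluation of both strategies."""

    trace_intervention: object
    trace_comparator: object
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    cea_qaly: CEAResult
    cea_ly: CEAResult

    @property
    def per_arm(self) -> dict:
        return {
            "intervention": self.trace_intervention.summary(),
            "comparator": self.trace_comparator.summary(),
        }

    def strategy_costs_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """(costs, QALYs) per strategy, intervention first."""
        return (
            np.array([self.trace_intervention.cost_total, self.trace_comparator.cost_total]),
            np.array([self.trace_intervention.qaly, self.trace_comparator.qaly]),
        )

    def to_dict(self) -> dict:
        return {
            "per_arm": self.per_arm,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "per_qaly": self.cea_qaly.rounded(),
            "per_ly": self.cea_ly.rounded(),
        }


@dataclass
class CEAModel:
    """The four-state brain-metastasis-aware CEA model for one input set."""

    config: ModelConfig
    survival_models: dict[str, dict[str, ParametricSurvivalModel]]
    utility_params: UtilityParams
    curves: TimeVaryingCurves
    cost_params: CostParams

    def __post_init__(self):
        for arm in ARMS:
            if arm not in self.survival_models:
                raise OverrideError(f"survival models missing for arm {arm!r}")
            missing = [tp for tp in TRANSITION_MAP if tp not in self.survival_models[arm]]
            if missing:
                raise OverrideError(f"{arm}: missing transition models {missing}")

    # -- override plumbing --------------------------------------------------
    def _apply_overrides(self, overrides):
        cfg = self.config
        util = copy.deepcopy(self.utility_params)
        costs = copy.deepcopy(self.cost_params)
        surv = {arm: dict(self.survival_models[arm]) for arm in ARMS}
        if not overrides:
            return cfg, util, costs, surv

        for key, value in overrides.items():
            parts = key.split(".")
            if key == "wtp":
                cfg = replace(cfg, wtp_per_qaly=float(value))
            elif key == "discount_rate":
                cfg = replace(cfg, discount_rate_annual=float(value))
            elif key == "horizon_years":
                cfg = replace(cfg, horizon_years=float(value))
            elif parts[0] == "utility" and len(parts) == 2:
                name = parts[1]
                if name.startswith("d_"):
                    cat = name[2:]
                    if cat not in AE_CATEGORIES:
                        raise OverrideError(f"unknown disutility {key!r}")
                    util.disutility[cat] = min(float(value), 0.0)
                elif hasattr(util, name):
                    setattr(util, name, float(value))
                else:
                    raise OverrideError(f"unknown utility parameter {key!r}")
            elif parts[0] == "cost" and len(parts) == 2:
                name = parts[1]
                if name.startswith("ae_"):
                    cat = name[3:]
                    if cat not in costs.ae_cost_per_event:
                        raise OverrideError(f"unknown AE cost {key!r}")
                    costs.ae_cost_per_event[cat] = max(float(value), 0.0)
                elif hasattr(costs, name):
                    setattr(costs, name, float(value))
                else:
                    raise OverrideError(f"unknown cost parameter {key!r}")
            elif parts[0] == "survival" and len(parts) in (3, 4):
                arm, tp = parts[1], parts[2]
                if arm not in surv or tp not in surv[arm]:
                    raise OverrideError(f"unknown survival parameter {key!r}")
                base = surv[arm][tp]
                if len(parts) == 3:
                    surv[arm][tp] = base.with_params(np.asarray(value, dtype=float))
                else:
                    idx = int(parts[3])
                    vec = base.params.copy()
                    if not 0 <= idx < vec.size:
                        raise OverrideError(f"coefficient index out of range in {key!r}")
                    vec[idx] = float(value)
                    surv[arm][tp] = base.with_params(vec)
            else:
                raise OverrideError(f"unknown model parameter {key!r}")
        return cfg, util, costs, surv

    # -- evaluation ----------------------------------------------------------
    def run(self, overrides: dict | None = None) -> ModelRun:
        cfg, util, costs, surv = self._apply_overrides(overrides)
        n = cfg.n_cycles
        traces = {}
        # PD states are reached mid-cycle on average, so their duration
        # clocks start half a cycle in; PF begins exactly at model start.
        offsets = {"PF": 0.0, "PD_noBM": 0.5, "PD_BM": 0.5}
        for arm in ARMS:
            exit_sets = exit_sets_from_models(surv[arm], arm)
            sched = build_schedule(exit_sets, n, cfg.cycle_len, duration_offset=offsets)
            rewards = build_reward_schedule(
                arm,
                n,
                util,
                self.curves,
                costs,
                u_pd_nobm=util.u_pd_nobm,
                u_pd_bm=util.u_pd_bm,
            )
            traces[arm] = run_cohort(cfg, sched, rewards, arm)
        inc = compare_arms(traces["intervention"], traces["comparator"])
        return ModelRun(
            trace_intervention=traces["intervention"],
            trace_comparator=traces["comparator"],
            delta_cost=inc.delta_cost,
            delta_qaly=inc.delta_qaly,
            delta_ly=inc.delta_ly,
            cea_qaly=cea_result(inc.delta_cost, inc.delta_qaly, cfg.wtp_per_qaly),
            cea_ly=cea_result(inc.delta_cost, inc.delta_ly, cfg.wtp_per_qaly),
        )

    # -- convenience ----------------------------------------------------------
    def replace(self, **kwargs) -> "CEAModel":
        """Copy with selected components swapped (pure; base untouched)."""
        return CEAModel(
            config=kwargs.get("config", self.config),
            survival_models=kwargs.get("survival_models", self.survival_models),
            utility_params=kwargs.get("utility_params", self.utility_params),
            curves=kwargs.get("curves", self.curves),
            cost_params=kwargs.get("cost_params", self.cost_params),
        )
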