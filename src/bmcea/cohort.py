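"""Discounted four-state Markov cohort simulation with tunnel states.

The cohort starts fully progression-free and flows along TP1..TP6 only —
no reverse moves.  Because transition hazards are clock-reset (they depend
on time since entering the current state), the two progressed-disease
states are duration-expanded: occupancy is tracked per (state, cycles
since state entry), so the semi-Markov hazards apply exactly.  PF is
entered only at model start, so PF duration equals model time and needs no
expansion.

Rewards (utility per cycle, cost per cycle) accrue per state with an
optional half-cycle correction: occupancy is averaged between cycle start
and cycle end (trapezoid) and discounted at the cycle midpoint.  A one-off
terminal supportive-care cost is charged to the fraction dying each cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .transitions import CycleTransitionSchedule

__all__ = [
    "CYCLE_LENGTH_YEARS",
    "ModelConfig",
    "CostParams",
    "RewardSchedule",
    "CohortTrace",
    "IncrementalResult",
    "run_cohort",
    "compare_arms",
    "build_reward_schedule",
]

#: 21-day cycle expressed in years.
CYCLE_LENGTH_YEARS = 21.0 / 365.25


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Global settings of the cost-effectiveness model.

    Defaults: 3-week cycles, 15-year horizon, 3% annual discount rate on
    both costs and health outcomes, willingness-to-pay of NT$3,023,055 per
    QALY (three times 2023 GDP per capita), half-cycle correction on.
    """

    cycle_len: float = CYCLE_LENGTH_YEARS
    horizon_years: float = 15.0
    discount_rate_annual: float = 0.03
    wtp_per_qaly: float = 3_023_055.0
    half_cycle_correction: bool = True

    def __post_init__(self):
        if self.cycle_len <= 0:
            raise CohortError("cycle_len must be positive")
        if self.horizon_years < self.cycle_len:
            raise CohortError("horizon must cover at least one cycle")
        if self.discount_rate_annual < 0:
            raise CohortError("discount rate must be non-negative")

    @property
    def n_cycles(self) -> int:
        # residual fraction of a final cycle is dropped
        return int(math.floor(self.horizon_years / self.cycle_len + 1e-9))

    def with_horizon(self, horizon_years: float) -> "ModelConfig":
        return replace(self, horizon_years=horizon_years)


@dataclass
class CostParams:
    """Per-cycle cost inputs in 2023 NT$ (point values for non-medication
    items, converted by the NHI point-to-currency factor at load time).

    Medication costs are weighted by the proportion of patients remaining
    on treatment each cycle; chemotherapy is given in the four induction
    cycles in both arms, atezolizumab from cycle 1 until discontinuation in
    the intervention arm only.
    """

    atezolizumab_per_cycle: float = 83_258.0
    chemo_per_cycle: float = 22_000.0
    induction_cycles: int = 4
    ae_cost_per_event: dict[str, float] = field(
        default_factory=lambda: {
            "leukocyte": 35_000.0,
            "anemia": 12_000.0,
            "platelet": 18_000.0,
        }
    )
    nonmed_pf_points_per_cycle: float = 16_000.0
    pd_nobm_med_per_cycle: float = 14_000.0
    pd_bm_med_per_cycle: float = 14_000.0
    nonmed_pd_nobm_points_per_cycle: float = 14_000.0
    nonmed_pd_bm_points_per_cycle: float = 20_000.0
    terminal_care_cost: float = 120_000.0
    conversion_factor: float = 0.9198

    def __post_init__(self):
        for name in (
            "atezolizumab_per_cycle",
            "chemo_per_cycle",
            "nonmed_pf_points_per_cycle",
            "pd_nobm_med_per_cycle",
            "pd_bm_med_per_cycle",
            "nonmed_pd_nobm_points_per_cycle",
            "nonmed_pd_bm_points_per_cycle",
            "terminal_care_cost",
        ):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be non-negative")
        if not 0 < self.conversion_factor <= 1.5:
            raise CohortError("conversion_factor outside a plausible range")


@dataclass
class RewardSchedule:
    """Cycle-resolved utilities and costs for one arm.

    ``utility_pf`` is the response-weighted, adverse-event-adjusted PF
    utility per cycle; PD utilities default to 0.76 (no brain metastases)
    and 0.72 (with brain metastases).  Costs are split into medication
    (PF-state systemic therapy), other PF costs (AE management +
    converted non-medication points), PD-state costs, and a one-off
    terminal supportive-care cost.
    """

    arm: str
    utility_pf: np.ndarray
    utility_pd_nobm: np.ndarray
    utility_pd_bm: np.ndarray
    cost_pf_medication: np.ndarray
    cost_pf_other: np.ndarray
    cost_pd_nobm: np.ndarray
    cost_pd_bm: np.ndarray
    terminal_cost: float = 0.0

    def __post_init__(self):
        n = len(self.utility_pf)
        arrays = {
            "utility_pf": self.utility_pf,
            "utility_pd_nobm": self.utility_pd_nobm,
            "utility_pd_bm": self.utility_pd_bm,
            "cost_pf_medication": self.cost_pf_medication,
            "cost_pf_other": self.cost_pf_other,
            "cost_pd_nobm": self.cost_pd_nobm,
            "cost_pd_bm": self.cost_pd_bm,
        }
        for name, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 0:
                arr = np.full(n, float(arr))
            if arr.shape != (n,):
                raise CohortError(f"{name} must cover all {n} cycles")
            setattr(self, name, arr)
        for name in ("utility_pf", "utility_pd_nobm", "utility_pd_bm"):
            a = getattr(self, name)
            if np.any(a < -1.0) or np.any(a > 1.0):
                raise CohortError(f"{name} outside [-1, 1]")
        for name in ("cost_pf_medication", "cost_pf_other", "cost_pd_nobm", "cost_pd_bm"):
            if np.any(getattr(self, name) < 0):
                raise CohortError(f"{name} must be non-negative")
        if self.terminal_cost < 0:
            raise CohortError("terminal_cost must be non-negative")

    @property
    def n_cycles(self) -> int:
        return len(self.utility_pf)


@dataclass
class CohortTrace:
    """State occupancy and discounted accumulators for one arm."""

    arm: str
    config: ModelConfig
    occupancy: np.ndarray  # (n_cycles+1, 4): PF, PD_noBM, PD_BM, death at cycle starts
    new_deaths: np.ndarray  # (n_cycles,)
    ly: float = 0.0
    qaly: float = 0.0
    cost_total: float = 0.0
    cost_medication: float = 0.0
    cost_pf_other: float = 0.0
    cost_pd: float = 0.0
    cost_terminal: float = 0.0

    def summary(self) -> dict:
        return {
            "arm": self.arm,
            "LY": self.ly,
            "QALY": self.qaly,
            "cost_total": self.cost_total,
            "cost_medication": self.cost_medication,
            "cost_pf_other": self.cost_pf_other,
            "cost_pd_state": self.cost_pd,
            "cost_terminal": self.cost_terminal,
        }


@dataclass
class IncrementalResult:
    """Intervention-minus-comparator discounted differences."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float


def run_cohort(
    config: ModelConfig,
    schedule: CycleTransitionSchedule,
    rewards: RewardSchedule,
    arm: str | None = None,
) -> CohortTrace:
    """Propagate the cohort through the duration-expanded state space.

    The whole cohort starts in PF at duration 0.  Each cycle, occupants of
    PF (duration = cycle index) and of every PD duration layer flow along
    their cause-specific exit probabilities; survivors advance one duration
    step.  Rewards use trapezoidal occupancy and midpoint discounting when
    ``config.half_cycle_correction`` is set, start-of-cycle occupancy and
    discounting otherwise.
    """
    arm = arm or rewards.arm
    n = config.n_cycles
    if schedule.horizon_cycles < n:
        raise CohortError(
            f"schedule covers {schedule.horizon_cycles} cycles < horizon {n}"
        )
    if rewards.n_cycles < n:
        raise CohortError(f"rewards cover {rewards.n_cycles} cycles < horizon {n}")
    if abs(schedule.cycle_len - config.cycle_len) > 1e-12:
        raise CohortError("schedule cycle length differs from config")

    p_pf = {d: schedule.probs["PF"][d] for d in schedule.probs["PF"]}
    s_pf = schedule.stay["PF"]
    p41 = schedule.probs["PD_noBM"]["PD_BM"]
    p51 = schedule.probs["PD_noBM"]["death"]
    s1 = schedule.stay["PD_noBM"]
    p62 = schedule.probs["PD_BM"]["death"]
    s2 = schedule.stay["PD_BM"]
    entry1 = schedule.entry_probs.get("PD_noBM", {})
    entry2 = schedule.entry_probs.get("PD_BM", {})
    e1_pd2_frac = entry1.get("PD_BM", 0.0)
    e1_dead_frac = entry1.get("death", 0.0)
    e2_dead_frac = entry2.get("death", 0.0)
    for origin in schedule.stay:
        if np.any(schedule.stay[origin] < -1e-12):
            raise CohortError(f"schedule rows for {origin} sum to more than 1")

    hcc = config.half_cycle_correction
    c = config.cycle_len
    r = config.discount_rate_annual
    t_reward = (np.arange(n) + (0.5 if hcc else 0.0)) * c
    disc = (1.0 + r) ** (-t_reward)

    pf = 1.0
    pd1 = np.zeros(n + 1)  # duration-indexed occupancy, PD without BM
    pd2 = np.zeros(n + 1)  # PD with BM
    dead = 0.0

    occupancy = np.zeros((n + 1, 4))
    new_deaths = np.zeros(n)
    ly = qaly = 0.0
    cost_med = cost_pf_other = cost_pd = cost_term = 0.0

    pd1_tot = 0.0
    pd2_tot = 0.0
    for k in range(n):
        occupancy[k] = (pf, pd1_tot, pd2_tot, dead)

        # flows out of each state this cycle
        pf_to_pd1 = pf * p_pf["PD_noBM"][k]
        pf_to_pd2 = pf * p_pf["PD_BM"][k]
        pf_to_dead = pf * p_pf["death"][k]
        pd1_act = pd1[: k + 1]
        pd2_act = pd2[: k + 1]
        pd1_stay_vec = pd1_act * s1[: k + 1]
        pd2_stay_vec = pd2_act * s2[: k + 1]
        pd1_stay_tot = float(pd1_stay_vec.sum())
        pd2_stay_tot = float(pd2_stay_vec.sum())
        pd1_to_pd2 = float(pd1_act @ p41[: k + 1])
        pd1_to_dead = pd1_tot - pd1_stay_tot - pd1_to_pd2
        pd2_to_dead = pd2_tot - pd2_stay_tot

        # cohorts reaching a PD state mid-cycle face the entry fraction of
        # that state's exit risk before the boundary (first-order composite
        # transitions; exact to the same order as the duration offset)
        e1 = pf_to_pd1
        e1_to_pd2 = e1 * e1_pd2_frac
        e1_to_dead = e1 * e1_dead_frac
        e1_settle = e1 - e1_to_pd2 - e1_to_dead
        e2 = pf_to_pd2 + pd1_to_pd2 + e1_to_pd2
        e2_to_dead = e2 * e2_dead_frac
        e2_settle = e2 - e2_to_dead

        deaths_k = pf_to_dead + pd1_to_dead + pd2_to_dead + e1_to_dead + e2_to_dead
        new_deaths[k] = deaths_k

        # end-of-cycle occupancy (before re-indexing durations)
        pf_end = pf * s_pf[k]
        pd1_end_tot = pd1_stay_tot + e1_settle
        pd2_end_tot = pd2_stay_tot + e2_settle
        dead_end = dead + deaths_k

        if hcc:
            w_pf = 0.5 * (pf + pf_end)
            w_pd1 = 0.5 * (pd1_tot + pd1_end_tot)
            w_pd2 = 0.5 * (pd2_tot + pd2_end_tot)
            w_alive = 0.5 * ((1.0 - dead) + (1.0 - dead_end))
        else:
            w_pf, w_pd1, w_pd2 = pf, pd1_tot, pd2_tot
            w_alive = 1.0 - dead

        dk = disc[k]
        ly += w_alive * c * dk
        qaly += (
            w_pf * rewards.utility_pf[k]
            + w_pd1 * rewards.utility_pd_nobm[k]
            + w_pd2 * rewards.utility_pd_bm[k]
        ) * c * dk
        cost_med += w_pf * rewards.cost_pf_medication[k] * dk
        cost_pf_other += w_pf * rewards.cost_pf_other[k] * dk
        cost_pd += (w_pd1 * rewards.cost_pd_nobm[k] + w_pd2 * rewards.cost_pd_bm[k]) * dk
        cost_term += deaths_k * rewards.terminal_cost * dk

        # advance durations
        pd1_new = np.zeros(n + 1)
        pd1_new[1 : k + 2] = pd1_stay_vec
        pd1_new[0] = e1_settle
        pd2_new = np.zeros(n + 1)
        pd2_new[1 : k + 2] = pd2_stay_vec
        pd2_new[0] = e2_settle
        pf, pd1, pd2, dead = pf_end, pd1_new, pd2_new, dead_end
        pd1_tot, pd2_tot = pd1_end_tot, pd2_end_tot

        total = pf + pd1_tot + pd2_tot + dead
        if abs(total - 1.0) > 1e-9:
            raise CohortError(f"mass conservation violated at cycle {k}: total={total!r}")

    occupancy[n] = (pf, pd1_tot, pd2_tot, dead)

    return CohortTrace(
        arm=arm,
        config=config,
        occupancy=occupancy,
        new_deaths=new_deaths,
        ly=ly,
        qaly=qaly,
        cost_total=cost_med + cost_pf_other + cost_pd + cost_term,
        cost_medication=cost_med,
        cost_pf_other=cost_pf_other,
        cost_pd=cost_pd,
        cost_terminal=cost_term,
    )


def compare_arms(trace_intervention: CohortTrace, trace_comparator: CohortTrace) -> IncrementalResult:
    """Discounted incremental cost/QALY/LY, intervention minus comparator."""
    if trace_intervention.config.n_cycles != trace_comparator.config.n_cycles:
        raise CohortError("arms were run over different horizons")
    return IncrementalResult(
        delta_cost=trace_intervention.cost_total - trace_comparator.cost_total,
        delta_qaly=trace_intervention.qaly - trace_comparator.qaly,
        delta_ly=trace_intervention.ly - trace_comparator.ly,
    )


def build_reward_schedule(
    arm: str,
    n_cycles: int,
    utility_params,
    curves,
    costs: CostParams,
    u_pd_nobm: float = 0.76,
    u_pd_bm: float = 0.72,
) -> RewardSchedule:
    """Assemble the cycle-wise reward inputs for one arm.

    PF utility per cycle is the response-weighted pre/post utility plus
    prevalence-weighted adverse-event disutilities (see
    :func:`bmcea.utilities.cycle_weighted_pf_utility`).  PF medication cost
    is chemotherapy during induction plus (intervention arm) atezolizumab,
    both weighted by the on-treatment proportion; other PF cost is the
    expected AE-management cost plus converted non-medication points.
    """
    cycles = np.arange(n_cycles)
    rp = curves.response_array(arm, n_cycles)
    u_pf = utility_params.u_pf_pre + (utility_params.u_pf_post - utility_params.u_pf_pre) * rp
    for cat, d in utility_params.disutility.items():
        u_pf = u_pf + d * curves.ae_array(arm, cat, n_cycles)

    on_treat = curves.on_treatment_array(arm, n_cycles)
    med = costs.chemo_per_cycle * (cycles < costs.induction_cycles) * on_treat
    if arm == "intervention":
        med = med + costs.atezolizumab_per_cycle * on_treat

    ae_cost = np.zeros(n_cycles)
    for cat, unit_cost in costs.ae_cost_per_event.items():
        ae_cost += unit_cost * curves.ae_array(arm, cat, n_cycles)
    nonmed_pf = costs.nonmed_pf_points_per_cycle * costs.conversion_factor

    cost_pd1 = (
        costs.pd_nobm_med_per_cycle
        + costs.nonmed_pd_nobm_points_per_cycle * costs.conversion_factor
    )
    cost_pd2 = (
        costs.pd_bm_med_per_cycle
        + costs.nonmed_pd_bm_points_per_cycle * costs.conversion_factor
    )

    return RewardSchedule(
        arm=arm,
        utility_pf=u_pf,
        utility_pd_nobm=np.full(n_cycles, u_pd_nobm),
        utility_pd_bm=np.full(n_cycles, u_pd_bm),
        cost_pf_medication=med,
        cost_pf_other=ae_cost + nonmed_pf,
        cost_pd_nobm=np.full(n_cycles, cost_pd1),
        cost_pd_bm=np.full(n_cycles, cost_pd2),
        terminal_cost=costs.terminal_care_cost,
    )
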