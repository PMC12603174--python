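"""Synthetic individual-patient data with known ground truth.

The real trial IPD (effectiveness, utilities, adverse events) is held by
the sponsor behind a data-sharing platform and the claims-based cost data
is license-restricted, so every estimation step in this package is
exercised on simulated cohorts that emulate the same record layouts: a
six-pathway multistate event history per patient with administrative right
censoring, a longitudinal EQ-5D-3L-scale utility panel driven by response
status and adverse-event (AE) episodes, AE onset/resolution times, and
treatment-discontinuation times.

Multistate trajectories are drawn by total-hazard inversion: for each
state visit the total cumulative hazard over the competing exits is
inverted against a unit-exponential draw (vectorised bisection), and the
exit cause is apportioned by the cause-specific hazard ratios at the event
time.  This is exact for the parametric model class and avoids
latent-failure-time assumptions.  A hazard that plateaus below the target
(e.g. Gompertz with negative shape) simply leaves the patient censored at
the administrative cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .survival import ParametricSurvivalModel, TransitionDataset
from .transitions import STATE_EXITS, TRANSITION_MAP
from .utilities import AE_CATEGORIES, UTILITY_RANGE, UtilityParams

__all__ = ["GeneratorConfig", "SyntheticCohort", "simulate", "to_transition_datasets", "empirical_occupancy"]


class SimulationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Truth parameters for the simulated trial.

    Defaults mirror the study conditions: 201 intervention / 202
    comparator patients, ~2 years of administrative follow-up, response
    and grade>=3 AE frequencies in the range reported for first-line
    atezolizumab + carboplatin/etoposide, and the base-case utility truth.
    """

    n_intervention: int = 201
    n_comparator: int = 202
    #: arm -> {TP1..TP6 -> ParametricSurvivalModel} true hazards
    survival_truth: Mapping[str, Mapping[str, ParametricSurvivalModel]] = None
    admin_censor_years: float = 2.0
    response_prob: dict[str, float] = field(
        default_factory=lambda: {"intervention": 0.60, "comparator": 0.64}
    )
    #: log-normal response-onset time (years): median ~6 weeks
    response_onset_mu: float = -2.1
    response_onset_sigma: float = 0.4
    #: AE episode onset rates per year while on treatment (all grades)
    ae_rates: dict[str, float] = field(
        default_factory=lambda: {"leukocyte": 1.4, "anemia": 0.8, "platelet": 0.5}
    )
    #: log-normal episode duration (years): median ~3 weeks
    ae_duration_mu: float = -2.85
    ae_duration_sigma: float = 0.5
    #: categorical grade distribution per episode (1..4)
    ae_grade_probs: tuple[float, ...] = (0.20, 0.20, 0.45, 0.15)
    #: intolerance hazard (per year) for stopping treatment before progression
    discontinuation_rate: float = 0.30
    utility_truth: UtilityParams = field(default_factory=UtilityParams)
    utility_residual_sd: float = 0.08
    utility_intercept_sd: float = 0.05
    cycle_len: float = 21.0 / 365.25
    seed: int = 20230
    #: switch off the per-patient longitudinal records for large cohorts
    #: used only for state-occupancy checks
    generate_utility_panel: bool = True
    generate_ae_episodes: bool = True

    def __post_init__(self):
        if self.survival_truth is None:
            from .parameters import default_survival_truth

            self.survival_truth = default_survival_truth()
        if self.n_intervention < 2 or self.n_comparator < 2:
            raise SimulationError("need at least 2 patients per arm")
        for v in (*self.ae_rates.values(), self.discontinuation_rate,
                  self.utility_residual_sd, self.utility_intercept_sd):
            if v < 0:
                raise SimulationError("rates and SDs must be non-negative")


@dataclass
class SyntheticCohort:
    """Generated IPD plus the truth that generated it."""

    visits: pd.DataFrame          # one row per state visit
    utility_panel: pd.DataFrame   # one row per patient-cycle in PF
    ae_episodes: pd.DataFrame
    discontinuations: pd.DataFrame
    followup: pd.DataFrame
    ground_truth: dict
    config: GeneratorConfig

    def export_csvs(self, directory):
        import os

        os.makedirs(directory, exist_ok=True)
        self.visits.to_csv(os.path.join(directory, "visits.csv"), index=False)
        self.utility_panel.to_csv(os.path.join(directory, "utility_panel.csv"), index=False)
        self.ae_episodes.to_csv(os.path.join(directory, "ae_episodes.csv"), index=False)
        self.discontinuations.to_csv(
            os.path.join(directory, "discontinuations.csv"), index=False
        )
        self.followup.to_csv(os.path.join(directory, "followup.csv"), index=False)


def _invert_total_hazard(models, E, t_max, iters=70):
    """Solve sum_k H_k(t) = E by bisection on [0, t_max] per element.

    Returns (t, exited) where exited is False when the total hazard at
    t_max stays below the draw (administrative censoring).
    """
    t_max = np.asarray(t_max, dtype=float)
    E = np.asarray(E, dtype=float)

    def H(t):
        return sum(m.cumhaz(t) for m in models)

    exited = H(t_max) >= E
    lo = np.zeros_like(t_max)
    hi = t_max.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = H(mid) < E
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    t = 0.5 * (lo + hi)
    return np.where(exited, t, t_max), exited


def _choose_cause(models, t, rng):
    """Pick the exit cause with probability proportional to h_k(t)."""
    hz = np.stack([m.hazard(t) for m in models])  # (K, n)
    tot = hz.sum(axis=0)
    # degenerate corner (all hazards ~0 at the event time): uniform choice
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, hz / np.where(tot > 0, tot, 1.0), 1.0 / len(models))
    u = rng.random(t.shape)
    cum = np.cumsum(p, axis=0)
    return (u[None, :] >= cum).sum(axis=0).clip(0, len(models) - 1)


def simulate(config: GeneratorConfig) -> SyntheticCohort:
    """Generate one reproducible synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    c = config.cycle_len
    cens = config.admin_censor_years

    visit_rows = []
    panel_rows = []
    episode_rows = []
    disc_rows = []
    fu_rows = []

    pid0 = 0
    for arm, n in (
        ("intervention", config.n_intervention),
        ("comparator", config.n_comparator),
    ):
        truth = config.survival_truth[arm]
        pids = np.arange(pid0, pid0 + n)
        pid0 += n

        # ---- multistate trajectory, wave by wave --------------------------
        # PF visit (everyone, entry at t=0)
        state_entry = {"PF": (pids, np.zeros(n))}
        pf_exit_time = np.full(n, cens)

        for origin in ("PF", "PD_noBM", "PD_BM"):
            if origin not in state_entry:
                continue
            ids, entry = state_entry[origin]
            if ids.size == 0:
                continue
            exits = STATE_EXITS[origin]
            models = [truth[tp] for _, tp in exits]
            remaining = cens - entry
            E = rng.exponential(size=ids.size)
            dt, exited = _invert_total_hazard(models, E, remaining)
            # strictly positive sojourns (bisection can return 0 only if E=0)
            dt = np.maximum(dt, 1e-9)
            cause = _choose_cause(models, np.maximum(dt, 1e-9), rng)

            dests = np.array([dest for dest, _ in exits])
            to_state = np.where(exited, dests[cause], None)
            for i, pid in enumerate(ids):
                visit_rows.append(
                    (
                        int(pid),
                        arm,
                        origin,
                        to_state[i],
                        float(entry[i]),
                        float(entry[i] + dt[i]),
                        bool(exited[i]),
                    )
                )
            if origin == "PF":
                pf_exit_time = entry + dt  # observed PF end for everyone

            # queue next-state entrants
            for dest in ("PD_noBM", "PD_BM"):
                sel = exited & (to_state == dest)
                if np.any(sel):
                    nxt_ids, nxt_entry = state_entry.get(dest, (np.array([], dtype=int), np.array([])))
                    state_entry[dest] = (
                        np.concatenate([nxt_ids, ids[sel]]),
                        np.concatenate([nxt_entry, (entry + dt)[sel]]),
                    )

        # ---- response onset ----------------------------------------------
        responds = rng.random(n) < config.response_prob[arm]
        onset = np.exp(
            rng.normal(config.response_onset_mu, config.response_onset_sigma, size=n)
        )
        resp_time = np.where(responds & (onset < pf_exit_time), onset, np.nan)

        # ---- treatment discontinuation -----------------------------------
        intol = rng.exponential(1.0 / max(config.discontinuation_rate, 1e-12), size=n)
        if arm == "intervention":
            stop = np.minimum(intol, pf_exit_time)  # until progression/intolerance
        else:
            stop = np.minimum(np.minimum(intol, pf_exit_time), 4 * c)  # induction only
        disc_event = (stop < cens - 1e-12).astype(int)
        stop = np.minimum(stop, cens)
        for i, pid in enumerate(pids):
            disc_rows.append((int(pid), arm, float(stop[i]), int(disc_event[i])))
            fu_rows.append((int(pid), arm, float(min(pf_exit_time[i], cens))))

        # ---- AE episodes (Poisson onsets while on treatment) -------------
        for i, pid in enumerate(pids) if config.generate_ae_episodes else ():
            horizon_i = stop[i]
            for cat, rate in config.ae_rates.items():
                t = 0.0
                while True:
                    t += rng.exponential(1.0 / rate) if rate > 0 else np.inf
                    if t >= horizon_i:
                        break
                    dur = np.exp(
                        rng.normal(config.ae_duration_mu, config.ae_duration_sigma)
                    )
                    grade = 1 + rng.choice(4, p=config.ae_grade_probs)
                    episode_rows.append(
                        (int(pid), arm, cat, int(grade), float(t), float(t + dur))
                    )

        # ---- PF utility panel --------------------------------------------
        b = rng.normal(0.0, config.utility_intercept_sd, size=n)
        ut = config.utility_truth
        lo, hi = UTILITY_RANGE
        epi_by_pid: dict[int, list] = {}
        for row in episode_rows:
            if row[1] == arm and row[3] >= 3:
                epi_by_pid.setdefault(row[0], []).append(row)
        for i, pid in enumerate(pids) if config.generate_utility_panel else ():
            end = min(pf_exit_time[i], cens)
            k = 0
            while k * c < end:
                g = k * c
                resp = int(not np.isnan(resp_time[i]) and resp_time[i] <= g)
                ae_flags = {}
                for cat in AE_CATEGORIES:
                    active = any(
                        r[2] == cat and r[4] < g + c and r[5] > g
                        for r in epi_by_pid.get(int(pid), [])
                    )
                    ae_flags[cat] = int(active)
                u = (
                    ut.u_pf_pre
                    + (ut.u_pf_post - ut.u_pf_pre) * resp
                    + sum(ut.disutility[cat] * ae_flags[cat] for cat in AE_CATEGORIES)
                    + b[i]
                    + rng.normal(0.0, config.utility_residual_sd)
                )
                panel_rows.append(
                    (
                        int(pid),
                        arm,
                        k,
                        float(np.clip(u, lo, hi)),
                        resp,
                        *[ae_flags[cat] for cat in AE_CATEGORIES],
                        "PF",
                    )
                )
                k += 1

    visits = pd.DataFrame(
        visit_rows,
        columns=["patient_id", "arm", "state", "to_state", "entry_years", "exit_years", "event"],
    )
    # topology / monotonicity sanity
    if (visits["exit_years"] <= visits["entry_years"]).any():
        raise SimulationError("non-increasing visit times generated")

    panel = pd.DataFrame(
        panel_rows,
        columns=[
            "patient_id",
            "arm",
            "cycle",
            "utility",
            "response",
            *[f"ae_{cat}" for cat in AE_CATEGORIES],
            "state",
        ],
    )
    episodes = pd.DataFrame(
        episode_rows,
        columns=["patient_id", "arm", "category", "grade", "onset_years", "resolution_years"],
    )
    discontinuations = pd.DataFrame(
        disc_rows, columns=["patient_id", "arm", "time_years", "event"]
    )
    followup = pd.DataFrame(fu_rows, columns=["patient_id", "arm", "end_years"])

    truth_record = {
        "survival": {
            arm: {tp: m.natural_params() for tp, m in config.survival_truth[arm].items()}
            for arm in config.survival_truth
        },
        "utility": {
            "u_pf_pre": config.utility_truth.u_pf_pre,
            "u_pf_post": config.utility_truth.u_pf_post,
            "disutility": dict(config.utility_truth.disutility),
        },
        "seed": config.seed,
    }
    return SyntheticCohort(
        visits=visits,
        utility_panel=panel,
        ae_episodes=episodes,
        discontinuations=discontinuations,
        followup=followup,
        ground_truth=truth_record,
        config=config,
    )


def empirical_occupancy(
    cohort: SyntheticCohort, arm: str, n_cycles: int, cycle_len: float
) -> np.ndarray:
    """Observed state-occupancy proportions at cycle starts, (n_cycles, 4)
    over (PF, PD_noBM, PD_BM, death).  Only meaningful when the cohort was
    simulated without administrative censoring inside the window."""
    visits = cohort.visits[cohort.visits["arm"] == arm]
    n_pat = visits["patient_id"].nunique()
    grid = np.arange(n_cycles) * cycle_len
    occ = np.zeros((n_cycles, 4))
    state_ix = {"PF": 0, "PD_noBM": 1, "PD_BM": 2}
    death_time = {}
    for row in visits.itertuples(index=False):
        j = state_ix[row.state]
        occ[:, j] += (grid >= row.entry_years) & (grid < row.exit_years)
        if row.event and row.to_state == "death":
            death_time[row.patient_id] = row.exit_years
    for t in death_time.values():
        occ[:, 3] += grid >= t
    return occ / n_pat


def to_transition_datasets(cohort: SyntheticCohort) -> dict[tuple[str, str], TransitionDataset]:
    """Clock-reset multistate layout: each state visit contributes its
    time-in-state to every competing exit of the origin state — an event
    for the exit taken, a censored record for the others."""
    out_times: dict[tuple[str, str], list] = {}
    out_events: dict[tuple[str, str], list] = {}
    for tp in TRANSITION_MAP:
        for arm in ("intervention", "comparator"):
            out_times[(tp, arm)] = []
            out_events[(tp, arm)] = []

    for row in cohort.visits.itertuples(index=False):
        origin = row.state
        if origin not in STATE_EXITS:
            raise SimulationError(f"visit in non-transient state {origin!r}")
        sojourn = row.exit_years - row.entry_years
        for dest, tp in STATE_EXITS[origin]:
            took = bool(row.event) and row.to_state == dest
            out_times[(tp, row.arm)].append(sojourn)
            out_events[(tp, row.arm)].append(int(took))

    datasets = {}
    for (tp, arm), times in out_times.items():
        if not times:
            continue
        datasets[(tp, arm)] = TransitionDataset(
            times=np.asarray(times),
            events=np.asarray(out_events[(tp, arm)]),
            transition_id=tp,
            arm=arm,
        )
    return datasets
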