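"""Per-cycle transition probabilities from competing cause-specific hazards.

The four-state structure is: progression-free (PF) can move to progressed
disease without brain metastases (PD_noBM, pathway TP1), progressed disease
with brain metastases (PD_BM, TP2), or death (TP3); PD_noBM can move to
PD_BM (TP4) or death (TP5); PD_BM can only move to death (TP6).  Death is
absorbing.

Hazards are clock-reset: they depend on time since entry into the origin
state.  Within a cycle of length ``c`` starting at duration ``u = d*c``
each cause-specific hazard is treated as piecewise constant, so with
cumulative-hazard increments ``dH_k = H_k(u+c) - H_k(u)`` the total exit
probability is ``1 - exp(-sum dH_k)`` apportioned to causes in proportion
to their increments.  This is exact for exponentials and converges to the
continuous-time competing-risks solution as the cycle length shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ParametricSurvivalModel

__all__ = [
    "STATES",
    "STATE_EXITS",
    "TRANSITION_MAP",
    "CompetingExitSet",
    "CycleTransitionSchedule",
    "cycle_probabilities",
    "build_schedule",
    "exit_sets_from_models",
]

STATES = ("PF", "PD_noBM", "PD_BM", "death")

# origin -> ordered (destination, transition id) pairs; death is absorbing
STATE_EXITS: dict[str, tuple[tuple[str, str], ...]] = {
    "PF": (("PD_noBM", "TP1"), ("PD_BM", "TP2"), ("death", "TP3")),
    "PD_noBM": (("PD_BM", "TP4"), ("death", "TP5")),
    "PD_BM": (("death", "TP6"),),
}

TRANSITION_MAP: dict[str, tuple[str, str]] = {
    tp: (origin, dest)
    for origin, exits in STATE_EXITS.items()
    for dest, tp in exits
}


class TransitionError(ValueError):
    pass


class ExtrapolationError(TransitionError):
    """Non-finite cumulative hazard while extrapolating a fitted curve."""


@dataclass
class CompetingExitSet:
    """The competing exits out of one origin state in one arm."""

    origin_state: str
    exits: list[tuple[str, ParametricSurvivalModel]]
    arm: str = "intervention"

    def __post_init__(self):
        if self.origin_state not in STATE_EXITS:
            raise TransitionError(
                f"{self.origin_state!r} is not a transient state ({list(STATE_EXITS)})"
            )
        if not self.exits:
            raise TransitionError(f"{self.origin_state}: exit list must be non-empty")
        dests = [d for d, _ in self.exits]
        if len(set(dests)) != len(dests):
            raise TransitionError(f"{self.origin_state}: duplicate exit destinations")
        allowed = {d for d, _ in STATE_EXITS[self.origin_state]}
        bad = set(dests) - allowed
        if bad:
            raise TransitionError(
                f"{self.origin_state}: destinations {sorted(bad)} violate the "
                f"state topology (allowed: {sorted(allowed)})"
            )


def cycle_probabilities(
    exit_set: CompetingExitSet, d, cycle_len: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exit probabilities for duration index ``d`` (scalar or array).

    Returns ``(p, stay)`` where ``p`` has one row per exit in the order of
    ``exit_set.exits`` (shape ``(n_exits,) + shape(d)``) and ``stay`` is
    ``1 - p.sum(axis=0)``.
    """
    if cycle_len <= 0:
        raise TransitionError("cycle_len must be positive")
    d = np.asarray(d)
    if np.any(d < 0):
        raise TransitionError("duration index must be non-negative")
    u = d * cycle_len

    dH = np.empty((len(exit_set.exits),) + u.shape)
    for k, (dest, model) in enumerate(exit_set.exits):
        inc = model.cumhaz(u + cycle_len) - model.cumhaz(u)
        if not np.all(np.isfinite(inc)):
            bad = ~np.isfinite(np.atleast_1d(inc))
            t_bad = np.atleast_1d(np.broadcast_to(u, bad.shape))[bad]
            raise ExtrapolationError(
                f"non-finite cumulative-hazard increment for "
                f"{exit_set.origin_state}->{dest} ({exit_set.arm}) near "
                f"t={np.atleast_1d(t_bad).flat[0]:.3f}y"
            )
        dH[k] = np.maximum(inc, 0.0)  # guard tiny negative rounding

    total = dH.sum(axis=0)
    p_exit = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, dH / np.where(total > 0, total, 1.0), 0.0)
    p = share * p_exit
    stay = 1.0 - p.sum(axis=0)
    return p, stay


@dataclass
class CycleTransitionSchedule:
    """Per-origin, per-duration exit probabilities for one arm.

    ``probs[origin]`` is a dict ``destination -> array over duration index
    d = 0..horizon_cycles-1``; ``stay[origin]`` is the complementary
    stay-in-state probability.
    """

    arm: str
    cycle_len: float
    horizon_cycles: int
    probs: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    stay: dict[str, np.ndarray] = field(default_factory=dict)
    #: exit probabilities over the initial partial cycle (duration offset)
    #: that a cohort entering the state mid-cycle faces before the next
    #: boundary; empty when no duration offset is used
    entry_probs: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for origin, dests in self.probs.items():
            for dest, arr in dests.items():
                for d, p in enumerate(arr):
                    rows.append((self.arm, origin, d, dest, float(p)))
            for d, s in enumerate(self.stay[origin]):
                rows.append((self.arm, origin, d, origin, float(s)))
        return pd.DataFrame(
            rows, columns=["arm", "origin", "duration_index", "destination", "probability"]
        )


def build_schedule(
    exit_sets: list[CompetingExitSet],
    horizon_cycles: int,
    cycle_len: float,
    duration_offset: dict[str, float] | float = 0.0,
) -> CycleTransitionSchedule:
    """Evaluate every competing exit set over d = 0..horizon_cycles-1.

    ``duration_offset`` (per origin state or global, in cycles) shifts the
    duration grid: an offset of 0.5 evaluates exits over
    [(d+0.5)c, (d+1.5)c], reflecting that a cohort reaching a state during
    a cycle has, at the next cycle boundary, already spent half a cycle
    there on average.  PF is entered exactly at model start and needs no
    offset.
    """
    if horizon_cycles < 1:
        raise TransitionError("horizon_cycles must be >= 1")
    arms = {es.arm for es in exit_sets}
    if len(arms) != 1:
        raise TransitionError("build_schedule expects exit sets from a single arm")
    sched = CycleTransitionSchedule(
        arm=arms.pop(), cycle_len=cycle_len, horizon_cycles=horizon_cycles
    )
    d = np.arange(horizon_cycles)
    for es in exit_sets:
        off = (
            duration_offset.get(es.origin_state, 0.0)
            if isinstance(duration_offset, dict)
            else float(duration_offset)
        )
        p, stay = cycle_probabilities(es, d + off, cycle_len)
        sched.probs[es.origin_state] = {
            dest: p[k] for k, (dest, _) in enumerate(es.exits)
        }
        sched.stay[es.origin_state] = stay
        if off > 0:
            pe, _ = cycle_probabilities(es, np.array(0.0), off * cycle_len)
            sched.entry_probs[es.origin_state] = {
                dest: float(pe[k]) for k, (dest, _) in enumerate(es.exits)
            }
    return sched


def exit_sets_from_models(
    models: dict[str, ParametricSurvivalModel], arm: str
) -> list[CompetingExitSet]:
    """Assemble the three competing exit sets from a TP1..TP6 model dict."""
    missing = [tp for tp in TRANSITION_MAP if tp not in models]
    if missing:
        raise TransitionError(f"missing transition models: {missing}")
    out = []
    for origin, exits in STATE_EXITS.items():
        out.append(
            CompetingExitSet(
                origin_state=origin,
                exits=[(dest, models[tp]) for dest, tp in exits],
                arm=arm,
            )
        )
    return out
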