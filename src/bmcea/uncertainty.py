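"""Decision-uncertainty analysis: one-way DSA, PSA, CEAC and EVPI.

Deterministic sensitivity analysis re-runs the full model at each
parameter's low and high bound (95% confidence bounds for survival
coefficients, +/-25% for the rest, user-supplied regional min/max for the
point-value conversion factor) and orders the tornado by the absolute
incremental-net-monetary-benefit range.

Probabilistic sensitivity analysis draws all parameters jointly —
beta for utilities and proportions (method of moments, SE = 10% of base),
gamma for costs (SE = 25% of base), negated gamma for disutilities, and a
multivariate normal on the unconstrained coefficient scale for each
transition's survival model using its fit covariance — and records the
per-strategy discounted (cost, QALY) pair per draw.  Each parameter has
its own deterministic random substream derived from the master seed, so
adding or removing one parameter does not shuffle the draws of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ARMS, CEAModel

__all__ = [
    "ParameterSpec",
    "PSADrawMatrix",
    "default_parameter_specs",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "evpi",
    "prob_cost_effective",
    "quadrant_shares",
]


class SpecError(ValueError):
    pass


@dataclass
class ParameterSpec:
    """One uncertain model input.

    ``dist`` in {"beta", "gamma", "neg_gamma", "normal", "mvn",
    "degenerate"}; ``base`` is a scalar (vector for "mvn", with ``vcov``
    in ``extra``).  ``low``/``high`` are the deterministic bounds.
    """

    name: str
    base: object
    low: object = None
    high: object = None
    dist: str = "degenerate"
    group: str = "other"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dist not in ("beta", "gamma", "neg_gamma", "normal", "mvn", "degenerate"):
            raise SpecError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist != "mvn":
            b = float(self.base)
            if self.low is not None and self.high is not None:
                if not float(self.low) <= b <= float(self.high):
                    raise SpecError(f"{self.name}: need low <= base <= high")
        else:
            if "vcov" not in self.extra:
                raise SpecError(f"{self.name}: mvn spec needs a vcov")

    # ---- sampling ---------------------------------------------------------
    def _rng(self, master_seed: int) -> np.random.Generator:
        digest = hashlib.sha256(self.name.encode()).digest()
        sub = int.from_bytes(digest[:4], "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([master_seed, sub]))

    def sample(self, n: int, master_seed: int) -> np.ndarray:
        rng = self._rng(master_seed)
        b = self.base
        if self.dist == "degenerate":
            return np.full(n, float(b))
        if self.dist == "beta":
            m = float(b)
            if not 0.0 < m < 1.0:
                return np.full(n, m)  # boundary utilities stay fixed
            sd = self.extra.get("se", 0.10 * m)
            nu = m * (1 - m) / sd**2 - 1.0
            if nu <= 0:
                raise SpecError(f"{self.name}: beta SE too large for mean {m}")
            return rng.beta(m * nu, (1 - m) * nu, size=n)
        if self.dist in ("gamma", "neg_gamma"):
            m = abs(float(b))
            if m == 0:
                return np.zeros(n)
            sd = self.extra.get("se", 0.25 * m)
            shape = (m / sd) ** 2
            draws = rng.gamma(shape, m / shape, size=n)
            return -draws if self.dist == "neg_gamma" else draws
        if self.dist == "normal":
            sd = self.extra.get("se", 0.25 * abs(float(b)))
            return rng.normal(float(b), sd, size=n)
        # mvn
        mean = np.asarray(b, dtype=float)
        vcov = np.asarray(self.extra["vcov"], dtype=float)
        if vcov.shape != (mean.size, mean.size):
            raise SpecError(f"{self.name}: vcov shape mismatch")
        return rng.multivariate_normal(mean, vcov, size=n, method="eigh")


@dataclass
class PSADrawMatrix:
    """Per-draw per-strategy discounted (cost, effect), intervention first."""

    costs: np.ndarray   # (n_draws, 2)
    effects: np.ndarray  # (n_draws, 2)
    seed: int
    parameter_draws: pd.DataFrame | None = None
    strategies: tuple[str, str] = ARMS

    def __post_init__(self):
        self.costs = np.asarray(self.costs, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.costs.shape != self.effects.shape or self.costs.ndim != 2:
            raise SpecError("costs and effects must be (n_draws, n_strategies)")
        if self.costs.shape[0] < 1:
            raise SpecError("PSA needs at least one draw")
        if not (np.all(np.isfinite(self.costs)) and np.all(np.isfinite(self.effects))):
            raise SpecError("non-finite PSA entries")

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs[:, 0] - self.costs[:, 1]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.effects[:, 0] - self.effects[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cost_intervention": self.costs[:, 0],
                "cost_comparator": self.costs[:, 1],
                "effect_intervention": self.effects[:, 0],
                "effect_comparator": self.effects[:, 1],
            }
        )


# ---------------------------------------------------------------------------
# Default parameter specs for a CEAModel
# ---------------------------------------------------------------------------


def default_parameter_specs(
    model: CEAModel,
    conversion_factor_bounds: tuple[float, float] = (0.88, 0.96),
    rel_range: float = 0.25,
) -> list[ParameterSpec]:
    """The standard uncertain-parameter list for a model instance.

    Survival coefficients vary within their 95% CIs (DSA) and jointly as a
    multivariate normal per transition (PSA); the conversion factor uses
    the supplied regional (min, max); everything else varies +/-25%.
    """
    specs: list[ParameterSpec] = []
    up = model.utility_params

    def pm(v):
        lo, hi = v * (1 - rel_range), v * (1 + rel_range)
        return (min(lo, hi), max(lo, hi))

    for name, val in (
        ("utility.u_pf_pre", up.u_pf_pre),
        ("utility.u_pf_post", up.u_pf_post),
        ("utility.u_pd_nobm", up.u_pd_nobm),
        ("utility.u_pd_bm", up.u_pd_bm),
    ):
        lo, hi = pm(val)
        specs.append(
            ParameterSpec(name, val, lo, min(hi, 1.0), dist="beta", group="utility")
        )
    for cat, d in up.disutility.items():
        lo, hi = pm(d)
        specs.append(
            ParameterSpec(f"utility.d_{cat}", d, lo, hi, dist="neg_gamma", group="utility")
        )

    cp = model.cost_params
    for name, val in (
        ("cost.atezolizumab_per_cycle", cp.atezolizumab_per_cycle),
        ("cost.chemo_per_cycle", cp.chemo_per_cycle),
        ("cost.nonmed_pf_points_per_cycle", cp.nonmed_pf_points_per_cycle),
        ("cost.pd_nobm_med_per_cycle", cp.pd_nobm_med_per_cycle),
        ("cost.pd_bm_med_per_cycle", cp.pd_bm_med_per_cycle),
        ("cost.nonmed_pd_nobm_points_per_cycle", cp.nonmed_pd_nobm_points_per_cycle),
        ("cost.nonmed_pd_bm_points_per_cycle", cp.nonmed_pd_bm_points_per_cycle),
        ("cost.terminal_care_cost", cp.terminal_care_cost),
    ):
        lo, hi = pm(val)
        specs.append(ParameterSpec(name, val, lo, hi, dist="gamma", group="cost"))
    for cat, val in cp.ae_cost_per_event.items():
        lo, hi = pm(val)
        specs.append(ParameterSpec(f"cost.ae_{cat}", val, lo, hi, dist="gamma", group="cost"))

    lo, hi = conversion_factor_bounds
    specs.append(
        ParameterSpec(
            "cost.conversion_factor",
            cp.conversion_factor,
            lo,
            hi,
            dist="beta",
            group="proportion",
            extra={"se": 0.10 * cp.conversion_factor},
        )
    )

    for arm in ARMS:
        for tp, m in model.survival_models[arm].items():
            if m.vcov is None or not np.all(np.isfinite(m.vcov)):
                continue
            specs.append(
                ParameterSpec(
                    f"survival.{arm}.{tp}",
                    m.params.copy(),
                    dist="mvn",
                    group="survival",
                    extra={"vcov": m.vcov},
                )
            )
    return specs


# ---------------------------------------------------------------------------
# Deterministic one-way sensitivity analysis
# ---------------------------------------------------------------------------


def _dsa_bounds(spec: ParameterSpec):
    """(low, high) override lists for one spec.

    Scalar specs yield one (key, value) pair per bound; mvn specs yield
    one row per coefficient, each varied +/-1.96 SE with the others held
    at base (rows are generated by the caller)."""
    return float(spec.low), float(spec.high)


def one_way_dsa(model: CEAModel, specs: list[ParameterSpec], wtp: float | None = None) -> pd.DataFrame:
    """Tornado table: each row is two full model runs (low/high bound),
    sorted by descending |INMB_high - INMB_low|.  A model failure at a
    bound flags the row rather than dropping it."""
    wtp = wtp if wtp is not None else model.config.wtp_per_qaly
    rows = []

    def run_at(key, value):
        res = model.run({key: value})
        ic = res.cea_qaly.icer
        # INMB at the run's own WTP so that varying the threshold itself
        # registers; for every other parameter this equals the base WTP
        return (ic if not isinstance(ic, str) else np.nan, res.cea_qaly.inmb)

    expanded: list[tuple[str, float, float]] = []
    for spec in specs:
        if spec.dist == "mvn":
            base = np.asarray(spec.base, dtype=float)
            se = np.sqrt(np.diag(np.asarray(spec.extra["vcov"], dtype=float)))
            for i in range(base.size):
                expanded.append(
                    (f"{spec.name}.{i}", base[i] - 1.96 * se[i], base[i] + 1.96 * se[i])
                )
        else:
            lo, hi = _dsa_bounds(spec)
            expanded.append((spec.name, lo, hi))

    for key, lo, hi in expanded:
        row = {"parameter": key, "low": lo, "high": hi, "failed": False}
        try:
            row["ICER_low"], row["INMB_low"] = run_at(key, lo)
            row["ICER_high"], row["INMB_high"] = run_at(key, hi)
            row["INMB_range"] = abs(row["INMB_high"] - row["INMB_low"])
        except Exception as exc:  # noqa: BLE001 - flagged, not dropped
            row.update(
                ICER_low=np.nan, ICER_high=np.nan, INMB_low=np.nan,
                INMB_high=np.nan, INMB_range=np.nan, failed=True, error=str(exc),
            )
        rows.append(row)

    df = pd.DataFrame(rows)
    return df.sort_values("INMB_range", ascending=False, na_position="last").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def run_psa(
    model: CEAModel,
    specs: list[ParameterSpec],
    n_draws: int = 5000,
    seed: int = 1,
    record_draws: bool = False,
) -> PSADrawMatrix:
    """Joint Monte-Carlo propagation of all parameter specs."""
    if n_draws < 1:
        raise SpecError("n_draws must be >= 1")
    # sample every parameter up front (validates hyperparameters first)
    samples: dict[str, np.ndarray] = {s.name: s.sample(n_draws, seed) for s in specs}

    costs = np.empty((n_draws, 2))
    effects = np.empty((n_draws, 2))
    for i in range(n_draws):
        overrides = {}
        for s in specs:
            v = samples[s.name][i]
            overrides[s.name] = np.asarray(v) if s.dist == "mvn" else float(v)
        res = model.run(overrides)
        c, e = res.strategy_costs_effects()
        costs[i] = c
        effects[i] = e

    record = None
    if record_draws:
        cols = {}
        for s in specs:
            if s.dist == "mvn":
                for j in range(np.asarray(s.base).size):
                    cols[f"{s.name}.{j}"] = samples[s.name][:, j]
            else:
                cols[s.name] = samples[s.name]
        record = pd.DataFrame(cols)
    return PSADrawMatrix(costs=costs, effects=effects, seed=seed, parameter_draws=record)


def ceac(matrix: PSADrawMatrix, wtp_grid) -> pd.DataFrame:
    """P(intervention cost-effective) = P(λ·ΔE − ΔC > 0) along a WTP grid."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise SpecError("empty WTP grid")
    de, dc = matrix.delta_effect, matrix.delta_cost
    prob = [(float(np.mean(l * de - dc > 0))) for l in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "p_cost_effective": prob})


def prob_cost_effective(matrix: PSADrawMatrix, wtp: float) -> float:
    return float(np.mean(wtp * matrix.delta_effect - matrix.delta_cost > 0))


def quadrant_shares(matrix: PSADrawMatrix) -> dict[str, float]:
    de, dc = matrix.delta_effect, matrix.delta_cost
    return {
        "NE": float(np.mean((de >= 0) & (dc >= 0))),
        "SE": float(np.mean((de >= 0) & (dc < 0))),
        "NW": float(np.mean((de < 0) & (dc >= 0))),
        "SW": float(np.mean((de < 0) & (dc < 0))),
    }


def evpi(matrix: PSADrawMatrix, wtp: float) -> float:
    """Per-person expected value of perfect information at WTP λ:

        EVPI = E[max_s NMB_s] − max_s E[NMB_s]  >= 0.
    """
    nmb = wtp * matrix.effects - matrix.costs  # (n_draws, n_strategies)
    return float(np.mean(np.max(nmb, axis=1)) - np.max(np.mean(nmb, axis=0)))
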