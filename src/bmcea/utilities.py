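"""Health-state utility estimation and cycle-wise reward curves.

The progression-free (PF) utility is not constant: it improves after a
treatment response and is depressed while a grade>=3 adverse event (AE)
episode is active.  A linear generalized-estimating-equations (GEE) model

    utility ~ 1 + response + ae_leukocyte + ae_anemia + ae_platelet

with patient-level clustering and an exchangeable working correlation
separates the pre-response PF utility (intercept), the response gain, and
the per-category AE disutilities; cluster-robust (sandwich) standard
errors account for repeated measures.

The fitted coefficients are combined with three time-varying curves —
per-cycle response proportion, AE prevalence per category, and the
proportion of patients remaining on treatment — to produce the weighted
PF utility and the medication-cost weights consumed by the cohort model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AE_CATEGORIES",
    "UtilityParams",
    "TimeVaryingCurves",
    "GEEUtilityFit",
    "fit_gee",
    "cycle_weighted_pf_utility",
    "curves_from_ipd",
]

#: AE categories modelled (grade >= 3, incidence > 2%): leukocyte
#: deficiencies, anemia, platelet deficiencies.
AE_CATEGORIES = ("leukocyte", "anemia", "platelet")

#: EQ-5D-3L value-set range for the utility scale.
UTILITY_RANGE = (-0.594, 1.0)


class UtilityError(ValueError):
    pass


@dataclass
class UtilityParams:
    """Utility and disutility inputs on the EQ-5D-3L scale.

    Base values: PF 0.74 before / 0.81 after treatment response; PD 0.76
    without and 0.72 with brain metastases; AE disutilities -0.0005
    (leukocyte), -0.0124 (anemia), -0.0692 (platelet).
    """

    u_pf_pre: float = 0.74
    u_pf_post: float = 0.81
    u_pd_nobm: float = 0.76
    u_pd_bm: float = 0.72
    disutility: dict[str, float] = field(
        default_factory=lambda: {
            "leukocyte": -0.0005,
            "anemia": -0.0124,
            "platelet": -0.0692,
        }
    )

    def __post_init__(self):
        lo, hi = UTILITY_RANGE
        for name in ("u_pf_pre", "u_pf_post", "u_pd_nobm", "u_pd_bm"):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise UtilityError(f"{name}={v} outside the 3L value range [{lo}, {hi}]")
        for cat, d in self.disutility.items():
            if d > 0:
                raise UtilityError(f"disutility[{cat}]={d} must be <= 0")


@dataclass
class TimeVaryingCurves:
    """Per-cycle response proportion, AE prevalence, on-treatment proportion.

    Arrays are indexed by cycle; queries beyond the stored range hold the
    last value (response, AE prevalence) or return the configured tail for
    the on-treatment curve (0 by default: nobody remains on treatment
    after the last observed discontinuation-risk interval).
    """

    resp: dict[str, np.ndarray]
    ae: dict[tuple[str, str], np.ndarray]
    treat: dict[str, np.ndarray]
    on_treat_tail: float = 0.0

    def _tail(self, arr: np.ndarray, cycle: int, tail=None):
        if cycle < len(arr):
            return float(arr[cycle])
        return float(arr[-1]) if tail is None else float(tail)

    def response_proportion(self, arm: str, cycle: int) -> float:
        return self._tail(self.resp[arm], cycle)

    def ae_prevalence(self, arm: str, cycle: int, category: str) -> float:
        return self._tail(self.ae[(arm, category)], cycle)

    def on_treatment(self, arm: str, cycle: int) -> float:
        return self._tail(self.treat[arm], cycle, tail=self.on_treat_tail)

    # vectorised accessors (tail-padded to n cycles)
    def _pad(self, arr: np.ndarray, n: int, tail=None) -> np.ndarray:
        if n <= len(arr):
            return np.asarray(arr[:n], dtype=float)
        fill = float(arr[-1]) if tail is None else float(tail)
        return np.concatenate([arr, np.full(n - len(arr), fill)])

    def response_array(self, arm: str, n: int) -> np.ndarray:
        return self._pad(self.resp[arm], n)

    def ae_array(self, arm: str, category: str, n: int) -> np.ndarray:
        return self._pad(self.ae[(arm, category)], n)

    def on_treatment_array(self, arm: str, n: int) -> np.ndarray:
        return self._pad(self.treat[arm], n, tail=self.on_treat_tail)

    def validate(self):
        for arm, a in self.resp.items():
            if np.any((a < 0) | (a > 1)):
                raise UtilityError(f"response proportion outside [0,1] for {arm}")
        for key, a in self.ae.items():
            if np.any((a < 0) | (a > 1)):
                raise UtilityError(f"AE prevalence outside [0,1] for {key}")
        for arm, a in self.treat.items():
            if np.any((a < 0) | (a > 1)):
                raise UtilityError(f"on-treatment proportion outside [0,1] for {arm}")
            if np.any(np.diff(a) > 1e-9):
                raise UtilityError(f"on-treatment proportion must be non-increasing ({arm})")
        return self

    def to_frame(self, arm: str) -> pd.DataFrame:
        n = len(self.resp[arm])
        return pd.DataFrame(
            {
                "cycle": np.arange(n),
                "response_proportion": self.resp[arm],
                "on_treatment": self.treat[arm][:n],
                **{
                    f"ae_prev_{c}": self.ae[(arm, c)][:n] for c in AE_CATEGORIES
                },
            }
        )


@dataclass
class GEEUtilityFit:
    """GEE estimates of PF utility components with robust inference."""

    params: UtilityParams
    coef: pd.Series
    robust_se: pd.Series
    conf_int: pd.DataFrame
    working_correlation: str
    n_patients: int
    n_obs: int


def fit_gee(
    panel: pd.DataFrame,
    working_correlation: str = "exchangeable",
    pd_utilities: tuple[float, float] = (0.76, 0.72),
) -> GEEUtilityFit:
    """Fit the PF-utility GEE on a longitudinal utility panel.

    ``panel`` needs columns ``patient_id, cycle, utility, response`` and
    one 0/1 indicator per AE category (``ae_leukocyte`` ...); a ``state``
    column, if present, restricts the fit to PF records.  The mean model
    is linear with identity link; the working correlation may be
    ``"exchangeable"`` or ``"independence"``.
    """
    import statsmodels.api as sm

    df = panel.copy()
    if "state" in df.columns:
        df = df[df["state"] == "PF"]
    ae_cols = [f"ae_{c}" for c in AE_CATEGORIES]
    required = ["patient_id", "utility", "response", *ae_cols]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise UtilityError(f"utility panel missing column(s): {missing}")
    if df["patient_id"].nunique() < 2:
        raise UtilityError("GEE needs at least 2 patients (clusters)")

    X = sm.add_constant(df[["response", *ae_cols]].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy())
            == np.linalg.matrix_rank(X.to_numpy())
        ]
        raise UtilityError(f"design matrix rank-deficient; collinear columns: {collinear}")

    cov = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }
    if working_correlation not in cov:
        raise UtilityError(
            f"working_correlation must be one of {sorted(cov)}, got {working_correlation!r}"
        )
    model = sm.GEE(
        df["utility"].astype(float),
        X,
        groups=df["patient_id"],
        family=sm.families.Gaussian(),
        cov_struct=cov[working_correlation](),
    )
    res = model.fit()

    coef = res.params
    u_pre = float(coef["const"])
    u_post = float(coef["const"] + coef["response"])
    lo, hi = UTILITY_RANGE
    params = UtilityParams(
        u_pf_pre=float(np.clip(u_pre, lo, hi)),
        u_pf_post=float(np.clip(u_post, lo, hi)),
        u_pd_nobm=pd_utilities[0],
        u_pd_bm=pd_utilities[1],
        disutility={c: min(float(coef[f"ae_{c}"]), 0.0) for c in AE_CATEGORIES},
    )
    return GEEUtilityFit(
        params=params,
        coef=coef,
        robust_se=res.bse,
        conf_int=res.conf_int(),
        working_correlation=working_correlation,
        n_patients=int(df["patient_id"].nunique()),
        n_obs=int(len(df)),
    )


def cycle_weighted_pf_utility(
    params: UtilityParams, curves: TimeVaryingCurves, arm: str, cycle: int
) -> float:
    """Response-weighted, AE-adjusted PF utility for one cycle:

        u = u_pre + (u_post - u_pre) * respProp + sum_c aePrev_c * d_c
    """
    rp = curves.response_proportion(arm, cycle)
    u = params.u_pf_pre + (params.u_pf_post - params.u_pf_pre) * rp
    for cat in AE_CATEGORIES:
        u += curves.ae_prevalence(arm, cycle, cat) * params.disutility.get(cat, 0.0)
    return u


# ---------------------------------------------------------------------------
# Curves from individual patient data
# ---------------------------------------------------------------------------


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of possibly overlapping [onset, resolution] intervals."""
    iv = sorted(iv)
    out: list[tuple[float, float]] = []
    for a, b in iv:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def curves_from_ipd(
    episodes: pd.DataFrame,
    responses: pd.DataFrame,
    discontinuations: pd.DataFrame,
    followup: pd.DataFrame,
    n_cycles: int,
    cycle_len: float,
    min_grade: int = 3,
    min_incidence: float = 0.02,
    on_treat_tail: float = 0.0,
) -> TimeVaryingCurves:
    """Build the three time-varying curves from event-level patient records.

    - ``episodes``: patient_id, arm, category, grade, onset_years,
      resolution_years.  Episodes below ``min_grade`` or in categories with
      incidence <= ``min_incidence`` are dropped; overlapping episodes of
      one patient-category are merged so prevalence never double counts.
    - ``responses``: patient_id, arm, response_time_years (NaN = none).
    - ``discontinuations``: patient_id, arm, time_years, event (1 =
      discontinued, 0 = administratively censored); the on-treatment curve
      is the Kaplan-Meier survivor of time to discontinuation.
    - ``followup``: patient_id, arm, end_years — observation window used
      for the at-risk denominators.
    """
    if (episodes["resolution_years"] < episodes["onset_years"]).any():
        raise UtilityError("AE episode resolution precedes onset")
    if (episodes["onset_years"] < 0).any():
        raise UtilityError("AE episode onset times must be non-negative")

    from lifelines import KaplanMeierFitter

    arms = sorted(followup["arm"].unique())
    grid = np.arange(n_cycles) * cycle_len

    resp: dict[str, np.ndarray] = {}
    ae: dict[tuple[str, str], np.ndarray] = {}
    treat: dict[str, np.ndarray] = {}

    epi = episodes[episodes["grade"] >= min_grade]

    for arm in arms:
        fu = followup[followup["arm"] == arm].set_index("patient_id")["end_years"]
        n_arm = len(fu)
        if n_arm == 0:
            raise UtilityError(f"no follow-up records for arm {arm!r}")
        # at-risk count per cycle: patients whose observation covers the cycle start
        at_risk = (fu.to_numpy()[None, :] > grid[:, None]).sum(axis=1).astype(float)
        at_risk = np.maximum(at_risk, 1.0)

        # response proportion among at-risk patients past their response onset
        r = responses[responses["arm"] == arm].set_index("patient_id")["response_time_years"]
        r = r.reindex(fu.index)
        resp_counts = np.zeros(n_cycles)
        for pid, end in fu.items():
            rt = r.get(pid, np.nan)
            if pd.isna(rt):
                continue
            mask = (grid >= rt) & (grid < end)
            resp_counts += mask
        resp[arm] = resp_counts / at_risk

        # AE prevalence per category, incidence filter on the arm level
        epi_arm = epi[epi["arm"] == arm]
        for cat in AE_CATEGORIES:
            sub = epi_arm[epi_arm["category"] == cat]
            incidence = sub["patient_id"].nunique() / n_arm
            prev = np.zeros(n_cycles)
            if incidence > min_incidence:
                for pid, grp in sub.groupby("patient_id"):
                    end = fu.get(pid, 0.0)
                    merged = _merge_intervals(
                        list(zip(grp["onset_years"], grp["resolution_years"]))
                    )
                    active = np.zeros(n_cycles, dtype=bool)
                    for a, b in merged:
                        # episode overlaps cycle [g, g+cycle_len)
                        active |= (a < grid + cycle_len) & (b > grid)
                    active &= grid < end
                    prev += active
            ae[(arm, cat)] = prev / at_risk

        # on-treatment proportion: product-limit estimate of discontinuation
        dc = discontinuations[discontinuations["arm"] == arm]
        km = KaplanMeierFitter()
        km.fit(dc["time_years"], event_observed=dc["event"])
        surv = km.survival_function_at_times(grid).to_numpy()
        last_risk = float(dc["time_years"].max())
        surv = np.where(grid <= last_risk, surv, on_treat_tail)
        treat[arm] = np.minimum.accumulate(surv)

    return TimeVaryingCurves(resp=resp, ae=ae, treat=treat, on_treat_tail=on_treat_tail).validate()
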