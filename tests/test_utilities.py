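"""GEE utility estimation and time-varying reward curves."""

import numpy as np
import pandas as pd
import pytest

from bmcea.utilities import (
    AE_CATEGORIES,
    TimeVaryingCurves,
    UtilityError,
    UtilityParams,
    curves_from_ipd,
    cycle_weighted_pf_utility,
    fit_gee,
)


def _curves(resp, prev_platelet=0.0):
    n = 10
    return TimeVaryingCurves(
        resp={"intervention": np.full(n, resp)},
        ae={
            ("intervention", "leukocyte"): np.zeros(n),
            ("intervention", "anemia"): np.zeros(n),
            ("intervention", "platelet"): np.full(n, prev_platelet),
        },
        treat={"intervention": np.ones(n)},
    )


@pytest.mark.parametrize(
    "resp,prev,expected",
    [
        (0.0, 0.0, 0.74),
        (1.0, 0.0, 0.81),
        (0.5, 0.1, 0.775 - 0.00692),
    ],
)
def test_cycle_weighted_pf_utility(resp, prev, expected):
    u = cycle_weighted_pf_utility(UtilityParams(), _curves(resp, prev), "intervention", 3)
    assert u == pytest.approx(expected, abs=1e-12)


def test_weighted_utility_monotonicity():
    p = UtilityParams()
    u_lo = cycle_weighted_pf_utility(p, _curves(0.2), "intervention", 0)
    u_hi = cycle_weighted_pf_utility(p, _curves(0.8), "intervention", 0)
    assert u_hi > u_lo  # increasing in response share when post > pre
    u_ae = cycle_weighted_pf_utility(p, _curves(0.2, 0.3), "intervention", 0)
    assert u_ae < u_lo  # decreasing in AE prevalence


def test_utility_params_validation():
    with pytest.raises(UtilityError):
        UtilityParams(u_pf_pre=1.2)
    with pytest.raises(UtilityError):
        UtilityParams(disutility={"leukocyte": 0.1, "anemia": -0.01, "platelet": -0.07})


def _panel(rng, n_pat=50, cycles=4, sd=0.05, intercept_sd=0.0):
    rows = []
    truth = UtilityParams()
    for pid in range(n_pat):
        b = rng.normal(0, intercept_sd)
        for k in range(cycles):
            resp = int(k >= cycles // 2 and pid % 2 == 0)
            ae = {c: int(rng.random() < 0.15) for c in AE_CATEGORIES}
            u = (
                truth.u_pf_pre
                + 0.07 * resp
                + sum(truth.disutility[c] * ae[c] for c in AE_CATEGORIES)
                + b
                + rng.normal(0, sd)
            )
            rows.append((pid, k, u, resp, *ae.values(), "PF"))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "cycle", "utility", "response",
                 *[f"ae_{c}" for c in AE_CATEGORIES], "state"],
    )


def test_gee_equals_ols_with_single_record_clusters(rng):
    import statsmodels.api as sm

    panel = _panel(rng, n_pat=120, cycles=1)
    fit = fit_gee(panel, working_correlation="independence")
    X = sm.add_constant(panel[["response", *[f"ae_{c}" for c in AE_CATEGORIES]]].astype(float))
    ols = sm.OLS(panel["utility"], X).fit()
    assert np.allclose(fit.coef.to_numpy(), ols.params.to_numpy(), atol=1e-8)


def test_working_correlations_agree_on_noise_free_data(rng):
    panel = _panel(rng, n_pat=40, cycles=3, sd=0.0)
    f_ex = fit_gee(panel, working_correlation="exchangeable")
    f_in = fit_gee(panel, working_correlation="independence")
    assert np.allclose(f_ex.coef.to_numpy(), f_in.coef.to_numpy(), atol=1e-8)


def test_gee_rank_deficiency_named():
    rng = np.random.default_rng(0)
    panel = _panel(rng, n_pat=30, cycles=2)
    panel["ae_anemia"] = panel["ae_leukocyte"]  # perfectly collinear
    with pytest.raises(UtilityError, match="ae_"):
        fit_gee(panel)


def test_gee_needs_clusters():
    rng = np.random.default_rng(0)
    panel = _panel(rng, n_pat=1, cycles=4)
    with pytest.raises(UtilityError):
        fit_gee(panel)


def test_bad_working_correlation_rejected(rng):
    with pytest.raises(UtilityError, match="working_correlation"):
        fit_gee(_panel(rng), working_correlation="toeplitz")


# ---------------------------------------------------------------------------
# curves_from_ipd
# ---------------------------------------------------------------------------

CYCLE = 21.0 / 365.25


def _ipd_frames(n_cycles=8):
    episodes = pd.DataFrame(
        {
            "patient_id": [1],
            "arm": ["intervention"],
            "category": ["anemia"],
            "grade": [3],
            "onset_years": [2 * CYCLE + 0.001],
            "resolution_years": [5 * CYCLE - 0.001],
        }
    )
    responses = pd.DataFrame(
        {"patient_id": [1], "arm": ["intervention"], "response_time_years": [np.nan]}
    )
    disc = pd.DataFrame(
        {"patient_id": [1], "arm": ["intervention"], "time_years": [n_cycles * CYCLE], "event": [0]}
    )
    fu = pd.DataFrame(
        {"patient_id": [1], "arm": ["intervention"], "end_years": [n_cycles * CYCLE]}
    )
    return episodes, responses, disc, fu


def test_single_patient_ae_prevalence_window():
    """An episode active over cycles 2-4 gives prevalence 1 there, 0 elsewhere."""
    episodes, responses, disc, fu = _ipd_frames()
    curves = curves_from_ipd(
        episodes, responses, disc, fu, n_cycles=8, cycle_len=CYCLE, min_incidence=0.0
    )
    prev = curves.ae[("intervention", "anemia")]
    assert np.allclose(prev[2:5], 1.0)
    assert np.allclose(np.delete(prev, [2, 3, 4]), 0.0)
    # no discontinuation events: everyone stays on treatment
    assert np.allclose(curves.treat["intervention"], 1.0)


def test_incidence_filter_drops_rare_categories():
    episodes, responses, disc, fu = _ipd_frames()
    # 1 of 1 patients affected = 100% incidence; raise the bar above it
    curves = curves_from_ipd(
        episodes, responses, disc, fu, n_cycles=8, cycle_len=CYCLE, min_incidence=1.5
    )
    assert np.allclose(curves.ae[("intervention", "anemia")], 0.0)


def test_overlapping_episodes_merged():
    episodes, responses, disc, fu = _ipd_frames()
    dup = episodes.copy()
    dup.loc[0, "onset_years"] = 3 * CYCLE
    dup.loc[0, "resolution_years"] = 6 * CYCLE - 0.001
    episodes = pd.concat([episodes, dup], ignore_index=True)
    curves = curves_from_ipd(
        episodes, responses, disc, fu, n_cycles=8, cycle_len=CYCLE, min_incidence=0.0
    )
    prev = curves.ae[("intervention", "anemia")]
    assert prev.max() == pytest.approx(1.0)  # never double counted


def test_bad_episode_times_rejected():
    episodes, responses, disc, fu = _ipd_frames()
    episodes.loc[0, "resolution_years"] = 0.0
    with pytest.raises(UtilityError):
        curves_from_ipd(episodes, responses, disc, fu, n_cycles=8, cycle_len=CYCLE)


def test_curves_from_simulated_cohort(trial_cohort):
    """Curves built from generated IPD track the generating process."""
    cfg = trial_cohort.config
    n_cycles = 20
    curves = curves_from_ipd(
        trial_cohort.ae_episodes,
        pd.DataFrame(
            {
                "patient_id": trial_cohort.followup["patient_id"],
                "arm": trial_cohort.followup["arm"],
                "response_time_years": np.nan,
            }
        ),
        trial_cohort.discontinuations,
        trial_cohort.followup,
        n_cycles=n_cycles,
        cycle_len=cfg.cycle_len,
    )
    curves.validate()
    # on-treatment curve starts at ~1 and declines
    for arm in ("intervention", "comparator"):
        t = curves.treat[arm]
        assert t[0] > 0.9
        assert t[-1] < t[0]
    # leukocyte episodes are the most frequent truth category, so their
    # early-cycle prevalence should clearly exceed the platelet one
    lk = curves.ae[("intervention", "leukocyte")][:6].mean()
    pl = curves.ae[("intervention", "platelet")][:6].mean()
    assert lk > pl


def test_on_treatment_tail_configurable():
    episodes, responses, disc, fu = _ipd_frames()
    disc["event"] = [1]
    disc["time_years"] = [2 * CYCLE]
    curves = curves_from_ipd(
        episodes, responses, disc, fu, n_cycles=8, cycle_len=CYCLE, min_incidence=0.0
    )
    # all patients discontinue by the last risk time; tail defaults to 0
    assert curves.treat["intervention"][-1] == 0.0
    assert curves.on_treatment("intervention", 100) == 0.0
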