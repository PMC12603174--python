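"""Parametric family definitions, MLE fitting and AIC/BIC selection."""

import math

import numpy as np
import pytest

from bmcea.survival import (
    FAMILIES,
    FAMILY_ORDER,
    DegenerateFitError,
    ParametricSurvivalModel,
    SurvivalError,
    TransitionDataset,
    fit_mle,
    get_family,
    models_from_json,
    models_to_json,
    select_model,
)

GRID = np.linspace(0.0, 5.0, 41)

# representative unconstrained parameter vectors per family
PARAM_SETS = {
    "exponential": [[0.0], [0.7], [-1.2]],
    "weibull": [[0.0, 0.0], [0.5, -0.7], [-0.4, 0.3]],
    "gompertz": [[0.5, 0.0], [-0.8, 0.2], [0.0, -1.0]],
    "loglogistic": [[0.3, 0.0], [0.8, -0.5], [-0.2, 0.4]],
    "lognormal": [[0.0, 0.0], [-1.0, -0.5], [0.5, 0.3]],
    "gengamma": [[0.0, 0.0, 1.0], [-0.5, -0.3, 0.01], [0.2, 0.1, -0.8]],
}


def _model(family, params):
    return ParametricSurvivalModel(family=get_family(family), params=np.asarray(params, float))


@pytest.mark.parametrize(
    "family,params",
    [(f, p) for f, ps in PARAM_SETS.items() for p in ps],
    ids=lambda v: str(v),
)
def test_family_identities(family, params):
    """S(0)=1, S non-increasing, H = -log S, f = h*S on a grid."""
    m = _model(family, params)
    S = m.sf(GRID)
    assert S[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(S) <= 1e-12)
    assert np.all((S >= 0) & (S <= 1))
    ok = S > 1e-12
    H = m.cumhaz(GRID)
    assert np.all(H >= -1e-12)
    assert np.all(np.diff(H) >= -1e-10)
    assert np.allclose(H[ok], -np.log(S[ok]), atol=1e-8)
    t_pos = GRID[1:]
    f = m.pdf(t_pos)
    hS = m.hazard(t_pos) * m.sf(t_pos)
    assert np.allclose(f, hS, atol=1e-8)


def test_exponential_closed_form():
    m = _model("exponential", [math.log(2.0)])
    assert m.sf(0.5) == pytest.approx(math.exp(-1.0), rel=1e-12)


def test_weibull_shape_one_is_exponential():
    w = _model("weibull", [0.0, math.log(0.5)])  # shape 1, scale 0.5 -> rate 2
    e = _model("exponential", [math.log(2.0)])
    assert np.allclose(w.sf(GRID), e.sf(GRID), atol=1e-12)


def test_gengamma_limits():
    """q -> 0 recovers the log-normal; q = 1 recovers the Weibull."""
    t = GRID[1:]
    gg0 = _model("gengamma", [0.2, math.log(0.7), 1e-7])
    ln = _model("lognormal", [0.2, math.log(0.7)])
    assert np.allclose(gg0.sf(t), ln.sf(t), atol=1e-6)
    gg1 = _model("gengamma", [math.log(0.8), math.log(1 / 1.3), 1.0])
    wb = _model("weibull", [math.log(1.3), math.log(0.8)])
    assert np.allclose(gg1.sf(t), wb.sf(t), atol=1e-9)


def test_negative_time_rejected():
    m = _model("exponential", [0.0])
    with pytest.raises(SurvivalError):
        m.sf(-0.1)


def test_nonfinite_params_rejected():
    with pytest.raises(SurvivalError):
        _model("weibull", [np.nan, 0.0])


def test_gompertz_negative_shape_plateau():
    """Decreasing-hazard Gompertz admits S(inf) > 0."""
    m = _model("gompertz", [-1.0, math.log(0.5)])  # H(inf) = rate/|shape| = 0.5
    assert m.sf(1e6) == pytest.approx(math.exp(-0.5), rel=1e-9)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def test_exponential_mle_closed_form():
    """Rate MLE = events / total time at risk."""
    times = np.array([0.5, 1.2, 0.3, 2.0, 0.9])
    events = np.array([1, 0, 1, 1, 0])
    fit = fit_mle(TransitionDataset(times, events), "exponential")
    assert fit.natural_params()["rate"] == pytest.approx(3.0 / times.sum(), rel=1e-6)


def test_all_censored_is_degenerate():
    with pytest.raises(DegenerateFitError):
        fit_mle(TransitionDataset([1.0, 2.0], [0, 0]), "exponential")


def test_too_few_events_is_degenerate():
    with pytest.raises(DegenerateFitError):
        fit_mle(TransitionDataset([1.0, 2.0, 0.5], [1, 0, 0]), "gengamma")


def test_weibull_recovery_with_censoring(rng):
    """Shape and scale recovered within 10% at n=500, ~20% censoring."""
    shape, scale = 1.3, 0.8
    t = scale * rng.weibull(shape, 500)
    tc = scale * (-math.log(0.2)) ** (1 / shape)
    data = TransitionDataset(np.minimum(t, tc), (t <= tc).astype(int))
    fit = fit_mle(data, "weibull")
    nat = fit.natural_params()
    assert nat["shape"] == pytest.approx(shape, rel=0.10)
    assert nat["scale"] == pytest.approx(scale, rel=0.10)
    # covariance is a usable positive semi-definite matrix
    assert np.all(np.linalg.eigvalsh(fit.vcov) >= -1e-10)


def test_local_maximum_property(rng):
    """Perturbing the optimum by +/-1% never increases the log-likelihood."""
    t = 0.7 * rng.weibull(1.2, 300)
    data = TransitionDataset(np.maximum(t, 1e-6), np.ones(300, dtype=int))
    for fam in ("exponential", "weibull", "lognormal", "gompertz"):
        fit = fit_mle(data, fam)
        base = fit.loglik

        def loglik_at(params):
            m = fit.with_params(params)
            return float(np.sum(np.log(np.maximum(m.pdf(data.times), 1e-300))))

        for i in range(fit.params.size):
            for sign in (+1, -1):
                p = fit.params.copy()
                p[i] += sign * 0.01 * max(abs(p[i]), 0.1)
                assert loglik_at(p) <= base + 1e-6


def test_exponential_nested_in_weibull(rng):
    t = rng.exponential(0.8, 200)
    data = TransitionDataset(np.maximum(t, 1e-6), np.ones(200, dtype=int))
    ll_e = fit_mle(data, "exponential").loglik
    ll_w = fit_mle(data, "weibull").loglik
    assert ll_e <= ll_w + 1e-6


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def test_aic_bic_formulas():
    m = ParametricSurvivalModel(
        family=get_family("weibull"), params=[0.0, 0.0], loglik=-100.0, n_obs=100
    )
    assert m.aic == pytest.approx(204.0)
    assert m.bic == pytest.approx(2 * math.log(100) + 200.0)  # ~209.21
    assert m.bic == pytest.approx(209.21, abs=0.01)


def test_selection_ranks_generating_family(rng):
    """Weibull data at n=1000: Weibull or its gengamma superset in top 2."""
    t = 0.8 * rng.weibull(1.3, 1000)
    data = TransitionDataset(np.maximum(t, 1e-6), np.ones(1000, dtype=int))
    fits = [fit_mle(data, fam) for fam in FAMILY_ORDER]
    sel = select_model(fits)
    top2 = {m.family.name for m in sel.ranked[:2]}
    assert top2 & {"weibull", "gengamma"}
    assert list(sel.table()["AIC"]) == sorted(sel.table()["AIC"])


def test_selection_empty_rejected():
    with pytest.raises(SurvivalError):
        select_model([])


def test_model_json_round_trip(tmp_path):
    m = _model("gompertz", [0.4, -0.3])
    m.vcov = np.eye(2) * 0.01
    m.loglik = -50.0
    m.n_obs = 80
    m.n_events = 60
    m.transition_id = "TP5"
    m.arm = "comparator"
    path = tmp_path / "models.json"
    models_to_json([m], path)
    (back,) = models_from_json(path)
    assert back.family.name == "gompertz"
    assert np.allclose(back.params, m.params)
    assert np.allclose(back.vcov, m.vcov)
    assert back.transition_id == "TP5" and back.arm == "comparator"


def test_transition_csv_round_trip(tmp_path):
    import pandas as pd

    from bmcea.survival import read_transition_datasets

    df = pd.DataFrame(
        {
            "id": [1, 2, 3, 1, 2, 3],
            "arm": ["intervention"] * 3 + ["comparator"] * 3,
            "transition_id": ["TP1"] * 6,
            "time_years": [0.5, 1.0, 0.2, 0.7, 0.4, 1.5],
            "event": [1, 0, 1, 1, 1, 0],
        }
    )
    path = tmp_path / "transitions.csv"
    df.to_csv(path, index=False)
    ds = read_transition_datasets(path)
    assert set(ds) == {("TP1", "intervention"), ("TP1", "comparator")}
    assert ds[("TP1", "intervention")].n_events == 2

    bad = df.drop(columns="event")
    bad_path = tmp_path / "bad.csv"
    bad.to_csv(bad_path, index=False)
    with pytest.raises(SurvivalError, match="event"):
        read_transition_datasets(bad_path)
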