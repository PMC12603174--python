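"""DSA, PSA, CEAC and EVPI behaviour."""

import numpy as np
import pandas as pd
import pytest

import bmcea
from bmcea.uncertainty import (
    ParameterSpec,
    PSADrawMatrix,
    SpecError,
    ceac,
    default_parameter_specs,
    evpi,
    one_way_dsa,
    prob_cost_effective,
    quadrant_shares,
    run_psa,
)


def _matrix(costs, effects, seed=0):
    return PSADrawMatrix(np.asarray(costs, float), np.asarray(effects, float), seed=seed)


# ---------------------------------------------------------------------------
# ParameterSpec sampling
# ---------------------------------------------------------------------------


def test_invalid_spec_rejected_before_sampling():
    with pytest.raises(SpecError):
        ParameterSpec("x", 0.5, 0.6, 0.7, dist="beta")  # base below low
    with pytest.raises(SpecError):
        ParameterSpec("x", 0.5, dist="weird")
    with pytest.raises(SpecError):
        ParameterSpec("x", [0.1, 0.2], dist="mvn")  # vcov missing
    s = ParameterSpec("x", 0.5, 0.4, 0.6, dist="beta", extra={"se": 10.0})
    with pytest.raises(SpecError, match="SE too large"):
        s.sample(5, 1)


def test_substreams_independent_of_other_parameters():
    """Each parameter's draws depend only on its name and the master seed."""
    a = ParameterSpec("utility.u_pd_nobm", 0.76, 0.5, 0.95, dist="beta")
    b = ParameterSpec("cost.terminal_care_cost", 1e5, 5e4, 2e5, dist="gamma")
    alone = a.sample(100, seed_master := 7)
    with_b = a.sample(100, seed_master)  # sampling b in between changes nothing
    b.sample(100, seed_master)
    again = a.sample(100, seed_master)
    assert np.array_equal(alone, with_b)
    assert np.array_equal(alone, again)


def test_distribution_moments(rng):
    g = ParameterSpec("c", 1000.0, 750.0, 1250.0, dist="gamma").sample(40000, 3)
    assert g.mean() == pytest.approx(1000.0, rel=0.01)
    assert g.std() == pytest.approx(250.0, rel=0.05)
    assert np.all(g > 0)
    d = ParameterSpec("d", -0.05, -0.0625, -0.0375, dist="neg_gamma").sample(40000, 3)
    assert np.all(d < 0)
    assert d.mean() == pytest.approx(-0.05, rel=0.02)
    b = ParameterSpec("u", 0.76, 0.57, 0.95, dist="beta").sample(40000, 3)
    assert np.all((b > 0) & (b < 1))
    assert b.mean() == pytest.approx(0.76, rel=0.01)
    assert b.std() == pytest.approx(0.076, rel=0.05)


# ---------------------------------------------------------------------------
# DSA
# ---------------------------------------------------------------------------


def test_dsa_unread_parameter_zero_range(base_model):
    """A disutility whose AE prevalence is identically zero moves nothing."""
    curves = bmcea.default_curves(base_model.config.n_cycles)
    for arm in ("intervention", "comparator"):
        curves.ae[(arm, "platelet")] = np.zeros_like(curves.ae[(arm, "platelet")])
    model = base_model.replace(curves=curves)
    spec = ParameterSpec("utility.d_platelet", -0.0692, -0.0865, -0.0519, dist="neg_gamma")
    row = one_way_dsa(model, [spec]).iloc[0]
    assert row["INMB_range"] == pytest.approx(0.0, abs=1e-9)


def test_dsa_wtp_linearity(base_model, base_run):
    wtp = base_model.config.wtp_per_qaly
    spec = ParameterSpec("wtp", wtp, 0.75 * wtp, 1.25 * wtp, dist="normal")
    row = one_way_dsa(base_model, [spec]).iloc[0]
    assert row["INMB_range"] == pytest.approx(
        0.5 * wtp * base_run.delta_qaly, rel=1e-9
    )


def test_dsa_tornado_order_and_top_parameters(base_model):
    specs = default_parameter_specs(base_model)
    table = one_way_dsa(base_model, specs)
    assert not table["failed"].any()
    ranges = table["INMB_range"].to_numpy()
    assert np.all(np.diff(ranges) <= 1e-9)  # descending
    # PD-without-BM utility is among the most influential inputs
    assert "utility.u_pd_nobm" in set(table.head(3)["parameter"])


def test_dsa_at_base_reproduces_base_case(base_model, base_run):
    """Overriding any scalar parameter with its base value is a no-op."""
    for name, value in [
        ("utility.u_pd_nobm", 0.76),
        ("cost.atezolizumab_per_cycle", 83_258.0),
        ("wtp", base_model.config.wtp_per_qaly),
    ]:
        res = base_model.run({name: value})
        assert res.cea_qaly.icer == base_run.cea_qaly.icer  # bit-identical
        assert res.delta_cost == base_run.delta_cost


def test_unknown_override_is_hard_error(base_model):
    from bmcea.model import OverrideError

    with pytest.raises(OverrideError):
        base_model.run({"utility.u_pd_nobmm": 0.7})
    with pytest.raises(OverrideError):
        base_model.run({"survival.intervention.TP9": [0.0]})


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


def test_degenerate_psa_reproduces_base(base_model, base_run):
    specs = [
        ParameterSpec("utility.u_pd_nobm", 0.76, dist="degenerate"),
        ParameterSpec("cost.terminal_care_cost", 120_000.0, dist="degenerate"),
    ]
    mat = run_psa(base_model, specs, n_draws=3, seed=9)
    assert np.allclose(mat.delta_cost, base_run.delta_cost)
    assert np.allclose(mat.delta_effect, base_run.delta_qaly)


def test_psa_reproducible_and_quadrants_partition(base_model):
    specs = default_parameter_specs(base_model)
    m1 = run_psa(base_model, specs, n_draws=40, seed=5)
    m2 = run_psa(base_model, specs, n_draws=40, seed=5)
    assert np.array_equal(m1.costs, m2.costs)
    assert np.array_equal(m1.effects, m2.effects)
    assert sum(quadrant_shares(m1).values()) == pytest.approx(1.0)


def test_ceac_limits_and_step():
    mat = _matrix(
        costs=[[100, 0], [80, 100], [50, 60]],
        effects=[[1.0, 0.5], [0.2, 0.4], [0.9, 0.1]],
    )
    curve = ceac(mat, [0.0])
    assert curve["p_cost_effective"][0] == np.mean(mat.delta_cost < 0)
    hi = ceac(mat, [1e12])["p_cost_effective"][0]
    assert hi == np.mean(mat.delta_effect > 0)
    # degenerate draws: step function at the base-case ICER
    base = _matrix(costs=[[150, 50]] * 4, effects=[[1.0, 0.5]] * 4)  # ICER 200
    assert ceac(base, [150])["p_cost_effective"][0] == 0.0
    assert ceac(base, [250])["p_cost_effective"][0] == 1.0
    probs = ceac(base, np.linspace(0, 1000, 21))["p_cost_effective"]
    assert set(probs) <= {0.0, 1.0}


def test_evpi_hand_computed_cases():
    dominant = _matrix(costs=[[0, 10], [0, 10]], effects=[[1, 0], [1, 0]])
    assert evpi(dominant, wtp=100.0) == 0.0
    # NMBs {A:10, B:0} and {A:0, B:10} -> EVPI 5
    split = _matrix(costs=[[-10, 0], [0, -10]], effects=[[0, 0], [0, 0]])
    assert evpi(split, wtp=50.0) == pytest.approx(5.0)


def test_evpi_brute_force_oracle(rng):
    """Vectorised EVPI equals an explicit per-draw loop within 1e-9."""
    n = 1000
    costs = rng.normal(1e6, 2e5, size=(n, 2))
    effects = rng.normal(2.0, 0.5, size=(n, 2))
    mat = _matrix(costs, effects)
    wtp = 5e5
    fast = evpi(mat, wtp)

    best_sum = 0.0
    mean_nmb = [0.0, 0.0]
    for i in range(n):
        nmbs = [wtp * effects[i, s] - costs[i, s] for s in (0, 1)]
        best_sum += max(nmbs)
        mean_nmb[0] += nmbs[0]
        mean_nmb[1] += nmbs[1]
    slow = best_sum / n - max(mean_nmb) / n
    assert fast == pytest.approx(slow, abs=1e-9)
    assert fast >= 0.0


def test_evpi_nonnegative_random(rng):
    for _ in range(20):
        n = int(rng.integers(2, 50))
        mat = _matrix(rng.normal(0, 1, (n, 2)), rng.normal(0, 1, (n, 2)))
        assert evpi(mat, float(rng.uniform(0, 10))) >= -1e-12


def test_ceac_in_unit_interval(base_model):
    specs = default_parameter_specs(base_model)
    mat = run_psa(base_model, specs, n_draws=60, seed=2)
    grid = np.linspace(0, 6e6, 13)
    curve = ceac(mat, grid)
    assert ((curve["p_cost_effective"] >= 0) & (curve["p_cost_effective"] <= 1)).all()
    assert prob_cost_effective(mat, base_model.config.wtp_per_qaly) == pytest.approx(
        float(
            np.interp(
                base_model.config.wtp_per_qaly,
                curve["wtp"],
                curve["p_cost_effective"],
            )
        ),
        abs=0.35,
    )
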