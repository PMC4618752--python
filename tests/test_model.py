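import math

import numpy as np
import pytest

from hepregen import (ModelParameters, SimulationError, basal_state,
                      growth_rate_rhs, initial_state, mbf_release_flux,
                      peak_stats, rhs, simulate)
from hepregen.model import STATE_NAMES, _IDX
from hepregen.parameters import basal_production_constants

from conftest import random_valid_state


# ---------------------------------------------------------------------------
# independent oracle: a from-scratch, dict-based evaluation of the governing
# equations under the package's documented conventions


def oracle_rhs(y, p: ModelParameters):
    s = dict(zip(STATE_NAMES, y))
    k = basal_production_constants(p)
    scale = (1 - p.phx_fraction) if p.demand_convention == "whole_liver" else 1.0
    N = s["Q"] + s["G_cell"] * (s["P"] + s["R"])
    D = p.M / (scale * max(N, 1e-3))
    GF = max(s["GF"], 1.0)

    if p.apoptosis_convention == "as_printed":
        sig_ap = 0.5 * (1 + math.tanh((p.theta_ap - D) / p.beta_ap))
    else:
        load = scale * (s["Q"] + s["P"] + s["R"]) / (p.apoptosis_load_scale * p.M)
        sig_ap = 0.5 * (1 + math.tanh((p.theta_ap - load) / p.beta_ap))
    sig_req = 0.5 * (1 + math.tanh((p.theta_req - GF) / p.beta_req))

    signal = max(s["IE"] - p.IE0, 0.0)
    if p.include_mbf:
        signal += max(s["MBF_free"], 0.0)
    out = {}
    prime = p.k_QP * signal * s["Q"]
    adv = p.k_PR * max(GF - p.GF0, 0.0) * s["P"]
    back = p.k_RQ * s["ECM"] * s["R"]
    reqP = p.k_req * sig_req * s["P"]
    reqR = p.k_req * sig_req * s["R"] if p.requiescence_on_replicating else 0.0
    apP = p.k_ap * sig_ap * (
        s["Q"] if p.apoptosis_p_convention == "Q_as_printed" else s["P"])
    out["Q"] = -prime + back + reqP + reqR - p.k_ap * sig_ap * s["Q"]
    out["P"] = prime - adv - reqP - apP
    out["R"] = adv - back + p.k_prol * s["R"] - reqR - p.k_ap * sig_ap * s["R"]

    if p.include_growth:
        gate = 0.5 * (1 + math.tanh(
            (D - p.basal_demand_per_cell) /
            (p.growth_gate_width * p.basal_demand_per_cell)))
        cap = max(0.0, 1.0 - (s["G_cell"] / p.growth_cap) ** 8)
        out["growth_act"] = (gate - s["growth_act"]) / p.growth_lag_h
        out["G_cell"] = (math.log(2) * 60 * p.G_rate * s["G_cell"]
                         * s["growth_act"] * cap)
    else:
        out["growth_act"] = 0.0
        out["G_cell"] = 0.0

    jak = p.V_JAK * s["IL6"] / (s["IL6"] + p.Km_JAK)
    out["IL6"] = p.k_IL6 * D - jak - p.kappa_IL6 * s["IL6"] + k.k1
    out["JAK"] = jak - p.kappa_JAK * s["JAK"] + k.k2
    pro2 = p.pro_STAT3 ** 2
    prod = p.V_STAT3 * s["JAK"] * pro2 / (
        pro2 + p.Km_STAT3 * (1 + s["SOCS3"] / p.KI_SOCS3))
    ie = p.V_IE * s["pSTAT3"] / (s["pSTAT3"] + p.Km_IE)
    socs = p.V_SOCS3 * s["pSTAT3"] / (s["pSTAT3"] + p.Km_SOCS3)
    out["pSTAT3"] = prod - ie - socs - p.kappa_STAT3 * s["pSTAT3"] + k.k3
    out["SOCS3"] = socs - p.kappa_SOCS3 * s["SOCS3"] + k.k4
    out["IE"] = ie - p.kappa_IE * s["IE"] + k.k5
    out["GF"] = p.k_GF * D - p.k_up * GF * s["ECM"] - p.kappa_GF * GF + k.k7
    if s["GF"] < 1.0:
        out["GF"] += (1.0 - s["GF"]) / 1e-2
    out["ECM"] = (-p.kappa_deg * max(s["IL6"], 0) * s["ECM"]
                  - p.kappa_ECM * s["ECM"] + k.k6)
    for name in ("IL6", "pSTAT3", "IE"):
        if s[name] < 0.0:
            out[name] -= s[name] / 1e-2
    if p.include_mbf:
        u = p.k_MBF * (1 / s["ECM"] - p.ECM0)
        u *= max(s["MBF_ECM"], 0.0) if u >= 0 else max(s["MBF_free"], 0.0)
        out["MBF_ECM"] = -u + p.k_up * GF * s["ECM"]
        out["MBF_free"] = u - p.kappa_MBF * s["MBF_free"]
    else:
        out["MBF_ECM"] = out["MBF_free"] = 0.0
    return np.array([out[name] for name in STATE_NAMES])


@pytest.mark.parametrize("variant", [
    {}, {"include_mbf": True}, {"include_growth": False},
    {"apoptosis_convention": "as_printed"},
    {"demand_convention": "remnant"},
])
def test_rhs_matches_independent_oracle(variant):
    """Implementation agrees with a hand-coded evaluation of the governing
    equations on random valid states to 1e-12 relative error."""
    p = ModelParameters(**variant)
    rng = np.random.default_rng(42)
    for _ in range(100):
        y = random_valid_state(rng)
        got = rhs(y, p)
        want = oracle_rhs(y, p)
        scale = np.maximum(np.abs(want), 1.0)
        assert np.max(np.abs(got - want) / scale) < 1e-12


def test_rhs_worked_example_ecm(nominal):
    """Doubling IL-6 at baseline drains ECM at kappa_deg per unit."""
    y = basal_state(nominal)
    y[_IDX["IL6"]] = 2.0
    d = rhs(y, nominal)
    # -7*2*1 - 33*1 + 40 = -7
    assert d[_IDX["ECM"]] == pytest.approx(-7.0, abs=1e-12)


def test_requiescence_sigmoid_half_maximal_at_threshold(nominal):
    # GF at theta_req makes sigma_req exactly 1/2: starting from the basal
    # state with one primed cell, the requiescence flux is k_req/2
    y = basal_state(nominal)
    y[_IDX["GF"]] = nominal.theta_req
    y[_IDX["P"]] = 1.0
    d = rhs(y, nominal)
    # P loses requiescence + advance; advance = k_PR*(GF-1)*P
    advance = nominal.k_PR * (nominal.theta_req - 1.0)
    assert d[_IDX["P"]] == pytest.approx(-0.5 * nominal.k_req - advance,
                                         rel=1e-9)


def test_rhs_rejects_nonfinite_state(nominal):
    y = initial_state(nominal)
    y[0] = np.nan
    with pytest.raises(SimulationError):
        rhs(y, nominal)


# ---------------------------------------------------------------------------
# simulation invariants


def test_initial_mass_fraction_is_remnant(nominal_trajectory):
    assert nominal_trajectory.mass_fraction[0] == pytest.approx(0.3)


def test_no_priming_no_growth_is_static(nominal):
    # without priming, growth or overload-driven apoptosis the remnant pool
    # cannot change (with apoptosis on, an unprimed remnant slowly fails)
    p = nominal.replace(k_QP=0.0, k_ap=0.0, include_growth=False)
    tr = simulate(p, horizon=100.0, output_grid=1.0)
    assert np.allclose(tr.series("Q"), 1.0, atol=1e-7)
    assert np.allclose(tr.mass_fraction, 0.3, atol=1e-7)


def test_steady_state_invariance_300h(nominal):
    """From the pre-PHx configuration all molecular fold-changes stay
    within 1e-6 of 1 over 300 h."""
    tr = simulate(nominal, horizon=300.0, output_grid=5.0,
                  y0=basal_state(nominal))
    for name in ("IL6", "JAK", "pSTAT3", "SOCS3", "IE", "GF", "ECM"):
        assert np.max(np.abs(tr.series(name) - 1.0)) < 1e-6, name
    assert np.max(np.abs(tr.series("Q") - 1.0 / 0.3)) < 1e-5


def test_nonnegativity_and_gf_floor(nominal_trajectory):
    tr = nominal_trajectory
    for name in ("Q", "P", "R", "IL6", "JAK", "pSTAT3", "SOCS3", "IE", "ECM"):
        assert np.min(tr.series(name)) >= 0.0, name
    assert np.min(tr.series("GF")) >= 1.0 - 1e-9


def test_replicating_fraction_bounded(nominal_trajectory):
    rf = nominal_trajectory.replicating_fraction
    assert np.all((rf >= 0.0) & (rf <= 1.0))


def test_tolerance_robustness(nominal):
    """Halving integrator tolerances moves mass_fraction by < 1e-4 rel."""
    a = simulate(nominal, output_grid=2.0, rtol=1e-8, atol=1e-10)
    b = simulate(nominal, output_grid=2.0, rtol=5e-9, atol=5e-11)
    rel = np.abs(a.mass_fraction - b.mass_fraction) / np.abs(b.mass_fraction)
    assert np.max(rel) < 1e-4


def test_simulation_is_deterministic(nominal):
    a = simulate(nominal, horizon=50.0, output_grid=1.0)
    b = simulate(nominal, horizon=50.0, output_grid=1.0)
    assert np.array_equal(a.data.to_numpy(), b.data.to_numpy())


def test_growth_rate_rhs_behaviour(nominal):
    y = basal_state(nominal)      # demand exactly basal, gate half-open
    y[_IDX["growth_act"]] = 1.0
    assert growth_rate_rhs(y, nominal) > 0.0
    y0 = initial_state(nominal)   # unmet demand, but activation starts at 0
    d0 = rhs(y0, nominal)
    assert d0[_IDX["growth_act"]] > 0.0
    assert growth_rate_rhs(y0, nominal.replace(include_growth=False)) == 0.0
    p0 = nominal.replace(G_rate=0.0)
    y0[_IDX["growth_act"]] = 1.0
    assert growth_rate_rhs(y0, p0) == 0.0


def test_mass_doubles_within_about_a_day(nominal_trajectory):
    """Hypertrophy plus replication roughly double remnant mass early
    (the qualitative feature the growth extension exists for)."""
    m24 = nominal_trajectory.at(30.0)
    assert m24 > 0.45


# ---------------------------------------------------------------------------
# matrix-bound factors


def test_mbf_release_flux_examples(nominal):
    p = nominal.replace(include_mbf=True)
    y = initial_state(p)
    assert mbf_release_flux(y, p) == pytest.approx(0.0)  # ECM at baseline
    y[_IDX["ECM"]] = 0.5
    # rate (1/0.5 - 1) = 1 acting on the full bound pool of 50
    assert mbf_release_flux(y, p) == pytest.approx(50.0)
    y[_IDX["MBF_ECM"]] = 0.0
    assert mbf_release_flux(y, p) == pytest.approx(0.0)  # exhausted
    y[_IDX["ECM"]] = -0.2
    with pytest.raises(SimulationError):
        mbf_release_flux(y, p)


def test_mbf_requires_flag(nominal):
    with pytest.raises(ValueError):
        mbf_release_flux(initial_state(nominal), nominal)


def test_mbf_mass_balance(mbf_trajectory):
    """Cumulative release equals pool depletion plus replenishment."""
    tr = mbf_trajectory
    t = tr.times
    release = tr.series("mbf_release_flux")
    replenish = (tr.params.k_up * np.maximum(tr.series("GF"), 1.0)
                 * tr.series("ECM"))
    cum_release = np.trapezoid(release, t)
    cum_replenish = np.trapezoid(replenish, t)
    pool_drop = tr.series("MBF_ECM")[0] - tr.series("MBF_ECM")[-1]
    assert cum_release == pytest.approx(pool_drop + cum_replenish, rel=1e-3)


def test_mbf_inert_when_disabled(nominal_trajectory):
    assert np.all(nominal_trajectory.series("MBF_ECM") == 50.0)
    assert np.all(nominal_trajectory.series("mbf_release_flux") == 0.0)


# ---------------------------------------------------------------------------
# peak reporting


def test_peak_stats_simple():
    pk = peak_stats([0, 1, 2], [0, 1, 0])
    assert (pk.time, pk.value, pk.flat) == (1.0, 1.0, False)


def test_peak_stats_flat_series():
    pk = peak_stats([0, 1, 2], [3.0, 3.0, 3.0])
    assert pk.flat and pk.time == 0.0 and pk.value == 3.0


def test_peak_stats_recovers_parabola_vertex():
    # y = 5 - 2(t - 1.3)^2 sampled on a grid not containing the vertex
    t = np.array([0.0, 1.0, 2.0])
    v = 5 - 2 * (t - 1.3) ** 2
    pk = peak_stats(t, v)
    assert pk.time == pytest.approx(1.3, abs=1e-12)
    assert pk.value == pytest.approx(5.0, abs=1e-12)


def test_peak_stats_errors():
    with pytest.raises(ValueError):
        peak_stats([], [])
    with pytest.raises(ValueError):
        peak_stats([0, 1], [np.inf, 0])


def test_trajectory_csv_round_trip(tmp_path, nominal):
    tr = simulate(nominal, horizon=10.0, output_grid=1.0)
    path = tmp_path / "traj.csv"
    tr.to_csv(path)
    from hepregen import Trajectory
    again = Trajectory.from_csv(path, nominal)
    assert np.allclose(again.mass_fraction, tr.mass_fraction, atol=1e-9)
    header = path.read_text().splitlines()[0]
    assert header.startswith("time_h,Q,P,R,G_cell,IL6")


# ---------------------------------------------------------------------------
# property-based checks


from hypothesis import given, settings, strategies as st


@settings(deadline=None, max_examples=50, derandomize=True)
@given(vertex_t=st.floats(0.55, 1.45), height=st.floats(-5.0, 5.0),
       curvature=st.floats(0.1, 50.0))
def test_peak_stats_refines_any_parabola(vertex_t, height, curvature):
    t = np.array([0.0, 1.0, 2.0])
    v = height - curvature * (t - vertex_t) ** 2
    pk = peak_stats(t, v)
    assert pk.time == pytest.approx(vertex_t, abs=1e-9)
    assert pk.value == pytest.approx(height, abs=1e-8)
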