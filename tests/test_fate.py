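"""Multimedia fate model: solver correctness, metrics, classification."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from chemprior.config import FateParameters, ThresholdConfig
from chemprior.fate import (COMPARTMENTS, DegenerateSystemError, FateInputError,
                            HalfLifeSet, build_steady_state_system,
                            build_two_region_system, classify_region,
                            compute_ctd, compute_pov, compute_te,
                            derive_halflives, run_fate, solve_steady_state)
from chemprior.substances import PropertySet, SubstanceRecord

from conftest import random_fate_inputs


def ode_steady_state(K, e, rtol=1e-12):
    """Independent oracle: integrate dm/dt = K m + e to steady state.

    The slowest relaxation timescale is bounded by the smallest total
    loss rate (the negated column sums), so integrating 60 of those
    timescales leaves a transient below e^-60.
    """
    slowest = 1.0 / np.min(-K.sum(axis=0))
    sol = solve_ivp(lambda t, m: K @ m + e, (0.0, 60.0 * slowest),
                    np.zeros(len(e)), method="LSODA", rtol=rtol, atol=1e-14)
    return sol.y[:, -1]


# --- half-life derivation ---------------------------------------------------

def test_sediment_doubles_water():
    hl = derive_halflives(PropertySet(t_half_water=60.0, t_half_air=1.0))
    assert hl.sediment == 120.0
    assert hl.provenance["sediment"] == "doubled_from_water"


@pytest.mark.parametrize("biowin3, expected_water", [
    (5.0, 0.17), (4.5, 1.25), (4.0, 2.33), (3.5, 8.67),
    (3.0, 15.0), (2.5, 37.5), (2.0, 60.0), (1.0, 180.0),
])
def test_biowin3_water_halflife_mapping(biowin3, expected_water):
    hl = derive_halflives(PropertySet(biowin3=biowin3, t_half_air=1.0))
    assert hl.water == expected_water
    assert hl.provenance["water"] == "mapped_from_biowin3"


def test_experimental_halflife_precedence():
    hl = derive_halflives(PropertySet(t_half_water=33.0, biowin3=5.0, t_half_air=1.0))
    assert hl.water == 33.0
    assert hl.provenance["water"] == "experimental"


def test_no_water_route_is_unresolvable():
    with pytest.raises(FateInputError):
        derive_halflives(PropertySet(t_half_air=1.0))


def test_missing_air_halflife_flagged():
    hl = derive_halflives(PropertySet(t_half_water=10.0))
    assert hl.provenance["air"] == "floor_default"
    assert hl.warnings


# --- steady-state system ----------------------------------------------------

def _hl(w=40.0, s=80.0, so=40.0, a=5.0):
    return HalfLifeSet(water=w, sediment=s, soil=so, air=a)


def test_zero_velocities_give_diagonal_system():
    params = FateParameters(u_air_water=0, u_air_soil=0, u_water_air=0,
                            u_soil_water=0, u_soil_air=0)
    props = PropertySet(log_kow=4.0, log_kaw=-3.0)
    K, e = build_steady_state_system(props, _hl(), params, "water")
    off = K - np.diag(np.diag(K))
    assert np.all(off == 0)
    assert e.tolist() == [0.0, 1.0, 0.0]


def test_columns_conserve_mass():
    props = PropertySet(log_kow=4.0, log_kaw=-3.0)
    K, _ = build_steady_state_system(props, _hl(), FateParameters(), "air")
    k_deg = np.array([math.log(2) / t for t in (5.0, 40.0, 40.0)])  # air,water,soil
    np.testing.assert_allclose(-K.sum(axis=0), k_deg, rtol=1e-12)


def test_decoupled_water_closed_form():
    params = FateParameters(u_air_water=0, u_air_soil=0, u_water_air=0,
                            u_soil_water=0, u_soil_air=0)
    props = PropertySet(log_kow=4.0, log_kaw=-3.0)
    K, e = build_steady_state_system(props, _hl(w=40.0), params, "water")
    m = solve_steady_state(K, e)
    k = math.log(2) / 40.0
    assert m[1] == pytest.approx(1.0 / k, rel=1e-12)
    assert m[0] == 0.0 and m[2] == 0.0


def test_solution_linear_in_emission():
    props = PropertySet(log_kow=5.0, log_kaw=-2.0)
    K, e = build_steady_state_system(props, _hl(), FateParameters(), "soil")
    m1 = solve_steady_state(K, e)
    m2 = solve_steady_state(K, 2.0 * e)
    np.testing.assert_allclose(m2, 2.0 * m1, rtol=1e-12)


def test_singular_system_names_compartment():
    K = np.diag([-1.0, 0.0, -1.0])
    with pytest.raises(DegenerateSystemError, match="water"):
        solve_steady_state(K, np.array([0.0, 1.0, 0.0]))


def test_steady_state_matches_ode_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        props, hl, params = random_fate_inputs(rng)
        scenario = COMPARTMENTS[rng.integers(0, 3)]
        K, e = build_steady_state_system(props, hl, params, scenario)
        m = solve_steady_state(K, e)
        oracle = ode_steady_state(K, e)
        np.testing.assert_allclose(m, oracle, rtol=1e-6, atol=1e-12)


# --- metrics ----------------------------------------------------------------

def test_pov_single_compartment_closed_form():
    k = math.log(2) / 40.0
    pov = compute_pov(np.array([1.0 / k, 0.0, 0.0]), np.array([k, 1.0, 1.0]))
    assert pov == pytest.approx(40.0 / math.log(2), rel=1e-12)


def test_pov_two_compartment_hand_value():
    k1, k2 = math.log(2) / 10.0, math.log(2) / 1000.0
    m = np.array([1.0, 1.0, 0.0])
    pov = compute_pov(m, np.array([k1, k2, 1.0]))
    assert pov == pytest.approx(2.0 / (k1 + k2), rel=1e-12)


def test_pov_limit_slowest_compartment():
    k_fast, k_slow = math.log(2) / 1.0, math.log(2) / 1000.0
    m = np.array([0.0, 1e-12, 1.0])
    pov = compute_pov(m, np.array([1.0, k_fast, k_slow]))
    assert pov == pytest.approx(1.0 / k_slow, rel=1e-6)


def test_ctd_all_mass_in_air():
    params = FateParameters(wind_speed_m_s=4.0)
    pov = 40.0 / math.log(2)  # ~57.7 days
    ctd, mobile = compute_ctd(np.array([1.0, 0.0, 0.0]), pov, params)
    assert mobile == "air"
    assert ctd == pytest.approx(4.0 * pov * 86.4, rel=1e-12)  # ~19,941 km
    assert ctd == pytest.approx(19941.0, rel=1e-3)


def test_ctd_no_mobile_mass():
    ctd, _ = compute_ctd(np.array([0.0, 0.0, 5.0]), 100.0, FateParameters())
    assert ctd == 0.0


def test_ctd_linear_in_mobile_fraction():
    params = FateParameters()
    full, _ = compute_ctd(np.array([1.0, 0.0, 1.0]), 50.0, params)
    half, _ = compute_ctd(np.array([0.5, 0.0, 1.5]), 50.0, params)
    assert half == pytest.approx(full / 2.0, rel=1e-12)


def test_te_zero_without_pathway():
    """No air deposition, no runoff, emission to soil: nothing can reach
    remote surface media."""
    params = FateParameters(u_air_water=0.0, u_air_soil=0.0, u_soil_water=0.0)
    props = PropertySet(log_kow=4.0, log_kaw=-3.0)
    assert compute_te(props, _hl(), params, "soil") == 0.0


def test_te_bounded():
    rng = np.random.default_rng(7)
    for _ in range(20):
        props, hl, params = random_fate_inputs(rng)
        te = compute_te(props, hl, params, COMPARTMENTS[rng.integers(0, 3)])
        assert 0.0 <= te <= 100.0


def test_two_region_mass_balance():
    """Emission = total degradation + advective export out of the system."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        props, hl, params = random_fate_inputs(rng)
        K, e, r = build_two_region_system(props, hl, params, "water")
        m = solve_steady_state(K, e)
        k_deg = np.array([r["k_deg_air"], r["k_deg_water"], r["k_deg_soil"]] * 2)
        degradation = float(k_deg @ m)
        export = r["k_adv_air"] * m[3] + r["k_adv_water"] * m[4]
        assert degradation + export == pytest.approx(1.0, rel=1e-9)


def test_closed_system_mass_balance():
    rng = np.random.default_rng(6)
    for _ in range(20):
        props, hl, params = random_fate_inputs(rng)
        K, e = build_steady_state_system(props, hl, params, "air")
        m = solve_steady_state(K, e)
        k_deg = np.array([math.log(2) / hl.air, math.log(2) / hl.water,
                          math.log(2) / hl.soil])
        assert float(k_deg @ m) == pytest.approx(1.0, rel=1e-9)


# --- classification ---------------------------------------------------------

@pytest.mark.parametrize("pov, ctd, te, region", [
    (200.0, 6000.0, 0.0, "A"),      # very persistent, POP-like
    (100.0, 1000.0, 1.0, "D"),
    (200.0, 1000.0, 1.0, "B"),      # only overall persistence high
    (100.0, 6000.0, 0.0, "C"),      # only long-range transport high
    (200.0, 1000.0, 3.0, "A"),      # TE alone can satisfy the LRTP leg
    (195.0, 6000.0, 3.0, "C"),      # strict boundary on Pov
    (200.0, 5097.0, 2.25, "B"),     # strict boundaries on CTD and TE
])
def test_region_classification(pov, ctd, te, region):
    assert classify_region(pov, ctd, te) == region


# --- orchestration ----------------------------------------------------------

def _record(**props):
    defaults = dict(log_kow=5.0, log_kaw=-3.0, t_half_water=300.0, t_half_air=100.0)
    defaults.update(props)
    return SubstanceRecord(cas="2921-88-2", props=PropertySet(**defaults))


def test_run_fate_contract():
    scenarios, summary = run_fate(_record())
    assert set(scenarios) == {"air", "water", "soil"}
    for res in scenarios.values():
        assert sum(res.mass_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= f <= 1.0 for f in res.mass_fractions.values())
    assert summary.pov_days == pytest.approx(
        max(r.pov_days for r in scenarios.values()))
    assert summary.ctd_km == pytest.approx(
        max(r.ctd_km for r in scenarios.values()))
    assert summary.te_percent == pytest.approx(
        max(r.te_percent for r in scenarios.values()))


def test_run_fate_extreme_persistence_is_region_a():
    _, summary = run_fate(_record(t_half_water=5000.0, t_half_air=5000.0))
    assert summary.region == "A"


def test_run_fate_attaches_cas_on_failure():
    rec = SubstanceRecord(cas="50-29-3", props=PropertySet(log_kow=5.0))
    with pytest.raises(FateInputError, match="50-29-3"):
        run_fate(rec)


def test_pov_monotone_in_halflives():
    rng = np.random.default_rng(9)
    for _ in range(10):
        props, hl, params = random_fate_inputs(rng)
        K, e = build_steady_state_system(props, hl, params, "water")
        m = solve_steady_state(K, e)
        k = np.array([math.log(2) / hl.air, math.log(2) / hl.water,
                      math.log(2) / hl.soil])
        pov = compute_pov(m, k)
        longer = HalfLifeSet(water=hl.water * 3, sediment=hl.sediment * 3,
                             soil=hl.soil * 3, air=hl.air * 3)
        K2, e2 = build_steady_state_system(props, longer, params, "water")
        m2 = solve_steady_state(K2, e2)
        k2 = k / 3.0
        assert compute_pov(m2, k2) >= pov


def test_metrics_independent_of_emission_magnitude():
    props = PropertySet(log_kow=5.0, log_kaw=-3.0)
    hl = _hl()
    params = FateParameters()
    K, e = build_steady_state_system(props, hl, params, "water")
    k = np.array([math.log(2) / hl.air, math.log(2) / hl.water,
                  math.log(2) / hl.soil])
    m1, m10 = solve_steady_state(K, e), solve_steady_state(K, 10 * e)
    assert compute_pov(m1, k) == pytest.approx(compute_pov(m10, k), rel=1e-12)
    np.testing.assert_allclose(m10 / m10.sum(), m1 / m1.sum(), rtol=1e-12)
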