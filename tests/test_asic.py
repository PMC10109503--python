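"""ASIC1a gating model: steady states, time constants, currents, protocols."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numba import njit
from scipy.optimize import brentq

from windup_asic.asic import (ASICParams, ASICState, activation_curve,
                              asic_current, h_inf, m_inf,
                              peak_product_pH, recovery_from_inactivation,
                              steady_state_curves, step_gating, tau_h)


# ---------------------------------------------------------------------------
# steady-state curves
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant,ph_m,ph_h,alpha", [
    ("homomeric", 6.46, 7.3, 1.3),
    ("heteromeric", 6.03, 6.74, 1.0),
])
def test_half_activation_points(variant, ph_m, ph_h, alpha):
    """Bisection on the implemented curves recovers the fitted half-points."""
    p = ASICParams.from_variant(variant)
    root_m = brentq(lambda x: m_inf(x, p) - 0.5, 5.0, 8.0, xtol=1e-12)
    assert root_m == pytest.approx(ph_m, abs=1e-6)
    root_h = brentq(lambda x: h_inf(x, p) - alpha / 2, 5.0, 9.0, xtol=1e-12)
    assert root_h == pytest.approx(ph_h, abs=1e-6)


def test_steady_state_values(homomeric, heteromeric):
    assert m_inf(6.46, homomeric) == pytest.approx(0.5)
    assert m_inf(6.03, heteromeric) == pytest.approx(0.5)
    assert m_inf(4.0, homomeric) == pytest.approx(0.99980, abs=1e-5)
    assert h_inf(7.3, homomeric) == pytest.approx(0.65)
    assert h_inf(6.74, heteromeric) == pytest.approx(0.5)
    # ceiling: the inactivation sigmoid saturates at alpha = 1.3
    assert h_inf(9.0, homomeric) == pytest.approx(1.3, abs=1e-6)


@given(ph=st.floats(min_value=3.0, max_value=10.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_m_decreasing_h_increasing(ph):
    p = ASICParams.homomeric_native()
    eps = 1e-4
    assert m_inf(ph + eps, p) < m_inf(ph, p)
    assert h_inf(ph + eps, p) > h_inf(ph, p)
    assert 0.0 < m_inf(ph, p) < 1.0
    assert 0.0 < h_inf(ph, p) < p.alpha


def test_nonfinite_ph_rejected(homomeric):
    for bad in (float("nan"), float("inf")):
        with pytest.raises(ValueError):
            m_inf(bad, homomeric)
        with pytest.raises(ValueError):
            h_inf(bad, homomeric)


# ---------------------------------------------------------------------------
# inactivation time constant
# ---------------------------------------------------------------------------

def test_tau_h_values(homomeric, heteromeric):
    # biased gaussian at its center: a1 + a3*pH - b3
    assert tau_h(7.144, homomeric) == pytest.approx(52.213, abs=0.01)
    # symmetrized exponential at its center: amplitude + offset
    assert tau_h(6.6, heteromeric) == pytest.approx(44.507, abs=1e-3)
    # far from the center the exponential vanishes, leaving the offset
    assert tau_h(4.0, heteromeric) == pytest.approx(1.645, abs=5e-4)


def test_tau_h_positive_and_peaked(homomeric, heteromeric):
    grid = np.linspace(4.0, 9.0, 501)
    for p in (homomeric, heteromeric):
        taus = np.array([tau_h(x, p) for x in grid])
        assert (taus > 0).all()
    het = np.array([tau_h(x, heteromeric) for x in grid])
    assert grid[het.argmax()] == pytest.approx(6.6, abs=0.01)


def test_tau_h_range_check(homomeric):
    with pytest.raises(ValueError):
        tau_h(3.0, homomeric)
    unchecked = ASICParams.homomeric_native(check_pH_range=False)
    assert tau_h(3.0, unchecked) > 0  # positivity floor applies


def test_alternative_tau_forms_positive():
    affine = ASICParams.homomeric_native(
        tau_h_form="affine", tau_h_coeffs=(160.4, 1195.32))
    piecewise = ASICParams.homomeric_native(
        tau_h_form="piecewise_affine", tau_h_coeffs=(10.18, 49.92, -558.3, 4143.0))
    for p in (affine, piecewise):
        for ph in np.arange(4.0, 9.0, 0.25):
            assert tau_h(float(ph), p) > 0


# ---------------------------------------------------------------------------
# gating dynamics
# ---------------------------------------------------------------------------

def test_h_fixed_point(homomeric):
    state = ASICState(h=h_inf(6.9, homomeric))
    out = step_gating(state, 6.9, 0.5, homomeric)
    assert out.h == pytest.approx(state.h, rel=1e-12)


def test_h_five_time_constants(homomeric):
    tau_ms = tau_h(7.4, homomeric) * 1000.0
    state = ASICState(h=0.0)
    n, dt = 500, 5 * tau_ms / 500
    # the exact-exponential update composes, so stepping in chunks is fine
    for _ in range(n):
        state = step_gating(state, 7.4, dt, homomeric)
    assert state.h == pytest.approx(h_inf(7.4, homomeric), rel=0.01)


def test_exponential_update_is_exact(homomeric):
    """1000 steps of 0.1 ms equal one 100 ms step at fixed pH."""
    s_many = ASICState(h=0.2)
    for _ in range(1000):
        s_many = step_gating(s_many, 6.9, 0.1, homomeric)
    s_once = step_gating(ASICState(h=0.2), 6.9, 100.0, homomeric)
    assert s_many.h == pytest.approx(s_once.h, abs=1e-9)


@njit(cache=True)
def _euler_h(h0, hinf, tau_ms, dt, n):
    h = h0
    for _ in range(n):
        h += dt * (hinf - h) / tau_ms
    return h


def test_update_matches_explicit_euler_oracle(homomeric):
    """Exact update vs brute-force Euler at dt = 1e-4 ms over 10 s."""
    ph = 7.0
    hinf = h_inf(ph, homomeric)
    tau_ms = tau_h(ph, homomeric) * 1000.0
    oracle = _euler_h(0.1, hinf, tau_ms, 1e-4, 100_000_000)
    state = step_gating(ASICState(h=0.1), ph, 10_000.0, homomeric)
    assert state.h == pytest.approx(oracle, rel=1e-4)


def test_step_gating_rejects_bad_dt(homomeric):
    with pytest.raises(ValueError):
        step_gating(ASICState(h=0.5), 7.4, 0.0, homomeric)


# ---------------------------------------------------------------------------
# current law
# ---------------------------------------------------------------------------

def test_mittx_current_and_ph_independence(homomeric):
    state = ASICState(h=0.3, mode="mittx")
    i_total, i_ca = asic_current(state, 7.4, -80.0, 0.2, homomeric)
    assert i_total == pytest.approx(-26.0)       # 0.2 nS * (-130 mV)
    assert i_ca == pytest.approx(-2.6)           # 10% calcium fraction
    i_acid, _ = asic_current(state, 5.0, -80.0, 0.2, homomeric)
    assert i_acid == i_total                     # locked open: pH-independent


def test_dynamic_current_and_ca_split(homomeric):
    state = ASICState(h=h_inf(7.0, homomeric))
    i_total, i_ca = asic_current(state, 7.0, -60.0, 1.0, homomeric)
    expected = 1.0 * m_inf(7.0, homomeric) * state.h * (-60.0 - 50.0)
    assert i_total == pytest.approx(expected)
    assert i_ca == pytest.approx(0.1 * i_total)
    no_ca = ASICParams.homomeric_native(ca_fraction=0.0)
    i_total2, i_ca2 = asic_current(state, 7.0, -60.0, 1.0, no_ca)
    assert i_ca2 == 0.0 and i_total2 == pytest.approx(i_total)


def test_negative_conductance_rejected(homomeric):
    with pytest.raises(ValueError):
        asic_current(ASICState(h=0.5), 7.0, -60.0, -1.0, homomeric)


# ---------------------------------------------------------------------------
# characterization protocols
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant", ["homomeric", "heteromeric"])
def test_peak_open_probability_vs_brute_force(variant):
    p = ASICParams.from_variant(variant)
    grid = np.linspace(4.0, 9.0, 5001)
    prods = np.array([m_inf(x, p) * h_inf(x, p) for x in grid])
    assert peak_product_pH(p) == pytest.approx(grid[prods.argmax()], abs=1e-9)


def test_recovery_from_inactivation_limits(heteromeric):
    tab = recovery_from_inactivation(heteromeric, [0.0, 1e9])
    h0 = h_inf(6.0, heteromeric) / h_inf(7.4, heteromeric)
    assert tab.recovery_fraction.iloc[0] == pytest.approx(h0, rel=1e-9)
    # alpha = 1: full recovery at long intervals under pH 7.4 conditioning
    assert tab.recovery_fraction.iloc[-1] == pytest.approx(1.0, rel=1e-6)


def test_activation_curve_normalized(homomeric):
    tab = activation_curve(homomeric)
    assert tab.g_rel.max() == pytest.approx(1.0)
    # conditioning at 7.4 then stepping to pH 6.0 gives a near-maximal response
    assert tab.loc[(tab.pH - 6.0).abs().idxmin(), "g_rel"] > 0.8


def test_steady_state_table_columns(homomeric):
    tab = steady_state_curves(homomeric, np.arange(4.0, 9.0, 0.05))
    assert list(tab.columns) == ["pH", "m_inf", "h_inf", "tau_h_s", "g_rel"]
    assert tab.g_rel.max() == pytest.approx(1.0)
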