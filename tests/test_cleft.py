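"""Synaptic cleft proton buffering: algebra, dynamics, pulses."""

import math

import numpy as np
import pytest
from numba import njit
from scipy.optimize import brentq

from windup_asic import _kernels as K
from windup_asic.cleft import (CleftParams, CleftState, buffered_total,
                               free_from_total, on_presynaptic_event,
                               step_cleft)


def test_buffered_total_examples(cleft_params):
    assert buffered_total(0.0, cleft_params) == 0.0
    # resting free concentration 10^-7.4 M = 10^-4.4 mM
    assert buffered_total(10 ** -4.4, cleft_params) == pytest.approx(1.618, abs=1e-3)


def test_buffered_total_strictly_increasing(cleft_params):
    xs = np.logspace(-8, 0, 200)
    ys = [buffered_total(x, cleft_params) for x in xs]
    assert all(b > a for a, b in zip(ys, ys[1:]))


def test_inverse_pair_roundtrip(cleft_params):
    for x in (1e-6, 1e-4, 1e-2):
        total = buffered_total(x, cleft_params)
        assert free_from_total(total, cleft_params) == pytest.approx(x, rel=1e-10)
    assert free_from_total(0.0, cleft_params) == 0.0
    t = 1.618
    assert buffered_total(free_from_total(t, cleft_params), cleft_params) == \
        pytest.approx(t, rel=1e-10)


def test_free_from_total_vs_bisection_oracle(cleft_params):
    """Cancellation-safe quadratic vs a bisection root-finder."""
    for total in np.logspace(-6, 1.3, 100):
        f = lambda h: buffered_total(h, cleft_params) - total
        oracle = brentq(f, 0.0, total, xtol=1e-300, rtol=1e-15)
        assert free_from_total(total, cleft_params) == pytest.approx(oracle, rel=1e-12)


def test_negative_inputs_rejected(cleft_params):
    with pytest.raises(ValueError):
        buffered_total(-1.0, cleft_params)
    with pytest.raises(ValueError):
        free_from_total(-1.0, cleft_params)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def test_equilibrium_is_fixed_point(cleft_params):
    state = CleftState.resting(cleft_params)
    out = state
    for i in range(100):
        out = step_cleft(out, i * 0.025, 0.025, cleft_params)
    assert out.H_free == pytest.approx(cleft_params.H0, rel=1e-12)
    assert out.pH == pytest.approx(7.4, abs=1e-12)


def test_acidified_state_recovers_monotonically(cleft_params):
    h_free = 10 ** -4.0  # pH 7.0
    state = CleftState(H_total=buffered_total(h_free, cleft_params),
                       H_free=h_free, pH=7.0)
    phs = [state.pH]
    for i in range(4000):
        state = step_cleft(state, i * 0.025, 0.025, cleft_params)
        phs.append(state.pH)
    assert all(b >= a for a, b in zip(phs, phs[1:]))
    assert phs[-1] < 7.4  # recovery takes seconds, not 100 ms


def test_equilibration_from_any_state(cleft_params):
    """With no source the cleft settles at pH 7.4 regardless of start."""
    for ph0 in (6.5, 7.0, 7.8):
        h_free = 10 ** (-ph0) * 1e3
        ht = buffered_total(h_free, cleft_params)
        # effective recovery time constant ~ tau * (1 + B0/Kd) ~ 4 s
        ht = K.cleft_substep(ht, 0.0, 60_000.0, 12_000_000,
                             cleft_params.B0, cleft_params.Kd,
                             cleft_params.H0, cleft_params.tau)
        ph = K.pH_from_free_mM(K.cleft_free_from_total(
            ht, cleft_params.B0, cleft_params.Kd))
        assert ph == pytest.approx(7.4, abs=1e-6)


def test_single_pulse_vs_fine_step_oracle(cleft_params):
    """pH at the end of one 1-ms pulse vs integration at dt = 1e-4 ms."""
    state = CleftState.resting(cleft_params)
    state = on_presynaptic_event(state, 0.0, cleft_params)
    for i in range(40):  # 40 * 0.025 ms = 1 ms
        state = step_cleft(state, i * 0.025, 0.025, cleft_params)
    ht_oracle = K.cleft_substep(buffered_total(cleft_params.H0, cleft_params),
                                cleft_params.q_amp, 1.0, 10_000,
                                cleft_params.B0, cleft_params.Kd,
                                cleft_params.H0, cleft_params.tau)
    ph_oracle = K.pH_from_free_mM(K.cleft_free_from_total(
        ht_oracle, cleft_params.B0, cleft_params.Kd))
    assert state.pH == pytest.approx(ph_oracle, abs=1e-4)


def test_positivity_under_default_drive(cleft_params):
    state = CleftState.resting(cleft_params)
    state = on_presynaptic_event(state, 0.0, cleft_params)
    for i in range(400):
        state = step_cleft(state, i * 0.025, 0.025, cleft_params)
        assert state.H_free > 0


@njit(cache=True)
def _drive_periodic(ht0, n_periods, q, pulse_ms, period_ms, dt, B0, Kd, H0, tau):
    """Periodic 1 Hz pulsing; returns H_total at the start of each period."""
    ht = ht0
    out = np.empty(n_periods)
    for k in range(n_periods):
        out[k] = ht
        ht = K.cleft_substep(ht, q, pulse_ms, int(pulse_ms / dt), B0, Kd, H0, tau)
        ht = K.cleft_substep(ht, 0.0, period_ms - pulse_ms,
                             int((period_ms - pulse_ms) / dt), B0, Kd, H0, tau)
    return out


def test_one_hz_quasi_steady_balance(cleft_params):
    """After 15 periods the per-period input matches the recovery to ~1%."""
    p = cleft_params
    ht0 = buffered_total(p.H0, p)
    trace = _drive_periodic(ht0, 40, p.q_amp, p.pulse_dur, 1000.0, 0.005,
                            p.B0, p.Kd, p.H0, p.tau)
    per_period_change = np.diff(trace)
    input_per_period = p.q_amp * p.pulse_dur  # 0.3 mM
    # near quasi-steady state the net change is a small fraction of the input
    assert abs(per_period_change[15]) < 0.35 * input_per_period
    assert abs(per_period_change[-1]) < 0.05 * input_per_period


# ---------------------------------------------------------------------------
# presynaptic events
# ---------------------------------------------------------------------------

def test_event_schedules_pulse_window(cleft_params):
    state = CleftState.resting(cleft_params)
    state = on_presynaptic_event(state, 1000.0, cleft_params)
    assert state.pending_pulses == [(1000.0, 1001.0)]


def test_duplicate_events_coalesced(cleft_params):
    state = CleftState.resting(cleft_params)
    state = on_presynaptic_event(state, 1000.0, cleft_params)
    state = on_presynaptic_event(state, 1000.2, cleft_params)
    assert len(state.pending_pulses) == 1


def test_no_events_no_drift(cleft_params):
    state = CleftState.resting(cleft_params)
    out = step_cleft(state, 0.0, 0.025, cleft_params)
    assert out.pH == pytest.approx(7.4, abs=1e-12)
    assert out.pending_pulses == []


def test_step_cleft_dt_validation(cleft_params):
    state = CleftState.resting(cleft_params)
    with pytest.raises(ValueError):
        step_cleft(state, 0.0, 0.05, cleft_params)
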