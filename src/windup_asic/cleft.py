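"""Buffered synaptic-cleft acidification model.

The free proton concentration in the cleft is in instantaneous
equilibrium with a single physiological buffer (total concentration B0,
dissociation constant Kd), so the conserved quantity is the *total*
proton concentration

    H_total = H * (1 + B0 / (H + Kd))

which obeys

    d/dt H_total = q(t) - (H - H0) / tau

where ``q(t)`` is a lumped proton source active for ``pulse_dur`` ms
after each presynaptic activation (membrane potential crossing
``spike_threshold``), and the second term is a homeostatic drive
returning the free concentration to its physiological baseline
``H0 = 10^-7.4 M``.  Although tau is short (0.1 ms by default), it acts
on the tiny *free* deviation: the buffering factor at rest is about
1 + B0/Kd ~ 4e4, so the effective recovery of the total pool takes
seconds and 1 Hz stimulation acidifies the cleft cumulatively.

Units: concentrations in mM, time in ms.  pH = -log10(H_free in M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import _kernels as K

__all__ = [
    "CleftParams",
    "CleftState",
    "buffered_total",
    "free_from_total",
    "step_cleft",
    "on_presynaptic_event",
]

#: maximum explicit-Euler substep for the cleft ODE, ms
MAX_SUBSTEP = 0.005
#: maximum engine step accepted by step_cleft, ms
MAX_STEP = 0.025
#: coalescing window for duplicate presynaptic events, ms
EVENT_REFRACTORY = 1.0


@dataclass(frozen=True)
class CleftParams:
    """Cleft buffer, source and homeostasis parameters.

    Defaults are the reference set: B0 = 22 mM, Kd = 10^-6.3 M,
    H0 = 10^-7.4 M, q = 0.3 mM/ms for 1 ms per activation, tau = 0.1 ms.
    """

    B0: float = 22.0                      # mM
    Kd: float = 10.0 ** (-6.3) * 1e3      # mM (10^-6.3 M)
    H0: float = 10.0 ** (-7.4) * 1e3      # mM (10^-7.4 M)
    q_amp: float = 0.3                    # mM/ms
    pulse_dur: float = 1.0                # ms
    tau: float = 0.1                      # ms
    spike_threshold: float = -30.0        # mV, presynaptic trigger

    def __post_init__(self):
        if not (self.B0 > 0 and self.Kd > 0 and self.tau > 0 and self.pulse_dur > 0):
            raise ValueError("B0, Kd, tau and pulse_dur must be positive")


@dataclass
class CleftState:
    """Total/free proton concentration and the pending pulse windows."""

    H_total: float                       # mM, the ODE state variable
    H_free: float                        # mM, derived
    pH: float                            # derived
    pending_pulses: list = field(default_factory=list)  # [(start, end)] ms

    @classmethod
    def resting(cls, params: CleftParams) -> "CleftState":
        Ht = buffered_total(params.H0, params)
        return cls(H_total=Ht, H_free=params.H0,
                   pH=K.pH_from_free_mM(params.H0), pending_pulses=[])


def buffered_total(H_free: float, params: CleftParams) -> float:
    """Total proton concentration (mM) for a given free concentration."""
    if H_free < 0:
        raise ValueError("H_free must be non-negative")
    return K.cleft_buffered_total(float(H_free), params.B0, params.Kd)


def free_from_total(H_total: float, params: CleftParams) -> float:
    """Free proton concentration (mM) for a given buffered total.

    Unique non-negative root of H^2 + H*(Kd + B0 - Ht) - Kd*Ht = 0,
    computed cancellation-safely (see :mod:`windup_asic._kernels`).
    """
    if H_total < 0:
        raise ValueError("H_total must be non-negative")
    return K.cleft_free_from_total(float(H_total), params.B0, params.Kd)


def q_at(t: float, pulses) -> bool:
    """Whether a proton pulse is active at time t (ms)."""
    for start, end in pulses:
        if start <= t < end:
            return True
    return False


def on_presynaptic_event(state: CleftState, t: float, params: CleftParams) -> CleftState:
    """Register a presynaptic activation: schedule a 1 ms proton pulse.

    Events arriving within 1 ms of an already-scheduled pulse start are
    coalesced into that pulse (the presynaptic depolarization that
    triggers them outlasts the detection threshold crossing).
    """
    if not math.isfinite(t):
        raise ValueError("event time must be finite")
    for start, _ in state.pending_pulses:
        if abs(t - start) < EVENT_REFRACTORY:
            return state
    pulses = sorted(state.pending_pulses + [(t, t + params.pulse_dur)])
    return CleftState(H_total=state.H_total, H_free=state.H_free,
                      pH=state.pH, pending_pulses=pulses)


def step_cleft(state: CleftState, t: float, dt: float, params: CleftParams) -> CleftState:
    """Advance the cleft ODE from t to t+dt (dt <= 0.025 ms).

    Integrates d(H_total)/dt = q(t) - (H_free - H0)/tau with explicit
    substeps of at most 0.005 ms, treating the pulse source as constant
    over each substep; then refreshes the derived free concentration and
    pH.  Expired pulse windows are dropped.
    """
    if not (0 < dt <= MAX_STEP):
        raise ValueError(f"dt must be in (0, {MAX_STEP}] ms")
    n_sub = max(1, int(math.ceil(dt / MAX_SUBSTEP)))
    h = dt / n_sub
    Ht = state.H_total
    for i in range(n_sub):
        t_sub = t + i * h
        q = params.q_amp if q_at(t_sub, state.pending_pulses) else 0.0
        Ht = K.cleft_substep(Ht, q, h, 1, params.B0, params.Kd, params.H0, params.tau)
    H_free = K.cleft_free_from_total(Ht, params.B0, params.Kd)
    pulses = [(s, e) for s, e in state.pending_pulses if e > t + dt]
    return CleftState(H_total=Ht, H_free=H_free,
                      pH=K.pH_from_free_mM(H_free), pending_pulses=pulses)
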