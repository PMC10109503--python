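"""Proton-gated ASIC1a channel models for native spinal currents.

Two parameterizations are shipped, fitted to the two classes of native
ASIC current recorded in rat spinal neurons: a *homomeric* ASIC1a model
("Type 1" currents) and an ASIC1a/ASIC2 *heteromeric* model ("Type 2").
Gating is Hodgkin-Huxley-like with activation ``m`` and inactivation
``h`` that depend on pH only:

    m_inf(pH) = 1 / (1 + 10^( n_m * (pH - pH0.5m)))
    h_inf(pH) = alpha / (1 + 10^(-n_h * (pH - pH0.5h)))
    I         = g * m * h * (V - E)

Activation is treated as instantaneous (its time constant is far below
the timescales of interest here); inactivation relaxes exponentially
toward ``h_inf`` with a pH-dependent time constant ``tau_h``.  A fraction
of the ASIC current (10% by default) is carried by calcium.

The ``mittx`` gating mode emulates the Texas coral-snake toxin MitTx,
which locks the channel open: the effective open fraction ``m*h`` is 1
regardless of pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels as K

__all__ = [
    "ASICParams",
    "ASICState",
    "m_inf",
    "h_inf",
    "tau_h",
    "step_gating",
    "asic_current",
    "steady_state_curves",
    "activation_curve",
    "recovery_from_inactivation",
    "characterization_protocols",
]

_TAU_FORMS = {
    "biased_gaussian": K.TAU_H_BIASED_GAUSSIAN,
    "symmetrized_exponential": K.TAU_H_SYM_EXPONENTIAL,
    "affine": K.TAU_H_AFFINE,
    "piecewise_affine": K.TAU_H_PIECEWISE_AFFINE,
}

#: validated pH range of the tau_h fits
PH_RANGE = (4.0, 9.0)


@dataclass(frozen=True)
class ASICParams:
    """Gating parameters of one ASIC population.

    The homomeric-native and heteromeric-native constructors carry the
    published steady-state parameters (slopes, half-points, h ceiling)
    and tau_h fits for the two native spinal current types.
    """

    variant: str
    n_m: float
    pH05m: float
    n_h: float
    pH05h: float
    alpha: float
    tau_h_form: str
    tau_h_coeffs: tuple
    E_rev: float = 50.0          # mV
    ca_fraction: float = 0.1     # fraction of current carried by Ca2+
    check_pH_range: bool = True

    def __post_init__(self):
        if not (self.n_m > 0 and self.n_h > 0 and self.alpha > 0):
            raise ValueError("n_m, n_h and alpha must be positive")
        if not 0.0 <= self.ca_fraction <= 1.0:
            raise ValueError("ca_fraction must lie in [0, 1]")
        if self.tau_h_form not in _TAU_FORMS:
            raise ValueError(f"unknown tau_h_form {self.tau_h_form!r}")

    @classmethod
    def homomeric_native(cls, **overrides) -> "ASICParams":
        defaults = dict(
            variant="homomeric_native",
            n_m=1.5, pH05m=6.46, n_h=4.6, pH05h=7.3, alpha=1.3,
            tau_h_form="biased_gaussian",
            # a1 [s], a2 [pH^-2], b2 [pH], a3 [s/pH], b3 [s]
            tau_h_coeffs=(49.196, 34.632, 7.144, 0.95, 3.77),
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def heteromeric_native(cls, **overrides) -> "ASICParams":
        defaults = dict(
            variant="heteromeric_native",
            n_m=1.94, pH05m=6.03, n_h=3.82, pH05h=6.74, alpha=1.0,
            tau_h_form="symmetrized_exponential",
            # amplitude [s], rate [pH^-1], center [pH], offset [s]
            tau_h_coeffs=(42.862, 5.375, 6.6, 1.645),
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_variant(cls, variant: str, **overrides) -> "ASICParams":
        if variant in ("homomeric", "homomeric_native"):
            return cls.homomeric_native(**overrides)
        if variant in ("heteromeric", "heteromeric_native"):
            return cls.heteromeric_native(**overrides)
        raise ValueError(f"unknown ASIC variant {variant!r}")

    def _tau_coeffs5(self):
        c = list(self.tau_h_coeffs) + [0.0] * 5
        return tuple(c[:5])


@dataclass
class ASICState:
    """Inactivation level and gating mode of one ASIC population."""

    h: float
    mode: str = "dynamic"  # "dynamic" or "mittx"

    @classmethod
    def resting(cls, params: ASICParams, pH: float = 7.4, mode: str = "dynamic"):
        return cls(h=h_inf(pH, params), mode=mode)


def _check_pH(pH) -> float:
    pH = float(pH)
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    return pH


def m_inf(pH: float, params: ASICParams) -> float:
    """Steady-state activation at a given pH (dimensionless, in (0, 1))."""
    return K.asic_m_inf(_check_pH(pH), params.n_m, params.pH05m)


def h_inf(pH: float, params: ASICParams) -> float:
    """Steady-state inactivation at a given pH (in (0, alpha))."""
    return K.asic_h_inf(_check_pH(pH), params.n_h, params.pH05h, params.alpha)


def tau_h(pH: float, params: ASICParams) -> float:
    """Inactivation time constant in seconds at a given pH.

    The fits are validated on pH in [4, 9]; outside that range a
    ``ValueError`` is raised unless ``params.check_pH_range`` is False,
    in which case a 1 ms positivity floor applies.
    """
    pH = _check_pH(pH)
    if params.check_pH_range and not (PH_RANGE[0] <= pH <= PH_RANGE[1]):
        raise ValueError(f"pH {pH} outside validated range {PH_RANGE}")
    c = params._tau_coeffs5()
    return K.asic_tau_h_s(pH, _TAU_FORMS[params.tau_h_form], *c)


def step_gating(state: ASICState, pH: float, dt: float, params: ASICParams) -> ASICState:
    """Advance the gating state by ``dt`` ms at the given cleft pH.

    Activation is instantaneous so it carries no state; inactivation h
    relaxes toward h_inf(pH) with the exact exponential update, which is
    step-size independent at fixed pH.  In ``mittx`` mode the channel is
    locked open and the state is returned unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.mode == "mittx":
        return ASICState(h=state.h, mode="mittx")
    pH = _check_pH(pH)
    c = params._tau_coeffs5()
    h_new = K.asic_h_step(state.h, pH, dt, params.n_h, params.pH05h,
                          params.alpha, _TAU_FORMS[params.tau_h_form], *c)
    return ASICState(h=h_new, mode="dynamic")


def asic_current(state: ASICState, pH: float, V: float, g_max: float,
                 params: ASICParams) -> tuple[float, float]:
    """ASIC current in pA: returns ``(I_total, I_ca)``.

    ``I_total = g_max * m * h * (V - E_rev)`` with g in nS and V in mV;
    the calcium component is ``ca_fraction * I_total``.  In mittx mode
    the open fraction is 1 and the current is pH-independent.
    """
    if g_max < 0:
        raise ValueError("g_max must be non-negative")
    if state.mode == "mittx":
        open_frac = 1.0
    else:
        open_frac = m_inf(pH, params) * state.h
    I_total = g_max * open_frac * (V - params.E_rev)
    return I_total, params.ca_fraction * I_total


# ---------------------------------------------------------------------------
# Standard characterization protocols
# ---------------------------------------------------------------------------


def steady_state_curves(params: ASICParams, pH_grid: np.ndarray | None = None) -> pd.DataFrame:
    """m_inf, h_inf, tau_h and relative conductance over a pH grid."""
    if pH_grid is None:
        pH_grid = np.linspace(PH_RANGE[0], PH_RANGE[1], 5001)
    pH_grid = np.asarray(pH_grid, dtype=float)
    m = np.array([m_inf(p, params) for p in pH_grid])
    h = np.array([h_inf(p, params) for p in pH_grid])
    t = np.array([tau_h(p, params) for p in pH_grid])
    prod = m * h
    g_rel = prod / prod.max() if prod.max() > 0 else prod
    return pd.DataFrame(
        {"pH": pH_grid, "m_inf": m, "h_inf": h, "tau_h_s": t, "g_rel": g_rel}
    )


def peak_product_pH(params: ASICParams, resolution: float = 0.001) -> float:
    """pH maximizing the steady-state open probability m_inf*h_inf."""
    n = int(round((PH_RANGE[1] - PH_RANGE[0]) / resolution)) + 1
    tab = steady_state_curves(params, np.linspace(*PH_RANGE, n))
    return float(tab.loc[(tab.m_inf * tab.h_inf).idxmax(), "pH"])


def activation_curve(params: ASICParams, test_pH: Sequence[float] | None = None,
                     cond_pH: float = 7.4) -> pd.DataFrame:
    """Peak relative conductance after a step from a conditioning pH.

    The channel is held at ``cond_pH`` until h equilibrates, then stepped
    to each test pH.  Activation is instantaneous and inactivation slow,
    so the peak open fraction is ``m_inf(test) * h_inf(cond)``; the curve
    is normalized to its own maximum.
    """
    if test_pH is None:
        test_pH = np.arange(4.0, 8.0 + 1e-9, 0.05)
    test_pH = np.asarray(test_pH, dtype=float)
    h0 = h_inf(cond_pH, params)
    peak = np.array([m_inf(p, params) * h0 for p in test_pH])
    g_rel = peak / peak.max() if peak.max() > 0 else peak
    return pd.DataFrame({"pH": test_pH, "g_peak": peak, "g_rel": g_rel})


def recovery_from_inactivation(params: ASICParams,
                               intervals_ms: Sequence[float],
                               cond_pH: float = 7.4,
                               test_pH: float = 6.0) -> pd.DataFrame:
    """Recovery of the peak test response vs inter-stimulus interval.

    Two identical acid test steps (to ``test_pH``) separated by a
    recovery interval at ``cond_pH``.  The first step fully inactivates
    the channel to ``h_inf(test_pH)``; during the interval h recovers
    toward ``h_inf(cond_pH)`` with ``tau_h(cond_pH)``.  The reported
    fraction is the second peak relative to the first, which reduces to
    ``h(interval) / h_inf(cond_pH)``.
    """
    h_cond = h_inf(cond_pH, params)
    h_test = h_inf(test_pH, params)
    tau_ms = tau_h(cond_pH, params) * 1000.0
    out = []
    for delta in intervals_ms:
        h_rec = h_cond + (h_test - h_cond) * math.exp(-float(delta) / tau_ms)
        out.append((float(delta), h_rec / h_cond))
    return pd.DataFrame(out, columns=["interval_ms", "recovery_fraction"])


def characterization_protocols(params: ASICParams) -> dict[str, pd.DataFrame]:
    """Run the standard channel characterization battery.

    Returns the steady-state curve table, the pH-dependent activation
    curve (conditioning at pH 7.4), and recovery from inactivation at
    pH 7.4 after a pH 6.0 test step.
    """
    intervals = np.concatenate([[0.0], np.logspace(1, 5.2, 40)])
    return {
        "steady_state": steady_state_curves(params),
        "activation": activation_curve(params),
        "recovery": recovery_from_inactivation(params, intervals),
    }
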