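"""Numba-compiled scalar kernels.

Every formula that appears both in the public module API and in the
simulation engine lives here exactly once, as an ``@njit`` scalar
function.  The Python-level wrappers in :mod:`windup_asic.asic` and
:mod:`windup_asic.cleft` call these, and the engine inlines them inside
its compiled loop, so there is no risk of the two drifting apart.
"""

import math

from numba import njit

# ---------------------------------------------------------------------------
# ASIC1a gating
# ---------------------------------------------------------------------------

TAU_H_BIASED_GAUSSIAN = 0
TAU_H_SYM_EXPONENTIAL = 1
TAU_H_AFFINE = 2
TAU_H_PIECEWISE_AFFINE = 3

TAU_H_FLOOR_S = 1e-3  # positivity floor (1 ms) when range checking is off


@njit(cache=True)
def asic_m_inf(pH, n_m, pH05m):
    """Steady-state activation: 1 / (1 + 10^(n_m * (pH - pH0.5m)))."""
    return 1.0 / (1.0 + 10.0 ** (n_m * (pH - pH05m)))


@njit(cache=True)
def asic_h_inf(pH, n_h, pH05h, alpha):
    """Steady-state inactivation: alpha / (1 + 10^(-n_h * (pH - pH0.5h)))."""
    return alpha / (1.0 + 10.0 ** (-n_h * (pH - pH05h)))


@njit(cache=True)
def asic_tau_h_s(pH, form, c0, c1, c2, c3, c4):
    """Inactivation time constant in seconds.

    form 0 (biased gaussian, homomeric native):
        tau = c0*exp(-c1*(pH-c2)^2) + c3*pH - c4
    form 1 (symmetrized exponential, heteromeric native):
        tau = c0*exp(-c1*|pH - c2|) + c3
    form 2 (affine):            tau = max(0, -c0*pH + c1)
    form 3 (piecewise affine):  tau = max(0, c0*pH - c1) if pH <= 7.37
                                else max(0, c2*pH + c3)
    A 1 ms floor keeps the result positive outside each fit's validity.
    """
    if form == 0:
        tau = c0 * math.exp(-c1 * (pH - c2) ** 2) + c3 * pH - c4
    elif form == 1:
        tau = c0 * math.exp(-c1 * abs(pH - c2)) + c3
    elif form == 2:
        tau = -c0 * pH + c1
        if tau < 0.0:
            tau = 0.0
    else:
        if pH <= 7.37:
            tau = c0 * pH - c1
        else:
            tau = c2 * pH + c3
        if tau < 0.0:
            tau = 0.0
    if tau < TAU_H_FLOOR_S:
        tau = TAU_H_FLOOR_S
    return tau


@njit(cache=True)
def asic_h_step(h, pH, dt_ms, n_h, pH05h, alpha, form, c0, c1, c2, c3, c4):
    """Exact exponential relaxation of h toward h_inf over dt_ms."""
    hinf = asic_h_inf(pH, n_h, pH05h, alpha)
    tau_ms = asic_tau_h_s(pH, form, c0, c1, c2, c3, c4) * 1000.0
    return hinf + (h - hinf) * math.exp(-dt_ms / tau_ms)


# ---------------------------------------------------------------------------
# Synaptic cleft proton buffering
# ---------------------------------------------------------------------------


@njit(cache=True)
def cleft_buffered_total(H_free, B0, Kd):
    """Total proton concentration H*(1 + B0/(H + Kd)); all in mM."""
    return H_free * (1.0 + B0 / (H_free + Kd))


@njit(cache=True)
def cleft_free_from_total(H_total, B0, Kd):
    """Invert the buffering relation for the free proton concentration.

    Solves H^2 + H*(Kd + B0 - Ht) - Kd*Ht = 0 for its non-negative root
    with the cancellation-safe quadratic formula (the linear coefficient
    b = Kd + B0 - Ht is large and positive in the physiological regime,
    where the naive (-b + sqrt(...))/2 loses all precision).
    """
    if H_total <= 0.0:
        return 0.0
    b = Kd + B0 - H_total
    c = -Kd * H_total
    disc = math.sqrt(b * b - 4.0 * c)
    if b >= 0.0:
        # root = 2c / (-b - disc) (both negative -> positive quotient)
        return -2.0 * c / (b + disc)
    return (-b + disc) / 2.0


@njit(cache=True)
def cleft_dHtotal_dt(H_free, q, H0, tau):
    """Right-hand side of the cleft ODE, mM/ms."""
    return q - (H_free - H0) / tau


@njit(cache=True)
def cleft_substep(H_total, q, dt, n_sub, B0, Kd, H0, tau):
    """Advance H_total over dt (ms) with n_sub explicit-Euler substeps."""
    h = dt / n_sub
    for _ in range(n_sub):
        H_free = cleft_free_from_total(H_total, B0, Kd)
        H_total += h * cleft_dHtotal_dt(H_free, q, H0, tau)
        if H_total < 0.0:
            H_total = 0.0
    return H_total


@njit(cache=True)
def pH_from_free_mM(H_free_mM):
    """pH = -log10 of the free proton concentration expressed in M."""
    return -math.log10(H_free_mM * 1e-3)


# ---------------------------------------------------------------------------
# Synaptic receptor kinetics
# ---------------------------------------------------------------------------


@njit(cache=True)
def dualexp_norm(tau_r, tau_d):
    """Peak normalization so g_max * norm * (e^-t/taud - e^-t/taur) peaks at g_max."""
    tp = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


@njit(cache=True)
def nmda_mg_block(V, mg_mM):
    """Voltage-dependent magnesium block of the NMDA receptor (Jahr-Stevens)."""
    return 1.0 / (1.0 + math.exp(-0.062 * V) * mg_mM / 3.57)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley rate functions (Traub-style, mV and ms)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def na_m_rates(V):
    a = 0.32 * _vtrap(V + 54.0, 4.0)
    b = 0.28 * _vtrap(-(V + 27.0), 5.0)
    return a, b


@njit(cache=True)
def na_h_rates(V):
    a = 0.128 * math.exp(-(V + 50.0) / 18.0)
    b = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
    return a, b


@njit(cache=True)
def k_n_rates(V):
    a = 0.032 * _vtrap(V + 52.0, 5.0)
    b = 0.5 * math.exp(-(V + 57.0) / 40.0)
    return a, b


@njit(cache=True)
def gate_step(x, a, b, dt):
    """Exponential-Euler update of a first-order HH gate."""
    tau = 1.0 / (a + b)
    xinf = a * tau
    return xinf + (x - xinf) * math.exp(-dt / tau)


@njit(cache=True)
def cal_m_inf(V, vh, k):
    return 1.0 / (1.0 + math.exp(-(V - vh) / k))


@njit(cache=True)
def hill2(x, kd):
    """Second-order Hill activation x^2/(x^2+kd^2)."""
    x2 = x * x
    return x2 / (x2 + kd * kd)


@njit(cache=True)
def hilln(x, kd, n):
    """Hill activation of order n."""
    xn = x ** n
    return xn / (xn + kd ** n)
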