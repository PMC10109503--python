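"""Conductance-based WDR projection neuron.

Three electrically coupled compartments: a dendrite carrying the
synaptic machinery and the plateau-potential channels (L-type calcium,
calcium-activated nonspecific cation CaAN, calcium-activated potassium
KCa), a soma with spike-generating Na/K-dr plus KCa and CaL, and an
axon-initial-segment compartment (Na/K-dr) on which spikes are detected.
Each compartment with calcium-carrying channels has a single
intracellular calcium pool with first-order extrusion; the dendritic
pool additionally receives the designated calcium fractions of the
NMDA, NK1 and ASIC currents.

The dendrite is electrotonically remote (thin, weakly coupled), so
synaptic volleys saturate it locally while small sustained currents --
NK1, ASIC, CaAN -- have large leverage on its baseline potential.
Windup arises from the temporal summation of the slow NK1 conductance
(the only accumulator that survives between 1 Hz stimuli), amplified
by the steep low-threshold dendritic CaL window current and by CaAN,
whose slow high-order calcium activation acts as a thresholded
integrator of *sustained* dendritic calcium.  Sustained calcium beyond
that range instead recruits the dendritic KCa conductance, which
hyperpolarizes the dendrite and suppresses windup -- the mechanism by
which large ASIC conductances (or MitTx-locked channels) invert the
sign of their own depolarizing effect.  The shipped parameter set is
calibrated so that, under the reference protocol, the control
simulation evokes fewer than 10 C/post-discharge spikes at the first
stimulus, a monotonically growing windup curve, and no windup when NK1
is removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _core as C
from ._kernels import na_m_rates, na_h_rates, k_n_rates, cal_m_inf, hill2, hilln

__all__ = ["NeuronParams", "NeuronState", "channel_currents",
           "step_neuron", "detect_spikes"]

MAX_DT = 0.025  # ms


def _area_cm2(length_um: float, diam_um: float) -> float:
    return math.pi * diam_um * length_um * 1e-8


@dataclass(frozen=True)
class NeuronParams:
    """Geometry, passive properties and channel densities.

    Geometry in um, specific capacitance in uF/cm2, densities in
    mS/cm2, coupling conductances in nS, calcium parameters in uM / ms.
    The KCa densities (2 soma / 2.5 dendrite mS/cm2) are the published
    tuned values; the remaining densities are calibration parameters of
    the host model.
    """

    # geometry (length, diameter) um
    dend_L: float = 400.0
    dend_diam: float = 1.0
    soma_L: float = 30.0
    soma_diam: float = 30.0
    axon_L: float = 50.0
    axon_diam: float = 1.0

    cm: float = 2.4                # uF/cm2
    g_leak: float = 0.1            # mS/cm2 (all compartments)
    E_leak: float = -65.0          # mV

    # channel densities, mS/cm2
    gNa_soma: float = 60.0
    gNa_axon: float = 180.0
    gKdr_soma: float = 18.0
    gKdr_axon: float = 45.0
    gKCa_soma: float = 2.0         # published tuned value
    gKCa_dend: float = 2.5         # published tuned value
    gCaL_dend: float = 0.04
    gCaL_soma: float = 0.15
    gCaAN_dend: float = 0.08

    # reversals, mV
    E_Na: float = 50.0
    E_K: float = -80.0
    E_Ca: float = 80.0
    E_CaAN: float = 0.0

    # axial coupling, nS
    g_dend_soma: float = 2.0
    g_soma_axon: float = 25.0

    # L-type calcium activation
    cal_vhalf: float = -45.0       # mV, dendritic (low-threshold, Cav1.3-like)
    cal_vhalf_soma: float = -20.0  # mV, somatic (high-threshold)
    cal_k: float = 3.0             # mV
    cal_tau: float = 2.0           # ms

    # calcium dynamics
    kd_kca: float = 12.0           # uM, dendritic KCa half-activation (Hill n=2)
    kd_kca_soma: float = 0.6       # uM, somatic KCa half-activation (saturating)
    kd_can: float = 1.25           # uM, CaAN half-activation
    can_hill: float = 4.0          # CaAN Hill order (sharp ignition)
    ca_gain_dend: float = 2.0e-4   # uM per pA*ms (lumped shell + buffering)
    cal_ca_weight: float = 0.1     # coupling of dendritic CaL flux into the pool
    ca_gain_soma: float = 1.0e-4
    tau_ca_dend: float = 600.0     # ms
    tau_can: float = 2000.0        # ms, slow CaAN activation
    tau_ca_soma: float = 250.0     # ms
    ca_rest: float = 0.05          # uM

    # scale factors used by pharmacological scenarios
    kca_scale: float = 1.0
    nk1_scale: float = 1.0

    def __post_init__(self):
        for name in ("gNa_soma", "gNa_axon", "gKdr_soma", "gKdr_axon",
                     "gKCa_soma", "gKCa_dend", "gCaL_dend", "gCaL_soma",
                     "gCaAN_dend", "g_leak", "kca_scale", "nk1_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- derived absolute quantities -------------------------------------
    @property
    def areas(self) -> tuple[float, float, float]:
        return (_area_cm2(self.dend_L, self.dend_diam),
                _area_cm2(self.soma_L, self.soma_diam),
                _area_cm2(self.axon_L, self.axon_diam))

    @property
    def capacitances_pF(self) -> tuple[float, float, float]:
        ad, as_, aa = self.areas
        return (self.cm * ad * 1e6, self.cm * as_ * 1e6, self.cm * aa * 1e6)

    def packed(self) -> np.ndarray:
        """Flat parameter vector for the compiled kernels (nS, pF, mV)."""
        ad, as_, aa = self.areas
        dens = lambda g, a: g * a * 1e6  # mS/cm2 * cm2 -> nS
        P = np.zeros(C.N_NP)
        P[C.NP_CD], P[C.NP_CS], P[C.NP_CA] = self.capacitances_pF
        P[C.NP_GLD] = dens(self.g_leak, ad)
        P[C.NP_GLS] = dens(self.g_leak, as_)
        P[C.NP_GLA] = dens(self.g_leak, aa)
        P[C.NP_ELEAK] = self.E_leak
        P[C.NP_GNAS] = dens(self.gNa_soma, as_)
        P[C.NP_GNAA] = dens(self.gNa_axon, aa)
        P[C.NP_GKS] = dens(self.gKdr_soma, as_)
        P[C.NP_GKA] = dens(self.gKdr_axon, aa)
        P[C.NP_GKCAD] = dens(self.gKCa_dend, ad) * self.kca_scale
        P[C.NP_GKCAS] = dens(self.gKCa_soma, as_) * self.kca_scale
        P[C.NP_GCALD] = dens(self.gCaL_dend, ad)
        P[C.NP_GCALS] = dens(self.gCaL_soma, as_)
        P[C.NP_GCAND] = dens(self.gCaAN_dend, ad)
        P[C.NP_ENA], P[C.NP_EK] = self.E_Na, self.E_K
        P[C.NP_ECA], P[C.NP_ECAN] = self.E_Ca, self.E_CaAN
        P[C.NP_GDS], P[C.NP_GSA] = self.g_dend_soma, self.g_soma_axon
        P[C.NP_CALVH], P[C.NP_CALK] = self.cal_vhalf, self.cal_k
        P[C.NP_CALTAU] = self.cal_tau
        P[C.NP_KDKCA], P[C.NP_KDCAN] = self.kd_kca, self.kd_can
        P[C.NP_CAGAIND], P[C.NP_CAGAINS] = self.ca_gain_dend, self.ca_gain_soma
        P[C.NP_TAUCAD], P[C.NP_TAUCAS] = self.tau_ca_dend, self.tau_ca_soma
        P[C.NP_CAREST] = self.ca_rest
        P[C.NP_CANTAU] = self.tau_can
        P[C.NP_CALVHS] = self.cal_vhalf_soma
        P[C.NP_CALCAW] = self.cal_ca_weight
        P[C.NP_KDKCAS] = self.kd_kca_soma
        P[C.NP_CANHILL] = self.can_hill
        return P


@dataclass
class NeuronState:
    """Compartment voltages, gating variables and calcium pools."""

    vec: np.ndarray
    spike_times: list = field(default_factory=list)

    @classmethod
    def resting(cls, params: NeuronParams, V0: float | None = None) -> "NeuronState":
        V = params.E_leak if V0 is None else V0
        s = np.zeros(C.N_STATE)
        s[C.SV_VD] = s[C.SV_VS] = s[C.SV_VA] = V
        for idx, rates in ((C.SV_MS, na_m_rates), (C.SV_HS, na_h_rates),
                           (C.SV_NS, k_n_rates), (C.SV_MA, na_m_rates),
                           (C.SV_HA, na_h_rates), (C.SV_NA, k_n_rates)):
            a, b = rates(V)
            s[idx] = a / (a + b)
        s[C.SV_MCALD] = cal_m_inf(V, params.cal_vhalf, params.cal_k)
        s[C.SV_MCALS] = cal_m_inf(V, params.cal_vhalf_soma, params.cal_k)
        s[C.SV_CAD] = s[C.SV_CAS] = params.ca_rest
        s[C.SV_MCAN] = hilln(params.ca_rest, params.kd_can, params.can_hill)
        return cls(vec=s)

    @property
    def V(self) -> np.ndarray:
        """Voltages (dendrite, soma, axon), mV."""
        return self.vec[[C.SV_VD, C.SV_VS, C.SV_VA]]

    @property
    def Ca(self) -> np.ndarray:
        """Calcium pools (dendrite, soma), uM."""
        return self.vec[[C.SV_CAD, C.SV_CAS]]


def channel_currents(state: NeuronState, params: NeuronParams) -> dict[str, float]:
    """Instantaneous intrinsic currents (pA, positive outward).

    Keys are ``<channel>_<compartment>``; the Ca-dependent activations
    are also reported (``mKCa_dend``, ``mCaAN_dend``).
    """
    P = params.packed()
    s = state.vec
    out = {}
    out["leak_dend"] = P[C.NP_GLD] * (s[C.SV_VD] - params.E_leak)
    out["leak_soma"] = P[C.NP_GLS] * (s[C.SV_VS] - params.E_leak)
    out["leak_axon"] = P[C.NP_GLA] * (s[C.SV_VA] - params.E_leak)
    mkca_d = hill2(s[C.SV_CAD], params.kd_kca)
    mcan_d = s[C.SV_MCAN]
    mkca_s = hill2(s[C.SV_CAS], params.kd_kca_soma)
    out["KCa_dend"] = P[C.NP_GKCAD] * mkca_d * (s[C.SV_VD] - params.E_K)
    out["CaAN_dend"] = P[C.NP_GCAND] * mcan_d * (s[C.SV_VD] - params.E_CaAN)
    out["CaL_dend"] = (P[C.NP_GCALD] * s[C.SV_MCALD]
                       * (s[C.SV_VD] - params.E_Ca))
    out["KCa_soma"] = P[C.NP_GKCAS] * mkca_s * (s[C.SV_VS] - params.E_K)
    out["CaL_soma"] = (P[C.NP_GCALS] * s[C.SV_MCALS]
                       * (s[C.SV_VS] - params.E_Ca))
    out["Na_soma"] = (P[C.NP_GNAS] * s[C.SV_MS] ** 3 * s[C.SV_HS]
                      * (s[C.SV_VS] - params.E_Na))
    out["Kdr_soma"] = P[C.NP_GKS] * s[C.SV_NS] ** 4 * (s[C.SV_VS] - params.E_K)
    out["Na_axon"] = (P[C.NP_GNAA] * s[C.SV_MA] ** 3 * s[C.SV_HA]
                      * (s[C.SV_VA] - params.E_Na))
    out["Kdr_axon"] = P[C.NP_GKA] * s[C.SV_NA] ** 4 * (s[C.SV_VA] - params.E_K)
    out["mKCa_dend"] = mkca_d
    out["mCaAN_dend"] = mcan_d
    return out


def step_neuron(state: NeuronState, synaptic_currents, dt: float,
                params: NeuronParams, ca_current_dend: float = 0.0) -> NeuronState:
    """Advance the neuron one step of ``dt`` ms (dt <= 0.025).

    ``synaptic_currents`` is a length-3 sequence of external currents
    (pA, positive outward) applied to dendrite, soma and axon;
    ``ca_current_dend`` is the calcium-carrying part of the dendritic
    external current.  Raises ``RuntimeError`` on numerical divergence.
    """
    if not (0 < dt <= MAX_DT):
        raise ValueError(f"dt must be in (0, {MAX_DT}] ms")
    I_d, I_s, I_a = (float(x) for x in synaptic_currents)
    s = state.vec.copy()
    status = C.neuron_step(s, I_d, I_s, I_a, float(ca_current_dend),
                           dt, params.packed())
    if status != 0:
        raise RuntimeError(f"membrane potential diverged (|V| > {C.V_ABORT} mV)")
    return NeuronState(vec=s, spike_times=list(state.spike_times))


def detect_spikes(V_trace: np.ndarray, dt: float,
                  threshold: float = 0.0,
                  refractory: float = C.SPIKE_REFRACTORY) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with a lockout.

    ``V_trace`` must be uniformly sampled at ``dt`` ms.  A spike is an
    upward crossing of ``threshold`` (0 mV) occurring at least
    ``refractory`` (2 ms) after the previous accepted spike.
    """
    V = np.asarray(V_trace, dtype=float)
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for i in up:
        t = i * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)
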