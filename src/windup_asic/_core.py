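"""Compiled single-step and full-simulation kernels.

The WDR neuron state and parameters are packed into flat float64 vectors
so both the Python-level ``step_neuron`` API and the fused co-simulation
loop (:func:`simulate`) run through the same compiled code.

State vector layout (SV_*): dendrite/soma/axon voltages, HH gates for
soma and axon, L-type calcium activation per compartment carrying CaL,
and the two intracellular calcium pools.

Sign convention: currents are in pA, positive outward; ``I = g (V - E)``.
"""

import math

import numpy as np
from numba import njit

from ._kernels import (
    asic_m_inf, asic_h_inf, asic_tau_h_s,
    cleft_free_from_total, cleft_dHtotal_dt, pH_from_free_mM,
    na_m_rates, na_h_rates, k_n_rates, gate_step,
    cal_m_inf, hill2, hilln, nmda_mg_block,
)

# --- state vector indices ---------------------------------------------------
SV_VD, SV_VS, SV_VA = 0, 1, 2
SV_MS, SV_HS, SV_NS = 3, 4, 5
SV_MA, SV_HA, SV_NA = 6, 7, 8
SV_MCALD, SV_MCALS = 9, 10
SV_CAD, SV_CAS = 11, 12
SV_MCAN = 13
N_STATE = 14

# --- neuron parameter vector indices ----------------------------------------
NP_CD, NP_CS, NP_CA = 0, 1, 2                    # capacitance, pF
NP_GLD, NP_GLS, NP_GLA = 3, 4, 5                 # leak, nS
NP_ELEAK = 6
NP_GNAS, NP_GNAA = 7, 8                          # Na, nS
NP_GKS, NP_GKA = 9, 10                           # K-dr, nS
NP_GKCAD, NP_GKCAS = 11, 12                      # KCa, nS
NP_GCALD, NP_GCALS = 13, 14                      # CaL, nS
NP_GCAND = 15                                    # CaAN (dendrite), nS
NP_ENA, NP_EK, NP_ECA, NP_ECAN = 16, 17, 18, 19
NP_GDS, NP_GSA = 20, 21                          # axial coupling, nS
NP_CALVH, NP_CALK, NP_CALTAU = 22, 23, 24
NP_KDKCA, NP_KDCAN = 25, 26                      # Hill Kd, uM
NP_CAGAIND, NP_CAGAINS = 27, 28                  # uM per pA*ms
NP_TAUCAD, NP_TAUCAS = 29, 30                    # ms
NP_CAREST = 31                                   # uM
NP_CANTAU = 32                                   # ms, slow CaAN activation
NP_CALVHS = 33                                   # mV, somatic CaL half-activation
NP_CALCAW = 34                                   # CaL coupling weight into dendritic pool
NP_KDKCAS = 35                                   # uM, somatic KCa half-activation
NP_CANHILL = 36                                  # CaAN Hill order
N_NP = 37

# --- receptor row layout (aggregated kernels) --------------------------------
# rows: 0 AMPA(Ad), 1 NMDA(Ad), 2 AMPA(C), 3 NMDA(C), 4 GABAA(C), 5 NK1(C)
RC_GNORM, RC_TAUR, RC_TAUD, RC_EREV, RC_CAFRAC, RC_NMDA = 0, 1, 2, 3, 4, 5
N_RC = 6
N_RECEPTORS = 6

# --- ASIC parameter vector ---------------------------------------------------
AP_NM, AP_PH05M, AP_NH, AP_PH05H, AP_ALPHA = 0, 1, 2, 3, 4
AP_FORM, AP_C0, AP_C1, AP_C2, AP_C3, AP_C4 = 5, 6, 7, 8, 9, 10
AP_EREV, AP_CAFRAC = 11, 12
N_AP = 13

# --- trace column layout ------------------------------------------------------
TR_T, TR_VD, TR_VS, TR_VA, TR_CAD, TR_CAS = 0, 1, 2, 3, 4, 5
TR_PH0, TR_PHMEAN, TR_IASIC, TR_IKCAD, TR_ICAND, TR_ICALD = 6, 7, 8, 9, 10, 11
TR_IAMPA, TR_INMDA, TR_IGABA, TR_INK1, TR_HASIC = 12, 13, 14, 15, 16
N_TRACE = 17

SPIKE_REFRACTORY = 2.0   # ms lockout for threshold-crossing detection
V_ABORT = 200.0          # |V| divergence guard, mV


@njit(cache=True)
def neuron_step(s, I_ext_d, I_ext_s, I_ext_a, I_ca_ext_d, dt, P):
    """Advance the three-compartment neuron by one step of dt ms.

    ``I_ext_*`` are external (synaptic) currents in pA, positive
    outward, treated as constant over the step; intrinsic conductances
    are integrated with exponential-Euler per compartment.
    ``I_ca_ext_d`` is the external calcium-carrying current (pA) added
    to the dendritic pool source (inward negative).  Returns 0, or 1 on
    numerical divergence.
    """
    Vd, Vs, Va = s[SV_VD], s[SV_VS], s[SV_VA]
    Cad, Cas = s[SV_CAD], s[SV_CAS]

    # --- conductances (nS) and their reversals per compartment -----------
    mkca_d = hill2(Cad, P[NP_KDKCA])
    mcan_d = s[SV_MCAN]
    mkca_s = hill2(Cas, P[NP_KDKCAS])

    g_cal_d = P[NP_GCALD] * s[SV_MCALD]
    g_kca_d = P[NP_GKCAD] * mkca_d
    g_can_d = P[NP_GCAND] * mcan_d

    g_na_s = P[NP_GNAS] * s[SV_MS] ** 3 * s[SV_HS]
    g_k_s = P[NP_GKS] * s[SV_NS] ** 4
    g_kca_s = P[NP_GKCAS] * mkca_s
    g_cal_s = P[NP_GCALS] * s[SV_MCALS]

    g_na_a = P[NP_GNAA] * s[SV_MA] ** 3 * s[SV_HA]
    g_k_a = P[NP_GKA] * s[SV_NA] ** 4

    # --- dendrite ---------------------------------------------------------
    Gd = P[NP_GLD] + g_cal_d + g_kca_d + g_can_d + P[NP_GDS]
    GEd = (P[NP_GLD] * P[NP_ELEAK] + g_cal_d * P[NP_ECA]
           + g_kca_d * P[NP_EK] + g_can_d * P[NP_ECAN] + P[NP_GDS] * Vs)
    Vinf_d = (GEd - I_ext_d) / Gd
    Vd_new = Vinf_d + (Vd - Vinf_d) * math.exp(-dt * Gd / P[NP_CD])

    # --- soma -------------------------------------------------------------
    Gs = (P[NP_GLS] + g_na_s + g_k_s + g_kca_s + g_cal_s
          + P[NP_GDS] + P[NP_GSA])
    GEs = (P[NP_GLS] * P[NP_ELEAK] + g_na_s * P[NP_ENA]
           + (g_k_s + g_kca_s) * P[NP_EK] + g_cal_s * P[NP_ECA]
           + P[NP_GDS] * Vd + P[NP_GSA] * Va)
    Vinf_s = (GEs - I_ext_s) / Gs
    Vs_new = Vinf_s + (Vs - Vinf_s) * math.exp(-dt * Gs / P[NP_CS])

    # --- axon -------------------------------------------------------------
    Ga = P[NP_GLA] + g_na_a + g_k_a + P[NP_GSA]
    GEa = (P[NP_GLA] * P[NP_ELEAK] + g_na_a * P[NP_ENA]
           + g_k_a * P[NP_EK] + P[NP_GSA] * Vs)
    Vinf_a = (GEa - I_ext_a) / Ga
    Va_new = Vinf_a + (Va - Vinf_a) * math.exp(-dt * Ga / P[NP_CA])

    # --- gating (exponential Euler at the pre-step voltages) -------------
    a, b = na_m_rates(Vs); s[SV_MS] = gate_step(s[SV_MS], a, b, dt)
    a, b = na_h_rates(Vs); s[SV_HS] = gate_step(s[SV_HS], a, b, dt)
    a, b = k_n_rates(Vs);  s[SV_NS] = gate_step(s[SV_NS], a, b, dt)
    a, b = na_m_rates(Va); s[SV_MA] = gate_step(s[SV_MA], a, b, dt)
    a, b = na_h_rates(Va); s[SV_HA] = gate_step(s[SV_HA], a, b, dt)
    a, b = k_n_rates(Va);  s[SV_NA] = gate_step(s[SV_NA], a, b, dt)

    minf = cal_m_inf(Vd, P[NP_CALVH], P[NP_CALK])
    s[SV_MCALD] = minf + (s[SV_MCALD] - minf) * math.exp(-dt / P[NP_CALTAU])
    minf = cal_m_inf(Vs, P[NP_CALVHS], P[NP_CALK])
    s[SV_MCALS] = minf + (s[SV_MCALS] - minf) * math.exp(-dt / P[NP_CALTAU])

    # slow calcium-activated nonspecific cation (CAN) activation
    can_inf = hilln(Cad, P[NP_KDCAN], P[NP_CANHILL])
    s[SV_MCAN] = can_inf + (s[SV_MCAN] - can_inf) * math.exp(-dt / P[NP_CANTAU])

    # --- calcium pools ----------------------------------------------------
    i_cal_d = g_cal_d * (Vd - P[NP_ECA])
    influx_d = -(P[NP_CALCAW] * i_cal_d + I_ca_ext_d)
    if influx_d < 0.0:
        influx_d = 0.0
    s[SV_CAD] = Cad + dt * (P[NP_CAGAIND] * influx_d
                            - (Cad - P[NP_CAREST]) / P[NP_TAUCAD])

    i_cal_s = g_cal_s * (Vs - P[NP_ECA])
    influx_s = -i_cal_s
    if influx_s < 0.0:
        influx_s = 0.0
    s[SV_CAS] = Cas + dt * (P[NP_CAGAINS] * influx_s
                            - (Cas - P[NP_CAREST]) / P[NP_TAUCAS])

    s[SV_VD], s[SV_VS], s[SV_VA] = Vd_new, Vs_new, Va_new
    if (abs(Vd_new) > V_ABORT or abs(Vs_new) > V_ABORT
            or abs(Va_new) > V_ABORT):
        return 1
    return 0


@njit(cache=True)
def simulate(n_steps, dt, rec_every,
             s, P,
             R,                      # (6, N_RC) receptor table
             ev_ad, ev_c,            # sorted fan-out event times, ms
             pulse_starts,           # (n_cleft, n_stims) per-cleft pulse starts
             B0, Kd, H0, q_amp, pulse_dur, tau_cleft, n_sub,
             g_asic, mittx, A,
             mg_mM,
             spikes, trace):
    """Fused co-simulation of neuron, synapses, clefts and ASIC gating.

    Returns ``(n_spikes, status)``; status 0 = ok, 1 = divergence (the
    abort time is written to ``spikes[n_spikes]`` in that case).
    """
    n_cleft = pulse_starts.shape[0]

    # receptor kernel state: rise/decay accumulators per receptor row
    xr = np.zeros(N_RECEPTORS)
    xd = np.zeros(N_RECEPTORS)
    dec_r = np.empty(N_RECEPTORS)
    dec_d = np.empty(N_RECEPTORS)
    for k in range(N_RECEPTORS):
        dec_r[k] = math.exp(-dt / R[k, RC_TAUR])
        dec_d[k] = math.exp(-dt / R[k, RC_TAUD])

    # cleft state
    Ht = np.empty(n_cleft)
    pH = np.empty(n_cleft)
    Ht0 = H0 * (1.0 + B0 / (H0 + Kd))
    for i in range(n_cleft):
        Ht[i] = Ht0
        pH[i] = pH_from_free_mM(H0)
    pulse_ptr = np.zeros(n_cleft, dtype=np.int64)

    # ASIC state
    h_asic = np.empty(n_cleft)
    h0 = asic_h_inf(7.4, A[AP_NH], A[AP_PH05H], A[AP_ALPHA])
    for i in range(n_cleft):
        h_asic[i] = h0

    ia, ic = 0, 0                 # event pointers
    n_spk = 0
    last_spike = -1e9
    prev_va = s[SV_VA]
    dt_sub = dt / n_sub
    i_rec = 0

    for step in range(n_steps):
        t = step * dt

        # 1. deliver synaptic events due by the end of this step
        while ia < ev_ad.shape[0] and ev_ad[ia] <= t:
            xr[0] += 1.0; xd[0] += 1.0
            xr[1] += 1.0; xd[1] += 1.0
            ia += 1
        while ic < ev_c.shape[0] and ev_c[ic] <= t:
            for k in range(2, 6):
                xr[k] += 1.0; xd[k] += 1.0
            ic += 1

        # 2. cleft ODE substeps (pulse source constant per substep)
        for i in range(n_cleft):
            ht = Ht[i]
            p = pulse_ptr[i]
            for j in range(n_sub):
                ts = t + j * dt_sub
                while (p < pulse_starts.shape[1]
                       and ts >= pulse_starts[i, p] + pulse_dur):
                    p += 1
                q = 0.0
                if (p < pulse_starts.shape[1]
                        and pulse_starts[i, p] <= ts):
                    q = q_amp
                hf = cleft_free_from_total(ht, B0, Kd)
                ht += dt_sub * cleft_dHtotal_dt(hf, q, H0, tau_cleft)
                if ht < 0.0:
                    ht = 0.0
            pulse_ptr[i] = p
            Ht[i] = ht
            pH[i] = pH_from_free_mM(cleft_free_from_total(ht, B0, Kd))

        # 3. ASIC gating and current (dendrite)
        Vd = s[SV_VD]
        I_asic = 0.0
        I_asic_ca = 0.0
        if g_asic > 0.0:
            for i in range(n_cleft):
                if mittx == 1:
                    open_frac = 1.0
                else:
                    tau_ms = asic_tau_h_s(pH[i], int(A[AP_FORM]), A[AP_C0],
                                          A[AP_C1], A[AP_C2], A[AP_C3],
                                          A[AP_C4]) * 1000.0
                    hinf = asic_h_inf(pH[i], A[AP_NH], A[AP_PH05H], A[AP_ALPHA])
                    h_asic[i] = hinf + (h_asic[i] - hinf) * math.exp(-dt / tau_ms)
                    open_frac = asic_m_inf(pH[i], A[AP_NM], A[AP_PH05M]) * h_asic[i]
                I_asic += g_asic * open_frac * (Vd - A[AP_EREV])
            I_asic_ca = A[AP_CAFRAC] * I_asic

        # 4. receptor conductances and currents (all on the dendrite)
        B = nmda_mg_block(Vd, mg_mM)
        I_syn = 0.0
        I_syn_ca = 0.0
        i_ampa = 0.0; i_nmda = 0.0; i_gaba = 0.0; i_nk1 = 0.0
        for k in range(N_RECEPTORS):
            g = R[k, RC_GNORM] * (xd[k] - xr[k])
            if g < 0.0:
                g = 0.0
            if R[k, RC_NMDA] == 1.0:
                g *= B
            i_k = g * (Vd - R[k, RC_EREV])
            I_syn += i_k
            I_syn_ca += R[k, RC_CAFRAC] * i_k
            if k == 0 or k == 2:
                i_ampa += i_k
            elif k == 1 or k == 3:
                i_nmda += i_k
            elif k == 4:
                i_gaba += i_k
            else:
                i_nk1 += i_k
            xr[k] *= dec_r[k]
            xd[k] *= dec_d[k]

        # 5. record (pre-step values of this instant)
        if rec_every > 0 and step % rec_every == 0 and i_rec < trace.shape[0]:
            mkca_d = hill2(s[SV_CAD], P[NP_KDKCA])
            mcan_d = s[SV_MCAN]
            gcal_d = P[NP_GCALD] * s[SV_MCALD]
            trace[i_rec, TR_T] = t
            trace[i_rec, TR_VD] = s[SV_VD]
            trace[i_rec, TR_VS] = s[SV_VS]
            trace[i_rec, TR_VA] = s[SV_VA]
            trace[i_rec, TR_CAD] = s[SV_CAD]
            trace[i_rec, TR_CAS] = s[SV_CAS]
            trace[i_rec, TR_PH0] = pH[0]
            ph_sum = 0.0
            for i in range(n_cleft):
                ph_sum += pH[i]
            trace[i_rec, TR_PHMEAN] = ph_sum / n_cleft
            trace[i_rec, TR_IASIC] = I_asic
            trace[i_rec, TR_IKCAD] = P[NP_GKCAD] * mkca_d * (s[SV_VD] - P[NP_EK])
            trace[i_rec, TR_ICAND] = P[NP_GCAND] * mcan_d * (s[SV_VD] - P[NP_ECAN])
            trace[i_rec, TR_ICALD] = gcal_d * (s[SV_VD] - P[NP_ECA])
            trace[i_rec, TR_IAMPA] = i_ampa
            trace[i_rec, TR_INMDA] = i_nmda
            trace[i_rec, TR_IGABA] = i_gaba
            trace[i_rec, TR_INK1] = i_nk1
            h_sum = 0.0
            for i in range(n_cleft):
                h_sum += h_asic[i]
            trace[i_rec, TR_HASIC] = h_sum / n_cleft
            i_rec += 1

        # 6. neuron step
        status = neuron_step(s, I_syn + I_asic, 0.0, 0.0,
                             I_syn_ca + I_asic_ca, dt, P)
        if status != 0:
            if n_spk < spikes.shape[0]:
                spikes[n_spk] = t
            return n_spk, 1

        # 7. spike detection on the axonal compartment
        va = s[SV_VA]
        if prev_va < 0.0 <= va and (t + dt) - last_spike >= SPIKE_REFRACTORY:
            if n_spk < spikes.shape[0]:
                spikes[n_spk] = t + dt
                n_spk += 1
            last_spike = t + dt
        prev_va = va

    return n_spk, 0
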