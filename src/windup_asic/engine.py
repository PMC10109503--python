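"""Scenario construction and windup-protocol execution.

A scenario is the full model of one simulated experiment: the WDR
neuron, 20 A-delta and 20 C-fiber synapses with per-synapse conduction
delays, one synaptic cleft per C synapse (optionally a single shared
cleft), and a postsynaptic ASIC population at each C synapse.  The
reference protocol delivers 15 stimulations 1 s apart starting at 1 s;
each stimulation produces one presynaptic event per fiber, fanned out to
its 20 synapses after their delays.  Pharmacological variants are
expressed as configuration: ASIC conductance and variant, the MitTx
locked-open mode, calcium-free ASICs, KCa block, NK1 removal, and
alternative cleft parameter sets.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import _core as C
from .asic import ASICParams, _TAU_FORMS
from .cleft import CleftParams, EVENT_REFRACTORY
from .metrics import SpikeTable, WindupCurve, classify_spikes, windup_curve
from .neuron import NeuronParams, NeuronState
from .synapses import RECEPTORS, assign_delays

__all__ = [
    "StimProtocol", "ScenarioConfig", "Scenario", "SimulationResult",
    "ScanCriteria", "build_scenario", "run_windup", "conductance_sweep",
    "parameter_scan",
]

G_ASIC_MAX = 15.0  # nS, upper end of the explored per-synapse range


@dataclass(frozen=True)
class StimProtocol:
    """Stimulation timing: n stimuli at fixed period from a start time."""

    n_stims: int = 15
    period: float = 1000.0      # ms
    first_stim: float = 1000.0  # ms
    total_duration: float | None = None

    def __post_init__(self):
        if self.n_stims < 1 or self.period <= 0:
            raise ValueError("need n_stims >= 1 and period > 0")
        if self.total_duration is None:
            object.__setattr__(self, "total_duration",
                               self.first_stim + self.n_stims * self.period)

    @property
    def stim_times(self) -> np.ndarray:
        return self.first_stim + self.period * np.arange(self.n_stims)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one simulated experiment."""

    asic_variant: str = "none"       # none | homomeric | heteromeric
    g_asic: float = 0.0              # nS per C synapse
    ca_fraction: float = 0.1         # ASIC calcium fraction (0 = no-Ca)
    mittx: bool = False              # locked-open ASIC mode
    kca_scale: float = 1.0           # 0 = KCa block (apamin + iberiotoxin)
    nk1_scale: float = 1.0           # 0 = NK1 removal
    cleft: CleftParams = field(default_factory=CleftParams)
    shared_cleft: bool = False       # one global cleft instead of 20
    neuron: NeuronParams = field(default_factory=NeuronParams)
    protocol: StimProtocol = field(default_factory=StimProtocol)
    seed: int = 0
    dt: float = 0.025                # ms
    rec_dt: float = 1.0              # trace decimation, ms

    def __post_init__(self):
        if self.asic_variant not in ("none", "homomeric", "heteromeric"):
            raise ValueError(
                f"asic_variant: unknown value {self.asic_variant!r}")
        if not 0.0 <= self.g_asic <= G_ASIC_MAX:
            raise ValueError(f"g_asic: must lie in [0, {G_ASIC_MAX}] nS")
        if not 0.0 <= self.ca_fraction <= 1.0:
            raise ValueError("ca_fraction: must lie in [0, 1]")
        if not (0 < self.dt <= 0.025):
            raise ValueError("dt: must lie in (0, 0.025] ms")
        if self.kca_scale < 0 or self.nk1_scale < 0:
            raise ValueError("kca_scale/nk1_scale: must be non-negative")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Spike times plus decimated traces from one scenario run."""

    spike_times: np.ndarray            # ms
    trace: pd.DataFrame
    stim_times: np.ndarray
    config: ScenarioConfig

    @property
    def n_stims(self) -> int:
        return len(self.stim_times)

    def spike_table(self, neuron_id: int = 0) -> SpikeTable:
        return SpikeTable.from_spike_times(
            self.spike_times, self.stim_times,
            period_ms=self.config.protocol.period, neuron_id=neuron_id)

    def windup(self) -> WindupCurve:
        labeled = classify_spikes(self.spike_table())
        return windup_curve(labeled, self.n_stims)

    def manifest(self) -> dict:
        return {"config_hash": self.config.config_hash(),
                "seed": self.config.seed,
                "n_spikes": int(len(self.spike_times))}


_TRACE_COLUMNS = {
    C.TR_T: "t_ms", C.TR_VD: "V_dend", C.TR_VS: "V_soma", C.TR_VA: "V_axon",
    C.TR_CAD: "Ca_dend", C.TR_CAS: "Ca_soma", C.TR_PH0: "pH_cleft0",
    C.TR_PHMEAN: "pH_mean", C.TR_IASIC: "I_ASIC", C.TR_IKCAD: "I_KCa_dend",
    C.TR_ICAND: "I_CaAN_dend", C.TR_ICALD: "I_CaL_dend",
    C.TR_IAMPA: "I_AMPA", C.TR_INMDA: "I_NMDA", C.TR_IGABA: "I_GABAA",
    C.TR_INK1: "I_NK1", C.TR_HASIC: "h_ASIC_mean",
}


class Scenario:
    """An assembled, runnable model (see :func:`build_scenario`)."""

    N_SYN_PER_FIBER = 20

    def __init__(self, config: ScenarioConfig):
        self.config = config
        n = self.N_SYN_PER_FIBER
        self.delays_ad = assign_delays(n, "Adelta", config.seed)
        self.delays_c = assign_delays(n, "C", config.seed)

        if config.asic_variant == "none":
            # placeholder parameter set; zero conductance
            self.asic_params = ASICParams.homomeric_native(
                ca_fraction=config.ca_fraction)
            self.g_asic = 0.0
        else:
            self.asic_params = ASICParams.from_variant(
                config.asic_variant, ca_fraction=config.ca_fraction)
            self.g_asic = config.g_asic

        self.neuron_params = replace(
            config.neuron, kca_scale=config.kca_scale,
            nk1_scale=config.nk1_scale)

    # -- packing ----------------------------------------------------------
    def _receptor_table(self) -> np.ndarray:
        R = np.zeros((C.N_RECEPTORS, C.N_RC))
        rows = [("AMPA", 1.0), ("NMDA", 1.0),          # A-delta
                ("AMPA", 1.0), ("NMDA", 1.0),
                ("GABAA", 1.0), ("NK1", self.config.nk1_scale)]
        for k, (name, scale) in enumerate(rows):
            r = RECEPTORS[name]
            R[k, C.RC_GNORM] = r.g_max * r.norm * scale
            R[k, C.RC_TAUR] = r.tau_rise
            R[k, C.RC_TAUD] = r.tau_decay
            R[k, C.RC_EREV] = r.E_rev
            R[k, C.RC_CAFRAC] = r.ca_fraction
            R[k, C.RC_NMDA] = 1.0 if name == "NMDA" else 0.0
        return R

    def _asic_vector(self) -> np.ndarray:
        p = self.asic_params
        A = np.zeros(C.N_AP)
        A[C.AP_NM], A[C.AP_PH05M] = p.n_m, p.pH05m
        A[C.AP_NH], A[C.AP_PH05H], A[C.AP_ALPHA] = p.n_h, p.pH05h, p.alpha
        A[C.AP_FORM] = _TAU_FORMS[p.tau_h_form]
        c5 = p._tau_coeffs5()
        A[C.AP_C0:C.AP_C0 + 5] = c5
        A[C.AP_EREV], A[C.AP_CAFRAC] = p.E_rev, p.ca_fraction
        return A

    def _events(self, protocol: StimProtocol):
        stim = protocol.stim_times
        ev_ad = np.sort((stim[:, None] + self.delays_ad[None, :]).ravel())
        ev_c = np.sort((stim[:, None] + self.delays_c[None, :]).ravel())
        if self.config.shared_cleft:
            # one global cleft: coalesce events within the refractory window
            starts = []
            for t in ev_c:
                if not starts or t - starts[-1] >= EVENT_REFRACTORY:
                    starts.append(t)
            pulse_starts = np.asarray(starts)[None, :]
        else:
            pulse_starts = stim[None, :] + self.delays_c[:, None]
        return ev_ad, ev_c, np.ascontiguousarray(pulse_starts, dtype=float)

    # -- execution --------------------------------------------------------
    def run(self, protocol: StimProtocol | None = None) -> SimulationResult:
        cfg = self.config
        protocol = protocol or cfg.protocol
        dt = cfg.dt
        n_steps = int(round(protocol.total_duration / dt))
        rec_every = max(1, int(round(cfg.rec_dt / dt)))
        n_rec = n_steps // rec_every + 1

        state = NeuronState.resting(self.neuron_params)
        s = state.vec.copy()
        P = self.neuron_params.packed()
        R = self._receptor_table()
        ev_ad, ev_c, pulse_starts = self._events(protocol)
        cl = cfg.cleft
        n_sub = max(1, int(math.ceil(dt / 0.005)))
        spikes = np.zeros(200_000)
        trace = np.zeros((n_rec, C.N_TRACE))

        n_spk, status = C.simulate(
            n_steps, dt, rec_every, s, P, R, ev_ad, ev_c, pulse_starts,
            cl.B0, cl.Kd, cl.H0, cl.q_amp, cl.pulse_dur, cl.tau, n_sub,
            self.g_asic, 1 if cfg.mittx else 0, self._asic_vector(),
            1.0, spikes, trace)
        if status != 0:
            raise RuntimeError(
                f"simulation diverged at t = {spikes[n_spk]:.3f} ms")

        n_filled = (n_steps + rec_every - 1) // rec_every
        tr = pd.DataFrame(trace[:n_filled],
                          columns=[_TRACE_COLUMNS[i] for i in range(C.N_TRACE)])
        return SimulationResult(spike_times=spikes[:n_spk].copy(), trace=tr,
                                stim_times=protocol.stim_times, config=cfg)


def build_scenario(config: ScenarioConfig) -> Scenario:
    """Assemble neuron + 40 synapses + clefts + ASIC populations."""
    return Scenario(config)


def run_windup(model: Scenario | ScenarioConfig,
               protocol: StimProtocol | None = None) -> SimulationResult:
    """Run the windup protocol on a scenario (built from config if needed)."""
    if isinstance(model, ScenarioConfig):
        model = build_scenario(model)
    return model.run(protocol)


def conductance_sweep(variant: str, g_list, base_config: ScenarioConfig
                      ) -> pd.DataFrame:
    """One windup run per maximal ASIC conductance, identical seed.

    Returns a table with per-g windup summary (input, total, AUC) and
    the per-stimulus counts.
    """
    if len(g_list) == 0:
        raise ValueError("g_list must be non-empty")
    rows = []
    for g in g_list:
        var = "none" if g == 0 else variant
        cfg = replace(base_config, asic_variant=var, g_asic=float(g))
        res = run_windup(cfg)
        curve = res.windup()
        rows.append({"g_asic_nS": float(g), "input": curve.input,
                     "total": curve.total, "auc": curve.auc,
                     "counts": curve.counts.tolist()})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScanCriteria:
    """Validity thresholds for the (q, tau) grid search.

    The published thresholds are not recoverable from the source, so
    these defaults are interpretive and configurable: the cleft pH must
    stay at or above ``ph_min`` throughout an ``n_stims_ph``-stimulation
    run, and the windup AUC and last-stimulus count must fall within the
    given relative tolerances of the reference (default-parameter) run.
    """

    ph_min: float = 7.0
    auc_rel_tol: float = 0.25
    count_rel_tol: float = 0.30
    n_stims_ph: int = 100


def parameter_scan(q_grid, tau_grid, base_config: ScenarioConfig,
                   criteria: ScanCriteria | None = None,
                   reference: tuple[float, float] | None = None
                   ) -> pd.DataFrame:
    """Map the validity zones of the cleft source/recovery parameters.

    For every (q, tau) cell: (i) ``ph_ok`` — minimum cleft pH over a
    long (``n_stims_ph``) stimulation train stays above the
    physiological bound; (ii) ``auc_ok`` — windup AUC within tolerance
    of the reference run; (iii) ``count_ok`` — last-stimulus spike count
    within tolerance of the reference run.  ``reference`` is the (q,
    tau) pair defining the reference behavior (default: the
    ``base_config`` cleft values).  q is capped at 2 mM/ms.
    """
    q_grid = list(q_grid)
    tau_grid = list(tau_grid)
    if not q_grid or not tau_grid:
        raise ValueError("grids must be non-empty")
    if any(q > 2.0 for q in q_grid):
        raise ValueError("q is capped at 2 mM/ms")
    criteria = criteria or ScanCriteria()

    if reference is None:
        reference = (base_config.cleft.q_amp, base_config.cleft.tau)
    ref_cfg = replace(base_config,
                      cleft=replace(base_config.cleft,
                                    q_amp=reference[0], tau=reference[1]))
    ref_curve = run_windup(ref_cfg).windup()
    ref_auc = ref_curve.auc
    ref_last = ref_curve.counts[-1]

    long_proto = replace(base_config.protocol, n_stims=criteria.n_stims_ph,
                         total_duration=None)
    rows = []
    for q in q_grid:
        for tau in tau_grid:
            cfg = replace(base_config,
                          cleft=replace(base_config.cleft,
                                        q_amp=float(q), tau=float(tau)))
            res = run_windup(cfg)
            curve = res.windup()
            long_res = run_windup(replace(cfg, protocol=long_proto))
            ph_min_seen = float(long_res.trace["pH_mean"].min())
            ph_ok = ph_min_seen >= criteria.ph_min
            auc_ok = (abs(curve.auc - ref_auc)
                      <= criteria.auc_rel_tol * max(ref_auc, 1e-9))
            count_ok = (abs(curve.counts[-1] - ref_last)
                        <= criteria.count_rel_tol * max(ref_last, 1e-9))
            rows.append({"q_mM_per_ms": float(q), "tau_ms": float(tau),
                         "ph_min": ph_min_seen, "ph_ok": ph_ok,
                         "auc": curve.auc, "auc_ok": auc_ok,
                         "last_count": float(curve.counts[-1]),
                         "count_ok": count_ok,
                         "all_ok": ph_ok and auc_ok and count_ok})
    return pd.DataFrame(rows)
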