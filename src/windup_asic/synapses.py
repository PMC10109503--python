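"""Synaptic inputs to the WDR dendrite.

The model neuron receives 20 A-delta-fiber synapses (AMPA + NMDA) and 20
C-fiber synapses (AMPA + NMDA + GABA_A + NK1, plus a postsynaptic ASIC
population handled in :mod:`windup_asic.asic`).  Each receptor follows a
dual-exponential conductance kernel normalized so its peak equals the
specified maximal conductance; successive activations summate linearly.
The slow NK1 kernel (tau_rise = 150 ms, tau_decay = 3000 ms) summates
strongly at 1 Hz and is the principal slow-depolarization substrate of
windup.  NMDA receptors carry the standard voltage-dependent magnesium
block.  NMDA and NK1 currents feed 10% of their charge into the
dendritic calcium pool, mirroring the ASIC treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K

__all__ = [
    "ReceptorKinetics",
    "SynapseSpec",
    "RECEPTORS",
    "receptor_conductance",
    "nmda_mg_block",
    "assign_delays",
    "default_synapses",
    "synapse_table",
]


@dataclass(frozen=True)
class ReceptorKinetics:
    """Dual-exponential kernel and reversal for one receptor type."""

    name: str
    g_max: float     # nS
    tau_rise: float  # ms
    tau_decay: float # ms
    E_rev: float     # mV
    ca_fraction: float = 0.0

    def __post_init__(self):
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")

    @property
    def norm(self) -> float:
        return K.dualexp_norm(self.tau_rise, self.tau_decay)

    @property
    def peak_time(self) -> float:
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)


# Reference receptor set.  AMPA/NMDA/GABA_A maximal conductances (6, 4,
# 0.3 nS) and the NK1 rise time (150 ms) and conductance (3 pS) are the
# published values; kinetic time constants and reversals are canonical.
RECEPTORS: dict[str, ReceptorKinetics] = {
    "AMPA": ReceptorKinetics("AMPA", 6.0, 0.5, 3.0, 0.0),
    "NMDA": ReceptorKinetics("NMDA", 4.0, 5.0, 80.0, 0.0, ca_fraction=0.1),
    "GABAA": ReceptorKinetics("GABAA", 0.3, 1.0, 10.0, -70.0),
    "NK1": ReceptorKinetics("NK1", 0.003, 150.0, 3000.0, 0.0, ca_fraction=0.1),
}

#: receptor complement per fiber class
FIBER_RECEPTORS = {
    "Adelta": ("AMPA", "NMDA"),
    "C": ("AMPA", "NMDA", "GABAA", "NK1"),
}

#: conduction-delay windows per fiber class, ms (uniform draw). Chosen so
#: monosynaptically evoked spikes land in the A-delta (20-90 ms) and
#: C-fiber (90-350 ms) latency windows.
DELAY_RANGES = {"Adelta": (20.0, 60.0), "C": (120.0, 260.0)}


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse: fiber class, conduction delay, receptor set."""

    fiber: str
    delay: float  # ms
    receptors: tuple = ()

    def __post_init__(self):
        if self.fiber not in FIBER_RECEPTORS:
            raise ValueError(f"unknown fiber class {self.fiber!r}")
        if not self.receptors:
            object.__setattr__(
                self, "receptors",
                tuple(RECEPTORS[r] for r in FIBER_RECEPTORS[self.fiber]))


def receptor_conductance(t_since_activation, spec: ReceptorKinetics):
    """Conductance (nS) of one kernel at time t after a single activation.

    ``g(t) = g_max * N * (exp(-t/tau_decay) - exp(-t/tau_rise))`` with N
    chosen so the peak equals ``g_max``.  Accepts scalars or arrays;
    negative times (before activation) give 0.
    """
    t = np.asarray(t_since_activation, dtype=float)
    g = spec.g_max * spec.norm * (np.exp(-t / spec.tau_decay) - np.exp(-t / spec.tau_rise))
    g = np.where(t < 0, 0.0, g)
    return float(g) if np.isscalar(t_since_activation) else g


def nmda_mg_block(V, mg_mM: float = 1.0):
    """Fraction of NMDA conductance unblocked at membrane potential V (mV)."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    B = 1.0 / (1.0 + np.exp(-0.062 * V) * mg_mM / 3.57)
    return float(B) if B.ndim == 0 else B


def assign_delays(n: int, fiber: str, seed: int) -> np.ndarray:
    """Reproducible per-synapse conduction delays (ms) for one fiber class.

    A-delta delays fall in [20, 60) ms and C delays in [120, 260) ms, so
    every C delay exceeds every A-delta delay and monosynaptic responses
    classify into the intended latency windows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = DELAY_RANGES[fiber]
    rng = np.random.default_rng(seed if fiber == "C" else seed + 1)
    return np.sort(rng.uniform(lo, hi, size=n))


def default_synapses(seed: int, n_per_fiber: int = 20) -> list[SynapseSpec]:
    """The reference 20 + 20 synapse architecture for a given seed."""
    out = []
    for fiber in ("Adelta", "C"):
        for d in assign_delays(n_per_fiber, fiber, seed):
            out.append(SynapseSpec(fiber=fiber, delay=float(d)))
    return out


def synapse_table(synapses: list[SynapseSpec]) -> pd.DataFrame:
    """Audit table (fiber, delay, per-receptor g_max) for a synapse list."""
    rows = []
    for i, s in enumerate(synapses):
        row = {"synapse": i, "fiber": s.fiber, "delay_ms": s.delay}
        for r in s.receptors:
            row[f"g_{r.name}_nS"] = r.g_max
        rows.append(row)
    return pd.DataFrame(rows)
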