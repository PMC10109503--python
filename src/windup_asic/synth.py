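"""Synthetic in vivo WDR recordings.

Emulates the statistical structure of extracellular windup recordings:
per-stimulus spike counts follow a saturating-exponential growth law

    mu_i = N1 + (Nmax - N1) * (1 - exp(-(i - 1) / kappa)),   i = 1..n

with Poisson count noise (optionally negative-binomial for
over-dispersion), spike latencies drawn from truncated log-normals
inside the C-fiber window, configurable A-delta and post-discharge
activity, and paired control/drug conditions in which the drug scales
the expected counts by a programmed inhibition fraction.  The generator
is an emulation device for testing the metrics pipeline, not a
mechanistic model; its defaults follow the recorded phenomenology (a
first-stimulus count below 10 spikes, plateau by the 13th-16th
stimulus of a 16-stimulus 1 Hz train).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import SpikeTable

__all__ = ["SynthConfig", "gen_recording", "gen_paired_cohort", "expected_counts"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters for one cohort of surrogate recordings."""

    n_neurons: int = 15
    n_stims: int = 16
    period_ms: float = 1000.0
    # saturating growth law for the expected C-fiber count
    N1: float = 4.0          # expected count at stimulus 1 (< 10)
    Nmax: float = 25.0       # plateau count
    kappa: float = 3.0       # growth constant, stimuli
    # latency structure (log-normal, truncated to each window)
    c_lat_mu: float = np.log(160.0)
    c_lat_sigma: float = 0.35
    pd_fraction: float = 0.15     # post-discharge counts as fraction of mu_i
    adelta_rate: float = 2.0      # expected A-delta spikes per stimulus
    # noise
    poisson: bool = True
    overdispersion: float = 0.0   # >0 switches to negative binomial
    # drug effect
    inhibition: float = 0.0       # multiplicative inhibition of counts
    inhibit_input: bool = True    # whether stimulus 1 is also inhibited
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.inhibition < 1:
            raise ValueError("inhibition must lie in [0, 1)")
        if self.n_neurons < 1 or self.n_stims < 1:
            raise ValueError("n_neurons and n_stims must be >= 1")


def expected_counts(config: SynthConfig) -> np.ndarray:
    """Expected C-fiber count mu_i per stimulus (before drug scaling)."""
    i = np.arange(1, config.n_stims + 1, dtype=float)
    mu = config.N1 + (config.Nmax - config.N1) * (1.0 - np.exp(-(i - 1) / config.kappa))
    return mu


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 config: SynthConfig) -> np.ndarray:
    if not config.poisson:
        return np.round(mu).astype(int)
    if config.overdispersion > 0:
        # negative binomial with variance mu * (1 + overdispersion)
        r = mu / config.overdispersion
        p = 1.0 / (1.0 + config.overdispersion)
        return rng.negative_binomial(np.maximum(r, 1e-9), p)
    return rng.poisson(mu)


def _truncated_lognormal(rng, mu, sigma, lo, hi, size):
    """Log-normal draws rejected into [lo, hi) (falls back to uniform)."""
    out = np.empty(size)
    filled = 0
    for _ in range(100):
        if filled >= size:
            break
        draw = rng.lognormal(mu, sigma, size=2 * (size - filled) + 8)
        good = draw[(draw >= lo) & (draw < hi)][: size - filled]
        out[filled:filled + len(good)] = good
        filled += len(good)
    if filled < size:
        out[filled:] = rng.uniform(lo, hi, size=size - filled)
    return out


def gen_recording(config: SynthConfig) -> SpikeTable:
    """One cohort of surrogate recordings as a stimulus-aligned table.

    Per neuron and stimulus, the realized C-window count is drawn around
    ``mu_i`` scaled by any programmed inhibition; post-discharge and
    A-delta spikes are added at their configured rates.  All latencies
    fall strictly inside their intended classification windows.
    Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mu = expected_counts(config)
    scale = np.full(config.n_stims, 1.0 - config.inhibition)
    if not config.inhibit_input:
        scale[0] = 1.0
    rows = []
    for nid in range(config.n_neurons):
        c_counts = _draw_counts(rng, mu * scale, config)
        pd_counts = _draw_counts(rng, config.pd_fraction * mu * scale, config)
        ad_counts = _draw_counts(
            rng, np.full(config.n_stims, config.adelta_rate), config)
        for i in range(config.n_stims):
            lat_c = _truncated_lognormal(rng, config.c_lat_mu, config.c_lat_sigma,
                                         90.0, 350.0, int(c_counts[i]))
            lat_pd = rng.uniform(350.0, 1000.0, size=int(pd_counts[i]))
            lat_ad = rng.uniform(20.0, 90.0, size=int(ad_counts[i]))
            for lat in (lat_c, lat_pd, lat_ad):
                for x in lat:
                    rows.append((nid, i + 1, float(x)))
    df = pd.DataFrame(rows, columns=["neuron_id", "stim_index", "latency_ms"])
    return SpikeTable(data=df, n_stims=config.n_stims, period_ms=config.period_ms)


def gen_paired_cohort(config: SynthConfig, inhibition_total: float
                      ) -> tuple[SpikeTable, SpikeTable]:
    """Paired control/drug recordings of the same neurons.

    The drug condition scales the expected counts by
    ``1 - inhibition_total`` and uses fresh noise draws (independent
    sub-seeds of ``config.seed``).
    """
    if not 0 <= inhibition_total < 1:
        raise ValueError("inhibition_total must lie in [0, 1)")
    ss = np.random.SeedSequence(config.seed).spawn(2)
    ctrl_seed, drug_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss)
    control = gen_recording(replace(config, inhibition=0.0, seed=ctrl_seed))
    drug = gen_recording(replace(config, inhibition=inhibition_total,
                                 seed=drug_seed))
    return control, drug
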