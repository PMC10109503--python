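"""Windup quantification from stimulus-aligned spike tables.

Evoked action potentials are classified by their latency after the
stimulation artifact: A-beta [0, 20) ms, A-delta [20, 90) ms, C-fiber
[90, 350) ms, post-discharge [350, 1000) ms (half-open windows; any
latency >= 1000 ms is labeled "other").  The windup curve is the number
of C plus post-discharge spikes per stimulus; its AUC is the trapezoidal
area above the first-stimulus baseline, with negative excess clipped to
zero by default.  The same pipeline applies unchanged to simulated and
recorded (or synthetic) spike tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WINDOWS", "SpikeTable", "WindupCurve",
    "classify_spikes", "windup_curve", "auc", "percent_inhibition",
    "psth", "compare_psth", "mean_curve",
]

#: latency windows, ms (half-open [lo, hi))
WINDOWS = (
    ("Abeta", 0.0, 20.0),
    ("Adelta", 20.0, 90.0),
    ("C", 90.0, 350.0),
    ("postdischarge", 350.0, 1000.0),
)

#: windows contributing to the windup count
WINDUP_WINDOWS = ("C", "postdischarge")


@dataclass
class SpikeTable:
    """Stimulus-aligned spike times for one or more neurons.

    ``data`` has columns (neuron_id, stim_index, latency_ms), stim_index
    1-based; ``n_stims`` and ``period_ms`` describe the protocol.
    """

    data: pd.DataFrame
    n_stims: int
    period_ms: float = 1000.0

    def __post_init__(self):
        required = {"neuron_id", "stim_index", "latency_ms"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"spike table missing columns {sorted(missing)}")
        if len(self.data) and (self.data["latency_ms"] < 0).any():
            raise ValueError("latencies must be non-negative")

    @classmethod
    def from_spike_times(cls, spike_times_ms, stim_times_ms,
                        period_ms: float = 1000.0, neuron_id: int = 0):
        """Build a table from absolute spike times and stimulus times.

        Each spike is assigned to the most recent stimulus at or before
        it; spikes preceding the first stimulus are dropped.
        """
        stim = np.sort(np.asarray(stim_times_ms, dtype=float))
        spk = np.asarray(spike_times_ms, dtype=float)
        idx = np.searchsorted(stim, spk, side="right") - 1
        keep = idx >= 0
        df = pd.DataFrame({
            "neuron_id": neuron_id,
            "stim_index": idx[keep] + 1,
            "latency_ms": spk[keep] - stim[idx[keep]],
        })
        return cls(data=df, n_stims=len(stim), period_ms=period_ms)

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, n_stims: int, period_ms: float = 1000.0):
        return cls(data=pd.read_csv(path), n_stims=n_stims, period_ms=period_ms)


@dataclass
class WindupCurve:
    """Per-stimulus C + post-discharge counts with summary quantities."""

    counts: np.ndarray               # per-stimulus, index 0 = stimulus 1
    clip_baseline: bool = True

    @property
    def n_stims(self) -> int:
        return len(self.counts)

    @property
    def input(self) -> float:
        """Count at the first stimulation (the 'input' of the neuron)."""
        return float(self.counts[0])

    @property
    def total(self) -> float:
        return float(np.sum(self.counts))

    @property
    def auc(self) -> float:
        return auc(self)


def classify_spikes(table: SpikeTable) -> pd.DataFrame:
    """Label each spike with its latency window.

    Returns a copy of the spike table with a ``window`` column in
    {Abeta, Adelta, C, postdischarge, other}.
    """
    lat = table.data["latency_ms"].to_numpy(dtype=float)
    if len(lat) and (lat < 0).any():
        raise ValueError("latencies must be non-negative")
    window = np.full(len(lat), "other", dtype=object)
    for name, lo, hi in WINDOWS:
        window[(lat >= lo) & (lat < hi)] = name
    out = table.data.copy()
    out["window"] = window
    return out


def windup_curve(labeled: pd.DataFrame, n_stims: int,
                 clip_baseline: bool = True) -> WindupCurve:
    """Per-stimulus count of C + post-discharge spikes (zero-filled)."""
    counts = np.zeros(n_stims)
    sel = labeled[labeled["window"].isin(WINDUP_WINDOWS)]
    grouped = sel.groupby("stim_index").size()
    for stim_idx, n in grouped.items():
        i = int(stim_idx) - 1
        if 0 <= i < n_stims:
            counts[i] = n
    return WindupCurve(counts=counts, clip_baseline=clip_baseline)


def auc(curve: WindupCurve) -> float:
    """Trapezoidal area of the windup curve above its first-point baseline.

    The baseline is the count at the first stimulation.  By default the
    excess is clipped at zero pointwise before integration (area above
    baseline); with ``curve.clip_baseline`` False the signed area is
    returned instead.
    """
    if curve.n_stims < 2:
        raise ValueError("need at least 2 stimuli for an AUC")
    excess = curve.counts - curve.counts[0]
    if curve.clip_baseline:
        excess = np.maximum(excess, 0.0)
    return float(np.trapezoid(excess))


def percent_inhibition(control: WindupCurve, drug: WindupCurve
                       ) -> tuple[float, float]:
    """Percent inhibition from total spike count and from AUC.

    Returns ``(pct_total, pct_auc)`` = 100 * (1 - drug/control) for each
    quantity.  A zero control denominator yields NaN for that entry
    rather than raising.
    """
    pct_total = (100.0 * (1.0 - drug.total / control.total)
                 if control.total > 0 else float("nan"))
    ctrl_auc, drug_auc = control.auc, drug.auc
    pct_auc = (100.0 * (1.0 - drug_auc / ctrl_auc)
               if ctrl_auc > 0 else float("nan"))
    return pct_total, pct_auc


def mean_curve(curves: list[WindupCurve]) -> WindupCurve:
    """Average windup curve across neurons (counts become floats)."""
    if not curves:
        raise ValueError("no curves to average")
    n = curves[0].n_stims
    if any(c.n_stims != n for c in curves):
        raise ValueError("curves have mismatched lengths")
    return WindupCurve(counts=np.mean([c.counts for c in curves], axis=0),
                       clip_baseline=curves[0].clip_baseline)


def psth(table: SpikeTable, binwidth: float = 20.0,
         stims: list[int] | None = None) -> pd.DataFrame:
    """Peristimulus time histogram: mean spikes per bin across neurons.

    ``stims`` selects the 1-based stimulus indices to pool (default
    all); bins tile [0, period).  Returns columns (t_lo, t_hi, mean_count).
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    df = table.data
    if stims is not None:
        df = df[df["stim_index"].isin(stims)]
    n_neurons = max(1, df["neuron_id"].nunique() if len(df) else 1)
    edges = np.arange(0.0, table.period_ms + binwidth / 2, binwidth)
    hist, _ = np.histogram(df["latency_ms"].to_numpy(dtype=float), bins=edges)
    n_sel = len(stims) if stims is not None else table.n_stims
    return pd.DataFrame({
        "t_lo": edges[:-1], "t_hi": edges[1:],
        "mean_count": hist / (n_neurons * max(1, n_sel)),
    })


def compare_psth(model: pd.DataFrame, reference: pd.DataFrame) -> float:
    """Root-mean-square distance between two identically binned PSTHs."""
    if len(model) != len(reference) or not np.allclose(
            model["t_lo"].to_numpy(), reference["t_lo"].to_numpy()):
        raise ValueError("PSTH binning mismatch")
    d = model["mean_count"].to_numpy() - reference["mean_count"].to_numpy()
    return float(np.sqrt(np.mean(d * d)))
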