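"""Windup quantification pipeline on hand-built spike tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from windup_asic.metrics import (SpikeTable, WindupCurve, WINDOWS, auc,
                                 classify_spikes, compare_psth, mean_curve,
                                 percent_inhibition, psth, windup_curve)


def _table(rows, n_stims=16):
    df = pd.DataFrame(rows, columns=["neuron_id", "stim_index", "latency_ms"])
    return SpikeTable(data=df, n_stims=n_stims)


# ---------------------------------------------------------------------------
# latency-window classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("latency,window", [
    (10.0, "Abeta"), (19.999, "Abeta"),
    (20.0, "Adelta"), (50.0, "Adelta"),
    (90.0, "C"), (150.0, "C"), (349.9, "C"),
    (350.0, "postdischarge"), (999.0, "postdischarge"),
    (1000.0, "other"),
])
def test_window_classification(latency, window):
    labeled = classify_spikes(_table([(0, 1, latency)]))
    assert labeled.window.iloc[0] == window


def test_windows_partition_no_gap_no_overlap():
    edges = [(lo, hi) for _, lo, hi in WINDOWS]
    assert edges[0][0] == 0.0 and edges[-1][1] == 1000.0
    for (_, hi), (lo, _) in zip(edges, edges[1:]):
        assert hi == lo


def test_negative_latency_rejected():
    with pytest.raises(ValueError):
        _table([(0, 1, -5.0)])


# ---------------------------------------------------------------------------
# windup curve
# ---------------------------------------------------------------------------

def test_empty_table_gives_zero_curve():
    curve = windup_curve(classify_spikes(_table([])), 16)
    assert curve.total == 0 and curve.auc == 0.0 and curve.n_stims == 16


def test_counts_c_plus_postdischarge_only():
    rows = [(0, 3, 120.0), (0, 3, 200.0), (0, 3, 400.0),  # 2 C + 1 PD
            (0, 3, 10.0), (0, 3, 50.0)]                   # Abeta + Adelta
    curve = windup_curve(classify_spikes(_table(rows)), 16)
    assert curve.counts[2] == 3
    assert curve.total == 3


def test_counts_invariant_to_row_order():
    rows = [(0, s, 100.0 + 10 * i) for i, s in enumerate([5, 2, 9, 2, 5, 5])]
    c1 = windup_curve(classify_spikes(_table(rows)), 16)
    c2 = windup_curve(classify_spikes(_table(rows[::-1])), 16)
    assert np.array_equal(c1.counts, c2.counts)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_examples():
    assert auc(WindupCurve(np.array([3.0, 3, 3, 3]))) == 0.0
    assert auc(WindupCurve(np.array([2.0, 4, 6, 8]))) == pytest.approx(9.0)
    assert auc(WindupCurve(np.array([5.0, 3, 3, 3]))) == 0.0  # clipped
    signed = WindupCurve(np.array([5.0, 3, 3, 3]), clip_baseline=False)
    assert auc(signed) < 0


def test_auc_invariant_to_constant_shift():
    a = auc(WindupCurve(np.array([2.0, 4, 7, 7, 9])))
    b = auc(WindupCurve(np.array([2.0, 4, 7, 7, 9]) + 11.0))
    assert a == pytest.approx(b)


def test_auc_needs_two_points():
    with pytest.raises(ValueError):
        auc(WindupCurve(np.array([3.0])))


# ---------------------------------------------------------------------------
# percent inhibition
# ---------------------------------------------------------------------------

def test_inhibition_identity_and_halving():
    ctrl = WindupCurve(np.array([2.0, 4, 6, 8]))
    assert percent_inhibition(ctrl, ctrl) == (0.0, 0.0)
    # halved counts: totals halve; excesses over the halved baseline halve too
    drug = WindupCurve(ctrl.counts / 2)
    pct_total, pct_auc = percent_inhibition(ctrl, drug)
    assert pct_total == pytest.approx(50.0)
    assert pct_auc == pytest.approx(50.0)


def test_inhibition_zero_denominator_marker():
    zero = WindupCurve(np.zeros(4))
    pct_total, pct_auc = percent_inhibition(zero, zero)
    assert np.isnan(pct_total) and np.isnan(pct_auc)


def test_mean_curve_across_neurons():
    m = mean_curve([WindupCurve(np.array([2.0, 4.0])),
                    WindupCurve(np.array([4.0, 8.0]))])
    assert np.allclose(m.counts, [3.0, 6.0])


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def test_psth_single_spike():
    tab = _table([(0, 1, 30.0)])
    h = psth(tab, binwidth=20.0, stims=[1])
    in_bin = (h.t_lo == 20.0)
    assert h.loc[in_bin, "mean_count"].iloc[0] == 1.0
    assert h.loc[~in_bin, "mean_count"].sum() == 0.0


def test_psth_conservation_and_neuron_invariance():
    rng = np.random.default_rng(0)
    rows = [(int(n), int(s), float(l)) for n, s, l in zip(
        rng.integers(0, 3, 60), rng.integers(1, 17, 60),
        rng.uniform(0, 1000, 60))]
    tab = _table(rows)
    h = psth(tab)
    n_neurons = 3
    assert h.mean_count.sum() * n_neurons * 16 == pytest.approx(60)
    shuffled = _table(sorted(rows, key=lambda r: r[2]))
    assert np.allclose(psth(shuffled).mean_count, h.mean_count)


def test_compare_psth_metric_properties():
    rng = np.random.default_rng(1)
    hs = []
    for _ in range(3):
        rows = [(0, 1, float(l)) for l in rng.uniform(0, 1000, 40)]
        hs.append(psth(_table(rows)))
    a, b, c = hs
    assert compare_psth(a, a) == 0.0
    dab, dbc, dac = compare_psth(a, b), compare_psth(b, c), compare_psth(a, c)
    assert dab == pytest.approx(compare_psth(b, a))
    assert dac <= dab + dbc + 1e-12


def test_compare_psth_shift_increases_distance():
    rows = [(0, 1, 100.0 + 7 * i) for i in range(10)]
    base = psth(_table(rows))
    shifted = psth(_table([(0, 1, l + 20.0) for _, _, l in rows]))
    assert compare_psth(base, shifted) > 0


def test_compare_psth_binning_mismatch():
    tab = _table([(0, 1, 30.0)])
    with pytest.raises(ValueError):
        compare_psth(psth(tab, binwidth=20.0), psth(tab, binwidth=50.0))


# ---------------------------------------------------------------------------
# assembling tables from absolute spike times
# ---------------------------------------------------------------------------

def test_from_spike_times_alignment():
    stims = [1000.0, 2000.0, 3000.0]
    spikes = [1150.0, 2400.0, 2990.0, 3500.0, 500.0]
    tab = SpikeTable.from_spike_times(spikes, stims)
    assert len(tab.data) == 4  # the 500 ms spike precedes the first stimulus
    row = tab.data.iloc[0]
    assert row.stim_index == 1 and row.latency_ms == pytest.approx(150.0)


@given(lat=st.lists(st.floats(min_value=0, max_value=999.9), max_size=30))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_every_latency_gets_exactly_one_window(lat):
    tab = _table([(0, 1, float(l)) for l in lat])
    labeled = classify_spikes(tab)
    assert (labeled.window != "other").all()
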