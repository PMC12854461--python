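"""Spike detection, amplitude-class sorting, and peristimulus histograms.

The ab1 sensillum is identified in recordings by its four spike sizes at
rest, so sorting here is deliberately one-dimensional: events are
clustered on peak amplitude alone, using an exact dynamic-programming
segmentation of the sorted amplitudes (deterministic, no seeds).  The
CO2-responsive unit is then picked by stimulus-locked rate contrast, not
by amplitude rank.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import signal

from .core import PSTH, SpikeEvent, SpikeTrain, VoltageRecording

__all__ = [
    "bandpass",
    "detect_spikes",
    "sort_units",
    "select_target_unit",
    "align_to_epochs",
    "build_psth",
    "DegenerateClusterError",
]


class DegenerateClusterError(ValueError):
    """Fewer distinct amplitudes than requested clusters."""


def bandpass(samples: np.ndarray, sampling_rate: float,
             low: float = 300.0, high: float = 3000.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; removes the LFP and drift."""
    nyq = sampling_rate / 2.0
    high = min(high, 0.95 * nyq)
    sos = signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, samples)


def noise_scale_mad(filtered: np.ndarray) -> float:
    """Robust noise SD estimate: scaled median absolute deviation."""
    med = np.median(filtered)
    return float(np.median(np.abs(filtered - med)) / 0.6745)


def detect_spikes(
    rec: VoltageRecording,
    k_mad: float = 5.0,
    min_separation: float = 0.5e-3,
    band: tuple[float, float] = (300.0, 3000.0),
    scale_floor: float = 1e-3,
) -> list[SpikeEvent]:
    """Detect spikes as filtered-trace local maxima above a robust threshold.

    The trace is band-pass filtered, the noise scale estimated by MAD
    (with an absolute floor ``scale_floor`` in mV so that noise-free
    traces still threshold sensibly), and positive peaks above ``k_mad``
    times that scale reported.  ``min_separation`` is the minimum
    distance between reported peaks; it is shorter than a single
    neuron's refractory period on purpose, because spikes from
    *different* units of the sensillum may fall arbitrarily close
    together.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    if len(rec.samples) == 0:
        raise ValueError("empty trace")
    filtered = bandpass(rec.samples, rec.sampling_rate, *band)
    scale = max(noise_scale_mad(filtered), scale_floor)
    distance = max(int(round(min_separation * rec.sampling_rate)), 1)
    peaks, props = signal.find_peaks(filtered, height=k_mad * scale, distance=distance)
    times = peaks / rec.sampling_rate
    heights = props["peak_heights"]
    return [SpikeEvent(float(t), float(a)) for t, a in zip(times, heights)]


# --------------------------------------------------------------------------
# 1-D optimal k-segmentation (exact within-cluster-SSE minimizer)
# --------------------------------------------------------------------------

def _segment_1d(sorted_vals: np.ndarray, k: int) -> np.ndarray:
    """Exact DP segmentation of sorted values into k contiguous segments
    minimizing total within-segment sum of squares.  Returns the segment
    index (0..k-1) of each value."""
    n = len(sorted_vals)
    ps = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    ps2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # cost of segment [i, j), vectorized over i
        cnt = j - i
        s = ps[j] - ps[i]
        return (ps2[j] - ps2[i]) - s * s / cnt

    # cost[m, j] = best cost of first j values in m+1 segments
    cost = np.full((k, n + 1), np.inf)
    back = np.zeros((k, n + 1), dtype=int)
    for j in range(1, n + 1):
        cost[0, j] = seg_cost(np.array([0]), j)[0]
    for m in range(1, k):
        for j in range(m + 1, n + 1):
            i = np.arange(m, j)
            total = cost[m - 1, i] + seg_cost(i, j)
            best = int(np.argmin(total))
            cost[m, j] = total[best]
            back[m, j] = i[best]
    labels = np.empty(n, dtype=int)
    j = n
    for m in range(k - 1, -1, -1):
        i = back[m, j] if m > 0 else 0
        labels[i:j] = m
        j = i
    return labels


def sort_units(events: Sequence[SpikeEvent], k: int = 4,
               replicate_id: int = 0) -> list[SpikeTrain]:
    """Cluster events into ``k`` amplitude classes.

    Labels are 1..k in ascending mean amplitude.  Clustering is an exact
    1-D k-segmentation of the sorted amplitudes, so it is deterministic
    and invariant to uniform rescaling of all amplitudes.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    events = list(events)
    if not events and k > 1:
        raise ValueError("cannot sort an empty event list into k > 1 classes")
    amps = np.array([e.amplitude for e in events])
    if len(np.unique(amps)) < k:
        raise DegenerateClusterError(
            f"only {len(np.unique(amps))} distinct amplitudes for k={k}"
        )
    order = np.argsort(amps, kind="stable")
    seg = _segment_1d(amps[order], k)
    labels = np.empty(len(events), dtype=int)
    labels[order] = seg + 1  # segments of sorted values are already amplitude-ordered
    trains = []
    for lab in range(1, k + 1):
        m = labels == lab
        times = np.array([e.time for e, keep in zip(events, m) if keep])
        unit_amps = amps[m]
        o = np.argsort(times)
        trains.append(SpikeTrain(unit_label=lab, times=times[o],
                                 replicate_id=replicate_id,
                                 amplitudes=unit_amps[o]))
    return trains


def select_target_unit(trains: Sequence[SpikeTrain],
                       epochs: Sequence[tuple[float, float]]) -> int:
    """Pick the CO2-responsive unit: largest (in-stimulus - pre-stimulus)
    rate contrast; ties broken by the lowest label."""
    if not epochs:
        raise ValueError("need at least one stimulus epoch")
    if not trains:
        raise ValueError("need at least one spike train")
    contrasts = []
    for tr in trains:
        in_rate = 0.0
        pre_rate = 0.0
        t_in = 0.0
        t_pre = 0.0
        for on, dur in epochs:
            t_in += dur
            in_rate += np.count_nonzero((tr.times >= on) & (tr.times < on + dur))
            pre = min(dur, on)
            t_pre += pre
            pre_rate += np.count_nonzero((tr.times >= on - pre) & (tr.times < on))
        in_rate = in_rate / t_in if t_in else 0.0
        pre_rate = pre_rate / t_pre if t_pre else 0.0
        contrasts.append(in_rate - pre_rate)
    contrasts = np.asarray(contrasts)
    best = int(np.argmax(contrasts))  # argmax takes the first (lowest-label) max
    if np.max(contrasts) <= 0:
        warnings.warn("no unit shows a positive stimulus-locked rate contrast",
                      stacklevel=2)
    return trains[best].unit_label


# --------------------------------------------------------------------------
# PSTH
# --------------------------------------------------------------------------

def align_to_epochs(times, epochs: Sequence[tuple[float, float]],
                    window: tuple[float, float]) -> list[np.ndarray]:
    """Split a spike-time vector into per-epoch times relative to onset."""
    from .core import as_times

    t = as_times(times)
    out = []
    for on, _dur in epochs:
        lo, hi = on + window[0], on + window[1]
        out.append(t[(t >= lo) & (t < hi)] - on)
    return out


def build_psth(
    neurons: Sequence[Sequence[np.ndarray]],
    bin_width: float = 0.05,
    window: tuple[float, float] = (-1.0, 3.0),
) -> PSTH:
    """Build a grand PSTH with the replicate -> neuron -> group hierarchy.

    ``neurons`` is a sequence over neurons; each neuron is a sequence of
    replicate spike-time arrays, *relative to stimulus onset* (see
    :func:`align_to_epochs`).  Per replicate, counts per bin are divided
    by ``bin_width``; per neuron, replicates are averaged; the grand PSTH
    is the unweighted mean over neurons (never a pooled-spike average).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if window[0] > 0 or window[1] <= 0:
        raise ValueError("window must span the stimulus onset")
    if len(neurons) == 0:
        raise ValueError("empty neuron group")
    edges = np.arange(window[0], window[1] + 0.5 * bin_width, bin_width)
    neuron_rates = []
    n_reps = None
    for reps in neurons:
        if len(reps) == 0:
            raise ValueError("a neuron must have at least one replicate")
        n_reps = len(reps) if n_reps is None else n_reps
        rep_rates = [
            np.histogram(np.asarray(r, dtype=float), bins=edges)[0] / bin_width
            for r in reps
        ]
        neuron_rates.append(np.mean(rep_rates, axis=0))
    neuron_rates = np.asarray(neuron_rates)
    return PSTH(
        bin_edges=edges,
        rates=neuron_rates.mean(axis=0),
        n_neurons=len(neurons),
        n_replicates_per_neuron=n_reps,
        neuron_rates=neuron_rates,
    )
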