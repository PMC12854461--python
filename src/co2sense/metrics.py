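"""Scalar response metrics for the CO2-responsive unit.

Onset rates are plain count-over-window rates anchored at the stimulus
valve epoch start (100 ms and 20 ms windows), ``onset_max`` is the peak
sliding-bin rate within the stimulus, baseline is the 1000 ms before
onset, steady state the final 1000 ms of the 2-s stimulus, and LFP
slopes are ordinary least-squares fits over 320 ms or 750 ms from onset.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import ResponseMetrics, as_times

__all__ = [
    "onset_rate",
    "window_rate",
    "baseline_rate",
    "steady_state_rate",
    "lfp_slope",
    "extract_lfp",
    "compute_metrics",
]

BASELINE_WIDTH = 1.0       # s before onset
STEADY_WIDTH = 1.0         # s, final second of the stimulus


def window_rate(train, start: float, width: float) -> float:
    """Spike count in [start, start + width) divided by width (spikes/s)."""
    if width <= 0:
        raise ValueError("width must be positive")
    t = as_times(train)
    return float(np.count_nonzero((t >= start) & (t < start + width)) / width)


def onset_rate(
    train,
    onset: float,
    width: float = 0.1,
    mode: str = "mean",
    bin_width: float = 0.05,
    stimulus_duration: float = 2.0,
    step: float = 1e-3,
) -> float:
    """Onset response rate in spikes/s.

    mode="mean": spike count in [onset, onset + width) / width.
    mode="max_bin": maximum sliding-bin rate (bin = ``bin_width``, step
    ``step``) anywhere within [onset, onset + stimulus_duration).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    t = as_times(train)
    if mode == "mean":
        return window_rate(t, onset, width)
    if mode == "max_bin":
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        starts = np.arange(onset, onset + stimulus_duration - bin_width + 0.5 * step, step)
        if starts.size == 0:
            starts = np.array([onset])
        # vectorized sliding counts via searchsorted on the sorted times
        ts = np.sort(t)
        lo = np.searchsorted(ts, starts, side="left")
        hi = np.searchsorted(ts, starts + bin_width, side="left")
        return float(np.max(hi - lo) / bin_width)
    raise ValueError(f"unknown mode {mode!r}")


def baseline_rate(train, onset: float, width: float = BASELINE_WIDTH) -> float:
    """Rate in the ``width`` seconds immediately before stimulus onset."""
    return window_rate(train, onset - width, width)


def steady_state_rate(train, onset: float, stimulus_duration: float = 2.0,
                      width: float = STEADY_WIDTH) -> float:
    """Rate in the final ``width`` seconds of the stimulus."""
    return window_rate(train, onset + stimulus_duration - width, width)


def lfp_slope(lfp: np.ndarray, sampling_rate: float, onset: float,
              duration: float = 0.320) -> float:
    """OLS slope (mV/s) of the LFP over [onset, onset + duration)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    lfp = np.asarray(lfp, dtype=float)
    s0 = int(round(onset * sampling_rate))
    s1 = int(round((onset + duration) * sampling_rate))
    if s0 < 0 or s1 > len(lfp):
        raise ValueError("window outside the trace")
    seg = lfp[s0:s1]
    if len(seg) < 2:
        raise ValueError("need at least 2 samples in the window")
    t = np.arange(len(seg)) / sampling_rate
    tc = t - t.mean()
    return float(np.dot(tc, seg - seg.mean()) / np.dot(tc, tc))


def extract_lfp(samples: np.ndarray, sampling_rate: float,
                cutoff: float = 100.0, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass of the raw trace; isolates the slow LFP."""
    nyq = sampling_rate / 2.0
    sos = signal.butter(order, cutoff / nyq, btype="low", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def compute_metrics(
    train,
    epochs: Sequence[tuple[float, float]],
    lfp: Optional[np.ndarray] = None,
    sampling_rate: Optional[float] = None,
    psth_bin_width: float = 0.05,
) -> ResponseMetrics:
    """Per-neuron metrics, averaged over the replicate stimulus epochs."""
    if not epochs:
        raise ValueError("need at least one stimulus epoch")
    t = as_times(train)
    vals = {"m100": [], "m20": [], "mx": [], "base": [], "steady": []}
    for on, dur in epochs:
        vals["m100"].append(onset_rate(t, on, 0.100))
        vals["m20"].append(onset_rate(t, on, 0.020))
        vals["mx"].append(onset_rate(t, on, mode="max_bin",
                                     bin_width=psth_bin_width,
                                     stimulus_duration=dur))
        vals["base"].append(baseline_rate(t, on))
        vals["steady"].append(steady_state_rate(t, on, stimulus_duration=dur))
    slope320 = slope750 = None
    if lfp is not None:
        if sampling_rate is None:
            raise ValueError("sampling_rate required with an LFP")
        slope320 = float(np.mean([lfp_slope(lfp, sampling_rate, on, 0.320)
                                  for on, _ in epochs]))
        slope750 = float(np.mean([lfp_slope(lfp, sampling_rate, on, 0.750)
                                  for on, _ in epochs]))
    return ResponseMetrics(
        onset_mean_100ms=float(np.mean(vals["m100"])),
        onset_mean_20ms=float(np.mean(vals["m20"])),
        onset_max=float(np.mean(vals["mx"])),
        baseline=float(np.mean(vals["base"])),
        steady_state=float(np.mean(vals["steady"])),
        lfp_slope_320=slope320,
        lfp_slope_750=slope750,
    )
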