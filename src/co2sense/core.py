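"""Shared domain containers for single-sensillum CO2-response analysis.

The containers here are deliberately thin: a recording is samples plus a
sampling rate and stimulus epochs, a spike train is a sorted vector of
times with a unit label.  Everything heavier (tables of onset rates, Ct
tables, trial summaries) lives in pandas DataFrames with documented
column conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VoltageRecording",
    "SpikeEvent",
    "SpikeTrain",
    "PSTH",
    "ResponseMetrics",
    "TrialRecord",
    "PositionAssay",
    "UndefinedIndexError",
]


class UndefinedIndexError(ValueError):
    """Raised when a preference index is undefined (e.g. a zero-egg trial)."""


@dataclass
class VoltageRecording:
    """Continuous extracellular trace with stimulus epochs.

    Attributes
    ----------
    samples : np.ndarray
        Voltage in mV, one continuous sweep containing all replicates.
    sampling_rate : float
        Samples per second.
    epochs : list of (onset_s, duration_s)
        Stimulus valve epochs, non-overlapping, in seconds from trace start.
    metadata : dict
        Free-form labels (genotype, species, condition, co2_fraction, seed).
    """

    samples: np.ndarray
    sampling_rate: float
    epochs: list[tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration
        eps = sorted(self.epochs)
        for (on, d) in eps:
            if d <= 0 or on < 0 or on + d > dur + 1e-9:
                raise ValueError(f"epoch ({on}, {d}) outside trace of {dur} s")
        for (a, da), (b, _db) in zip(eps, eps[1:]):
            if a + da > b:
                raise ValueError("stimulus epochs overlap")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class SpikeEvent:
    """A detected spike: peak time (s) and peak amplitude (mV, filtered)."""

    time: float
    amplitude: float


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit within one recording.

    ``unit_label`` is 1-based and ordered by ascending mean amplitude of
    the unit's events (the field convention for naming ab1 units A-D by
    spike size is a separate, biological labelling).
    """

    unit_label: int
    times: np.ndarray
    replicate_id: int = 0
    amplitudes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PSTH:
    """Peristimulus time histogram, hierarchy replicate -> neuron -> group."""

    bin_edges: np.ndarray          # s, relative to stimulus onset
    rates: np.ndarray              # spikes/s, grand mean across neurons
    n_neurons: int
    n_replicates_per_neuron: int
    neuron_rates: Optional[np.ndarray] = None  # (n_neurons, n_bins)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) != len(self.bin_edges) - 1:
            raise ValueError("len(rates) must equal len(bin_edges) - 1")
        if np.any(self.rates < 0):
            raise ValueError("PSTH rates must be non-negative")


@dataclass
class ResponseMetrics:
    """Scalar response metrics for one neuron (averaged over replicates)."""

    onset_mean_100ms: float
    onset_mean_20ms: float
    onset_max: float
    baseline: float
    steady_state: float
    lfp_slope_320: Optional[float] = None
    lfp_slope_750: Optional[float] = None


@dataclass
class TrialRecord:
    """One two-choice oviposition trial.

    For the ``co2`` condition, eggs are counted on the 1% side
    (``eggs_high``) and the 0.04% side (``eggs_low``).  For the ``air``
    and ``no_air`` control conditions the chamber is undivided and the
    single pooled count lives in ``eggs_pooled``.
    """

    n_flies: int
    condition: str = "co2"
    eggs_high: Optional[int] = None
    eggs_low: Optional[int] = None
    eggs_pooled: Optional[int] = None
    duration_h: float = 16.0

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if self.condition not in ("co2", "air", "no_air"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "co2":
            if self.eggs_high is None or self.eggs_low is None:
                raise ValueError("co2 trials need eggs_high and eggs_low")
            if self.eggs_high < 0 or self.eggs_low < 0:
                raise ValueError("egg counts must be non-negative")
        else:
            if self.eggs_pooled is None or self.eggs_pooled < 0:
                raise ValueError("control trials need a non-negative pooled count")

    @property
    def total_eggs(self) -> int:
        if self.condition == "co2":
            return int(self.eggs_high) + int(self.eggs_low)
        return int(self.eggs_pooled)


@dataclass
class PositionAssay:
    """Two 15-min position readings with the CO2 sides swapped in between.

    Counts are stored relative to the CO2 condition: ``*_high`` is the
    number of flies on whichever physical side carried 1% CO2 during that
    reading, so the side swap is already folded into the bookkeeping.
    """

    reading1: tuple[int, int]  # (flies_high, flies_low)
    reading2: tuple[int, int]
    n_flies: int

    def __post_init__(self) -> None:
        for r in (self.reading1, self.reading2):
            if min(r) < 0:
                raise ValueError("fly counts must be non-negative")
            if sum(r) > self.n_flies:
                raise ValueError("counted flies exceed flies loaded")


def as_times(train_or_times) -> np.ndarray:
    """Accept a SpikeTrain or a bare array of times; return sorted float array."""
    if isinstance(train_or_times, SpikeTrain):
        return train_or_times.times
    return np.asarray(train_or_times, dtype=float)
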