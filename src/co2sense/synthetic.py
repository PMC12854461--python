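"""Synthetic data with known ground truth.

This module generates every input the downstream analysis consumes:

* extracellular voltage traces from an ab1-like sensillum (four units of
  distinct spike amplitude, one of them CO2-responsive, plus a slow local
  field potential and Gaussian noise),
* onset-rate tables over a 3 x 3 grid of (cis-regulatory element x coding
  sequence) genotypes following a multiplicative effects model,
* two-choice oviposition trials with a programmable true preference, and
* qPCR Ct tables with separate biological and technical noise.

Everything is driven by an explicit integer seed: the same configuration
and seed always yield bit-identical output.

The spiking model is an inhomogeneous renewal process: candidate events
are drawn by thinning at hazard ``r(t) / (1 - r(t) * refractory)`` with an
absolute dead time, which makes the *realized* rate equal the programmed
rate function r(t) rather than the dead-time-depressed rate a naively
thinned Poisson process would produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import TrialRecord, VoltageRecording

__all__ = [
    "UnitSpec",
    "LfpSpec",
    "RecordingConfig",
    "GroundTruth",
    "fidelity_config",
    "TrialConfig",
    "CtConfig",
    "simulate_recording",
    "simulate_rate_table",
    "simulate_oviposition_trial",
    "simulate_ct_table",
    "ct_config_from_rq",
    "spike_template",
    "write_recording",
    "read_recording",
]

CIS_ELEMENTS = ("mel", "sub", "suz")
CDS_ELEMENTS = ("mel", "sub", "suz")


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSpec:
    """One unit of the sensillum.

    amplitude is in multiples of the recording noise SD; a unit with
    ``peak_rate`` set is CO2-responsive: at stimulus onset its rate steps
    to ``peak_rate`` and relaxes exponentially (time constant
    ``adaptation_tau``) toward ``steady_rate``, returning to
    ``baseline_rate`` at stimulus offset.
    """

    amplitude: float
    baseline_rate: float
    peak_rate: Optional[float] = None
    adaptation_tau: float = 0.25
    steady_rate: Optional[float] = None
    refractory: float = 1.5e-3

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.baseline_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.refractory <= 0:
            raise ValueError("refractory must be positive")
        if self.peak_rate is not None:
            steady = self.steady_rate if self.steady_rate is not None else 0.0
            if not (self.peak_rate >= steady >= 0):
                raise ValueError("need peak_rate >= steady_rate >= 0")
            if self.adaptation_tau <= 0:
                raise ValueError("adaptation_tau must be positive")

    @property
    def responsive(self) -> bool:
        return self.peak_rate is not None

    def rate_at(self, t: np.ndarray, epochs: Sequence[tuple[float, float]]) -> np.ndarray:
        """Programmed instantaneous rate (spikes/s) at times ``t``."""
        t = np.asarray(t, dtype=float)
        r = np.full_like(t, self.baseline_rate)
        if self.responsive:
            steady = self.steady_rate if self.steady_rate is not None else 0.0
            for on, dur in epochs:
                m = (t >= on) & (t < on + dur)
                r[m] = steady + (self.peak_rate - steady) * np.exp(
                    -(t[m] - on) / self.adaptation_tau
                )
        return r

    def mean_rate(self, start: float, width: float,
                  epochs: Sequence[tuple[float, float]], n: int = 2001) -> float:
        """Time-averaged programmed rate over [start, start + width)."""
        tt = start + (np.arange(n) + 0.5) * (width / n)
        return float(np.mean(self.rate_at(tt, epochs)))


@dataclass(frozen=True)
class LfpSpec:
    """Local field potential: downward onset ramp, exponential recovery."""

    onset_slope: float = -3.0       # mV/s, <= 0
    deflection_depth: float = -1.5  # mV, <= 0
    recovery_tau: float = 1.0       # s

    def __post_init__(self) -> None:
        if self.onset_slope > 0:
            raise ValueError("onset_slope must be <= 0")
        if self.deflection_depth > 0:
            raise ValueError("deflection_depth must be <= 0")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be positive")


def _default_units() -> tuple[UnitSpec, ...]:
    # Four amplitude classes at rest, the second-smallest one CO2-responsive
    # (ab1C is neither the largest nor the smallest spike of the sensillum).
    return (
        UnitSpec(amplitude=8.0, baseline_rate=2.0),
        UnitSpec(amplitude=14.0, baseline_rate=4.0, peak_rate=180.0,
                 adaptation_tau=0.25, steady_rate=40.0),
        UnitSpec(amplitude=20.0, baseline_rate=3.0),
        UnitSpec(amplitude=26.0, baseline_rate=5.0),
    )


@dataclass(frozen=True)
class RecordingConfig:
    """Layout and content of one simulated sensillum recording.

    Defaults mirror the study protocol: a 2-s CO2 pulse with 10-s rests,
    five replicate pulses per sensillum, 10 kHz sampling.
    """

    sampling_rate: float = 10_000.0
    n_replicates: int = 5
    stimulus_duration: float = 2.0
    rest_duration: float = 10.0
    pre_stimulus: float = 2.0
    units: tuple[UnitSpec, ...] = field(default_factory=_default_units)
    noise_sd: float = 0.05          # mV
    lfp: LfpSpec = field(default_factory=LfpSpec)
    co2_fraction: float = 0.01      # metadata only; does not drive kinetics
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.stimulus_duration <= 0 or self.rest_duration < 0:
            raise ValueError("bad epoch durations")
        if self.pre_stimulus < 0:
            raise ValueError("pre_stimulus must be non-negative")
        if len(self.units) != 4:
            raise ValueError("a sensillum has exactly 4 units")
        amps = [u.amplitude for u in self.units]
        if len(set(amps)) != 4:
            raise ValueError("unit amplitudes must be pairwise distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def epochs(self) -> list[tuple[float, float]]:
        cycle = self.stimulus_duration + self.rest_duration
        return [
            (self.pre_stimulus + i * cycle, self.stimulus_duration)
            for i in range(self.n_replicates)
        ]

    @property
    def duration(self) -> float:
        cycle = self.stimulus_duration + self.rest_duration
        return self.pre_stimulus + self.n_replicates * cycle


def fidelity_config(seed: int = 0) -> "RecordingConfig":
    """Recording configuration used to quantify sorting fidelity.

    Amplitude classes are separated by 6 noise SD and all rates stay at
    or below 100 spikes/s, which keeps cross-unit waveform overlaps —
    the irreducible error source for amplitude-only sorting — below the
    percent level.  Baseline rates are a few spikes/s, typical of large
    basiconic sensillum units at rest.
    """
    units = (
        UnitSpec(amplitude=8.0, baseline_rate=1.5),
        UnitSpec(amplitude=14.0, baseline_rate=3.0, peak_rate=100.0,
                 adaptation_tau=0.25, steady_rate=40.0),
        UnitSpec(amplitude=20.0, baseline_rate=1.0),
        UnitSpec(amplitude=26.0, baseline_rate=2.0),
    )
    return RecordingConfig(units=units, seed=seed)


@dataclass
class GroundTruth:
    """What the simulator actually put into a recording."""

    spike_times: dict[int, np.ndarray]   # unit index (0-based) -> times, s
    lfp: np.ndarray                      # clean LFP, mV
    true_lfp_slope: float                # mV/s at onset
    config: RecordingConfig

    def true_rate(self, unit: int, start: float, width: float) -> float:
        """Time-averaged programmed rate of ``unit`` over a window."""
        return self.config.units[unit].mean_rate(start, width, self.config.epochs)

    @property
    def responsive_unit(self) -> int:
        for i, u in enumerate(self.config.units):
            if u.responsive:
                return i
        raise ValueError("no responsive unit in configuration")


@dataclass(frozen=True)
class TrialConfig:
    """One simulated oviposition trial."""

    n_flies: int = 12
    mean_eggs_per_fly: float = 5.0
    true_opi: float = 0.0
    dispersion: float = 2.0          # negative-binomial size; smaller = heavier tails
    condition: str = "co2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if self.mean_eggs_per_fly < 0:
            raise ValueError("mean_eggs_per_fly must be non-negative")
        if abs(self.true_opi) > 1:
            raise ValueError("|true_opi| must be <= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.condition not in ("co2", "air", "no_air"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class CtConfig:
    """qPCR Ct table layout: per-(gene, sample) means plus two noise tiers."""

    means: Mapping[tuple[str, str], float]  # (gene, sample) -> mean Ct, cycles
    biological_sd: float = 0.0
    technical_sd: float = 0.0
    n_bio: int = 3
    n_tech: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.means:
            raise ValueError("means must be non-empty")
        for (g, s), m in self.means.items():
            if not (0 < m < 40):
                raise ValueError(f"Ct mean for ({g}, {s}) must lie in (0, 40)")
        if self.biological_sd < 0 or self.technical_sd < 0:
            raise ValueError("SDs must be non-negative")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("need at least one replicate of each kind")


# --------------------------------------------------------------------------
# spike waveform and renewal-process sampling
# --------------------------------------------------------------------------

def spike_template(sampling_rate: float, duration: float = 1.5e-3) -> np.ndarray:
    """Stereotyped biphasic spike waveform, positive peak normalized to 1.

    A narrow positive lobe (1/3 of the duration) followed by a shallower
    negative lobe; only the amplitude class matters downstream, so the
    exact shape is a modelling convenience.
    """
    n = max(int(round(duration * sampling_rate)), 3)
    n_pos = max(int(round(0.27 * n)), 1)
    n_neg = n - n_pos
    pos = np.sin(np.pi * (np.arange(n_pos) + 0.5) / n_pos)
    neg = -0.25 * np.sin(np.pi * (np.arange(n_neg) + 0.5) / n_neg)
    return np.concatenate([pos, neg])


def _draw_renewal_spikes(unit: UnitSpec, epochs, duration, rng) -> np.ndarray:
    """Inhomogeneous renewal process via thinning with absolute dead time."""
    tau = unit.refractory

    def hazard(t):
        r = unit.rate_at(t, epochs)
        if np.any(r * tau >= 1.0):
            raise ValueError("rate too high for the refractory period")
        return r / (1.0 - r * tau)

    peak = unit.peak_rate if unit.responsive else unit.baseline_rate
    r_max = max(float(peak), float(unit.baseline_rate))
    if r_max == 0.0:
        return np.array([])
    h_max = r_max / (1.0 - r_max * tau)
    # candidate homogeneous process at h_max, oversampled deterministically
    n_cand = rng.poisson(h_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    u = rng.uniform(0.0, 1.0, size=n_cand)
    h = hazard(cand)
    accept_p = h / h_max
    out = []
    last = -np.inf
    for t, ui, p in zip(cand, u, accept_p):
        if t - last < tau:
            continue
        if ui < p:
            out.append(t)
            last = t
    return np.asarray(out)


def _render_lfp(cfg: RecordingConfig) -> np.ndarray:
    """Clean LFP: linear ramp at onset_slope down to deflection_depth, held
    through the stimulus, exponential recovery after offset."""
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    v = np.zeros(n)
    spec = cfg.lfp
    for on, dur in cfg.epochs:
        off = on + dur
        m = (t >= on) & (t < off)
        ramp = spec.onset_slope * (t[m] - on)
        v[m] += np.maximum(ramp, spec.deflection_depth)
        v_off = max(spec.onset_slope * dur, spec.deflection_depth)
        m2 = t >= off
        v[m2] += v_off * np.exp(-(t[m2] - off) / spec.recovery_tau)
    return v


def simulate_recording(cfg: RecordingConfig) -> tuple[VoltageRecording, GroundTruth]:
    """Simulate one sensillum recording and its ground truth.

    The trace is the sum of the rendered spike waveforms of all four
    units, the slow LFP, and white Gaussian noise of ``cfg.noise_sd``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sampling_rate))
    template = spike_template(cfg.sampling_rate)

    spike_times: dict[int, np.ndarray] = {}
    trace = np.zeros(n)
    for i, unit in enumerate(cfg.units):
        times = _draw_renewal_spikes(unit, cfg.epochs, cfg.duration, rng)
        spike_times[i] = times
        amp = unit.amplitude * cfg.noise_sd if cfg.noise_sd > 0 else unit.amplitude
        for s in np.round(times * cfg.sampling_rate).astype(int):
            hi = min(s + len(template), n)
            trace[s:hi] += amp * template[: hi - s]

    lfp = _render_lfp(cfg)
    trace += lfp
    if cfg.noise_sd > 0:
        trace += rng.normal(0.0, cfg.noise_sd, size=n)

    rec = VoltageRecording(
        samples=trace,
        sampling_rate=cfg.sampling_rate,
        epochs=cfg.epochs,
        metadata={
            "co2_fraction": cfg.co2_fraction,
            "seed": cfg.seed,
            "noise_sd": cfg.noise_sd,
            "kind": "synthetic",
        },
    )
    truth = GroundTruth(
        spike_times=spike_times,
        lfp=lfp,
        true_lfp_slope=cfg.lfp.onset_slope,
        config=cfg,
    )
    return rec, truth


# --------------------------------------------------------------------------
# onset-rate tables (multiplicative genotype model)
# --------------------------------------------------------------------------

def simulate_rate_table(
    cis_effects: Sequence[float],
    cds_effects: Sequence[float],
    base_rate: float,
    noise_cv: float = 0.0,
    n_per_cell: int = 10,
    seed: int = 0,
    cis_labels: Sequence[str] = CIS_ELEMENTS,
    cds_labels: Sequence[str] = CDS_ELEMENTS,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an onset-rate table under the multiplicative model.

    Cell (i, j) holds ``n_per_cell`` gamma-distributed draws with mean
    ``base_rate * cis_i * cds_j`` and coefficient of variation
    ``noise_cv`` (exact values when ``noise_cv`` is 0).  Returns a
    long-format DataFrame (cis, cds, zygosity, replicate_id, onset_rate)
    and a truth dict with the factors and cell means.
    """
    cis = np.asarray(cis_effects, dtype=float)
    cds = np.asarray(cds_effects, dtype=float)
    if len(cis) != len(cis_labels) or len(cds) != len(cds_labels):
        raise ValueError("effects and labels must align")
    if np.any(cis <= 0) or np.any(cds <= 0) or base_rate <= 0:
        raise ValueError("effects and base_rate must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be at least 1")

    rng = np.random.default_rng(seed)
    rows = []
    cell_means = {}
    for ci, cl in zip(cis, cis_labels):
        for dj, dl in zip(cds, cds_labels):
            mean = base_rate * ci * dj
            cell_means[(cl, dl)] = mean
            if noise_cv == 0:
                draws = np.full(n_per_cell, mean)
            else:
                shape = 1.0 / noise_cv**2
                draws = rng.gamma(shape, mean / shape, size=n_per_cell)
            for r, v in enumerate(draws):
                rows.append((cl, dl, "hom", r, float(v)))
    table = pd.DataFrame(
        rows, columns=["cis", "cds", "zygosity", "replicate_id", "onset_rate"]
    )
    truth = {
        "base_rate": float(base_rate),
        "cis_effects": dict(zip(cis_labels, cis)),
        "cds_effects": dict(zip(cds_labels, cds)),
        "cell_means": cell_means,
    }
    return table, truth


# --------------------------------------------------------------------------
# behavioral trials
# --------------------------------------------------------------------------

def simulate_oviposition_trial(cfg: TrialConfig) -> TrialRecord:
    """Simulate one 16-h two-choice egg-laying trial.

    The total egg count is negative binomial with mean
    ``n_flies * mean_eggs_per_fly`` (between-trial overdispersion set by
    ``dispersion``); in the ``co2`` condition each egg lands on the 1%
    side with probability ``(1 + true_opi) / 2``.
    """
    rng = np.random.default_rng(cfg.seed)
    mu = cfg.n_flies * cfg.mean_eggs_per_fly
    if mu == 0:
        total = 0
    else:
        k = cfg.dispersion
        total = int(rng.negative_binomial(k, k / (k + mu)))
    if cfg.condition != "co2":
        return TrialRecord(n_flies=cfg.n_flies, condition=cfg.condition,
                           eggs_pooled=total)
    p_high = (1.0 + cfg.true_opi) / 2.0
    eggs_high = int(rng.binomial(total, p_high)) if total else 0
    return TrialRecord(
        n_flies=cfg.n_flies,
        condition="co2",
        eggs_high=eggs_high,
        eggs_low=total - eggs_high,
    )


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

def simulate_ct_table(cfg: CtConfig) -> pd.DataFrame:
    """Simulate a Ct table (long format: gene, sample, bio_replicate,
    tech_replicate, ct).

    Each biological replicate carries an independent Gaussian offset per
    (gene, sample); each well adds independent technical noise.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for (gene, sample), mean in cfg.means.items():
        for b in range(cfg.n_bio):
            bio = rng.normal(0.0, cfg.biological_sd) if cfg.biological_sd else 0.0
            for t in range(cfg.n_tech):
                tech = rng.normal(0.0, cfg.technical_sd) if cfg.technical_sd else 0.0
                rows.append((gene, sample, b, t, mean + bio + tech))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "bio_replicate", "tech_replicate", "ct"]
    )


def ct_config_from_rq(
    rq_by_sample: Mapping[str, float],
    target_gene: str = "Gr63a",
    reference_gene: str = "TBP",
    calibrator: Optional[str] = None,
    reference_ct: float = 24.0,
    calibrator_target_ct: float = 30.0,
    **kwargs,
) -> CtConfig:
    """Build a CtConfig whose programmed fold-changes equal ``rq_by_sample``.

    The reference gene is flat across samples; the target gene's mean Ct
    for each sample is shifted by ``-log2(RQ / RQ_calibrator)`` relative
    to the calibrator, so the ddCt pipeline recovers the requested RQs in
    the noiseless limit.
    """
    if calibrator is None:
        calibrator = min(rq_by_sample, key=rq_by_sample.get)
    if calibrator not in rq_by_sample:
        raise ValueError("calibrator must be one of the samples")
    rq_cal = rq_by_sample[calibrator]
    means = {}
    for sample, rq in rq_by_sample.items():
        if rq <= 0:
            raise ValueError("RQ values must be positive")
        means[(reference_gene, sample)] = reference_ct
        means[(target_gene, sample)] = calibrator_target_ct - np.log2(rq / rq_cal)
    return CtConfig(means=means, **kwargs)


# --------------------------------------------------------------------------
# I/O: recordings as an HDF5 container + JSON sidecar
# --------------------------------------------------------------------------

def write_recording(path, rec: VoltageRecording, truth: Optional[GroundTruth] = None) -> None:
    """Write a recording to HDF5 (one dataset per replicate epoch plus the
    full sweep) with a JSON metadata sidecar next to it."""
    import h5py

    path = str(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("sweep", data=rec.samples)
        for i, (on, dur) in enumerate(rec.epochs):
            s0 = int(round(on * rec.sampling_rate))
            s1 = int(round((on + dur) * rec.sampling_rate))
            f.create_dataset(f"replicate_{i}", data=rec.samples[s0:s1])
        if truth is not None:
            g = f.create_group("ground_truth")
            for u, times in truth.spike_times.items():
                g.create_dataset(f"unit_{u}_times", data=times)
            g.create_dataset("lfp", data=truth.lfp)
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "epochs": [list(e) for e in rec.epochs],
        **{k: v for k, v in rec.metadata.items()},
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_recording(path) -> VoltageRecording:
    """Read a recording written by :func:`write_recording`."""
    import h5py

    path = str(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    with h5py.File(path, "r") as f:
        samples = f["sweep"][:]
    return VoltageRecording(
        samples=samples,
        sampling_rate=meta.pop("sampling_rate"),
        epochs=[tuple(e) for e in meta.pop("epochs")],
        metadata=meta,
    )
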