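# Methods

This note documents the models, estimators, and numerical choices
behind `co2sense`, and what the synthetic-data round trips do and do
not demonstrate about real recordings.

## Synthetic sensillum recordings

A recording is the sum of four point-process spike trains rendered as
stereotyped waveforms, a slow local field potential (LFP), and white
Gaussian noise.  The default protocol mirrors the study design the
package targets: a 2-s CO₂ pulse with 10-s rests, five replicate
pulses per sensillum, 2 s of pre-stimulus baseline, 10 kHz sampling.

**Spiking model.**  Each unit is an inhomogeneous renewal process with
an absolute refractory period (default 1.5 ms).  Candidate events are
drawn by thinning a homogeneous process at the hazard

    h(t) = r(t) / (1 − r(t)·τ_ref),

with the hazard suppressed for τ_ref after each accepted event.  The
correction in the denominator makes the *realized* rate equal the
programmed rate function r(t); a naively thinned Poisson process with
dead time would realize only r/(1 + r·τ_ref) (for example ~182 spikes/s
when 250 are programmed).  Because mean inter-event interval equals
τ_ref + 1/h, this identity is exact in equilibrium; the only residual
bias is a transient of order τ_ref after rate steps, which is
negligible for the windows used here.  The model requires
r(t)·τ_ref < 1.

The CO₂-responsive unit follows a step-and-adapt rate function: at
stimulus onset the rate jumps to `peak_rate` and relaxes exponentially
(time constant `adaptation_tau`, default 250 ms) toward `steady_rate`,
returning to `baseline_rate` at offset.  The other three units fire at
constant baseline rates.  `GroundTruth.true_rate` integrates this
rate function over any window, which is what "programmed value" means
in all recovery tests.

**Waveform.**  Spikes are rendered as a fixed biphasic template of
1.5 ms total duration: a sharp positive lobe (27% of the duration)
followed by a shallow negative lobe at 25% relative amplitude,
scaled per unit by `amplitude × noise_sd` (with `noise_sd = 0` the
amplitude is in mV directly).  Only the amplitude class carries
information downstream, so the template is a modelling convenience; it
is deliberately sharp-peaked so that near-coincident spikes from
different units remain resolvable, which is also a property of real
basiconic sensillum spikes.

**LFP.**  From each stimulus onset the LFP ramps down at `onset_slope`
(mV/s, ≤ 0) until it reaches `deflection_depth`, holds, and after
offset recovers exponentially with `recovery_tau`.  Defaults
(−3 mV/s, −1.5 mV, 1 s) give deflections of the magnitude seen in
odor-evoked antennal recordings.

**CO₂ concentration** is carried as metadata only (`co2_fraction`,
default 0.01); the kinetic parameters are explicit and not derived
from it.

## Spike detection and sorting

Detection band-passes the trace (zero-phase Butterworth, 300–3000 Hz,
order 4), estimates the noise scale robustly as MAD/0.6745 with an
absolute floor of 10⁻³ mV (so clean, noise-free traces threshold
sensibly), and reports positive local maxima above `k_mad` × scale
(default 5).  The minimum separation between reported peaks is 0.5 ms —
deliberately *shorter* than a neuron's refractory period, because
spikes of different units in a multi-unit sensillum recording can fall
arbitrarily close together; a 1.5-ms peak separation would silently
merge a measurable fraction of cross-unit near-coincidences.  Within a
sorted unit, inter-spike intervals still respect the refractory period.

Sorting clusters peak amplitudes into *k* classes by exact
dynamic-programming segmentation of the sorted amplitudes (minimum
within-class sum of squares).  This is the 1-D specialization of
k-means that is globally optimal, deterministic, and invariant under
uniform amplitude rescaling — no seeds, no initialization sensitivity.
Labels are 1..k by ascending mean amplitude.

The CO₂-responsive unit is selected by stimulus-locked rate contrast
(in-stimulus minus pre-stimulus rate, ties to the lowest label, with a
warning when no unit shows positive contrast), not by amplitude rank,
since the amplitude rank of the responsive neuron is a biological fact
the analysis should not assume.

**What fidelity numbers mean.**  Sorting fidelity is quantified on the
`fidelity_config` conditions: amplitude classes at 8/14/20/26 noise SD
(6-SD gaps), baseline rates 1–3 spikes/s, responsive unit peaking at
100 spikes/s.  Under these conditions detection + sorting recovers
≥ 99% of ground-truth spikes with correct labels (a spike counts as
recovered when a correctly labelled event lies within 0.5 ms).  The
residual ~0.8% is dominated by genuinely overlapping cross-unit spikes
— amplitude superposition and trailing-lobe distortion — which no
amplitude-only sorter can resolve; overlap resolution by template
matching is out of scope.  At substantially higher aggregate rates or
smaller amplitude gaps the overlap fraction grows accordingly, so the
99% figure should not be extrapolated to arbitrary recordings.

## PSTH and response metrics

PSTHs use the fixed hierarchy replicate → neuron → group: per-replicate
binned counts divided by the bin width (default 50 ms), averaged within
neuron, then an unweighted mean across neurons.  This matches the
convention where each grey line is one neuron's five-replicate average
and the colored line averages the neurons; it is *not* a pooled-spike
average, so neurons with more spikes do not dominate.

Scalar metrics, per stimulus epoch and averaged over epochs:

| metric | definition | default window |
|---|---|---|
| onset mean | count / width from valve-opening onset | 100 ms or 20 ms |
| onset max | max sliding-bin rate within the stimulus (bin = PSTH bin width, 1-ms steps) | 50-ms bin |
| baseline | count / width immediately before onset | 1000 ms |
| steady state | count / width, final part of the 2-s stimulus | 1000 ms |
| LFP slope | OLS slope of voltage vs time from onset | 320 ms or 750 ms |

Onset is the stimulus valve epoch start from metadata, not an
LFP-derived latency.  All windows are half-open `[start, start+width)`.
The slope uses ordinary least squares rather than an endpoint
difference because it is unbiased under additive noise and is the
standard reading of "rate of change" for a noisy ramp.  An
`extract_lfp` helper (zero-phase low-pass, 100 Hz) isolates the slow
component from a raw trace before slope fitting.

## The genotype scaling model

Nine genotypes form a 3 × 3 table of (cis-regulatory element × coding
sequence), each cell holding replicate onset rates.  When a cell could
only be recorded heterozygous, its homozygous rate distribution is
predicted from the rest of the table under a multiplicative-effects
assumption (cell mean = base × cis effect × CDS effect):

1. For each *donor* CDS `d` ≠ target CDS, a scaling factor is the
   unweighted mean over the two non-target cis elements `c` of
   `mean(c, target_cds) / mean(c, d)`.
2. `n_points` rates (default 5) are drawn without replacement, seeded,
   from the donor cell `(target_cis, d)` and multiplied by that factor.
3. The two routes are pooled into 2 × `n_points` predicted rates.

Pooling uses both routes symmetrically; the two 5-point estimates have
no principled ordering, and pooling uses all the information either one
contains.  Heterozygous recordings of the target cell are reported
alongside but never enter the prediction.  Under an exactly
multiplicative table the procedure is exact for every cell (the factor
reduces to the CDS-effect ratio and the donor cell supplies
base × cis), and predictions scale equivariantly with any global
rescaling of the table.  The route mapping is overridable via the
`routes` argument for designs where different donor cells are
appropriate.

Validation predicts a cell with *known* homozygous recordings — the
prediction never touches the control cell, because the factor ratios
use only the other cis elements and the donors only the other CDS — and
compares predicted vs recorded rates with a two-sided Wilcoxon rank-sum
test.  Simulations in the test suite show the validation is
non-significant in ≥ 90% of runs when the multiplicative model holds
(noise CV 0.1, 10 rates/cell) and flags a 30% non-multiplicative
interaction in ≥ 80% of runs at matched noise.

## Behavioral indices

- OPI = (eggs on the 1% CO₂ side − eggs on the 0.04% side) / total
  eggs, per 16-h two-choice trial.  Zero-egg trials have no OPI
  (`UndefinedIndexError`) but are retained in egg-count summaries, as
  are the undivided air / no-air control trials.
- PPI: per 15-min reading, (flies on the 1% side − flies on the 0.04%
  side) / flies counted, averaged over the two readings taken with the
  CO₂ sides swapped.  Counts are stored relative to the CO₂ condition,
  so the swap is handled in the bookkeeping.  Flies not visible in
  either half of a reading are excluded from that reading's
  denominator — the index describes the flies whose position is known.
- Eggs per fly divides by the number of flies *loaded*, not counted.

The trial simulator draws total eggs from a negative binomial (mean
`n_flies × mean_eggs_per_fly`, default 12 × 5; dispersion 2) to mimic
the heavy between-trial variability of overnight oviposition assays,
then allocates eggs to the high-CO₂ side binomially with probability
(1 + true_opi)/2.  Consequently the expected OPI equals `true_opi`
and pooled-egg OPI estimates converge at the binomial rate.

## Statistical battery

- **Holm correction** (reported as Q-values) via
  `statsmodels.stats.multitest`; the package convention is that every
  family of pairwise tests is Holm-adjusted.
- **Wilcoxon tests** via scipy: rank-sum (Mann–Whitney) for independent
  groups, signed-rank behind a `paired` flag.  Exact p-values for
  small, tieless samples; normal approximation with tie correction
  otherwise.  Independent-group designs default to the rank-sum form
  even where a protocol text says "signed-rank", because unpaired
  designs admit no meaningful pairing; the paired form remains
  available.
- **ANOVA + Tukey HSD** via scipy/statsmodels (classical pooled
  variance, studentized-range distribution), with all-pairs adjusted
  p-values.
- **Compact letter display** by the insert–absorb algorithm: start
  with one column holding all groups; for each significant pair, split
  every column containing both members into two columns (each missing
  one member), then absorb columns contained in another.  Letters are
  assigned per column, ordered by each column's first group.  By
  construction a significant pair never shares a letter and every
  non-significant pair shares at least one; the test suite checks both
  invariants and letter-count minimality against a brute-force
  clique-cover oracle on up to six groups.
- **qPCR relative quantification.**  Technical replicates are collapsed
  by the arithmetic mean of Ct; ΔCt = Ct_target − Ct_reference per
  biological replicate; amplification efficiency is fixed at 2 (100%).
  The `ddct` convention exponentiates ΔCt − mean ΔCt(calibrator), the
  `dct` convention exponentiates ΔCt directly; in both, per-replicate
  RQs are finally rescaled by the calibrator sample's mean RQ, which
  pins the calibrator's mean RQ to exactly 1.  Under that normalization
  the two conventions produce identical numbers (they differ only by
  the constant removed in the rescale); both names are kept because
  both appear in qPCR reporting practice and the intermediate ΔΔCt
  column is convention-specific.
- **Pearson correlation** via scipy, with constant inputs rejected as
  undefined rather than returned as NaN.

The family-wise error of the Kruskal–Wallis + pairwise-Wilcoxon + Holm
pipeline is checked by simulation (1000 global-null replicates, 3
groups of 8): the any-pair false-positive rate stays at or below 6% at
α = 0.05 — below α because of the discreteness of exact rank tests.

## qPCR fold-change round trip

Raw antennal Ct values are not published as machine-readable data, so
the fold-change check is a round trip: a synthetic Ct table is
programmed with the study's species means — RQ 5 (D. subpulchrella),
1.2 (D. suzukii), 1 (D. melanogaster calibrator), 3 biological × 3
technical replicates, TBP reference flat at 24 cycles — with biological
and technical SDs of 0.25 and 0.15 cycles, typical of careful SYBR
qPCR.  The ΔΔCt pipeline recovers the programmed means exactly in the
noiseless limit and within the replicate-noise sampling band
otherwise.  This demonstrates the estimator, not the biology: it cannot
validate the original measurements, only that the quantification
recovers what the data contain.

## Problem sizes and numerical choices

Recovery statistics are computed at fixed, seeded scales chosen to make
Monte-Carlo error small relative to the tolerances being checked: 200
simulated sensilla for sorting fidelity and rate recovery, 500 tables
for the scaling model, 500 ramps for the LFP slope, 1000 replicates for
the family-wise error, ≥ 10 000 pooled eggs for the OPI round trip.
All generators take explicit integer seeds and are bit-reproducible;
clustering and letter assignment are deterministic by construction.
Degenerate inputs fail loudly: empty traces, fewer distinct amplitudes
than classes, zero-egg trials, constant correlation inputs, and
all-identical ANOVA groups raise typed errors instead of returning
silent values.

## Known limitations

- No biophysics: the simulator reproduces the statistical structure of
  recordings (amplitude classes, adaptation, LFP ramp), not
  transduction mechanisms; passing round trips say nothing about real
  receptor kinetics.
- Amplitude-only sorting cannot resolve overlapping spikes; fidelity
  figures hold for well-separated classes at moderate rates.
- The scaling model is the study's empirical procedure; it assumes
  multiplicative cis × CDS effects and does not model dominance or
  dosage mechanisms.
- The LFP is treated as a single summed signal; no source separation
  is attempted.
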