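# Methods

This note records the models, numerical choices and limitations behind
`emma_eog`, in the order the data flow through the package.

## Signal model and epoching

A recording is one EOG channel in mV (post-amplification, hardware band-pass
0.5–29 Hz assumed) and optionally an RMS-EMG channel, both sampled at a
common rate (default 64 Hz).  The epoch grid is anchored at sample 0 with
4-s epochs (256 samples at 64 Hz); a trailing partial epoch is discarded.
Sample indices are 0-based with half-open spans.  Zeitgeber time is supplied
by the user as the ZT hour of the first sample (ZT0 = lights on in a 12:12
light/dark cycle); 2-h bins are labelled by their right edge (ZT2 = [ZT0,
ZT2)).  Software re-filtering of externally supplied raw signals
(`bandpass_eog`) exists but is off by default — recorded signals are
expected to be hardware filtered already.

File formats are plain text: CSV with one column per channel, hypnograms as
one WAKE/NREM/REM label per epoch.  EDF is read through `mne` when
installed; fixtures are always written as CSV so they survive any
text-only pipeline.

## The low-cut filter

The slow band is removed with a stationary (undecimated) dyadic wavelet
transform using the quadratic-spline biorthogonal wavelet `bior2.2`, 8
decomposition levels, with detail levels 4–8 *and* the final approximation
zeroed before inverse transform.  Zeroing the approximation matters: a
retained approximation would keep the < 0.125 Hz content the filter exists
to remove.  The measured frequency response (FFT of the impulse response,
which is also the oracle used in the tests) is ≤ 0.06 across 0.25–2 Hz,
half-power near 4 Hz, and flat (ripple < 5%) above ~6 Hz.  Any dyadic
filter bank with this stop band is equivalent for the purpose; the wavelet
is configurable.  Boundary handling is symmetric extension (128 samples),
cropped back to the input length.  The filter is linear and shift-invariant,
so filtering the whole recording once and slicing windows from it is
identical (away from the recording edges) to filtering each window — the
batch detector exploits this.

A consequence worth knowing: a unipolar deflection loses its DC content, so
a filtered eye-movement pulse of ~95 ms keeps only ~65% of its peak value
and acquires flanking undershoots of roughly a quarter of the filtered peak.
Both effects shape the detector's operating point below.

## Candidate detection

The continuous wavelet transform uses the real Mexican hat (second
derivative of a Gaussian, two vanishing moments) on a geometric grid of 8
octaves × 8 voices, finest scale 2 samples.  Candidates are local maxima of
the finest-scale modulus (strict `>` on the left, `≥` on the right, so
plateaus resolve to the earliest sample) that exceed the universal threshold
sd(modulus) × √(2 ln n) with n = 256, the per-epoch sample length.

Because the threshold uses the standard deviation of the *modulus* (≈ 0.6 ×
the coefficient sd for Gaussian noise), it sits near 2 coefficient-sd and is
deliberately permissive: on pure noise several candidates per epoch survive
it.  Rejection of noise is the job of the two secondary criteria; measured
end-to-end, the false-detection rate on event-free synthetic recordings is
≈ 0.02 per epoch (asserted < 0.5 in the tests).

In batch runs the sd is taken over the finest-scale modulus of the whole
sleep portion of the recording (with n kept at 256).  This follows the
fixed, training-set-style threshold derivation and avoids a failure mode of
purely per-window statistics: in burst-rich windows the events themselves
inflate the local modulus sd and suppress their smaller neighbours
(measured sensitivity loss ≈ 8 percentage points).  `threshold_support =
"window"` restores fully local behaviour and is what a standalone
single-epoch call uses.

## Delineation and criteria

An eye movement is start → peak → end, all change points of the filtered
signal.  The wavelet localises the peak to within ±1–2 samples, so the peak
is the *nearest* extremum of the branch indicated by the sign of the finest-
scale coefficient (positive → local maximum); start and end are the nearest
opposite extrema before and after.  A candidate with no bracketing extremum
is discarded and its ±5-sample neighbourhood excluded from the lag-2
background.

The amplitude criterion keeps a signed peak only beyond 4 × P85 (or below
4 × P15) of the filtered signal; the lag-2 criterion requires the maximal
|x[t] − x[t−2]| touching the event span to exceed 2 × Q95 of the lag-2
differences of the candidate-free background.  In batch runs both supports
are the sleep portion of the whole recording, for the same reason as above.

Adjacent singularities: delineations describing the same deflection collapse
to one event; a follower that shares a change point with its predecessor but
fails the amplitude criterion is absorbed into the predecessor's return
phase; same-direction stacked deflections sharing only a start/end change
point count separately.  Overlapping delineations that are neither resolve
to the larger absolute deflection — the rationale is that a filter-induced
rebound after (or between) large deflections is the return phase of its
neighbour, not an eye movement of its own.  Detected events are therefore
strictly ordered and non-overlapping.

Each epoch is analysed on three windows (−1 s, 0 s, +1 s; the third window
is read as the symmetric counterpart of the first).  Detections whose peaks
agree within 2 samples are deduplicated keeping the one farthest from its
window's edges, and an event belongs to the epoch containing its peak.
Every threshold is relative to the signal, so detection is exactly
equivariant under positive rescaling, and the pipeline contains no
randomness.

Reported morphology: signed filtered amplitude at the peak in mV (including
amplification — no gain correction), duration start→end in ms, deflection
velocities |Δ|/Δt in mV/ms, direction from the amplitude sign.

## Validation metrics

Event level: greedy one-to-one matching of detection peaks to reference
peaks within a tolerance (default 50 ms) gives sensitivity and PPV.  Epoch
level: 2 × 2 tabulation of event presence per epoch gives sensitivity,
specificity, PPV and NPV — the granularity at which visual validation is
typically done.  Both are reported because event-wise and epoch-wise
figures answer different questions.

## Bursts, densities, stability, arousals

A burst is a maximal run of ≥ 2 events whose end→start gaps are ≤ 200 ms
(peak-to-peak gaps are a config alternative).  REM density is events per
4-s epoch of a stage; burst density counts bursts by their first event's
epoch.  Densities are emitted per stage × time bin (whole day, light/dark
period, or 2-h ZT bins); bins with no epochs of the stage are omitted.

The ICC of a per-animal-per-day measure comes from the one-way
random-intercept model y_ij = μ + a_i + e_ij.  Two estimators: classical
ANOVA moments (negative between-variance truncated at 0) and REML via the
closed-form profiled likelihood in the variance ratio, optimised as a
bounded scalar problem (tolerance 1e-12) — exact, fast, and identical to
the ANOVA solution on balanced designs with interior solutions; statsmodels
MixedLM serves as an independent cross-check in the tests.  Benchmark
labels use half-open intervals with boundaries assigned upward (0.2 →
"fair").  No confidence intervals by default; a seeded animal-resampling
bootstrap is available.  Note the estimator property quantified in the
tests: with few animals (k = 6) the mean of per-dataset ICC *estimates*
sits ≈ 0.07 below the true ratio (Jensen bias of a noisy ratio), even
though the variance components themselves are recovered without bias — an
inherent property of the statistic, reproduced identically by lme4.

Micro-arousals are maximal runs of RMS-EMG above k × a 30-s rolling-median
sleep baseline (k = 3 by default; both config-exposed, since no published
amplitude criterion exists), shorter than 4 s; longer runs are state
transitions and are excluded.  Association of events/bursts with arousals
is interval overlap with an optional padding window (default 0 ms), or
same-epoch co-occurrence (`mode="epoch"`), the mode used for
published-style tables.  Per-stage 2 × 2 tables are tested with the Pearson
chi-square, Yates continuity correction by default — the correction is the
convention under which the published worked-example statistics (158.4 and
25.4 on the percentage-implied counts) reproduce exactly, verified against
the textbook formula.  Externally supplied arousal annotations bypass EMG
detection entirely.

## The synthetic generator

The generator emulates the recording conditions the detector targets, not
mouse physiology in general:

- **Stage architecture**: alternating WAKE/NREM/REM bouts with exponential
  lengths (means per phase: WAKE 120 s light / 480 s dark, NREM 360/240 s,
  REM 60/50 s; NREM→REM probability 0.35/0.20), giving more NREM in the
  light phase, on a 4-s epoch grid.
- **EOG** = band-limited Gaussian noise (0.5–29 Hz, sd 10 mV) + slow
  leakage (0.5–2 Hz, sd 20 mV, stressing the low-cut filter) + biphasic
  events.  The event template is a raised-cosine pulse (half-period out,
  half-period back; a derivative-of-Gaussian alternative would be a
  one-line swap), with even sample counts so the peak falls exactly on a
  sample.
- **Events**: rates 0.96 per REM-sleep epoch and 0.18 per NREM epoch;
  cluster model with burst probability 0.19 and burst size 2 + Poisson(0.5),
  chosen so ~37% of events fall in bursts; amplitudes N(124, 83²) mV
  truncated at 0 (46% upward); durations N(95, 36²) ms truncated
  symmetrically at [45, 145] ms so the realized mean stays 95 ms.  Clusters
  are placed uniformly within their epoch with ≥ 250 ms separation;
  placements that do not fit are dropped, which leaves realized REM-stage
  rates ~5% below nominal at the default density.
- **EMG/arousals**: baseline 1.0 ± 0.1 a.u. with 5× surges of 0.5–3 s;
  spontaneous arousals at 0.5/min of sleep plus event-coupled arousals with
  stage/burst-specific probabilities (0.73 NREM-burst, 0.32 NREM-single,
  0.07 REM-burst, 0.10 REM-single), mimicking the published association
  pattern.

All draws come from a single `numpy.random.default_rng` (PCG64) seeded from
the config, so recordings, ground truth and written fixtures are
reproducible bit-for-bit.  Ground-truth burst membership is computed by the
same ≤ 200 ms gap rule the metrics use.

What the generator does *not* emulate: realistic EEG, movement artifacts,
electrode drift, inter-animal variability in noise levels, or any
dependence of event morphology on vigilance stage beyond rates.  Passing
the recovery suites therefore demonstrates the pipeline's correctness under
its stated signal model, not field performance on recorded animals.

### Detector operating point

The amplitude criterion makes events below ≈ 4 × P85 of the background
invisible by construction, and the low-cut filter attenuates long events
further.  The detector recovery suite therefore evaluates recordings whose
amplitudes are drawn at or above that detectability floor (the analytic
4 × P85 of the Gaussian background, ≈ 93 mV at the default noise levels),
with everything else at defaults: measured event-level sensitivity is
0.92–0.99 and PPV 0.94–0.97 across seeds at ~1100 sleep epochs per run.
Under the untruncated published amplitude distribution, overall sensitivity
drops to ≈ 0.7 (the sub-threshold share) while sensitivity restricted to
supra-floor events stays ≥ 0.9 — the intended reading of the criterion.

## Problem sizes

Simulations in the test-suite and acceptance script use 0.5–6 h recordings
(450–5400 epochs), 500-replicate ICC designs and 1000-table chi-square
calibrations; the full test suite runs in well under a minute and the
acceptance script in a few seconds, so all sizes could be scaled up freely.

## Known limitations

- Events slower than ~150 ms with amplitudes near the detection floor are
  attenuated into invisibility by the low-cut filter; a published
  sensitivity in the mid-80% range against human scorers is consistent with
  this physics.
- The 64 Hz sampling rate caps detectable event sharpness; everything above
  29 Hz is gone at acquisition.
- The lag-2 criterion deliberately rejects slow, low-velocity deflections;
  it trades sensitivity to sluggish events for robustness to regular
  artifacts.
- Micro-arousal detection depends on two unpublished constants (baseline
  window, k); treat absolute arousal counts as config-dependent and prefer
  externally scored annotations where available.
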