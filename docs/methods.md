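# Methods

## Problem and scope

`qrsbench` quantifies the *temporal* quality of QRS detection: how the
classic confusion-count statistics change when the pairing tolerance (DTT)
between a reference beat label and an algorithm beat label is tightened,
and how stable the detection instant is under added muscle-artifact (EMG)
noise. The package contains five cooperating parts: WFDB/CSV I/O, a
synthetic-data generator, the relative-SNR noise mixer, a traced
Pan-Tompkins-style detector, and the evaluation/sweep machinery.

## Pairing and statistics

**Tolerance pairing.** References and detections are matched one-to-one
when `|det − ref| ≤ DTT` samples (the comparison is inclusive, reading the
"must not exceed" rule literally). The matching is greedy by ascending
absolute distance with ties broken toward the earlier reference, then the
earlier detection. Greedy matching equals the maximum-cardinality matching
whenever consecutive events are separated by more than 2·DTT — always true
for the standard grid (DTT ≤ 59 samples) against a detector with a >108
sample refractory — and never exceeds it otherwise; both facts are property
tested against an exhaustive brute-force matcher.

**Statistics.** DER = (FP+FN)/(TP+FN), Se = TP/(TP+FN), PPV = TP/(TP+FP),
F1 = 2·PPV·Se/(PPV+Se), all kept at full precision internally and rounded
to two decimals only for display. DER deliberately may exceed 100%.
A zero denominator (no reference beats, or no detections for PPV) raises
`UndefinedMetricError` rather than returning a number.

**JF benchmark.** Proximity pairing is mutual-nearest-neighbor with no
tolerance cap; equidistant candidates resolve toward the earlier label.
Unpaired detections count as FP_JF and unpaired references as FN_JF — this
includes labels before the first and after the last matched pair, a case
the benchmark's original description leaves open. Δ̄ is the mean of
*absolute* pair distances ("average time distance" is read as a magnitude),
converted to ms via the sampling rate. JF = F1_JF · 1/(1 + Δ̄/12 ms).

**DTT in ms.** `dtt_to_ms` reports `round(DTT·1000/fs, 2)`; at 360 Hz this
gives 8.33 ms for 3 samples and 97.22 ms for 35. Published tables of the
same grid occasionally print values computed from a pre-rounded 2.778 ms
sampling period (97.23, 86.12, 163.90, …); the computed value is used
everywhere here.

## Noise mixing

RMS is computed over the full record (N = record length), and the SNR is
*relative*: the raw record's intrinsic noise stays in the numerator, with
no attempt to estimate clean-signal power. The scaling factor
`m = (RMSs/RMSn)·10^(−tSNR/20)` makes the round trip
`relative_snr(signal, m·noise)` exact to well below 1e−9 dB (it is exact
in floating point up to log/exp rounding). "No noise added" is a sentinel
(`None`) mapped to m = 0, not an infinite dB value. The noise channel is
channel 0 of the noise record (the source database does not state which
channel was used; the choice is recorded in mixing manifests). If a noise
trace is shorter than the signal it is tiled end-to-end, if longer it is
truncated — real database records are equal length, so this path only
serves synthetic inputs.

## Detector

The feature chain is causal throughout: order-1 Butterworth bandpass
5–15 Hz (run with `sosfilt`, no forward–backward filtering), first
difference, element-wise squaring, and a trailing moving average over
`round(150 ms · fs)` samples (54 at 360 Hz) with a growing window during
warm-up. **No group-delay compensation is applied anywhere**, and the
reported detection point is the feature-signal candidate index itself. Both
choices are deliberate: the object of study is precisely the uncompensated
delay (tens of samples) and its interaction with the plateau of the moving
average.

The decision stage scans *strict* local maxima (`mwa[i−1] < mwa[i] and
mwa[i+1] < mwa[i]`; a flat plateau yields no candidate — kept verbatim,
since this ambiguity is the mechanism behind the noise-improves-DER
anomaly). A candidate is accepted iff it exceeds the adaptive threshold
and lies more than 0.3·fs samples (300 ms, an extension of the classic
200 ms physiological refractory) after the previous label. Threshold
updates follow the classic recipe: running signal peak ← 0.125·v +
0.875·previous on accepted candidates, running noise peak likewise on
rejected ones, threshold = noise + 0.25·(signal − noise). When the gap
since the last label exceeds 1.66× the running 8-interval RR average, the
gap's rejected candidates are re-scanned at half threshold and the largest
is emitted retroactively (signal peak ← 0.25·v + 0.75·previous); whether
the original implementation emits retroactively or merely adapts its
threshold is unspecified, so retroactive emission is implemented and such
labels are flagged `searchback` in the trace.

**Initialization.** The running signal/noise peaks seed from the max and
mean of the feature signal over the first 2 s, and candidates in the first
300 ms are never accepted. Both rules are data-driven and homogeneous of
degree 2 in the input amplitude, so detections are invariant under any
positive rescaling of the input — a property test.

**Filter constants are an open degree of freedom.** The exact bandpass
design of the studied implementation is not published; the 5–15 Hz order-1
causal choice is this package's documented default, and every constant sits
in `DetectorConfig` so trace tables from a specific implementation can be
matched empirically.

**Trace.** Every candidate evaluation is a `CandidateTraceRow` with the
four condition booleans; `accepted` is by construction their conjunction
(warm-up suppression folds into the threshold flag). Replaying the trace
(`accepted or searchback` rows) reproduces the beat labels exactly.
`trace_window` returns the local-peak rows of a strip bracketed by
boundary-sample rows, mirroring the truth-table layout used for
strip-level audits.

## Synthetic data

The generator states a fixed world; it is not tuned to outcomes:

* ECG: 360 Hz, single channel, millivolts. QRS = Gaussian bump with
  SD = qrs_width_ms/5 (default width 100 ms, amplitude 1 mV — a typical
  R amplitude in lead II), optional opposite-sign T bump 300 ms later
  (0.2 mV), sinusoidal baseline wander (0.05 mV at 0.3 Hz). RR intervals
  either given explicitly or Gaussian (mean 0.8 s ≈ 75 bpm, SD 0.05 s),
  floored above the 200 ms physiological refractory. Annotations are the
  exact template centers — ground truth coincides with the waveform by
  construction.
* Noise: Gaussian, band-limited to 15–110 Hz (order-4 Butterworth) so it
  overlaps the detector passband as real EMG artifact does, rescaled to
  the requested RMS exactly.
* All randomness flows through an explicit integer seed
  (`numpy.random.default_rng`); there is no global random state, and the
  mixing/detection/evaluation stages are fully deterministic.

**What a green synthetic test does and does not establish.** The synthetic
beats are identical, so the detector's delay is *constant* (≈39 samples
with the defaults) and tightening DTT past it flips the record from perfect
to total failure in one step; real records show a graded collapse because
their beat morphology and local noise vary. Synthetic tests therefore
establish the pipeline's correctness (counts, pairing, pooling, SNR
arithmetic, refractory and scale invariances, the existence and direction
of the plateau-delay anomaly) but not the database-level DER magnitudes,
which depend on real morphology variety and on the unpublished filter
constants.

## Sweep and pooling

Detection depends on the record and SNR but not on DTT, so the sweep
factorizes: one detector run per (record, SNR) cell, with pairings re-run
per DTT from the cached detections (48×18 runs and 48×18×15 pairings at
full scale). Pooled statistics for each (DTT, SNR) cell are recomputed
from the *summed* TP/FN/FP counts over records — never by averaging
per-record percentages. TP/TB is emitted alongside DER so both efficiency
conventions are available. Reports are deterministic CSVs plus a JSON
manifest archiving the grids and every detector constant.

## Numerical choices and degenerate inputs

* Tolerance comparisons are inclusive; all tie-breaks resolve toward the
  earlier label, making every pairing deterministic and order-independent.
* Jitter is kept signed (det − ref) internally; the JF discount consumes
  the mean of absolute values. Histogram bins are aligned at zero.
* WFDB format-212 writing rounds to the nearest ADC unit and refuses
  (with the sample index) any amplitude outside the 12-bit range;
  round-trips are exact to one ADC quantum (1/gain mV). Zero-length
  records are rejected at write time.
* Annotation parsing is strict: truncated streams and unknown extended
  codes raise with the byte offset rather than skipping. The beat-code
  alphabet used by `filter_beat_annotations` is the standard WFDB beat set
  (N L R B A a J S V r F e j n E / f Q ?); which codes the published
  database totals counted is not stated, and the pooled count itself is
  the verification.
* Empty detection lists are valid detector output; metrics on them raise
  only where a denominator vanishes.

## Known limitations

* The detector's filter topology is a documented guess (see above);
  database-level truth-table reproduction requires matching those
  constants empirically.
* Multi-segment WFDB records, variable-layout headers and signal formats
  other than 212/16 are unsupported and raise explicitly; annotation
  *writing* is supported only in the CSV dialect.
* Only muscle-artifact-style noise is modelled; baseline-wander and
  electrode-motion noise records, and per-segment SNR scheduling, are out
  of scope.
* The synthetic generator makes no claim of clinical morphology (no
  arrhythmia shapes, single channel only).
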