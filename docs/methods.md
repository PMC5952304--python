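# Methods

This note records the models, operational definitions and numerical
choices behind the package, in the spirit of a methods section: what is
computed, under which assumptions, and where a qualitative rule had to
be given a quantitative form.

## Band-power quantification

The power pipeline mirrors standard practice for chemoconvulsant EEG:
a zero-phase 4th-order Butterworth band-pass (applied forward–backward
with `sosfiltfilt`, so transients are not delayed), followed by epoch
integration of the squared signal. Two bands are predefined: 1–100 Hz
for broadband inspection and 20–70 Hz for power quantification, the
γ-range that discriminates ictal spiking from movement noise.

Per-epoch power is

    P(e) = ( Σ_e x(t)² Δt ) / ( T_epoch / 60 )   [µV²/min]

with `T_epoch = 300 s` by default. The µV²/min convention is fixed by
this package: the integral of the squared µV trace over the epoch,
divided by the epoch length in minutes (a constant 40-Hz sinusoid of
amplitude A therefore yields 60·A²/2 per epoch). Published group power
values from other laboratories are not comparable unless they used the
same normalization, which is typically unstated; absolute power values
are therefore validated against closed forms, not against published
group means. Baseline-relative power subtracts the mean epoch power of
a pre-drug window; negative values mean quieting below baseline and are
expected after an effective anticonvulsant. Epochs are anchored at the
recording start and a trailing partial epoch is dropped (logged).

## Amplitude statistics and thresholds

All detectors are threshold-based, referenced to an event-free baseline
window of the same recording:

* **amplitude statistic** — 95th percentile of |x| over the window.
  The multiplier thresholds ("2×", "3× baseline") apply to this
  statistic. The percentile is robust to the handful of large samples
  a noisy baseline may contain, unlike the peak; the reference is a
  deliberate operational choice, since "2× of a baseline period" does
  not by itself name a statistic.
* **RMS** — used wherever the 1-s sliding RMS envelope is compared to a
  threshold (ramp, shutoff, post-ictal suppression). Envelope criteria
  use `multiplier × baseline RMS`; comparing an RMS envelope to a
  percentile-of-|x| statistic would mix scales.

For zero-mean Gaussian noise the two references are locked together
(95th pct of |x| = 1.96 × RMS), which the synthetic generator exploits
for calibration.

Threshold crossings are strict inequalities throughout (`> 2×`, `> 3×`),
which makes boundary behaviour deterministic and testable.

## Spike detection

A spike is a contiguous supra-threshold excursion of |x|, merged with
neighbours closer than 50 ms (refractory grouping), accepted only if its
width at half peak is below 200 ms — the sharpness gate that encodes
"abrupt and sharp transients". Raising the multiplier can only shrink
the detected set (monotonicity), and scaling trace and baseline together
leaves detections unchanged (amplitude equivariance); both are enforced
by property tests.

## SE-onset rule (acute, 2×/10-min profile)

Onset is the first spike train — inter-spike gaps ≤ 2 s — persisting
more than 10 s and followed within 60 s by the envelope dropping below
threshold ("rapid quieting" after the initial discrete seizure). Trains
that never quiet do not qualify; detection then moves to later trains.

## Five-criterion SRS detector (chronic, 3×/5-min profile)

Candidate episodes are spike trains (gap ≤ 2 s, ≥ 3 spikes). Train
endpoints are first trimmed to the *continuous-spiking core*: a spike
opens (closes) the event only if ≥ 2 further spikes follow (precede) it
within the 2-s gap window. This guards the measured span against
isolated marginal transients — e.g. a sub-threshold ramp spike pushed
over threshold by a noise excursion seconds before dense spiking begins.

Each candidate is audited against five flags; acceptance requires all:

1. **quiet_before** — no detected spike in the 300 s before onset *and*
   pre-onset RMS < 2× baseline RMS. A post-ictal suppression period
   counts as quiet (it contains no spikes), so closely spaced seizures
   are only limited by the 5-min spike-free requirement.
2. **gradual_ramp** — the envelope takes ≥ 2 s to rise from the
   envelope threshold to 90 % of the event maximum. The sub-threshold
   reference point is the end of the last *sustained* (≥ 0.25 s)
   sub-threshold run, so single-sample dips of the sliding RMS do not
   truncate the measured rise time.
3. **sustained_spiking** — event longer than 20 s, and at most 20 % of
   the 1-s windows tiled across it lack a spike.
4. **abrupt_shutoff** — the envelope falls from ≥ 50 % of the event
   maximum to below threshold within ≤ 2 s.
5. **postictal_suppression** — envelope ≤ 50 % of baseline RMS for
   ≥ 30 s, beginning within 15 s of the last spike (the grace window
   admits a brief after-discharge).

"Gradual" (≥ 2 s) and "abrupt" (≤ 2 s) quantify wording like
"typically over several seconds"; both are profile parameters, as are
the suppression fraction (0.5) and every window above. Rejected
candidates are returned with their flags so borderline events can be
reviewed rather than silently discarded.

Seizure duration is the time from the first to the last detected spike
within the accepted event — the period in which spikes persisted, ending
just before the post-ictal depression. It requires at least two spikes.

## Movement-artifact removal

Large single transients not of cerebral origin are removed before
detection: a supra-threshold excursion is deleted (replaced by linear
interpolation) only if it is isolated — no other supra-threshold
excursion within ± 2 s — and shorter than 200 ms. Excursions inside
labelled or detected seizures are never touched, and ictal spikes are
intrinsically protected because they have close neighbours. Removal
must precede SRS screening: an artifact landing in a pre-onset window
would otherwise veto a genuine seizure through the quiet-before rule.
The isolation radius and width bound are this package's operational
reading of "single transients"; removed events are returned as
annotations for audit.

## Synthetic generator

The generator produces the study conditions for validation, not a
physiological simulation:

* **Background** — band-limited (1–100 Hz) Gaussian noise with 1/f
  spectral shaping, rescaled to an exact target RMS (default 10 µV).
* **Spikes** — derivative-of-Gaussian biphasic wavelets (σ = 4–8 ms,
  total width ≈ 30–60 ms), peak amplitudes expressed as multiples of
  the nominal amplitude statistic 1.96 × baseline RMS, so generator
  multipliers and detector ratios share one scale.
* **Seizures** — a linear amplitude ramp (default 8 s) into a sustained
  plateau (default 33 s at 8× baseline, 10 spikes/s), decay within
  0.5 s, then background scaled to 30 % RMS for 60 s. The defaults are
  chosen so a default seizure satisfies all five SRS criteria with a
  clear margin — a borderline fixture would measure detector luck, not
  detector correctness.
* **SE scenario** — an initial discrete seizure (≈ 16 s of spiking,
  then quieting) followed from +36 s by near-continuous 8-Hz spiking at
  4× baseline until the end of the SE interval.
* **Artifacts** — single isolated wavelets (width < 100 ms, default 5×)
  kept ≥ 5 s from any seizure and from each other, so the removal
  oracle is unambiguous.

Ground truth records events *as realized in the rendered trace*: spike
peaks are measured on the final waveform, noise included, because that
is what any threshold detector observes. (With noise-free nominal peaks
the duration oracle is systematically biased: noise makes late-ramp
spikes detectable before their nominal threshold crossing.)

A single seeded RNG stream drives everything; identical configs produce
bit-identical traces and labels. What the generator does **not**
emulate: non-stationary background (sleep/wake spectra), electrode
drift, chewing/grooming artifact trains, after-discharges with complex
morphology, or multi-channel structure. Passing the recovery benchmark
therefore demonstrates that the detectors implement the stated rules
faithfully on signals that obey the rules' premises — not field
performance on arbitrary real recordings.

## Detector-recovery benchmark

Ten seeded 2-h recordings, each with 20 compliant seizures (onsets
343 s apart, leaving > 5 spike-free minutes before every onset) and 20
isolated artifacts placed *inside* the following seizure's pre-onset
window — so the benchmark passes only if artifact removal and detection
cooperate. Reported: sensitivity and precision of accepted events
against ground truth (overlap matching), the maximum absolute error of
recovered durations against the realized supra-threshold spiking
interval, completeness of artifact removal, and bit-identity of seizure
samples after removal. Typical results: sensitivity ≥ 0.98, precision
1.0, duration error ≤ ~1 s. The 2-h × 10 size keeps the full benchmark
at a few minutes on one CPU while still exercising 200 events.

## Outcome statistics

* **Fisher exact, two-sided** — the point-probability rule (sum of
  hypergeometric probabilities of all tables no more probable than the
  observed one), the convention of mainstream statistical software;
  delegated to `scipy.stats.fisher_exact` and verified exhaustively
  against direct enumeration for every table with total ≤ 40.
* **Mann–Whitney** — U from midranks, reported as min(U₁, U₂). Exact
  two-sided p by the permutation distribution of the rank sum (a
  subset-sum recursion over doubled midranks, so ties are exact) when
  min(n) ≤ 8 and n₁+n₂ ≤ 25; otherwise the normal approximation with
  tie and continuity corrections via scipy.
* **2^−ΔΔCT** — ΔCT = CT(target) − geometric mean of the housekeeping
  CTs (β-actin, GAPDH, HPRT1); ΔΔCT references the *arithmetic* mean
  ΔCT of the control group (the mean type is not dictated by the
  method's usual description; the arithmetic mean on the CT scale is
  the standard choice). Fold change is 2^−ΔΔCT per sample, averaged
  per group.
* **Reductions** — incidence reduction = 1 − ratio of per-group
  positive fractions, rounded to the nearest integer percent as
  typically reported; frequency reduction = 1 − ratio of per-subject
  event rates, left unrounded (the per-rat-rate arithmetic; with the
  published counts, 7 events/11 rats vs 76/10, it gives 91.6 %, and the
  total-count variant 1 − 7/76 gives 90.8 % — both are above the 90 %
  figure usually quoted).
* **FJB classification** — degenerating ⇔ strictly more than 10 (i.e.
  ≥ 11) FluoroJade-B-positive cells per section.

Kruskal–Wallis and ANOVA comparisons are out of scope: they require the
raw per-animal data, which are not published.

## File formats and determinism

EDF files are written with one 1-s data record per second, 16-bit
digitization over a symmetric physical range in µV; the range stored in
the 8-character header field is the one used for digitization, so
round-trips are exact to half a quantization step. Recordings must span
a whole number of seconds — the writer raises rather than padding. On
read, mV and V physical dimensions are converted to µV and unknown
dimensions are an error. CSV traces are a single µV column with a JSON
sidecar carrying the sampling rate. Annotation tables are CSV with a
JSON attributes column; overlapping seizure rows are permitted on read
but logged.

Pipeline reports are canonical JSON (sorted keys, fixed layout, no
timestamps): the same configuration and seed produce byte-identical
bytes. Stage timings go to the log only.

## Known limitations

* The detectors assume a stationary baseline within a recording; slow
  drift would require re-baselining, which is not implemented.
* Envelope criteria use a fixed 1-s RMS window; seizures shorter than a
  few seconds are below the design range of the SRS rules anyway
  (> 20 s), but the SE-onset rule inherits the same smoothing.
* The exact Mann–Whitney path is quadratic in the doubled rank-sum
  range; it is intended for the small group sizes of animal studies.
* The EDF writer emits single-channel files; multi-channel export is
  out of scope.
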