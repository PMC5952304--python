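# ictal

Rule-based analysis of rodent cortical EEG for organophosphate
status-epilepticus (SE) studies: band-power quantification, spike / SE /
spontaneous-seizure detection, behavioral scoring rubrics, and the
outcome statistics used to compare anticonvulsant treatments — together
with a seeded synthetic-EEG generator so every stage can be validated
against known ground truth.

## Who this is for

Experimental epilepsy labs that record cortical EEG from chemoconvulsant
models (e.g. DFP-induced SE in rats), score seizure behavior, count
degenerating neurons, and run qRT-PCR panels — and want the
quantification rules they apply by hand or in one-off scripts as a
tested, reproducible library.

## The rules it implements

**Band power.** The trace is zero-phase band-passed (20–70 Hz for power
quantification) and the squared amplitude is integrated over 300-s
epochs:

    P(e) = ( Σ_e x(t)² Δt ) / ( T_epoch / 60 )        [µV²/min]

optionally re-expressed relative to a pre-drug baseline window, so
quieting below baseline appears as negative power.

**Spike detection.** A spike is an abrupt sharp transient whose absolute
amplitude strictly exceeds *m* × the baseline amplitude statistic (the
95th percentile of |x| over an event-free baseline window), with
*m* = 2 against a 10-min baseline in the acute setting and *m* = 3
against a 5-min baseline in chronic recordings; transients wider than
200 ms at half peak are not spikes.

**SE onset.** The first supra-threshold spike train that persists
> 10 s (no inter-spike gap > 2 s) and is followed within 60 s by the
1-s RMS envelope dropping below threshold.

**Spontaneous recurrent seizures (SRS).** A spiking episode is accepted
only if it satisfies all five criteria: (1) ≥ 5 min of normal baseline
before the event, (2) gradual (not abrupt) ramp-up of spiking,
(3) continuous high-frequency spiking at 3× baseline lasting > 20 s,
(4) abrupt shutoff of spiking, and (5) clear post-ictal suppression
lasting ≥ 30 s. Rejected candidates are returned with per-criterion
flags for audit. Seizure duration is measured from the initial spike to
the last detectable spike before the post-ictal depression.

**Behavioral instruments.** The modified Racine scale with its SE rule
(≥ 2 events in stages 3, 4 or 6 within a 5-min window), the 12-item
modified Irwin screen (0–24; fail at ≥ 12), and the novel-object
recognition discrimination index DI = (novel − familiar)/(novel +
familiar), with the < 30 % familiarization exclusion.

**Outcome statistics.** Two-sided Fisher exact tests on 2×2 outcome
tables, Mann–Whitney U (exact by enumeration for small samples, normal
approximation with tie correction otherwise), 2^−ΔΔCT fold changes
against the geometric mean of β-actin/GAPDH/HPRT1 cycle thresholds, the
"> 10 FluoroJade-B⁺ cells per section" neurodegeneration classification,
and incidence / frequency reduction percentages.

## Worked example

`examples/simulate_and_detect.py` builds a 30-min synthetic recording
with three compliant seizures plus movement artifacts, removes the
artifacts and screens for SRS:

```
simulated 1800 s, 3 seizures, 3 artifacts
baseline amplitude statistic 19.7 µV, RMS 10.1 µV
removed 3 isolated movement artifacts
3 seizures accepted, 0 candidates rejected

  seizure   322.5-  361.2 s  duration  38.7 s  post-ictal suppression  59.3 s
  seizure   802.6-  841.4 s  duration  38.7 s  post-ictal suppression  59.4 s
  seizure  1302.6- 1341.2 s  duration  38.6 s  post-ictal suppression  59.4 s
```

Each accepted event reports its detected span (first to last detectable
spike), the spike-persistence duration, and how long the EEG stayed
below half the baseline RMS afterwards. The other examples cover
baseline-relative band power over an SE episode (`band_power.py`),
electrographic SE-onset detection plus the behavioral rubrics
(`se_onset_and_behavior.py`), and the outcome statistics on published
count tables (`outcome_statistics.py`):

```
SRS incidence, diazepam vs urethane: p = 0.001 (Fisher exact)
incidence reduction: 73%
frequency reduction: 91.6%
housekeeping CT geometric mean: 18.9 cycles
```

A thin CLI mirrors the pipeline stages (`ictal simulate | power |
detect-spikes | detect-seizures | detect-se | stats | report`); the
`report` subcommand runs a YAML-configured pipeline end-to-end and
emits a deterministic JSON report.

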