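"""Simulate a chronic recording and screen it for spontaneous seizures.

Builds a 30-min synthetic cortical EEG with three compliant seizures and
a handful of movement artifacts, removes the artifacts, and runs the
five-criterion spontaneous-recurrent-seizure (SRS) detector.
"""

from ictal import (DetectionProfile, SeizureSpec, SimConfig,
                   compute_baseline, detect_spikes, detect_srs, generate_eeg,
                   remove_artifact_transients, seizure_duration)

config = SimConfig(
    duration=1800.0,          # 30 min at 500 Hz
    seed=42,
    baseline_rms=10.0,        # µV background
    seizure_specs=tuple(
        SeizureSpec(onset=onset, plateau_duration=33.0)
        for onset in (320.0, 800.0, 1300.0)
    ),
    artifact_rate=12.0,       # movement artifacts per hour
)
record, truth = generate_eeg(config)
print(f"simulated {record.duration:.0f} s, {len(truth.seizures)} seizures, "
      f"{truth.artifacts.size} artifacts")

profile = DetectionProfile.chronic()   # 3x a 5-min baseline
baseline = compute_baseline(record, (0.0, 300.0))
print(f"baseline amplitude statistic {baseline.amplitude_stat:.1f} µV, "
      f"RMS {baseline.rms:.1f} µV")

cleaned, removed = remove_artifact_transients(record, baseline,
                                              multiplier=profile.multiplier)
print(f"removed {len(removed)} isolated movement artifacts")

result = detect_srs(cleaned, baseline, profile)
spikes = detect_spikes(cleaned, baseline, profile)
print(f"{len(result.accepted)} seizures accepted, "
      f"{len(result.rejected)} candidates rejected\n")
for event in result.accepted:
    print(f"  seizure {event.onset:7.1f}-{event.offset:7.1f} s  "
          f"duration {seizure_duration(event, spikes):5.1f} s  "
          f"post-ictal suppression {event.suppression_duration:5.1f} s")

# Each line is one electrographic seizure: its span (first to last
# detectable spike), the spike-persistence duration, and how long the
# EEG stayed suppressed below half the baseline RMS afterwards.
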