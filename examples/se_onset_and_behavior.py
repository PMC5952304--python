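"""Electrographic SE-onset detection and behavioral scoring rubrics.

Detects status-epilepticus onset on a simulated acute recording (2x
baseline rule), then applies the behavioral instruments: the modified
Racine SE rule, the modified Irwin health screen, and the novel-object
recognition discrimination index.
"""

from ictal import (IrwinAssessment, NORTrial, RacineObservation, SimConfig,
                   compute_baseline, declare_se, detect_se_onset,
                   discrimination_index, familiarization_valid,
                   generate_se_scenario, irwin_total)

# --- electrographic onset: first spike train > 10 s with rapid quieting
config = SimConfig(duration=1800.0, seed=7)
record, truth = generate_se_scenario(config, se_onset=600.0, se_duration=900.0)
baseline = compute_baseline(record, (0.0, 600.0))
onset = detect_se_onset(record, baseline)
print(f"electrographic SE onset: {onset:.1f} s (simulated at 600 s)")

# --- behavioral SE: >= 2 stage-3/4/6 events within a 5-min window
observations = [RacineObservation(t, s) for t, s in
                [(30, 1), (35, 2), (40, 4), (43, 4), (50, 5)]]
print(f"behavioral SE declared at {declare_se(observations):.0f} min "
      "(second whole-body clonus)")

# --- modified Irwin test, day 1 vs day 4 after SE
day1 = IrwinAssessment((2, 1, 1, 2, 1, 1, 1, 2, 1, 1, 1, 1), "24h")
day4 = IrwinAssessment((0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 1, 0), "day4")
for label, assessment in [("24 h", day1), ("day 4", day4)]:
    total, verdict = irwin_total(assessment)
    print(f"Irwin {label}: total {total}/24 -> {verdict}")

# --- novel object recognition
print("familiarized (48%/52% split):", familiarization_valid(48.0, 52.0))
trial = NORTrial(time_novel=24.0, time_familiar=15.0)
print(f"discrimination index: {discrimination_index(trial):+.2f} "
      "(positive = preference for the novel object)")
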