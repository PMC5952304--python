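"""Baseline statistics, spike/SE/SRS detectors, and the independent
brute-force recheck of accepted seizures."""

import numpy as np
import pytest

from ictal import (BaselineStats, DetectionProfile, EEGRecord, SeizureSpec,
                   SimConfig, compute_baseline, detect_se_onset,
                   detect_spikes, detect_srs, generate_eeg,
                   generate_se_scenario, rms_envelope, seizure_duration)
from ictal.detect import SRS_CRITERIA
from conftest import make_sine_record


# ---------------------------------------------------------------- baseline

def test_baseline_sinusoid_amplitude_stat():
    """95th percentile of |A sin| is A sin(0.95 π/2) ≈ 0.9969 A."""
    record = make_sine_record(9.973, 4.0, duration=120.0)
    stats = compute_baseline(record, (0.0, 120.0))
    assert 0.9 * 4.0 <= stats.amplitude_stat <= 4.0
    assert stats.amplitude_stat == pytest.approx(
        4.0 * np.sin(0.95 * np.pi / 2), rel=2e-3)
    assert stats.rms == pytest.approx(4.0 / np.sqrt(2), rel=1e-3)


def test_baseline_scales_homogeneously(quiet_record):
    record, _ = quiet_record
    s1 = compute_baseline(record, (0.0, 300.0))
    s3 = compute_baseline(record.with_samples(3.0 * record.samples),
                         (0.0, 300.0))
    assert s3.amplitude_stat == pytest.approx(3.0 * s1.amplitude_stat)
    assert s3.rms == pytest.approx(3.0 * s1.rms)


def test_baseline_window_too_short(quiet_record):
    record, _ = quiet_record
    with pytest.raises(ValueError, match="60 s"):
        compute_baseline(record, (0.0, 30.0))


def test_zero_signal_baseline_guards_downstream():
    record = EEGRecord(np.zeros(500 * 120), 500.0)
    stats = compute_baseline(record, (0.0, 120.0))
    assert stats.amplitude_stat == 0.0
    with pytest.raises(ValueError, match="zero"):
        detect_spikes(record, stats, DetectionProfile.chronic())


# ------------------------------------------------------------------ spikes

def _flat_baseline(stat=10.0, rms=5.0):
    return BaselineStats(window=(0.0, 300.0), amplitude_stat=stat, rms=rms)


def test_flat_trace_no_spikes():
    record = EEGRecord(np.zeros(5000), 500.0)
    assert detect_spikes(record, _flat_baseline(),
                         DetectionProfile.chronic()) == []


def test_single_transient_detected(quiet_record):
    from ictal import inject_artifacts
    record, _ = quiet_record
    dirty, _ = inject_artifacts(record, [200.0], 3.0)
    baseline = compute_baseline(record, (0.0, 300.0))
    profile = DetectionProfile.chronic()
    spikes = [s for s in detect_spikes(dirty, baseline, profile)
              if abs(s.time - 200.0) < 0.5]
    assert len(spikes) == 1
    assert spikes[0].ratio == pytest.approx(3.0, rel=0.2)
    assert spikes[0].width < 200.0


def test_threshold_is_strict():
    x = np.zeros(5000)
    x[2500] = 20.0  # exactly multiplier x amplitude_stat for 2 x 10
    record = EEGRecord(x, 500.0)
    profile = DetectionProfile.acute()
    assert detect_spikes(record, _flat_baseline(10.0),
                         profile) == []
    x[2500] = 20.0001
    assert len(detect_spikes(EEGRecord(x, 500.0), _flat_baseline(10.0),
                             profile)) == 1


def test_wide_excursion_rejected_by_sharpness_gate():
    x = np.zeros(5000, dtype=float)
    x[1000:1300] = 50.0  # 600 ms plateau: not a sharp transient
    record = EEGRecord(x, 500.0)
    assert detect_spikes(record, _flat_baseline(10.0),
                         DetectionProfile.chronic()) == []


def test_multiplier_monotonicity(srs_record, srs_baseline):
    record, _, _ = srs_record
    low = DetectionProfile(multiplier=2.0, baseline_duration=300.0)
    high = DetectionProfile(multiplier=3.0, baseline_duration=300.0)
    assert len(detect_spikes(record, srs_baseline, high)) \
        <= len(detect_spikes(record, srs_baseline, low))


def test_amplitude_equivariance(srs_record):
    record, _, _ = srs_record
    profile = DetectionProfile.chronic()
    b1 = compute_baseline(record, (0.0, 300.0))
    s1 = detect_spikes(record, b1, profile)
    scaled = record.with_samples(2.5 * record.samples)
    b2 = compute_baseline(scaled, (0.0, 300.0))
    s2 = detect_spikes(scaled, b2, profile)
    assert [s.time for s in s1] == [s.time for s in s2]


# ---------------------------------------------------------------- SE onset

def test_quiet_recording_has_no_se(quiet_record):
    record, _ = quiet_record
    baseline = compute_baseline(record, (0.0, 300.0))
    assert detect_se_onset(record, baseline) is None


def test_se_onset_recovered():
    config = SimConfig(duration=1800.0, seed=7)
    record, _ = generate_se_scenario(config, 600.0, 900.0)
    baseline = compute_baseline(record, (0.0, 600.0))
    onset = detect_se_onset(record, baseline)
    assert onset == pytest.approx(600.0, abs=1.0)


def test_short_spike_train_is_not_se():
    """An 8-s train fails the >10 s persistence rule."""
    spec = SeizureSpec(onset=300.0, ramp_duration=0.5, plateau_duration=7.0,
                       offset_duration=0.5, plateau_amplitude_multiplier=5.0,
                       suppression_duration=20.0, suppression_fraction=0.6)
    config = SimConfig(duration=600.0, seed=21, seizure_specs=(spec,))
    record, _ = generate_eeg(config)
    baseline = compute_baseline(record, (0.0, 300.0))
    assert detect_se_onset(record, baseline) is None


# --------------------------------------------------------------------- SRS

def test_compliant_seizure_accepted(srs_record, srs_baseline,
                                    chronic_profile):
    record, truth, _ = srs_record
    result = detect_srs(record, srs_baseline, chronic_profile)
    assert len(result.accepted) == 1
    event = result.accepted[0]
    assert all(event.criteria[k] for k in SRS_CRITERIA)
    a, b = truth.seizures[0]
    assert a <= event.onset <= event.offset <= b + 1.0
    assert event.suppression_duration >= 30.0


def test_short_event_rejected_on_sustained_spiking():
    spec = SeizureSpec(onset=320.0, ramp_duration=4.0, plateau_duration=10.0,
                       offset_duration=0.5)
    config = SimConfig(duration=500.0, seed=33, seizure_specs=(spec,))
    record, _ = generate_eeg(config)
    baseline = compute_baseline(record, (0.0, 300.0))
    result = detect_srs(record, baseline)
    assert result.accepted == []
    assert len(result.rejected) == 1
    assert not result.rejected[0].criteria["sustained_spiking"]


def test_short_suppression_rejected():
    spec = SeizureSpec(onset=320.0, plateau_duration=33.0,
                       suppression_duration=10.0)
    config = SimConfig(duration=500.0, seed=34, seizure_specs=(spec,))
    record, _ = generate_eeg(config)
    baseline = compute_baseline(record, (0.0, 300.0))
    result = detect_srs(record, baseline)
    assert result.accepted == []
    assert len(result.rejected) == 1
    assert not result.rejected[0].criteria["postictal_suppression"]


def test_abrupt_onset_rejected_on_gradual_ramp():
    spec = SeizureSpec(onset=320.0, ramp_duration=0.1, plateau_duration=33.0)
    config = SimConfig(duration=500.0, seed=35, seizure_specs=(spec,))
    record, _ = generate_eeg(config)
    baseline = compute_baseline(record, (0.0, 300.0))
    result = detect_srs(record, baseline)
    assert result.accepted == []
    assert any(not e.criteria["gradual_ramp"] for e in result.rejected)


def test_record_too_short_for_srs():
    record = EEGRecord(np.zeros(500 * 120), 500.0)
    with pytest.raises(ValueError, match="too short"):
        detect_srs(record, _flat_baseline())


# ---------------------------------------------------------------- duration

def test_seizure_duration_bracketing_spikes():
    from ictal import SeizureEvent, SpikeEvent
    event = SeizureEvent(onset=0.0, offset=36.0)
    spikes = [SpikeEvent(0.0, 50.0, 5.0, 20.0),
              SpikeEvent(36.0, 50.0, 5.0, 20.0)]
    assert seizure_duration(event, spikes) == 36.0


def test_seizure_duration_single_spike_error():
    from ictal import SeizureEvent, SpikeEvent
    event = SeizureEvent(onset=0.0, offset=10.0)
    with pytest.raises(ValueError, match="two spikes"):
        seizure_duration(event, [SpikeEvent(5.0, 50.0, 5.0, 20.0)])


def test_recovered_duration_close_to_truth(srs_record, srs_baseline,
                                           chronic_profile):
    record, truth, _ = srs_record
    result = detect_srs(record, srs_baseline, chronic_profile)
    spikes = detect_spikes(record, srs_baseline, chronic_profile)
    event = result.accepted[0]
    detail = truth.seizure_details[0]
    a, b = detail.spiking_interval(chronic_profile.multiplier,
                                   truth.amplitude_stat)
    assert seizure_duration(event, spikes) == pytest.approx(b - a, abs=2.0)


# --------------------------------------------- independent brute-force check

def _oracle_recheck(record, baseline, profile, event):
    """Re-verify the five criteria by a naive window scan, independent of
    the detector's envelope/grouping code paths."""
    x = record.samples
    fs = record.sampling_rate
    thr = profile.multiplier * baseline.amplitude_stat

    # naive spike scan: contiguous |x| > thr runs, merged across 50 ms
    spike_times = []
    above = np.abs(x) > thr
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and (above[j] or (j - i) < int(0.05 * fs)):
                if above[j]:
                    last = j
                j += 1
            seg = np.abs(x[i:last + 1])
            spike_times.append((i + int(np.argmax(seg))) / fs)
            i = j
        else:
            i += 1
    spike_times = np.array(spike_times)

    def window_rms(t0, t1):
        seg = x[int(t0 * fs):int(t1 * fs)]
        return np.sqrt(np.mean(seg ** 2))

    ok_quiet = not np.any((spike_times >= event.onset - 300.0)
                          & (spike_times < event.onset - 1e-9))
    ok_quiet &= window_rms(event.onset - 300.0, event.onset) \
        < profile.quiet_rms_multiplier * baseline.rms

    n_win = int(np.ceil(event.offset - event.onset))
    hits = sum(
        1 for k in range(n_win)
        if np.any((spike_times >= event.onset + k)
                  & (spike_times < event.onset + k + 1))
    )
    ok_sustained = (event.offset - event.onset > profile.min_ictal_duration
                    and 1 - hits / n_win <= 0.2 + 1e-9)

    # suppression: 1-s RMS windows stepped by 0.25 s after the offset
    supp_thr = profile.suppression_rms_fraction * baseline.rms
    below = 0.0
    started = False
    t = event.offset
    while t + 1.0 <= record.duration and below < 30.0:
        if window_rms(t, t + 1.0) <= supp_thr:
            started = True
            below += 0.25
        elif started:
            break
        elif t > event.offset + profile.suppression_search:
            break
        t += 0.25
    ok_suppression = below >= profile.min_suppression_duration - 1.0

    return ok_quiet and ok_sustained and ok_suppression


def test_accepted_events_pass_independent_recheck(srs_record, srs_baseline,
                                                  chronic_profile):
    record, _, _ = srs_record
    result = detect_srs(record, srs_baseline, chronic_profile)
    assert result.accepted
    for event in result.accepted:
        assert _oracle_recheck(record, srs_baseline, chronic_profile, event)
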