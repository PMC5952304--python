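"""Rule-based spike, status-epilepticus and spontaneous-seizure detectors.

Two detection regimes are used in the organophosphate SE model:

* **acute** (during and after the convulsant): spikes are abrupt, sharp
  transients with amplitude >2x a 10-min pre-drug baseline period; SE
  onset is the first electrographic seizure whose large-amplitude spikes
  persist for >10 s followed by a rapid quieting.
* **chronic** (weeks later, screening for spontaneous recurrent
  seizures, SRS): spikes are >3x a 5-min baseline, and a spiking episode
  counts as an SRS only if it satisfies all five of: (1) normal baseline
  activity for >=5 min before the event, (2) gradual (not abrupt) ramp-up
  of spiking, (3) continuous high-frequency spiking lasting >20 s,
  (4) abrupt shutoff of spiking, and (5) clear post-ictal suppression
  lasting >=30 s.

Amplitude thresholds compare |voltage| against ``multiplier x
amplitude_stat`` where the amplitude statistic is the 95th percentile of
the absolute baseline voltage; envelope criteria compare a 1-s sliding
RMS envelope against ``multiplier x baseline RMS`` (the RMS scale is the
coherent one for an RMS envelope).  All threshold crossings are strict
inequalities, matching the ">2x"/">3x" wording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import EEGRecord


@dataclass(frozen=True)
class BaselineStats:
    """Amplitude statistics of an event-free baseline window."""

    window: tuple[float, float]
    amplitude_stat: float   # 95th percentile of |x| over the window, µV
    rms: float              # RMS over the window, µV

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]


@dataclass(frozen=True)
class DetectionProfile:
    """Tunable parameters of the detectors.

    The defaults of :meth:`acute` and :meth:`chronic` encode the study's
    two regimes; the remaining fields operationalize the qualitative
    wording of the detection rules (see docs/methods.md).
    """

    multiplier: float
    baseline_duration: float
    min_quiet_before: float = 300.0
    min_ictal_duration: float = 20.0
    min_suppression_duration: float = 30.0
    min_ramp_duration: float = 2.0
    max_shutoff_duration: float = 2.0
    suppression_rms_fraction: float = 0.5
    quiet_rms_multiplier: float = 2.0
    refractory: float = 0.05
    max_spike_width: float = 0.2
    max_interspike_gap: float = 2.0
    min_se_train_duration: float = 10.0
    quieting_horizon: float = 60.0
    envelope_window: float = 1.0
    suppression_search: float = 15.0
    max_empty_window_fraction: float = 0.2
    ramp_reference_run: float = 0.25

    def __post_init__(self) -> None:
        for name in ("multiplier", "baseline_duration", "min_quiet_before",
                     "min_ictal_duration", "min_suppression_duration",
                     "min_ramp_duration", "max_shutoff_duration",
                     "suppression_rms_fraction", "refractory",
                     "max_spike_width", "max_interspike_gap",
                     "envelope_window"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def acute(cls) -> "DetectionProfile":
        """2x threshold against a 10-min pre-drug baseline."""
        return cls(multiplier=2.0, baseline_duration=600.0)

    @classmethod
    def chronic(cls) -> "DetectionProfile":
        """3x threshold against a 5-min baseline (SRS screening)."""
        return cls(multiplier=3.0, baseline_duration=300.0)


@dataclass(frozen=True)
class SpikeEvent:
    """One detected sharp transient."""

    time: float             # s, at the absolute peak
    peak_amplitude: float   # µV, |x| at the peak
    ratio: float            # peak / baseline amplitude statistic
    width: float            # ms, width at half peak


#: Names of the five SRS detection rules, in order.
SRS_CRITERIA = ("quiet_before", "gradual_ramp", "sustained_spiking",
                "abrupt_shutoff", "postictal_suppression")


@dataclass(frozen=True)
class SeizureEvent:
    """A candidate ictal episode with its per-criterion audit flags."""

    onset: float
    offset: float
    criteria: dict = field(default_factory=dict)
    n_spikes: int = 0
    peak_envelope: float = 0.0
    ramp_time: float = float("nan")
    shutoff_time: float = float("nan")
    suppression_duration: float = 0.0

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def accepted(self) -> bool:
        return all(self.criteria.get(k, False) for k in SRS_CRITERIA)


@dataclass
class DetectionResult:
    """Accepted SRS events plus the rejected candidates kept for audit."""

    accepted: list[SeizureEvent]
    rejected: list[SeizureEvent]

    def __iter__(self):
        return iter(self.accepted)

    def __len__(self) -> int:
        return len(self.accepted)


@dataclass(frozen=True)
class _Group:
    """A merged run of supra-threshold samples."""

    start: int
    stop: int          # exclusive
    peak_index: int
    peak_amplitude: float


def _supra_groups(x: np.ndarray, threshold: float,
                  merge_gap_samples: int) -> list[_Group]:
    """Contiguous |x| > threshold runs, merged across short gaps."""
    mask = np.abs(x) > threshold
    if not mask.any():
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    # merge runs separated by less than the refractory gap
    keep = np.r_[True, starts[1:] - stops[:-1] >= merge_gap_samples]
    g_starts = starts[keep]
    g_stops = stops[np.r_[keep[1:], True]]
    groups = []
    for a, b in zip(g_starts, g_stops):
        seg = np.abs(x[a:b])
        p = a + int(np.argmax(seg))
        groups.append(_Group(int(a), int(b), p, float(seg.max())))
    return groups


def _half_peak_width(x: np.ndarray, peak_index: int, fs: float) -> float:
    """Width (ms) of the contiguous region around the peak where
    |x| stays above half the peak amplitude."""
    half = abs(x[peak_index]) / 2.0
    lo = peak_index
    while lo > 0 and abs(x[lo - 1]) >= half:
        lo -= 1
    hi = peak_index
    while hi < x.size - 1 and abs(x[hi + 1]) >= half:
        hi += 1
    return (hi - lo + 1) / fs * 1000.0


def compute_baseline(record: EEGRecord,
                     window: tuple[float, float]) -> BaselineStats:
    """Amplitude statistics over a pre-event baseline window.

    The window must be at least 60 s long.  The amplitude statistic is
    the 95th percentile of |x|; a zero statistic (flat signal) is
    returned as-is and rejected downstream by the spike detector.
    """
    t0, t1 = window
    if t1 - t0 < 60.0:
        raise ValueError("baseline window must be at least 60 s long")
    x = record.slice(t0, t1)
    return BaselineStats(
        window=(float(t0), float(t1)),
        amplitude_stat=float(np.percentile(np.abs(x), 95)),
        rms=float(np.sqrt(np.mean(x * x))),
    )


def detect_spikes(record: EEGRecord, baseline: BaselineStats,
                  profile: DetectionProfile) -> list[SpikeEvent]:
    """Sharp transients with |x| strictly above ``multiplier x
    amplitude_stat``, merged within a 50-ms refractory window, with
    width at half peak below 200 ms."""
    if baseline.amplitude_stat <= 0:
        raise ValueError("baseline amplitude statistic is zero; cannot "
                         "form a spike threshold")
    fs = record.sampling_rate
    thr = profile.multiplier * baseline.amplitude_stat
    groups = _supra_groups(record.samples, thr,
                           int(round(profile.refractory * fs)))
    out = []
    for g in groups:
        width = _half_peak_width(record.samples, g.peak_index, fs)
        if width >= profile.max_spike_width * 1000.0:
            continue
        out.append(SpikeEvent(
            time=record.start_time + g.peak_index / fs,
            peak_amplitude=g.peak_amplitude,
            ratio=g.peak_amplitude / baseline.amplitude_stat,
            width=width,
        ))
    return out


def rms_envelope(record: EEGRecord, window: float = 1.0) -> np.ndarray:
    """Sliding-window RMS envelope (per-sample, centred window)."""
    size = max(int(round(window * record.sampling_rate)), 1)
    return np.sqrt(uniform_filter1d(record.samples ** 2, size=size,
                                    mode="nearest"))


def _last_sustained_below(below: np.ndarray, min_run: int) -> int | None:
    """Index just past the end of the last ``True`` run of length
    >= ``min_run`` in a boolean mask, or ``None`` if there is none."""
    if not below.any():
        return None
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        stops = np.r_[stops, below.size]
    long_enough = (stops - starts) >= min_run
    if not long_enough.any():
        return None
    return int(stops[long_enough][-1])


def _group_spike_trains(times: np.ndarray, max_gap: float) -> list[np.ndarray]:
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_gap) + 1
    return np.split(times, breaks)


def _trim_to_dense(times: np.ndarray, window: float,
                   min_companions: int = 2) -> np.ndarray:
    """Trim train endpoints to the continuous-spiking core: a spike only
    opens (closes) the event if at least ``min_companions`` further
    spikes follow (precede) it within ``window`` seconds.  Guards the
    measured span against isolated marginal transients at the fringes."""
    while times.size > min_companions:
        if np.sum((times > times[0])
                  & (times <= times[0] + window)) >= min_companions:
            break
        times = times[1:]
    while times.size > min_companions:
        if np.sum((times < times[-1])
                  & (times >= times[-1] - window)) >= min_companions:
            break
        times = times[:-1]
    return times


def detect_se_onset(record: EEGRecord, baseline: BaselineStats,
                    profile: DetectionProfile | None = None) -> float | None:
    """Onset of status epilepticus under the acute rule.

    SE onset is the first time a supra-threshold spike train (no
    inter-spike gap above 2 s) persists for more than 10 s and is
    followed within 60 s by the RMS envelope dropping below the
    threshold (the "rapid quieting" after the initial seizure).
    Returns ``None`` if no such train exists.
    """
    if profile is None:
        profile = DetectionProfile.acute()
    spikes = detect_spikes(record, baseline, profile)
    if not spikes:
        return None
    env = rms_envelope(record, profile.envelope_window)
    env_thr = profile.multiplier * baseline.rms
    fs = record.sampling_rate
    times = np.array([s.time for s in spikes])
    for train in _group_spike_trains(times, profile.max_interspike_gap):
        if train[-1] - train[0] <= profile.min_se_train_duration:
            continue
        i0 = record.index_at(train[-1])
        i1 = record.index_at(train[-1] + profile.quieting_horizon) + 1
        below = np.flatnonzero(env[i0:i1] < env_thr)
        if below.size:
            return float(train[0])
    return None


def detect_srs(record: EEGRecord, baseline: BaselineStats,
               profile: DetectionProfile | None = None) -> DetectionResult:
    """Screen a chronic recording for spontaneous recurrent seizures.

    Candidate episodes are trains of supra-threshold spikes; each is
    audited against the five SRS criteria and returned in
    ``result.accepted`` (all criteria true) or ``result.rejected``
    (with the per-criterion flags preserved).
    """
    if profile is None:
        profile = DetectionProfile.chronic()
    min_len = (profile.min_quiet_before + profile.min_ictal_duration
               + profile.min_suppression_duration)
    if record.duration < min_len:
        raise ValueError(
            f"record of {record.duration:.0f} s is too short for SRS "
            f"screening (needs >= {min_len:.0f} s)"
        )
    spikes = detect_spikes(record, baseline, profile)
    spike_times = np.array([s.time for s in spikes])
    env = rms_envelope(record, profile.envelope_window)
    env_thr = profile.multiplier * baseline.rms
    supp_thr = profile.suppression_rms_fraction * baseline.rms
    fs = record.sampling_rate
    t_start = record.start_time

    accepted, rejected = [], []
    for train in _group_spike_trains(spike_times, profile.max_interspike_gap):
        if train.size < 3:
            continue  # stray spikes, not a candidate episode
        train = _trim_to_dense(train, profile.max_interspike_gap)
        onset, offset = float(train[0]), float(train[-1])
        i_on, i_off = record.index_at(onset), record.index_at(offset)
        crit: dict[str, bool] = {}

        # (1) normal baseline activity for >= 5 min before the event
        pre0 = onset - profile.min_quiet_before
        has_room = pre0 >= t_start
        no_pre_spikes = not np.any(
            (spike_times >= pre0) & (spike_times < onset))
        pre_quiet = False
        if has_room:
            pre = record.slice(pre0, onset)
            pre_quiet = np.sqrt(np.mean(pre * pre)) \
                < profile.quiet_rms_multiplier * baseline.rms
        crit["quiet_before"] = bool(has_room and no_pre_spikes and pre_quiet)

        # (2) gradual ramp: envelope takes >= min_ramp_duration to rise
        # from the envelope threshold to 90% of the event maximum.  The
        # sub-threshold reference is the end of the last sub-threshold
        # run lasting >= ramp_reference_run, so single-sample dips of
        # the sliding RMS do not truncate the measured rise time.
        env_max = float(env[i_on:i_off + 1].max())
        i_lo = record.index_at(max(onset - 30.0, t_start))
        seg = env[i_lo:i_off + 1]
        at90 = np.flatnonzero(seg >= 0.9 * env_max)
        ramp_time = float("nan")
        if at90.size:
            i90 = at90[0]
            min_run = max(int(round(profile.ramp_reference_run * fs)), 1)
            ref = _last_sustained_below(seg[:i90] < env_thr, min_run)
            if ref is not None:
                ramp_time = (i90 - ref) / fs
        crit["gradual_ramp"] = bool(
            np.isfinite(ramp_time) and ramp_time >= profile.min_ramp_duration)

        # (3) continuous spiking > 20 s: tile 1-s windows across the
        # event; at most 20% may lack a supra-threshold spike
        long_enough = offset - onset > profile.min_ictal_duration
        n_windows = max(int(np.ceil(offset - onset)), 1)
        edges = onset + np.arange(n_windows + 1.0)
        occupied = np.unique(np.clip(
            np.searchsorted(edges, train, side="right") - 1, 0, n_windows - 1))
        empty_frac = 1.0 - occupied.size / n_windows
        crit["sustained_spiking"] = bool(
            long_enough and empty_frac <= profile.max_empty_window_fraction)

        # (4) abrupt shutoff: envelope falls from >= 50% of the event
        # maximum to below threshold within max_shutoff_duration
        i_hi = record.index_at(offset + 5.0)
        seg = env[i_on:i_hi + 1]
        at50 = np.flatnonzero(seg >= 0.5 * env_max)
        shutoff_time = float("nan")
        if at50.size:
            i50 = at50[-1]
            below = np.flatnonzero(seg[i50:] < env_thr)
            if below.size:
                shutoff_time = below[0] / fs
        crit["abrupt_shutoff"] = bool(
            np.isfinite(shutoff_time)
            and shutoff_time <= profile.max_shutoff_duration)

        # (5) post-ictal suppression: envelope RMS <= fraction of
        # baseline RMS for >= 30 s, starting within the search horizon
        i_hi = record.index_at(offset + profile.suppression_search)
        start_rel = np.flatnonzero(env[i_off:i_hi + 1] <= supp_thr)
        supp_duration = 0.0
        if start_rel.size:
            j = i_off + start_rel[0]
            above = np.flatnonzero(env[j:] > supp_thr)
            run = above[0] if above.size else env.size - j
            supp_duration = run / fs
        crit["postictal_suppression"] = bool(
            supp_duration >= profile.min_suppression_duration)

        event = SeizureEvent(
            onset=onset, offset=offset, criteria=crit,
            n_spikes=int(train.size), peak_envelope=env_max,
            ramp_time=ramp_time, shutoff_time=shutoff_time,
            suppression_duration=supp_duration,
        )
        (accepted if event.accepted else rejected).append(event)
    return DetectionResult(accepted=accepted, rejected=rejected)


def seizure_duration(event: SeizureEvent,
                     spikes: list[SpikeEvent]) -> float:
    """Seizure duration as the period in which spikes persisted: from
    the initial spike to the last detectable spike before the
    post-ictal depression."""
    times = [s.time for s in spikes
             if event.onset <= s.time <= event.offset]
    if len(times) < 2:
        raise ValueError("need at least two spikes within the event span")
    return max(times) - min(times)
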