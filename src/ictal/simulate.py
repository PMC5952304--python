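"""Seeded generative model of rodent cortical EEG with ground-truth labels.

The generator emulates the phenomenology of cortical screw-electrode
recordings in the organophosphate status-epilepticus (SE) model: a
band-limited 1/f Gaussian background, sharp biphasic interictal spikes,
electrographic seizures with a gradual amplitude ramp, a sustained
high-amplitude spiking plateau, an abrupt offset and a post-ictal
suppression period, hours-long SE with near-continuous spiking, and
isolated movement artifacts.  It makes no claim of physiological realism;
its purpose is to provide recordings whose true event times are known
exactly so the rule-based detectors can be validated.

Amplitude convention
--------------------
Spike peaks are expressed as multiples of the *baseline amplitude
statistic*, the 95th percentile of the absolute voltage of the background
noise.  For zero-mean Gaussian noise that statistic equals 1.96 x RMS, so
a "3x baseline" spike has peak amplitude ``3 * 1.96 * baseline_rms``.
This makes the generator's multipliers directly comparable to the
detector's thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import Annotation, AnnotationSet, EEGRecord

#: 95th percentile of |X| for X ~ N(0, 1); converts an RMS to the
#: baseline amplitude statistic used for spike thresholds.
GAUSSIAN_P95 = 1.959964


@dataclass(frozen=True)
class SeizureSpec:
    """Prescription for one synthetic electrographic seizure.

    The amplitude envelope rises linearly from baseline to the plateau
    over ``ramp_duration`` (the "gradual ramp up of spiking"), stays at
    ``plateau_amplitude_multiplier`` times the baseline amplitude
    statistic for ``plateau_duration``, decays within ``offset_duration``
    (the "abrupt shutoff"), after which the background RMS is scaled by
    ``suppression_fraction`` for ``suppression_duration`` (the post-ictal
    suppression).
    """

    onset: float
    ramp_duration: float = 8.0
    plateau_duration: float = 30.0
    offset_duration: float = 0.5
    plateau_amplitude_multiplier: float | None = None
    suppression_duration: float = 60.0
    suppression_fraction: float = 0.3
    spike_rate: float = 10.0

    def __post_init__(self) -> None:
        for name in ("ramp_duration", "plateau_duration", "offset_duration",
                     "suppression_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.suppression_fraction < 1:
            raise ValueError("suppression_fraction must be in [0, 1)")
        if self.plateau_amplitude_multiplier is not None \
                and not self.plateau_amplitude_multiplier > 0:
            raise ValueError("plateau_amplitude_multiplier must be > 0")
        if not self.spike_rate > 0:
            raise ValueError("spike_rate must be > 0")

    @property
    def offset(self) -> float:
        """End of ictal spiking (start of the post-ictal suppression)."""
        return self.onset + self.ramp_duration + self.plateau_duration \
            + self.offset_duration

    @property
    def end(self) -> float:
        """End of the whole episode including the suppression."""
        return self.offset + self.suppression_duration


@dataclass(frozen=True)
class SimConfig:
    """Full prescription for one synthetic recording.

    ``spike_amplitude_multiplier`` is the default plateau multiplier for
    seizures whose :class:`SeizureSpec` leaves it unset.  ``seed`` is
    mandatory: the same config always yields a bit-identical trace.
    """

    duration: float
    seed: int
    sampling_rate: float = 500.0
    baseline_rms: float = 10.0
    spike_amplitude_multiplier: float = 8.0
    seizure_specs: tuple[SeizureSpec, ...] = ()
    artifact_rate: float = 0.0
    artifact_amplitude_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.baseline_rms > 0:
            raise ValueError("baseline_rms must be > 0")
        if not self.spike_amplitude_multiplier > 0:
            raise ValueError("spike_amplitude_multiplier must be > 0")
        if not self.artifact_amplitude_multiplier > 0:
            raise ValueError("artifact_amplitude_multiplier must be > 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        object.__setattr__(self, "seizure_specs", tuple(self.seizure_specs))
        specs = sorted(self.seizure_specs, key=lambda s: s.onset)
        for spec in specs:
            if spec.onset < 0 or spec.end > self.duration:
                raise ValueError(
                    f"seizure spec at onset {spec.onset} s extends outside "
                    f"the {self.duration} s recording"
                )
        for a, b in zip(specs, specs[1:]):
            if b.onset < a.end:
                raise ValueError(
                    f"seizure specs at {a.onset} s and {b.onset} s overlap "
                    "(including the post-ictal suppression window)"
                )

    @property
    def amplitude_stat(self) -> float:
        """Nominal baseline amplitude statistic (95th pct of |noise|)."""
        return GAUSSIAN_P95 * self.baseline_rms

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "seed": self.seed,
            "sampling_rate": self.sampling_rate,
            "baseline_rms": self.baseline_rms,
            "spike_amplitude_multiplier": self.spike_amplitude_multiplier,
            "artifact_rate": self.artifact_rate,
            "artifact_amplitude_multiplier": self.artifact_amplitude_multiplier,
            "seizure_specs": [
                {
                    "onset": s.onset,
                    "ramp_duration": s.ramp_duration,
                    "plateau_duration": s.plateau_duration,
                    "offset_duration": s.offset_duration,
                    "plateau_amplitude_multiplier": s.plateau_amplitude_multiplier,
                    "suppression_duration": s.suppression_duration,
                    "suppression_fraction": s.suppression_fraction,
                    "spike_rate": s.spike_rate,
                }
                for s in self.seizure_specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        specs = tuple(SeizureSpec(**s) for s in d.pop("seizure_specs", []))
        return cls(seizure_specs=specs, **d)


@dataclass(frozen=True)
class SeizureTruth:
    """Realized ground truth for one generated seizure.

    ``spike_peaks`` are measured on the rendered trace (noise included),
    so they are exactly what an ideal threshold detector observes.
    """

    onset: float
    offset: float
    spike_times: np.ndarray
    spike_peaks: np.ndarray  # µV, realized absolute peak of each spike
    suppression_end: float

    def spiking_interval(self, min_multiplier: float,
                         amplitude_stat: float) -> tuple[float, float]:
        """First-to-last spike interval among spikes whose peak exceeds
        ``min_multiplier x amplitude_stat`` (the measured seizure span a
        threshold detector at that multiplier can recover)."""
        thr = min_multiplier * amplitude_stat
        supra = self.spike_times[self.spike_peaks > thr]
        if supra.size == 0:
            raise ValueError("no spike exceeds the requested multiplier")
        return float(supra[0]), float(supra[-1])


@dataclass
class GroundTruth:
    """Exact event labels for a generated recording."""

    spikes: np.ndarray
    seizures: list[tuple[float, float]]
    artifacts: np.ndarray
    se_interval: tuple[float, float] | None = None
    seizure_details: list[SeizureTruth] = field(default_factory=list)
    amplitude_stat: float = 0.0
    baseline_rms: float = 0.0

    def to_annotations(self) -> AnnotationSet:
        events = [Annotation("spike", float(t), float(t)) for t in self.spikes]
        events += [Annotation("seizure", a, b) for a, b in self.seizures]
        events += [Annotation("artifact", float(t), float(t))
                   for t in self.artifacts]
        if self.se_interval is not None:
            events.append(Annotation("se_onset", *map(float, self.se_interval)))
        return AnnotationSet(events)


def _pink_band_noise(rng: np.random.Generator, n: int, fs: float,
                     rms: float) -> np.ndarray:
    """Band-limited (1-100 Hz) Gaussian noise with 1/f spectral shaping,
    rescaled to the requested RMS over the full length."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spectrum * shaping, n=n)
    high = min(100.0, 0.45 * fs)
    sos = sps.butter(4, [1.0, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return x * (rms / np.sqrt(np.mean(x * x)))


def _wavelet(fs: float, sigma: float) -> np.ndarray:
    """Derivative-of-Gaussian biphasic transient, unit peak amplitude."""
    half = int(round(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    return -(t / sigma) * np.exp(0.5 - t * t / (2 * sigma * sigma))


def _add_transient(trace: np.ndarray, fs: float, time: float, peak: float,
                   sigma: float) -> None:
    w = peak * _wavelet(fs, sigma)
    center = int(round(time * fs))
    half = (w.size - 1) // 2
    lo, hi = center - half, center + half + 1
    wlo = max(0, -lo)
    whi = w.size - max(0, hi - trace.size)
    lo, hi = max(lo, 0), min(hi, trace.size)
    if hi > lo:
        trace[lo:hi] += w[wlo:whi]


def _seizure_envelope_fraction(t: np.ndarray, spec: SeizureSpec) -> np.ndarray:
    """Fraction of the plateau amplitude at spike times ``t``."""
    frac = np.zeros_like(t)
    ramp_end = spec.onset + spec.ramp_duration
    plateau_end = ramp_end + spec.plateau_duration
    if spec.ramp_duration > 0:
        m = (t >= spec.onset) & (t < ramp_end)
        frac[m] = (t[m] - spec.onset) / spec.ramp_duration
    frac[(t >= ramp_end) & (t < plateau_end)] = 1.0
    if spec.offset_duration > 0:
        m = (t >= plateau_end) & (t < spec.offset)
        frac[m] = 1.0 - (t[m] - plateau_end) / spec.offset_duration
    return frac


def generate_eeg(config: SimConfig) -> tuple[EEGRecord, GroundTruth]:
    """Render a recording from ``config`` and return it with its labels.

    The same config (seed included) always produces a bit-identical trace
    and identical ground truth.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)
    trace = _pink_band_noise(rng, n, fs, config.baseline_rms)

    # Post-ictal suppression: scale the background after each seizure.
    for spec in config.seizure_specs:
        if spec.suppression_duration > 0:
            i0 = int(round(spec.offset * fs))
            i1 = min(int(round(spec.end * fs)), n)
            trace[i0:i1] *= spec.suppression_fraction

    amp_stat = config.amplitude_stat
    details: list[SeizureTruth] = []
    pending: list[tuple[SeizureSpec, np.ndarray]] = []
    all_spike_times: list[np.ndarray] = []
    for spec in sorted(config.seizure_specs, key=lambda s: s.onset):
        mult = spec.plateau_amplitude_multiplier
        if mult is None:
            mult = config.spike_amplitude_multiplier
        span = spec.offset - spec.onset
        k = np.arange(int(np.floor(span * spec.spike_rate)))
        times = spec.onset + (k + 0.5) / spec.spike_rate \
            + rng.uniform(-0.2, 0.2, size=k.size) / spec.spike_rate
        times = times[(times >= spec.onset) & (times < spec.offset)]
        frac = _seizure_envelope_fraction(times, spec)
        keep = frac > 0.02
        times, frac = times[keep], frac[keep]
        peaks = frac * mult * amp_stat
        sigmas = rng.uniform(0.004, 0.008, size=times.size)
        for t, p, s in zip(times, peaks, sigmas):
            _add_transient(trace, fs, t, p, s)
        pending.append((spec, times))
        all_spike_times.append(times)

    # Ground truth records the peaks as realized in the rendered trace
    # (noise included): that is what a threshold detector observes.
    half = int(round(0.02 * fs))
    for spec, times in pending:
        idx = np.round(times * fs).astype(int)
        realized = np.array([
            float(np.max(np.abs(trace[max(0, i - half):i + half + 1])))
            for i in idx
        ])
        details.append(SeizureTruth(
            onset=spec.onset, offset=spec.offset,
            spike_times=times, spike_peaks=realized,
            suppression_end=spec.end,
        ))

    # Movement artifacts: isolated biphasic transients at Poisson times,
    # kept >= 5 s away from any seizure episode and from each other so
    # the artifact-removal oracle is unambiguous.
    artifact_times: list[float] = []
    if config.artifact_rate > 0:
        n_art = rng.poisson(config.artifact_rate * config.duration / 3600.0)
        exclusion = [(s.onset - 5.0, s.end + 5.0) for s in config.seizure_specs]
        tries = 0
        while len(artifact_times) < n_art and tries < 100 * max(n_art, 1):
            tries += 1
            t = float(rng.uniform(1.0, config.duration - 1.0))
            if any(a <= t <= b for a, b in exclusion):
                continue
            if any(abs(t - u) < 5.0 for u in artifact_times):
                continue
            artifact_times.append(t)
        artifact_times.sort()
        for t in artifact_times:
            sigma = float(rng.uniform(0.008, 0.012))
            _add_transient(trace, fs, t,
                           config.artifact_amplitude_multiplier * amp_stat,
                           sigma)

    spikes = (np.concatenate(all_spike_times) if all_spike_times
              else np.empty(0))
    truth = GroundTruth(
        spikes=np.sort(spikes),
        seizures=[(s.onset, s.offset) for s in
                  sorted(config.seizure_specs, key=lambda s: s.onset)],
        artifacts=np.asarray(artifact_times),
        seizure_details=details,
        amplitude_stat=amp_stat,
        baseline_rms=config.baseline_rms,
    )
    record = EEGRecord(trace, fs, channel_label="synthetic-cortex")
    return record, truth


def generate_se_scenario(config: SimConfig, se_onset: float,
                         se_duration: float) -> tuple[EEGRecord, GroundTruth]:
    """Recording with status epilepticus: one initial discrete seizure at
    ``se_onset`` (>10 s of spiking followed by a rapid quieting) and then
    near-continuous supra-threshold spiking until
    ``se_onset + se_duration``.

    ``se_duration == 0`` degenerates to :func:`generate_eeg` with the
    same seed; otherwise ``se_duration`` must be at least 60 s so the
    initial-seizure / quieting / continuous-spiking structure fits.
    """
    if se_onset < 0 or se_onset + se_duration > config.duration:
        raise ValueError("SE interval extends outside the recording")
    if se_duration == 0:
        record, truth = generate_eeg(config)
        truth.se_interval = (se_onset, se_onset)
        return record, truth
    if se_duration < 60:
        raise ValueError("se_duration must be 0 or at least 60 s")

    initial = SeizureSpec(
        onset=se_onset, ramp_duration=1.0, plateau_duration=14.0,
        offset_duration=1.0, plateau_amplitude_multiplier=5.0,
        suppression_duration=18.0, suppression_fraction=0.6, spike_rate=8.0,
    )
    cont_onset = initial.end + 2.0  # 36 s after SE onset
    continuous = SeizureSpec(
        onset=cont_onset, ramp_duration=4.0,
        plateau_duration=se_onset + se_duration - cont_onset - 6.0,
        offset_duration=2.0, plateau_amplitude_multiplier=4.0,
        suppression_duration=0.0, suppression_fraction=0.5, spike_rate=8.0,
    )
    full = replace(config,
                   seizure_specs=config.seizure_specs + (initial, continuous))
    record, truth = generate_eeg(full)
    truth.se_interval = (se_onset, se_onset + se_duration)
    return record, truth


def inject_artifacts(record: EEGRecord, times: list[float],
                     multiplier: float) -> tuple[EEGRecord, GroundTruth]:
    """Add one isolated biphasic transient (width < 100 ms) at each of
    ``times``, with peak amplitude ``multiplier`` times the record's own
    baseline amplitude statistic (95th percentile of |voltage|)."""
    t0, t1 = record.start_time, record.start_time + record.duration
    for t in times:
        if not t0 <= t < t1:
            raise ValueError(f"artifact time {t} s outside the record span")
    stat = float(np.percentile(np.abs(record.samples), 95))
    trace = record.samples.copy()
    for t in times:
        _add_transient(trace, record.sampling_rate, t - record.start_time,
                       multiplier * stat, 0.010)
    truth = GroundTruth(
        spikes=np.empty(0), seizures=[],
        artifacts=np.asarray(sorted(float(t) for t in times)),
        amplitude_stat=stat,
    )
    return record.with_samples(trace), truth
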