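"""Band-power quantification of EEG traces.

The study convention: band-pass the trace (1-100 Hz for inspection,
20-70 Hz for power quantification), square the amplitude signal,
integrate over 300-s epochs, and report power per epoch in µV²/min.  The
per-epoch formula is

    power(e) = (sum over e of x(t)^2 * dt) / (epoch_duration / 60)

i.e. the integral of the squared signal over the epoch divided by the
epoch length in minutes.  Power may be re-expressed relative to a
pre-drug baseline window, in which case values can be negative (quieting
below baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import Annotation, AnnotationSet, EEGRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter prescription (Butterworth, zero-phase default)."""

    low_cut: float
    high_cut: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, sampling_rate: float) -> None:
        if self.high_cut >= sampling_rate / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz is at or above the Nyquist "
                f"frequency {sampling_rate / 2} Hz"
            )


#: The study's two analysis bands.
BROADBAND = FilterSpec(1.0, 100.0)
GAMMA_BAND = FilterSpec(20.0, 70.0)


@dataclass(frozen=True)
class BandPowerSeries:
    """Per-epoch integrated band power (µV²/min convention)."""

    epoch_duration: float
    epoch_start_times: np.ndarray
    power: np.ndarray
    baseline_mean_power: float | None = None
    relative: bool = False

    def __post_init__(self) -> None:
        starts = np.asarray(self.epoch_start_times, dtype=np.float64)
        power = np.asarray(self.power, dtype=np.float64)
        if starts.shape != power.shape or starts.ndim != 1:
            raise ValueError("epoch_start_times and power must be 1-D, same length")
        if not np.all(np.isfinite(power)):
            raise ValueError("power values must be finite")
        if not self.relative and np.any(power < 0):
            raise ValueError("absolute power must be non-negative")
        if starts.size > 1 and not np.allclose(
                np.diff(starts), self.epoch_duration):
            raise ValueError("epochs must be contiguous and non-overlapping")
        object.__setattr__(self, "epoch_start_times", starts)
        object.__setattr__(self, "power", power)

    @property
    def n_epochs(self) -> int:
        return int(self.power.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_start_s": self.epoch_start_times,
            "power": self.power,
        })


@dataclass(frozen=True)
class PowerWindowSummary:
    """Mean band power over a window expressed in hours."""

    window: tuple[float, float]
    mean_power: float
    n_epochs: int

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy t0 < t1")
        if self.n_epochs < 1:
            raise ValueError("summary needs at least one epoch")


def bandpass(record: EEGRecord, spec: FilterSpec) -> EEGRecord:
    """Band-pass filter a record; zero-phase (no group delay) by default."""
    spec.validate_for(record.sampling_rate)
    sos = sps.butter(spec.order, [spec.low_cut, spec.high_cut],
                     btype="bandpass", fs=record.sampling_rate, output="sos")
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, record.samples)
    else:
        filtered = sps.sosfilt(sos, record.samples)
    return record.with_samples(filtered)


def epoch_power(record: EEGRecord, epoch_duration: float = 300.0) -> BandPowerSeries:
    """Integrate squared amplitude over consecutive epochs.

    A trailing partial epoch is dropped (and logged); a record shorter
    than one epoch is an error.
    """
    fs = record.sampling_rate
    per_epoch = int(round(epoch_duration * fs))
    n_epochs = record.n_samples // per_epoch
    if n_epochs == 0:
        raise ValueError(
            f"record of {record.duration:.1f} s is shorter than one "
            f"{epoch_duration:.0f}-s epoch"
        )
    dropped = record.n_samples - n_epochs * per_epoch
    if dropped:
        logger.info("epoch_power: dropped trailing partial epoch of %.1f s",
                    dropped / fs)
    x = record.samples[:n_epochs * per_epoch].reshape(n_epochs, per_epoch)
    integral = np.sum(x * x, axis=1) / fs          # µV² · s
    power = integral / (epoch_duration / 60.0)     # µV² / min
    starts = record.start_time + epoch_duration * np.arange(n_epochs)
    return BandPowerSeries(epoch_duration, starts, power)


def relative_power(series: BandPowerSeries,
                   baseline_window: tuple[float, float]) -> BandPowerSeries:
    """Express power relative to the mean over ``baseline_window`` (s)."""
    t0, t1 = baseline_window
    mask = (series.epoch_start_times >= t0) & (series.epoch_start_times < t1)
    if not mask.any():
        raise ValueError("baseline window covers no epoch")
    baseline = float(np.mean(series.power[mask]))
    return replace(series, power=series.power - baseline,
                   baseline_mean_power=baseline, relative=True)


def window_mean_power(series: BandPowerSeries, t0: float,
                      t1: float) -> PowerWindowSummary:
    """Mean of epochs whose start lies in ``[t0, t1)`` hours."""
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    starts_h = series.epoch_start_times / 3600.0
    mask = (starts_h >= t0) & (starts_h < t1)
    if not mask.any():
        raise ValueError(f"no epoch starts within [{t0}, {t1}) h")
    return PowerWindowSummary(
        window=(t0, t1),
        mean_power=float(np.mean(series.power[mask])),
        n_epochs=int(mask.sum()),
    )


def remove_artifact_transients(
    record: EEGRecord,
    baseline,
    multiplier: float = 3.0,
    isolation: float = 2.0,
    max_width: float = 0.2,
    protect_intervals: list[tuple[float, float]] = (),
) -> tuple[EEGRecord, AnnotationSet]:
    """Remove isolated large movement artifacts from a trace.

    A supra-threshold excursion (|x| > ``multiplier`` x baseline
    amplitude statistic) is removed only if it is *isolated* — no other
    supra-threshold excursion within +-``isolation`` seconds — and
    shorter than ``max_width`` seconds, the operational reading of
    "single transients not of cerebral origin".  Excursions inside
    ``protect_intervals`` (detected or labelled seizures) are never
    touched.  Removed stretches are replaced by linear interpolation
    between the surrounding samples and returned as annotations.
    """
    from .detect import BaselineStats, _supra_groups  # local to avoid cycle

    assert isinstance(baseline, BaselineStats)
    if baseline.amplitude_stat <= 0:
        raise ValueError("baseline amplitude statistic must be positive")
    fs = record.sampling_rate
    thr = multiplier * baseline.amplitude_stat
    groups = _supra_groups(record.samples, thr, int(round(0.05 * fs)))
    if not groups:
        return record, AnnotationSet()

    peak_times = np.array([record.start_time + g.peak_index / fs
                           for g in groups])
    cleaned = record.samples.copy()
    removed: list[Annotation] = []
    for i, g in enumerate(groups):
        t = peak_times[i]
        neighbours = np.abs(peak_times - t) <= isolation
        if neighbours.sum() > 1:
            continue  # not isolated
        if (g.stop - g.start) / fs >= max_width:
            continue  # too long to be a single transient
        if any(a <= t < b for a, b in protect_intervals):
            continue
        # widen to where the trace re-enters the baseline amplitude range
        lo, hi = g.start, g.stop
        floor = baseline.amplitude_stat
        limit = int(round(0.15 * fs))
        while lo > max(0, g.start - limit) and abs(cleaned[lo - 1]) > floor:
            lo -= 1
        while hi < min(cleaned.size, g.stop + limit) and abs(cleaned[hi]) > floor:
            hi += 1
        a = cleaned[lo - 1] if lo > 0 else 0.0
        b = cleaned[hi] if hi < cleaned.size else 0.0
        cleaned[lo:hi] = np.linspace(a, b, hi - lo + 2)[1:-1]
        removed.append(Annotation(
            "artifact", record.start_time + lo / fs,
            record.start_time + hi / fs,
            {"peak_amplitude": float(g.peak_amplitude)},
        ))
    if removed:
        logger.info("remove_artifact_transients: removed %d transients",
                    len(removed))
    return record.with_samples(cleaned), AnnotationSet(removed)
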