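"""Core containers shared across the package.

All times are seconds from the start of the recording; intervals are
half-open ``[onset, offset)`` so that adjacent events never overlap.
Voltages are microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

#: Closed vocabulary of annotation kinds.
ANNOTATION_KINDS = ("spike", "seizure", "artifact", "se_onset")


@dataclass(frozen=True)
class EEGRecord:
    """A uniformly sampled single-channel voltage trace in microvolts.

    Parameters
    ----------
    samples
        Voltage samples in µV.
    sampling_rate
        Sampling rate in Hz; the study convention is 500 Hz.
    start_time
        Seconds from the recording origin of the first sample.
    channel_label
        Free-text channel name (e.g. ``"cortex-L"``).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    channel_label: str = "EEG"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Length of the trace in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample times, seconds from the recording origin."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (clipped to the valid range)."""
        i = int(round((t - self.start_time) * self.sampling_rate))
        return min(max(i, 0), self.n_samples - 1)

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open window ``[t0, t1)``."""
        i0 = int(round((t0 - self.start_time) * self.sampling_rate))
        i1 = int(round((t1 - self.start_time) * self.sampling_rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError(f"window [{t0}, {t1}) is empty for this record")
        return self.samples[i0:i1]

    def with_samples(self, samples: np.ndarray) -> "EEGRecord":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    def rms(self, t0: float | None = None, t1: float | None = None) -> float:
        x = self.samples if t0 is None else self.slice(t0, t1)
        return float(np.sqrt(np.mean(np.square(x))))


@dataclass(frozen=True)
class Annotation:
    """One labelled event; instantaneous events have ``offset == onset``."""

    kind: str
    onset: float
    offset: float
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(
                f"unknown annotation kind {self.kind!r}; "
                f"expected one of {ANNOTATION_KINDS}"
            )
        if self.offset < self.onset:
            raise ValueError("offset must be >= onset")


class AnnotationSet:
    """An ordered collection of :class:`Annotation` events."""

    def __init__(self, events: Iterable[Annotation] = ()) -> None:
        self.events: list[Annotation] = sorted(
            events, key=lambda e: (e.onset, e.offset, e.kind)
        )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.events == other.events

    def of_kind(self, kind: str) -> "AnnotationSet":
        return AnnotationSet(e for e in self.events if e.kind == kind)

    def add(self, event: Annotation) -> None:
        self.events.append(event)
        self.events.sort(key=lambda e: (e.onset, e.offset, e.kind))

    def overlapping_pairs(self, kind: str = "seizure") -> list[tuple[Annotation, Annotation]]:
        """Pairs of same-kind events whose intervals overlap (for QC logs)."""
        evs = [e for e in self.events if e.kind == kind]
        out = []
        for a, b in zip(evs, evs[1:]):
            if b.onset < a.offset:
                out.append((a, b))
        return out
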