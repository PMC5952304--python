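"""Behavioral instruments: modified Racine scale, modified Irwin test,
and the novel-object-recognition (NOR) discrimination index.

Scores are inputs here — observers score the animals; this module only
encodes the rubrics and the derived classifications.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Modified Racine scale for organophosphate exposure: behavioral score
#: -> (label, observed motor behaviors).
RACINE_SCALE = {
    0: ("Normal behavior", "Walking, exploring, sniffing, grooming"),
    1: ("Freeze behavior",
        "Immobile, staring, heightened startle, curled-up posture"),
    2: ("Repetitive behavior",
        "Blinking, chewing, head bobbing, scratching, face washing, "
        "whisker twitching"),
    3: ("Early seizure behavior", "Myoclonic jerks, partial body clonus"),
    4: ("Advance seizure behavior", "Whole-body clonus"),
    5: ("SE", "Repeated seizure activity (>=2 events in stages 3, 4, or 6 "
        "within a 5-min window)"),
    6: ("Intense seizure behavior",
        "Repetitive jumping or bouncing, wild running, tonic seizures"),
    7: ("Death", ""),
}

#: Racine stages whose repetition within 5 min declares SE.
SE_QUALIFYING_STAGES = frozenset({3, 4, 6})

#: Sliding window (minutes) for the SE declaration rule, endpoints
#: inclusive.
SE_WINDOW_MINUTES = 5.0

#: The 12 observational items of the modified Irwin test, each scored
#: 0 (normal), 1 (mild/moderate impairment) or 2 (severe impairment).
IRWIN_ITEMS = (
    "ptosis", "exophthalmos", "lacrimation", "body_posture", "bushy_tail",
    "tremors", "running_vs_walking", "dragging_body", "hyper_hypoactive",
    "aggression_when_handled", "muscle_tone_when_handled",
    "vocalization_when_handled",
)

#: An animal fails the Irwin screen at or above this total.
IRWIN_FAIL_THRESHOLD = 12


@dataclass(frozen=True)
class RacineObservation:
    """One scored observation, ``time`` in minutes from dosing."""

    time: float
    score: int

    def __post_init__(self) -> None:
        if self.score not in RACINE_SCALE:
            raise ValueError(f"Racine score must be 0-7, got {self.score}")


@dataclass(frozen=True)
class IrwinAssessment:
    """One administration of the 12-item modified Irwin test."""

    item_scores: tuple[int, ...]
    timepoint: str = ""

    def __post_init__(self) -> None:
        scores = tuple(self.item_scores)
        if len(scores) != len(IRWIN_ITEMS):
            raise ValueError(f"expected {len(IRWIN_ITEMS)} item scores, "
                             f"got {len(scores)}")
        for s in scores:
            if s not in (0, 1, 2):
                raise ValueError(f"item scores must be 0, 1 or 2; got {s}")
        object.__setattr__(self, "item_scores", scores)


@dataclass(frozen=True)
class NORTrial:
    """Exploration times (s) in the novel-object-recognition test."""

    time_novel: float
    time_familiar: float

    def __post_init__(self) -> None:
        if self.time_novel < 0 or self.time_familiar < 0:
            raise ValueError("exploration times must be non-negative")
        if self.time_novel + self.time_familiar == 0:
            raise ValueError("at least one exploration time must be positive")


def declare_se(observations: list[RacineObservation]) -> float | None:
    """Time (min) at which behavioral SE is declared, or ``None``.

    SE is declared at the first observation such that at least two
    observations with scores in stages {3, 4, 6} fall within any sliding
    5-min window (endpoints inclusive).  Observations must be
    time-sorted.
    """
    times = [o.time for o in observations]
    if times != sorted(times):
        raise ValueError("observations must be sorted by time")
    qualifying = [o.time for o in observations
                  if o.score in SE_QUALIFYING_STAGES]
    for prev, cur in zip(qualifying, qualifying[1:]):
        if cur - prev <= SE_WINDOW_MINUTES:
            return cur
    return None


def irwin_total(assessment: IrwinAssessment) -> tuple[int, str]:
    """Total Irwin score and its classification.

    0 is a normal healthy rat; 1-11 a healthy animal that appears
    slightly impaired; >=12 fails the screen.
    """
    total = sum(assessment.item_scores)
    if total == 0:
        label = "normal"
    elif total < IRWIN_FAIL_THRESHOLD:
        label = "impaired"
    else:
        label = "fail"
    return total, label


def discrimination_index(trial: NORTrial) -> float:
    """DI = (novel - familiar) / (novel + familiar), in [-1, 1]."""
    return (trial.time_novel - trial.time_familiar) \
        / (trial.time_novel + trial.time_familiar)


def familiarization_valid(time_left: float, time_right: float) -> bool:
    """Whether a rat familiarized during training.

    Rats that spent <30% of the exploration time with either identical
    object did not familiarize and are excluded from the DI analysis;
    exactly 30% is still valid.
    """
    total = time_left + time_right
    if total <= 0:
        raise ValueError("total exploration time must be positive")
    return min(time_left, time_right) / total >= 0.30
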