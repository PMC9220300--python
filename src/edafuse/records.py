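"""Core data types and the discrete-emotion -> valence/arousal label model.

Electrodermal activity (EDA) studies that collect one of seven discrete
emotion labels per trial commonly collapse them onto the two axes of the
circumplex model of affect: valence (pleasant vs. unpleasant) and arousal
(activated vs. calm). This module defines the subject/recording containers
used throughout the package and the fixed grouping of the seven-emotion
vocabulary into binary valence and arousal classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "EMOTIONS",
    "SubjectMeta",
    "EdaRecording",
    "VaLabel",
    "map_emotion_to_va",
    "count_va_groups",
    "binarize_ratings",
]

#: Closed seven-emotion vocabulary.
EMOTIONS = ("happy", "surprise", "disgust", "anger", "fear", "sad", "neutral")

# Circumplex grouping: positive valence = {neutral, surprise, happy};
# high arousal = {surprise, fear, anger, happy}.
_POSITIVE_VALENCE = frozenset({"neutral", "surprise", "happy"})
_HIGH_AROUSAL = frozenset({"surprise", "fear", "anger", "happy"})


@dataclass(frozen=True)
class VaLabel:
    """Binary valence/arousal label.

    Attributes
    ----------
    valence : str
        ``"positive"`` or ``"negative"``.
    arousal : str
        ``"high"`` or ``"low"``.
    """

    valence: str
    arousal: str

    def __post_init__(self) -> None:
        if self.valence not in ("positive", "negative"):
            raise ValueError(f"valence must be 'positive' or 'negative', got {self.valence!r}")
        if self.arousal not in ("high", "low"):
            raise ValueError(f"arousal must be 'high' or 'low', got {self.arousal!r}")


@dataclass(frozen=True)
class SubjectMeta:
    """Participant metadata: identifier, gender token, integer age.

    Gender and age are the two covariates that feed the gender-age relation
    graph; ``age`` is validated against a plausible range at construction.
    """

    subject_id: str
    gender: str
    age: int
    age_range: tuple[int, int] = field(default=(10, 90), compare=False)

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be 'F' or 'M', got {self.gender!r}")
        lo, hi = self.age_range
        if not (lo <= int(self.age) <= hi):
            raise ValueError(f"age {self.age} outside plausible range [{lo}, {hi}]")


@dataclass
class EdaRecording:
    """A single skin-conductance recording (one trial, one subject).

    Attributes
    ----------
    subject_id, trial_id : str
        Identifiers linking the recording to metadata and labels.
    samples : ndarray
        Conductance values in microsiemens (or normalized units after
        preprocessing), sampled uniformly at ``fs`` Hz.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : VaLabel | str | None
        Optional trial label: a :class:`VaLabel`, or a discrete emotion token.
    """

    subject_id: str
    trial_id: str
    samples: np.ndarray
    fs: float
    label: object | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def replace_samples(self, samples: np.ndarray, fs: float | None = None) -> "EdaRecording":
        """Return a copy of the recording with new samples (and optionally fs)."""
        return EdaRecording(
            subject_id=self.subject_id,
            trial_id=self.trial_id,
            samples=samples,
            fs=self.fs if fs is None else fs,
            label=self.label,
        )


def _check_emotion(emotion: str) -> str:
    if emotion not in EMOTIONS:
        raise ValueError(
            f"unknown emotion token {emotion!r}; expected one of {sorted(EMOTIONS)}"
        )
    return emotion


def map_emotion_to_va(emotion: str) -> VaLabel:
    """Map a discrete emotion token onto binary valence/arousal classes.

    The grouping follows the two-dimensional circumplex model: positive
    valence covers neutral, surprise and happy; high arousal covers surprise,
    fear, anger and happy. The mapping is total and deterministic on the
    seven-token vocabulary.
    """
    _check_emotion(emotion)
    return VaLabel(
        valence="positive" if emotion in _POSITIVE_VALENCE else "negative",
        arousal="high" if emotion in _HIGH_AROUSAL else "low",
    )


def count_va_groups(counts: Mapping[str, int]) -> dict[str, int]:
    """Aggregate per-emotion trial counts into the four valence/arousal groups.

    Parameters
    ----------
    counts : mapping
        Non-negative trial count per emotion token.

    Returns
    -------
    dict
        Totals for ``positive``, ``negative``, ``high`` and ``low``. Mass is
        conserved: positive+negative == high+low == sum of the inputs.
    """
    totals = {"positive": 0, "negative": 0, "high": 0, "low": 0}
    for emotion, n in counts.items():
        _check_emotion(emotion)
        n = int(n)
        if n < 0:
            raise ValueError(f"count for {emotion!r} is negative: {n}")
        va = map_emotion_to_va(emotion)
        totals[va.valence] += n
        totals[va.arousal] += n
    return totals


def binarize_ratings(
    valence_rating: float, arousal_rating: float, threshold: float = 5.0
) -> VaLabel:
    """Binarize continuous 1-9 affect ratings at a threshold.

    Ratings strictly above ``threshold`` map to positive valence / high
    arousal; ties go to the negative/low side. The default threshold 5 is the
    midpoint of the 1-9 self-assessment scale.
    """
    for name, r in (("valence", valence_rating), ("arousal", arousal_rating)):
        if not (1.0 <= r <= 9.0):
            raise ValueError(f"{name} rating {r} outside [1, 9]")
    return VaLabel(
        valence="positive" if valence_rating > threshold else "negative",
        arousal="high" if arousal_rating > threshold else "low",
    )
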