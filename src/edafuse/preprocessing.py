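"""Signal conditioning for raw EDA/GSR recordings.

The chain covers the conditioning steps typical for wrist-worn (4 Hz) and
lab-grade (downsampled 128 Hz) skin-conductance data: per-participant min-max
normalization, running median filtering, polyphase resampling, and trial
segmentation with pre-trial baseline removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import scipy.ndimage
import scipy.signal

from .records import EdaRecording

__all__ = [
    "PreprocessConfig",
    "min_max_normalize",
    "normalize_subject",
    "median_filter",
    "resample",
    "segment_and_debase",
    "preprocess_trials",
]


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    median_window: odd number of samples in the running median (11 removes
    transient artifacts at both 4 and 128 Hz). target_fs: resampling target in
    Hz; None keeps the native rate. trial_s/pretrial_s: segmentation geometry
    in seconds. normalize: apply per-participant min-max scaling.
    """

    median_window: int = 11
    target_fs: float | None = None
    trial_s: float = 60.0
    pretrial_s: float = 3.0
    normalize: bool = True
    normalize_first: bool = True  # 4 Hz style: normalize before median filtering

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError(f"median_window must be odd and >= 1, got {self.median_window}")
        if self.trial_s <= 0:
            raise ValueError("trial_s must be > 0")
        if self.pretrial_s < 0:
            raise ValueError("pretrial_s must be >= 0")


def _minmax(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi - lo == 0:
        warnings.warn("constant signal: min-max normalization maps all samples to 0")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def min_max_normalize(rec: EdaRecording) -> EdaRecording:
    """Min-max normalize a single recording to [0, 1].

    The minimum maps to 0 and the maximum to 1; a constant signal maps to all
    zeros with a warning. Normalization over a participant's concatenated
    recordings (the scope that removes between-participant level differences)
    is provided by :func:`normalize_subject`.
    """
    x = rec.samples
    return rec.replace_samples(_minmax(x, float(x.min()), float(x.max())))


def normalize_subject(recs: Sequence[EdaRecording]) -> list[EdaRecording]:
    """Min-max normalize all of one participant's recordings jointly.

    The min and max are taken over the concatenation of the participant's
    samples, so relative tonic-level differences between that participant's
    trials are preserved while between-participant level differences are
    removed.
    """
    if not recs:
        return []
    ids = {r.subject_id for r in recs}
    if len(ids) > 1:
        raise ValueError(f"normalize_subject got recordings from multiple subjects: {sorted(ids)}")
    allx = np.concatenate([r.samples for r in recs])
    lo, hi = float(allx.min()), float(allx.max())
    return [r.replace_samples(_minmax(r.samples, lo, hi)) for r in recs]


def median_filter(samples: np.ndarray, window: int) -> np.ndarray:
    """Running median with replicate-edge padding.

    Element ``i`` of the output is the median of the ``window`` samples
    centered at ``i``; the signal is extended at both ends by repeating the
    edge values so the output length equals the input length.
    """
    samples = np.asarray(samples, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    if window > samples.size:
        raise ValueError(
            f"median window {window} longer than signal of {samples.size} samples"
        )
    return scipy.ndimage.median_filter(samples, size=window, mode="nearest")


def resample(rec: EdaRecording, target_fs: float) -> EdaRecording:
    """Resample a recording to ``target_fs`` Hz with anti-aliasing.

    Uses polyphase filtering at the rational rate ``target_fs / rec.fs``; the
    low-pass stage of :func:`scipy.signal.resample_poly` prevents aliasing
    when downsampling. Duration is preserved to within one sample period.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = scipy.signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator,
                                     padtype="line")
    return rec.replace_samples(out, fs=target_fs)


def segment_and_debase(rec: EdaRecording, cfg: PreprocessConfig) -> EdaRecording:
    """Cut a trial segment and subtract the pre-trial baseline mean.

    The recording is read as ``pretrial_s`` seconds of baseline followed by
    ``trial_s`` seconds of trial; the mean of the baseline window is
    subtracted from every trial sample. With ``pretrial_s == 0`` the trial is
    returned unshifted.
    """
    n_pre = int(round(cfg.pretrial_s * rec.fs))
    n_trial = int(round(cfg.trial_s * rec.fs))
    needed = n_pre + n_trial
    if rec.samples.size < needed:
        raise ValueError(
            f"recording too short to segment: need {needed} samples "
            f"({cfg.pretrial_s}+{cfg.trial_s} s at {rec.fs} Hz), have {rec.samples.size}"
        )
    baseline = float(rec.samples[:n_pre].mean()) if n_pre > 0 else 0.0
    return rec.replace_samples(rec.samples[n_pre:needed] - baseline)


def preprocess_trials(
    recs: Sequence[EdaRecording],
    cfg: PreprocessConfig,
    dataset_style: str = "pafew",
) -> list[EdaRecording]:
    """Run the dataset-appropriate conditioning chain over a set of trials.

    pafew style (wrist-worn, 4 Hz): per-participant min-max normalization,
    then median filtering. deap style (128 Hz target): resample, segment with
    baseline removal, then per-participant normalization.
    """
    if dataset_style not in ("pafew", "deap"):
        raise ValueError(f"dataset_style must be 'pafew' or 'deap', got {dataset_style!r}")
    by_subject: dict[str, list[EdaRecording]] = {}
    for r in recs:
        by_subject.setdefault(r.subject_id, []).append(r)

    out: list[EdaRecording] = []
    for sid in by_subject:
        group = by_subject[sid]
        if dataset_style == "pafew":
            if cfg.normalize and cfg.normalize_first:
                group = normalize_subject(group)
            group = [
                r.replace_samples(median_filter(r.samples, cfg.median_window))
                for r in group
            ]
            if cfg.normalize and not cfg.normalize_first:
                group = normalize_subject(group)
        else:
            if cfg.target_fs is not None:
                group = [resample(r, cfg.target_fs) for r in group]
            group = [segment_and_debase(r, cfg) for r in group]
            if cfg.normalize:
                group = normalize_subject(group)
        out.extend(group)
    return out
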