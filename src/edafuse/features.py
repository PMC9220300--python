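"""Statistical feature extraction from preprocessed EDA trials.

Two feature registries are provided, matching the two acquisition styles:

* ``pafew`` — 11 time-domain statistics per trial: seven basic moments
  (mean, kurtosis, skewness, max, min, std, variance) plus four differential
  statistics on the first and second discrete differences.
* ``deap`` — skin-conductance-response (SCR) event features: peak count,
  mean peak amplitude, mean rise time, local-minimum count, plus the first
  two statistical moments.

Moments use the population (divide-by-N) convention throughout.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .records import EdaRecording

__all__ = [
    "PAFEW_FEATURES",
    "DEAP_FEATURES",
    "feature_registry",
    "basic_stats",
    "diff_stats",
    "scr_events",
    "build_feature_matrix",
]

PAFEW_FEATURES = (
    "MeanEDA", "KurtEDA", "SkewEDA", "MaxEDA", "MinEDA", "StdEDA", "VarEDA",
    "MeanAbsDiff", "MeanNegativeDiff", "MeanSecAbsDiff", "MeanSecNegativeDiff",
)
DEAP_FEATURES = (
    "NPeaks", "MeanPeakAmplitude", "MeanRiseTime", "NLocalMinima",
    "MeanEDA", "StdEDA",
)


def feature_registry() -> dict[str, list[str]]:
    """The named feature sets per acquisition style (exportable as JSON)."""
    return {"pafew": list(PAFEW_FEATURES), "deap": list(DEAP_FEATURES)}


def basic_stats(samples: np.ndarray) -> dict[str, float]:
    """Seven basic statistics of a trial signal.

    Variance and standard deviation use the population convention
    (``Var == Std**2``). For a zero-variance signal, skewness and kurtosis
    are reported as 0 with a warning rather than NaN.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError(f"basic_stats needs >= 4 samples (kurtosis), got {x.size}")
    mean = float(x.mean())
    var = float(x.var())
    std = float(np.sqrt(var))
    if var == 0.0:
        warnings.warn("zero-variance signal: skewness and kurtosis set to 0")
        skew = kurt = 0.0
    else:
        z = (x - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    return {
        "MeanEDA": mean,
        "KurtEDA": kurt,
        "SkewEDA": skew,
        "MaxEDA": float(x.max()),
        "MinEDA": float(x.min()),
        "StdEDA": std,
        "VarEDA": var,
    }


def diff_stats(samples: np.ndarray) -> dict[str, float]:
    """First- and second-difference statistics.

    MeanAbsDiff is the mean absolute first difference; MeanNegativeDiff is
    the mean over the strictly negative first differences (0 when the signal
    is non-decreasing), capturing the recovery-slope magnitude of SCR decay.
    The Sec variants apply the same definitions to second differences.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError(f"diff_stats needs >= 3 samples, got {x.size}")
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)

    def neg_mean(d: np.ndarray) -> float:
        neg = d[d < 0]
        return float(neg.mean()) if neg.size else 0.0

    return {
        "MeanAbsDiff": float(np.abs(d1).mean()),
        "MeanNegativeDiff": neg_mean(d1),
        "MeanSecAbsDiff": float(np.abs(d2).mean()),
        "MeanSecNegativeDiff": neg_mean(d2),
    }


def scr_events(
    samples: np.ndarray, fs: float, amplitude_threshold: float = 0.01
) -> dict[str, float]:
    """Skin-conductance-response event features via trough-to-peak detection.

    A peak is a local maximum whose rise from the preceding onset exceeds
    ``amplitude_threshold``; the onset is found by walking back from the
    peak while the signal strictly ascends (this lands on the preceding
    local minimum, or on the edge of a flat baseline). Amplitude is the
    onset-to-peak rise and rise time the onset-to-peak interval in seconds.
    Also reports the count of local minima and the first two moments.
    """
    x = np.asarray(samples, dtype=float)
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    maxima, _ = scipy.signal.find_peaks(x)
    minima, _ = scipy.signal.find_peaks(-x)

    amplitudes: list[float] = []
    rise_times: list[float] = []
    for p in maxima:
        onset = int(p)
        while onset > 0 and x[onset - 1] < x[onset]:
            onset -= 1
        rise = x[p] - x[onset]
        if rise > amplitude_threshold:
            amplitudes.append(float(rise))
            rise_times.append((p - onset) / fs)

    n_peaks = len(amplitudes)
    if n_peaks == 0:
        warnings.warn("no SCR peaks detected: amplitude/rise-time features set to 0")
    return {
        "NPeaks": float(n_peaks),
        "MeanPeakAmplitude": float(np.mean(amplitudes)) if n_peaks else 0.0,
        "MeanRiseTime": float(np.mean(rise_times)) if n_peaks else 0.0,
        "NLocalMinima": float(minima.size),
        "MeanEDA": float(x.mean()),
        "StdEDA": float(np.sqrt(x.var())),
    }


def _trial_features(rec: EdaRecording, dataset_style: str,
                    amplitude_threshold: float) -> dict[str, float]:
    if dataset_style == "pafew":
        return {**basic_stats(rec.samples), **diff_stats(rec.samples)}
    return scr_events(rec.samples, rec.fs, amplitude_threshold)


def build_feature_matrix(
    trials: Sequence[EdaRecording],
    dataset_style: str = "pafew",
    amplitude_threshold: float = 0.01,
) -> pd.DataFrame:
    """Extract the per-trial statistical feature matrix S.

    Returns a DataFrame indexed by ``(subject_id, trial_id)`` with one column
    per registry feature (11 for ``pafew``, 6 for ``deap``), in a stable
    documented order. All cells are finite; an empty trial list yields an
    empty frame with the full column header.
    """
    if dataset_style not in ("pafew", "deap"):
        raise ValueError(f"dataset_style must be 'pafew' or 'deap', got {dataset_style!r}")
    columns = PAFEW_FEATURES if dataset_style == "pafew" else DEAP_FEATURES
    rows = []
    index = []
    for rec in trials:
        feats = _trial_features(rec, dataset_style, amplitude_threshold)
        rows.append([feats[c] for c in columns])
        index.append((rec.subject_id, rec.trial_id))
    idx = pd.MultiIndex.from_tuples(index, names=["subject_id", "trial_id"]) if index \
        else pd.MultiIndex.from_arrays([[], []], names=["subject_id", "trial_id"])
    df = pd.DataFrame(rows, index=idx, columns=list(columns), dtype=float)
    if len(df) and not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("non-finite feature values produced")
    return df
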