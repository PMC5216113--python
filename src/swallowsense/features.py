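"""Per-cycle feature extraction and information-gain diagnostics.

Each breathing cycle is summarized by 11 features: the magnitudes of
the first five DFT coefficients of the normalized (128-point, 0–100)
cycle, the number of ±10 crossings of its first derivative (NTC), and
the pre-normalization durations and depths (inhale/exhale/total
duration, inhale/exhale depth).

NTC captures the extra fluctuations a swallow apnea imprints on the
cycle: the derivative of a smooth normalized cycle stays well inside
±10, while the apnea blip drives it across those levels. Compared with
zero crossings (NZC), the ±10 levels ignore the slow inhale/exhale
slopes and respond only to fast transients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .segmentation import NORMALIZED_LENGTH, BreathingCycle, NormalizedCycle, normalize_cycle

__all__ = [
    "FEATURE_NAMES",
    "fft_features",
    "ntc",
    "feature_vector",
    "CycleFeaturizer",
    "FeatureMeritReport",
    "merit",
]

FEATURE_NAMES = (
    "fft_mag_0", "fft_mag_1", "fft_mag_2", "fft_mag_3", "fft_mag_4",
    "ntc",
    "inhale_duration", "exhale_duration", "total_duration",
    "inhale_depth", "exhale_depth",
)

NTC_LEVEL = 10.0


def fft_features(cycle: NormalizedCycle | np.ndarray) -> np.ndarray:
    """Magnitudes of the unnormalized DFT coefficients k = 0..4."""
    x = cycle.samples if isinstance(cycle, NormalizedCycle) else np.asarray(cycle, float)
    if x.shape != (NORMALIZED_LENGTH,):
        raise ValueError(f"expected {NORMALIZED_LENGTH} samples, got {x.shape}")
    return np.abs(np.fft.fft(x)[:5])


def _level_crossings(d: np.ndarray, level: float) -> int:
    """Events where the sequence ``d`` crosses or exactly hits ``level``.

    A strict sign change of ``d - level`` between consecutive non-zero
    entries counts once; a run of exact hits counts once (not as two
    crossings).
    """
    s = d - level
    exact = 0
    prev_zero = False
    for v in s:
        if v == 0:
            if not prev_zero:
                exact += 1
            prev_zero = True
        else:
            prev_zero = False
    nz = s[s != 0]
    strict = int(np.count_nonzero(np.sign(nz[:-1]) != np.sign(nz[1:]))) if nz.size > 1 else 0
    return exact + strict


def ntc(cycle: NormalizedCycle | np.ndarray, level: float = NTC_LEVEL) -> int:
    """Number of ±``level`` crossings of the first derivative.

    The derivative is the per-sample forward difference of the
    normalized cycle (units: normalized amplitude per interpolation
    step), so the count is invariant to adding a constant offset.
    """
    x = cycle.samples if isinstance(cycle, NormalizedCycle) else np.asarray(cycle, float)
    d = np.diff(x)
    return _level_crossings(d, level) + _level_crossings(d, -level)


def feature_vector(cycle: BreathingCycle) -> np.ndarray:
    """The 11-feature description of one breathing cycle."""
    norm = normalize_cycle(cycle)
    return np.concatenate([
        fft_features(norm),
        [float(ntc(norm))],
        [cycle.inhale_duration, cycle.exhale_duration, cycle.total_duration,
         cycle.inhale_depth, cycle.exhale_depth],
    ])


class CycleFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from breathing cycles to the 11-column feature table."""

    def fit(self, X=None, y=None) -> "CycleFeaturizer":
        return self

    def transform(self, X: list[BreathingCycle]) -> pd.DataFrame:
        rows = [feature_vector(c) for c in X]
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


@dataclass
class FeatureMeritReport:
    """Information gain of each feature about the cycle class."""

    merits: pd.Series  # bits, indexed by feature name
    class_entropy: float  # H(C), bits


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def merit(features: pd.DataFrame, labels: np.ndarray, n_bins: int = 10) -> FeatureMeritReport:
    """Information gain H(C) − H(C|A) per feature, in bits.

    H(C) = −Σ_c p(c) log2 p(c) over the class distribution and
    H(C|A) = −Σ_a p(a) Σ_c p(c|a) log2 p(c|a) over the feature
    discretized into ``n_bins`` equal-frequency bins (features with few
    distinct values collapse to fewer bins). With a single class
    present, H(C) = 0 and every merit is 0.
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts().to_numpy(float)
    h_c = _entropy(counts / counts.sum())
    merits = {}
    for col in features.columns:
        x = features[col].to_numpy(float)
        if h_c == 0.0:
            merits[col] = 0.0
            continue
        try:
            binned = pd.qcut(x, n_bins, duplicates="drop", labels=False)
        except ValueError:  # all-identical feature
            merits[col] = 0.0
            continue
        h_c_given_a = 0.0
        for _, idx in pd.Series(np.arange(len(x))).groupby(binned).groups.items():
            sub = labels[np.asarray(idx)]
            p_a = len(sub) / len(labels)
            sub_counts = pd.Series(sub).value_counts().to_numpy(float)
            h_c_given_a += p_a * _entropy(sub_counts / sub_counts.sum())
        merits[col] = h_c - h_c_given_a
    return FeatureMeritReport(pd.Series(merits), h_c)
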