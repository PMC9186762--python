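"""Per-object intensity statistics over raw pixel values.

Moments use the population (n-denominator) convention so that a balanced
two-valued region {0, 10} has SD exactly 5.  Histogram statistics use 64
bins spanning the per-object min-max range: energy is the sum of squared
bin probabilities (1 for a constant object) and entropy is in bits.
Zero-variance regions define skewness, excess kurtosis and CV as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

HIST_BINS = 64


@dataclass
class IntensityStats:
    mean: float
    total: float
    sd: float
    cv: float
    skewness: float
    kurtosis: float
    energy: float
    entropy: float


def intensity_stats(values: np.ndarray, bins: int = HIST_BINS) -> IntensityStats:
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    mean = float(v.mean())
    total = float(v.sum())
    sd = float(v.std(ddof=0))
    cv = sd / mean if mean != 0 else 0.0
    if sd == 0:
        skew = kurt = 0.0
        p = np.array([1.0])
    else:
        skew = float(sps.skew(v, bias=True))
        kurt = float(sps.kurtosis(v, fisher=True, bias=True))
        counts, _ = np.histogram(v, bins=bins, range=(v.min(), v.max()))
        p = counts / counts.sum()
        p = p[p > 0]
    energy = float((p**2).sum())
    entropy = float(-(p * np.log2(p)).sum())
    return IntensityStats(mean, total, sd, cv, skew, kurt, energy, entropy)


def intensity_spreading(values: np.ndarray, distances: np.ndarray) -> float:
    """Outer-half mean intensity over inner-half mean, halves by distance rank.

    Quantifies whether stain is concentrated centrally (<1) or displaced
    toward the object rim (>1).  NaN when the inner half carries no signal.
    """
    v = np.asarray(values, float).ravel()
    d = np.asarray(distances, float).ravel()
    if v.size < 2:
        return np.nan
    order = np.argsort(d, kind="stable")
    half = v.size // 2
    inner = v[order[:half]]
    outer = v[order[half:]]
    if inner.mean() == 0:
        return np.nan
    return float(outer.mean() / inner.mean())
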