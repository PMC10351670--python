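"""First-order (histogram) statistics of ROI intensities."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .roi import RoiVolume

__all__ = ["first_order_features"]


def first_order_features(roi: RoiVolume, g_levels: int = 32) -> dict:
    """Histogram-shape features of the in-mask intensity distribution.

    Skewness and kurtosis use the conventional moment estimators
    ``m3 / m2^(3/2)`` and ``m4 / m2^2`` (Pearson kurtosis, 3 for a normal).
    Entropy is computed in bits over a ``g_levels`` equal-width histogram of
    the in-mask values.
    """
    v = roi.values
    if v.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    counts, _ = np.histogram(v, bins=g_levels) if v.max() > v.min() else (
        np.array([v.size]), None)
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    q = np.percentile(v, [5, 25, 75, 95])
    feats = {
        "fo_mean": float(v.mean()),
        "fo_median": float(np.median(v)),
        "fo_sd": float(v.std()),
        "fo_variance": float(v.var()),
        "fo_skewness": float(stats.skew(v, bias=True)),
        "fo_kurtosis": float(stats.kurtosis(v, fisher=False, bias=True)),
        "fo_min": float(v.min()),
        "fo_max": float(v.max()),
        "fo_range": float(v.max() - v.min()),
        "fo_energy": float((v**2).sum()),
        "fo_entropy": entropy,
        "fo_p5": float(q[0]),
        "fo_p25": float(q[1]),
        "fo_p75": float(q[2]),
        "fo_p95": float(q[3]),
        "fo_iqr": float(q[2] - q[1]),
    }
    if roi.intensities[roi.mask].std() == 0:
        feats["fo_skewness"] = 0.0
        feats["fo_kurtosis"] = 0.0
    return feats
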