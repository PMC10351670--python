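"""Grey-level co-occurrence matrices and derived features.

The GLCM records how often pairs of discretized grey levels occur at adjacent
voxels.  Co-occurrences are counted at a distance of one voxel along all 26
3D neighbour offsets; only pairs with both endpoints inside the mask
contribute (mask-restricted counting, avoiding partial-volume contamination
from outside the ROI).  Each per-offset matrix is symmetrized, normalized to
sum 1, and the 26 matrices are averaged.
"""

from __future__ import annotations

import itertools

import numpy as np

from .roi import DiscretizedRoi

__all__ = ["GLCM_OFFSETS", "compute_glcm", "glcm_features"]

#: all 26 one-voxel neighbour offsets in 3D
GLCM_OFFSETS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _shifted_pairs(levels: np.ndarray, offset):
    """Slices of `levels` pairing each voxel with its neighbour at `offset`."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, levels.shape):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


def compute_glcm(d_roi: DiscretizedRoi) -> np.ndarray:
    """Averaged, symmetric, normalized g x g co-occurrence matrix."""
    g = d_roi.g
    acc = np.zeros((g, g))
    n_valid = 0
    for off in GLCM_OFFSETS:
        a, b = _shifted_pairs(d_roi.levels, off)
        valid = (a > 0) & (b > 0)       # both endpoints in mask
        if not valid.any():
            continue
        counts = np.zeros((g, g))
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
        counts = counts + counts.T      # symmetrize
        acc += counts / counts.sum()
        n_valid += 1
    if n_valid == 0:
        raise ValueError("ROI too small: no in-mask voxel pairs for GLCM")
    return acc / n_valid


def glcm_features(m: np.ndarray) -> dict:
    """Standard scalar features of a normalized co-occurrence matrix.

    Grey-level indices run 1..G.  Entropy is in bits.  For a degenerate
    matrix with zero marginal variance (constant ROI) correlation is defined
    as 1.
    """
    g = m.shape[0]
    i = np.arange(1, g + 1)[:, None] * np.ones((1, g))
    j = i.T
    p = m / m.sum()
    pi = p.sum(axis=1)
    mu_i = float((np.arange(1, g + 1) * pi).sum())
    var_i = float(((np.arange(1, g + 1) - mu_i) ** 2 * pi).sum())
    nz = p[p > 0]
    diff = np.abs(i - j)
    feats = {
        "glcm_contrast": float((p * (i - j) ** 2).sum()),
        "glcm_dissimilarity": float((p * diff).sum()),
        "glcm_homogeneity": float((p / (1.0 + diff)).sum()),
        "glcm_idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "glcm_asm": float((p**2).sum()),
        "glcm_energy": float(np.sqrt((p**2).sum())),
        "glcm_entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm_autocorrelation": float((p * i * j).sum()),
        "glcm_cluster_shade": float((p * (i + j - 2 * mu_i) ** 3).sum()),
        "glcm_cluster_prominence": float((p * (i + j - 2 * mu_i) ** 4).sum()),
        "glcm_max_probability": float(p.max()),
    }
    if var_i > 0:
        feats["glcm_correlation"] = float(
            (p * (i - mu_i) * (j - mu_i)).sum() / var_i)
    else:
        feats["glcm_correlation"] = 1.0
    return feats
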