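"""Grey-level run-length matrices and derived features.

A run is a maximal sequence of consecutive voxels with the same discretized
grey level along a direction, broken by the mask boundary.  Runs are
enumerated along the 13 unique 3D directions (the 26 neighbour offsets
collapse pairwise, since a run read forwards or backwards is the same run).
Features are computed per direction and averaged.
"""

from __future__ import annotations

import numpy as np

from .roi import DiscretizedRoi

__all__ = ["GLRLM_DIRECTIONS", "compute_glrlm", "glrlm_features"]

#: the 13 unique (up to sign) one-voxel 3D directions
GLRLM_DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _shift(arr: np.ndarray, d, fill=0):
    """Array whose value at v equals ``arr[v + d]`` (fill outside the grid)."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for di, n in zip(d, arr.shape):
        if di == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif di > 0:
            src.append(slice(di, n))
            dst.append(slice(0, n - di))
        else:
            src.append(slice(0, n + di))
            dst.append(slice(-di, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _direction_matrix(levels: np.ndarray, g: int, d) -> np.ndarray:
    """Run-length matrix (g x max_run) for one direction."""
    inside = levels > 0
    nxt = _shift(levels, d)
    cont = inside & (nxt == levels) & (nxt > 0)   # run continues at v -> v+d
    # chain length L[v] = 1 + (cont[v] ? L[v+d] : 0), solved by iteration
    run_len = np.ones(levels.shape, dtype=np.int64)
    run_len[~inside] = 0
    while True:
        upd = np.where(cont, 1 + _shift(run_len, d), run_len)
        upd[~inside] = 0
        if np.array_equal(upd, run_len):
            break
        run_len = upd
    prev = _shift(levels, tuple(-x for x in d))
    starts = inside & (prev != levels)
    lv = levels[starts]
    ln = run_len[starts]
    rmax = int(ln.max()) if ln.size else 1
    mat = np.zeros((g, rmax))
    np.add.at(mat, (lv - 1, ln - 1), 1.0)
    return mat


def compute_glrlm(d_roi: DiscretizedRoi) -> dict:
    """Run-length matrices keyed by direction."""
    if not d_roi.mask.any():
        raise ValueError("empty ROI")
    return {d: _direction_matrix(d_roi.levels, d_roi.g, d)
            for d in GLRLM_DIRECTIONS}


def _features_one(mat: np.ndarray, n_voxels: int) -> dict:
    g, rmax = mat.shape
    n_r = mat.sum()
    gl = np.arange(1, g + 1)[:, None]
    rl = np.arange(1, rmax + 1)[None, :]
    row = mat.sum(axis=1)   # per grey level
    col = mat.sum(axis=0)   # per run length
    return {
        "glrlm_sre": float((mat / rl**2).sum() / n_r),
        "glrlm_lre": float((mat * rl**2).sum() / n_r),
        "glrlm_gln": float((row**2).sum() / n_r),
        "glrlm_rln": float((col**2).sum() / n_r),
        "glrlm_rp": float(n_r / n_voxels),
        "glrlm_lglre": float((mat / gl**2).sum() / n_r),
        "glrlm_hglre": float((mat * gl**2).sum() / n_r),
        "glrlm_srlgle": float((mat / (gl**2 * rl**2)).sum() / n_r),
        "glrlm_srhgle": float((mat * gl**2 / rl**2).sum() / n_r),
        "glrlm_lrlgle": float((mat * rl**2 / gl**2).sum() / n_r),
        "glrlm_lrhgle": float((mat * gl**2 * rl**2).sum() / n_r),
    }


def glrlm_features(matrices: dict, n_voxels: int) -> dict:
    """Per-direction features averaged over the 13 directions."""
    per_dir = [_features_one(m, n_voxels) for m in matrices.values()]
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}
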