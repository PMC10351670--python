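"""End-to-end texture extraction for one ROI or a hemisphere pair.

Pipeline order: optional denoising hook -> mean +/- 3 SD trimming ->
z-scoring -> equal-width discretization -> first-order / GLCM / GLRLM
features, plus ROI volume.  For bilateral structures, features (and volume)
are computed per hemisphere and averaged element-wise.
"""

from __future__ import annotations

import logging

import pandas as pd

from .roi import RoiVolume, trim_extremes, znormalize, discretize, volume_mm3
from .firstorder import first_order_features
from .glcm import compute_glcm, glcm_features
from .glrlm import compute_glrlm, glrlm_features

log = logging.getLogger(__name__)

__all__ = ["extract_features", "extract_all"]

MIN_ROI_VOXELS = 27


def extract_features(roi: RoiVolume, g_levels: int = 32, trim_sigma: float = 3.0,
                     denoise_hook=None) -> pd.Series:
    """Full feature vector for a single ROI.

    ``denoise_hook``, if given, is called with the raw :class:`RoiVolume` and
    must return one; the default is a no-op (denoising upstream of texture
    extraction has been reported not to change feature characterization
    appreciably, so it is left pluggable).
    """
    if roi.n_voxels < MIN_ROI_VOXELS:
        raise ValueError(f"ROI too small: {roi.n_voxels} < {MIN_ROI_VOXELS} voxels")
    if denoise_hook is not None:
        roi = denoise_hook(roi)
    vol = volume_mm3(roi)
    roi, n_trimmed = trim_extremes(roi, n_sigma=trim_sigma)
    if n_trimmed:
        log.debug("trimmed %d extreme voxels", n_trimmed)
    roi = znormalize(roi)
    d_roi = discretize(roi, g_levels=g_levels)
    feats = {}
    feats.update(first_order_features(roi, g_levels=g_levels))
    feats.update(glcm_features(compute_glcm(d_roi)))
    feats.update(glrlm_features(compute_glrlm(d_roi), roi.n_voxels))
    feats["volume"] = vol
    s = pd.Series(feats, dtype=float)
    if not s.map(lambda v: v == v and abs(v) != float("inf")).all():
        raise ValueError("non-finite feature value produced")
    return s


def extract_all(roi_left: RoiVolume | None, roi_right: RoiVolume | None,
                g_levels: int = 32, trim_sigma: float = 3.0,
                denoise_hook=None, allow_single: bool = False) -> pd.Series:
    """Hemisphere-averaged feature vector.

    Each hemisphere is preprocessed and featurized independently and the two
    vectors are averaged element-wise (volume included).  If one hemisphere
    is missing, behaviour depends on ``allow_single``: error (default) or
    single-hemisphere passthrough with a ``single_hemisphere`` flag of 1.
    """
    rois = [r for r in (roi_left, roi_right) if r is not None]
    if not rois:
        raise ValueError("both hemispheres missing")
    if len(rois) == 1 and not allow_single:
        raise ValueError("one hemisphere missing (set allow_single=True to permit)")
    vecs = [extract_features(r, g_levels=g_levels, trim_sigma=trim_sigma,
                             denoise_hook=denoise_hook) for r in rois]
    out = sum(vecs) / len(vecs)
    out["single_hemisphere"] = float(len(vecs) == 1)
    return out
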