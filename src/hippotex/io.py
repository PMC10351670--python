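"""File I/O and pipeline configuration.

NIfTI-1 volumes are read and written with nibabel; voxel spacing is taken
from the affine.  Tables are CSV (UTF-8, comma, header, empty field for
missing); fitted models serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict

import nibabel as nib
import numpy as np
import yaml

from .texture.roi import RoiVolume

__all__ = ["read_volume_pair", "write_volume_pair", "PipelineConfig"]


def read_volume_pair(image_path, mask_path, hemisphere: str = "left") -> RoiVolume:
    """Load an intensity volume + binary mask pair as a :class:`RoiVolume`.

    The two files must have congruent shapes and affines; spacing comes from
    the affine's column norms.  An all-zero mask is rejected.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    if img.shape != msk.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {msk.shape}")
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise ValueError("image and mask affines differ")
    data = np.asarray(img.get_fdata(), dtype=float)
    mask = np.asarray(msk.get_fdata()) > 0.5
    if not mask.any():
        raise ValueError("empty ROI: mask selects no voxels")
    spacing = tuple(float(np.linalg.norm(img.affine[:3, i])) for i in range(3))
    return RoiVolume(data, mask, spacing=spacing, hemisphere=hemisphere)


def write_volume_pair(roi: RoiVolume, image_path, mask_path):
    """Write a :class:`RoiVolume` as a NIfTI image + mask pair."""
    affine = np.diag(list(roi.spacing) + [1.0])
    nib.save(nib.Nifti1Image(roi.intensities.astype(np.float32), affine),
             str(image_path))
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), affine),
             str(mask_path))


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, with the study constants as
    defaults: CSF amyloid threshold 980 pg/mL with a 5% borderline band,
    32 grey-level bins, mean +/- 3 SD intensity trimming, mean +/- 3 x IQR
    feature-cell exclusion, 5% PCA retention, 9-DoF progression splines,
    3-6 DoF trajectory splines, 1-6 DoF dual-timescale terms, 1000-rep
    bootstrap."""

    outdir: str = "hippotex_out"
    seed: int = 0
    # cohort simulation
    n_per_group: int = 25
    visit_schedule: tuple = (0.0, 1.0, 2.0, 3.0)
    # texture
    phantom_shape: tuple = (14, 14, 14)
    bins: int = 32
    trim_sigma: float = 3.0
    # feature reduction
    feature_iqr_mult: float = 3.0
    pca_retention: float = 0.05
    # cross-sectional
    analysis_iqr_mult: float = 1.5
    csf_threshold: float = 980.0
    centiloid_threshold: float = 24.0
    borderline_frac: float = 0.05
    # progression / trajectories
    staging_outcomes: tuple = ("adas13", "cdrsb", "mmse", "centiloid")
    progression_dof: int = 9
    trajectory_dof_range: tuple = (3, 4, 5, 6)
    dual_dof_range: tuple = (1, 2, 3, 4, 5, 6)
    quantile_trim: float = 0.05
    # prediction
    n_boot: int = 1000
    horizon_months: float = 24.0
    window_months: float = 12.0

    def __post_init__(self):
        for name in ("bins", "trim_sigma", "feature_iqr_mult", "pca_retention",
                     "analysis_iqr_mult", "csf_threshold", "borderline_frac",
                     "n_boot", "progression_dof"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.seed is None:
            raise ValueError("config field 'seed' is required "
                             "(stochastic stages need a seed)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("visit_schedule", "phantom_shape", "staging_outcomes",
                    "trajectory_dof_range", "dual_dof_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)   # the hash identifies the analysis, not paths
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
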