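"""3D ROI phantoms with controllable texture.

A phantom is an ellipsoidal ROI inside a rectangular grid, filled with a
constant base level plus a seeded field of hyperintense blobs (Gaussian
bumps of controllable width) and optional white noise — a stand-in for the
"clustered hyperintensity" appearance texture analysis is meant to quantify.
Wider blobs give smoother images and hence lower co-occurrence contrast,
which the test suite exploits as a monotonicity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..texture.roi import RoiVolume
from .cohort import SpecError

__all__ = ["PhantomSpec", "generate_phantom"]


@dataclass
class PhantomSpec:
    """Generating parameters for a textured ROI phantom."""

    shape: tuple = (16, 16, 16)
    base_level: float = 100.0
    cluster_count: int = 8
    blob_sigma: float = 1.0
    blob_amplitude: float = 40.0
    noise_sd: float = 5.0
    radius_scale: float = 1.0
    spacing: tuple = (1.0, 1.0, 1.0)
    hemisphere: str = "left"
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 3 for s in self.shape):
            raise SpecError("shape must be 3 axes, each >= 3 voxels")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.cluster_count < 0:
            raise SpecError("cluster_count must be >= 0")
        if self.blob_sigma < 0:
            raise SpecError("blob_sigma must be >= 0")
        if self.blob_sigma > 0 and 6 * self.blob_sigma >= min(self.shape):
            raise SpecError("blob_sigma too large for grid shape")
        if not 0.1 <= self.radius_scale <= 1.0:
            raise SpecError("radius_scale must be in [0.1, 1]")


def _ellipsoid_mask(shape, scale: float = 1.0) -> np.ndarray:
    centre = [(n - 1) / 2.0 for n in shape]
    semi = [max(scale * (n / 2.0 - 0.5), 1.0) for n in shape]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> RoiVolume:
    """Generate a seeded textured phantom as a :class:`RoiVolume`."""
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.shape, spec.radius_scale)
    field = np.zeros(spec.shape)
    if spec.cluster_count > 0:
        in_idx = np.argwhere(mask)
        picks = in_idx[rng.integers(len(in_idx), size=spec.cluster_count)]
        field[tuple(picks.T)] += spec.blob_amplitude
    if spec.noise_sd > 0:
        field += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.blob_sigma > 0 and (spec.cluster_count > 0 or spec.noise_sd > 0):
        # blob_sigma is the correlation length of the textured field: the
        # blob impulses and the stochastic component are smoothed together,
        # so larger sigma gives a smoother image and lower GLCM contrast
        field = gaussian_filter(field, sigma=spec.blob_sigma)
    img = float(spec.base_level) + field
    return RoiVolume(img, mask, spacing=tuple(spec.spacing),
                     hemisphere=spec.hemisphere)
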