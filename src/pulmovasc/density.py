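"""Vessel-density quantification on binarized 3D stacks.

Mirrors transparent-lung density measurement: binary conversion of the 3D
image, then the fraction (and physical volume) of foreground within a region
of interest. Otsu's criterion on the ROI histogram is the default threshold
rule; the chosen threshold is always reported for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .types import VolumeImage

__all__ = ["DensityResult", "binarize_volume", "vessel_density"]


@dataclass
class DensityResult:
    threshold: float
    method: str
    foreground_voxels: int
    roi_voxels: int
    density_fraction: float
    physical_volume: float  # um^3 of foreground inside the ROI


def binarize_volume(
    volume: VolumeImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    roi_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Binary conversion of a 3D stack.

    Returns ``(mask, threshold)`` with ``mask = intensity > threshold``
    (strict, so an all-background volume maps to an empty mask). With
    ``method="otsu"`` the threshold minimizes intra-class variance over the
    ROI histogram; a constant-intensity volume has no definable threshold and
    raises. With ``method="fixed"`` the caller supplies ``fixed_threshold``.
    """
    if volume.voxels.size == 0:
        raise ValueError("empty volume")
    vox = volume.voxels
    if roi_mask is not None:
        if roi_mask.shape != vox.shape:
            raise ValueError("roi_mask shape mismatch")
        sample = vox[roi_mask]
        if sample.size == 0:
            raise ValueError("empty ROI")
    else:
        sample = vox.ravel()

    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required when method='fixed'")
        threshold = float(fixed_threshold)
    elif method == "otsu":
        if sample.min() == sample.max():
            raise ValueError("constant-intensity volume: Otsu threshold undefined")
        threshold = float(threshold_otsu(sample))
    else:
        raise ValueError(f"unknown method {method!r}")
    return vox > threshold, threshold


def vessel_density(
    mask: np.ndarray,
    roi_mask: np.ndarray | None,
    spacing: tuple[float, float, float],
    threshold: float = float("nan"),
    method: str = "fixed",
) -> DensityResult:
    """Foreground fraction and physical foreground volume within the ROI.

    ``roi_mask=None`` uses the whole grid. ``density_fraction`` is exactly
    ``foreground_voxels / roi_voxels`` and ``physical_volume`` is
    ``foreground_voxels x voxel volume`` in um^3.
    """
    mask = np.asarray(mask, dtype=bool)
    if roi_mask is None:
        roi_mask = np.ones_like(mask, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != mask.shape:
        raise ValueError("mask and roi_mask must have the same shape")
    roi_voxels = int(roi_mask.sum())
    if roi_voxels == 0:
        raise ValueError("empty ROI")
    fg = int((mask & roi_mask).sum())
    voxel_volume = float(np.prod(spacing))
    return DensityResult(
        threshold=threshold,
        method=method,
        foreground_voxels=fg,
        roi_voxels=roi_voxels,
        density_fraction=fg / roi_voxels,
        physical_volume=fg * voxel_volume,
    )
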