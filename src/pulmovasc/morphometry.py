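"""2D histomorphometry and organ-weight indices.

Percent medial wall thickness of a pulmonary artery cross-section,
``[(SMC thickness x 2) / vessel diameter] x 100`` with the external (outer)
diameter — the only reading that keeps the percentage <= 100 for a
geometrically possible annulus — plus diameter-based vessel size classes and
Fulton's right-ventricular-hypertrophy index ``RV / (LV + S)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "MorphometryRecord",
    "HeartWeights",
    "percent_wall_thickness",
    "measure_annulus",
    "classify_vessel",
    "fulton_index",
    "SMALL_ARTERY",
    "ARTERIOLE",
]

SMALL_ARTERY = "small_artery"
ARTERIOLE = "arteriole"


@dataclass
class MorphometryRecord:
    """One vessel cross-section's wall measurements (all lengths in um)."""

    vessel_id: str
    external_diameter: float
    smc_thickness: float  # single-side medial thickness
    percent_wall_thickness: float
    vessel_class: str | None = None


@dataclass
class HeartWeights:
    rv_mg: float
    lv_mg: float
    septum_mg: float

    def __post_init__(self) -> None:
        if min(self.rv_mg, self.lv_mg, self.septum_mg) <= 0:
            raise ValueError("all chamber weights must be positive")

    @property
    def fulton_index(self) -> float:
        return fulton_index(self.rv_mg, self.lv_mg, self.septum_mg)


def percent_wall_thickness(smc_thickness_um: float, diameter_um: float) -> float:
    """[(SMC thickness x 2) / vessel diameter] x 100."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    if smc_thickness_um < 0:
        raise ValueError("thickness must be non-negative")
    if 2 * smc_thickness_um > diameter_um:
        raise ValueError(
            f"doubled wall thickness {2 * smc_thickness_um} um exceeds the external "
            f"diameter {diameter_um} um: geometrically impossible annulus"
        )
    return (smc_thickness_um * 2.0 / diameter_um) * 100.0


def measure_annulus(
    section_image: np.ndarray,
    pixel_size_um: float,
    threshold: float | None = None,
    vessel_id: str = "vessel",
) -> MorphometryRecord:
    """Automated wall morphometry on one approximately annular cross-section.

    The bright wall is segmented (Otsu unless a ``threshold`` is given),
    reduced to its largest connected component and hole-filled. Outer and
    inner diameters are equivalent-circle diameters from the filled and
    lumen areas, ``d = 2 sqrt(A / pi)``; wall thickness is half their
    difference. A filled disk (no lumen) yields inner diameter 0 and 100%
    wall thickness.
    """
    img = np.asarray(section_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("section_image must be a non-empty 2D image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size must be positive")
    if threshold is None:
        if img.min() == img.max():
            raise ValueError("constant image: no annular component found")
        threshold = float(threshold_otsu(img))
    bw = img > threshold
    labels, n = ndimage.label(bw)
    if n == 0:
        raise ValueError("no annular component found above threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == int(np.argmax(counts))
    filled = ndimage.binary_fill_holes(comp)

    px_area = pixel_size_um ** 2
    area_out = float(filled.sum()) * px_area
    area_in = float((filled & ~comp).sum()) * px_area
    d_out = 2.0 * np.sqrt(area_out / np.pi)
    d_in = 2.0 * np.sqrt(area_in / np.pi)
    thickness = (d_out - d_in) / 2.0
    return MorphometryRecord(
        vessel_id=vessel_id,
        external_diameter=d_out,
        smc_thickness=thickness,
        percent_wall_thickness=percent_wall_thickness(thickness, d_out),
    )


def classify_vessel(record: MorphometryRecord, cutoff_um: float) -> str:
    """Diameter-based size class: ``small_artery`` when the external diameter
    is >= ``cutoff_um``, else ``arteriole``.

    The anatomic classification (terminal bronchiole vs acinar level) has no
    universal diameter equivalent, so the cutoff is the analyst's explicit
    choice — there is deliberately no default.
    """
    if record.external_diameter <= 0:
        raise ValueError("diameter must be positive")
    if cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    cls = SMALL_ARTERY if record.external_diameter >= cutoff_um else ARTERIOLE
    record.vessel_class = cls
    return cls


def fulton_index(rv_mg: float, lv_mg: float, septum_mg: float) -> float:
    """Right-ventricular-hypertrophy index RV / (LV + S); unit-free."""
    if min(rv_mg, lv_mg, septum_mg) <= 0:
        raise ValueError("all chamber weights must be positive")
    return rv_mg / (lv_mg + septum_mg)
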