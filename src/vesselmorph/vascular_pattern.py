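"""Spatial vascularity pattern: where in the lesion do the vessels live?

The lesion mask is eroded (disk structuring element), its area centroid is
the geometric center, and the largest centroid-to-mask distance is ``r_max``.
Pixels of the eroded mask within ``center_fraction * r_max`` of the centroid
form the *center region*; the rest is the *peripheral region*. The vessel
density ratio is

    VDR = density(center) / density(peripheral)

with density = vessel-pixel fraction of the region, and the spatial
vascularity pattern is the threshold SVP = 1 if VDR >= 1 (intratumoral,
centrally concentrated) else SVP = 0 (peritumoral).

The diagnostic reading of SVP flips with lesion size: in masses <= 20 mm a
peripheral pattern (SVP 0) leans benign and a central one (SVP 1) leans
malignant, while in masses > 20 mm the association reverses (large malignant
tumors develop necrotic, avascular cores and peripheral neovasculature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import LesionMaskError, NoVesselsError
from .image import as_binary

__all__ = [
    "LesionGeometry",
    "VascularPattern",
    "SvpInterpretation",
    "SIZE_THRESHOLD_MM",
    "build_lesion_geometry",
    "compute_vdr_svp",
    "interpret_svp",
]

SIZE_THRESHOLD_MM = 20.0
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class LesionGeometry:
    """Eroded lesion mask partitioned into center and peripheral regions."""

    mask: np.ndarray  # original lesion mask (0/1)
    eroded_mask: np.ndarray
    center_rc: tuple[float, float]
    r_max_px: float
    center_region: np.ndarray
    peripheral_region: np.ndarray


@dataclass(frozen=True)
class VascularPattern:
    density_center: float
    density_peripheral: float
    vdr: float
    svp: int


@dataclass(frozen=True)
class SvpInterpretation:
    lesion_size_mm: float
    svp: int
    leaning: str  # "benign-leaning" | "malignant-leaning"


def build_lesion_geometry(
    mask,
    erosion_radius_px: int = 3,
    center_fraction: float = 0.5,
) -> LesionGeometry:
    """Erode the lesion mask and split it into center and peripheral regions.

    ``center_fraction`` sets the center/periphery boundary as a fraction of
    the largest radius (default 0.5, ~25% of the area for a disk).
    """
    arr = as_binary(mask)
    if arr.sum() < 100:
        raise LesionMaskError("lesion mask must contain at least 100 pixels")
    labels, n = ndi.label(arr, structure=_STRUCT8)
    if n > 1:
        warnings.warn(
            f"lesion mask has {n} connected components; using the largest", stacklevel=2
        )
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        arr = (labels == int(counts.argmax())).astype(np.uint8)
    if erosion_radius_px > 0:
        eroded = ndi.binary_erosion(arr.astype(bool), structure=disk(erosion_radius_px))
    else:
        eroded = arr.astype(bool)
    if not eroded.any():
        raise LesionMaskError("lesion too small for erosion radius")
    rows, cols = np.nonzero(eroded)
    center = (float(rows.mean()), float(cols.mean()))
    dist = np.hypot(rows - center[0], cols - center[1])
    r_max = float(dist.max())
    if r_max <= 0:
        raise LesionMaskError("lesion degenerates to a point after erosion")
    center_region = np.zeros_like(eroded)
    center_region[rows[dist <= center_fraction * r_max], cols[dist <= center_fraction * r_max]] = True
    peripheral_region = eroded & ~center_region
    if not center_region.any() or not peripheral_region.any():
        raise LesionMaskError("center/peripheral partition is empty; lesion too small")
    if not eroded[int(round(center[0])), int(round(center[1]))]:
        warnings.warn("geometric center falls outside the lesion mask", stacklevel=2)
    return LesionGeometry(
        mask=arr,
        eroded_mask=eroded,
        center_rc=center,
        r_max_px=r_max,
        center_region=center_region,
        peripheral_region=peripheral_region,
    )


def compute_vdr_svp(image, geom: LesionGeometry) -> VascularPattern:
    """Vessel density ratio and SVP for a vessel image within a lesion geometry."""
    vessels = as_binary(image).astype(bool)
    if vessels.shape != geom.mask.shape:
        raise LesionMaskError(
            f"vessel image shape {vessels.shape} does not match lesion mask shape {geom.mask.shape}"
        )
    n_center = int(geom.center_region.sum())
    n_periph = int(geom.peripheral_region.sum())
    density_center = float((vessels & geom.center_region).sum()) / n_center
    density_peripheral = float((vessels & geom.peripheral_region).sum()) / n_periph
    if density_center == 0.0 and density_peripheral == 0.0:
        raise NoVesselsError("no vessels in lesion: both region densities are zero")
    vdr = density_center / density_peripheral if density_peripheral > 0 else float("inf")
    svp = 1 if vdr >= 1.0 else 0
    return VascularPattern(
        density_center=density_center,
        density_peripheral=density_peripheral,
        vdr=vdr,
        svp=svp,
    )


def interpret_svp(svp: int, lesion_size_mm: float) -> SvpInterpretation:
    """Size-conditional diagnostic leaning of an SVP value."""
    if lesion_size_mm <= 0:
        raise LesionMaskError("lesion size must be positive")
    if svp not in (0, 1):
        raise ValueError("svp must be 0 or 1")
    small = lesion_size_mm <= SIZE_THRESHOLD_MM
    if small:
        leaning = "benign-leaning" if svp == 0 else "malignant-leaning"
    else:
        leaning = "malignant-leaning" if svp == 0 else "benign-leaning"
    return SvpInterpretation(lesion_size_mm=lesion_size_mm, svp=svp, leaning=leaning)
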