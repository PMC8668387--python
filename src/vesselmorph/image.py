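"""Binary vessel images: the unit every metric consumes.

A binary vessel image is a 2D grid of {0, 1} where nonzero means "vessel".
Images come from contrast-free ultrasound microvessel imaging after upstream
segmentation (out of scope here); this module only loads, validates and saves
such masks. Any nonzero value in a file is mapped to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import InputError, NoVesselsError

__all__ = ["BinaryVesselImage", "as_binary", "load_binary_image", "save_binary_image"]


def as_binary(image) -> np.ndarray:
    """Coerce an array-like (or :class:`BinaryVesselImage`) to a 2D uint8 0/1 array."""
    if isinstance(image, BinaryVesselImage):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) masks
        arr = arr[..., :3].max(axis=-1)
    if arr.ndim != 2:
        raise InputError(f"expected a 2D image, got shape {arr.shape}")
    return (arr != 0).astype(np.uint8)


@dataclass(frozen=True)
class BinaryVesselImage:
    """A validated 2D 0/1 vessel mask with optional physical pixel size.

    Parameters
    ----------
    pixels
        2D uint8 array with values in {0, 1}; nonzero = vessel.
    pixel_size_mm
        Isotropic pixel edge length in millimetres, if known.
    """

    pixels: np.ndarray
    pixel_size_mm: float | None = None

    def __post_init__(self):
        arr = as_binary(self.pixels)
        object.__setattr__(self, "pixels", arr)
        if self.pixel_size_mm is not None and self.pixel_size_mm <= 0:
            raise InputError("pixel_size_mm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_vessel_pixels(self) -> int:
        return int(self.pixels.sum())

    def require_vessels(self) -> "BinaryVesselImage":
        if self.n_vessel_pixels == 0:
            raise NoVesselsError("no vessels: the binary image has no nonzero pixels")
        return self

    @classmethod
    def load(cls, path, pixel_size_mm: float | None = None) -> "BinaryVesselImage":
        return cls(load_binary_image(path), pixel_size_mm=pixel_size_mm)


def load_binary_image(path) -> np.ndarray:
    """Read a PNG or TIFF mask; any nonzero pixel becomes 1."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read image: no such file {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except InputError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any decode failure
        raise InputError(f"cannot read image {path}: {exc}") from exc
    return as_binary(arr)


def save_binary_image(path, image) -> None:
    """Write a 0/255 8-bit mask as PNG or TIFF by extension."""
    path = Path(path)
    arr = (as_binary(image) * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)
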