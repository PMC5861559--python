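"""Raster-image container with sensor metadata.

Conventions used throughout the package: 0-based coordinates, pixel centers
at integer coordinates, row-major ``(row, col)`` order.  Intensities are kept
as floats in [0, 1] internally and quantized only on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterImage", "read_image", "write_image"]


@dataclass
class RasterImage:
    """A 2-D (grayscale) or 2-D x 3 (RGB) intensity raster.

    Parameters
    ----------
    intensities
        Finite, non-negative array, shape ``(rows, cols)`` or
        ``(rows, cols, 3)``.
    pixel_pitch
        Sensor pixel pitch in micrometres (pixels are assumed square).
    bit_depth
        ``8``, ``16`` or ``"float"``; controls quantization on write.
    """

    intensities: np.ndarray
    pixel_pitch: float
    bit_depth: int | str = "float"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim not in (2, 3):
            raise ValueError("intensities must be 2-D or 2-D x 3")
        if self.intensities.ndim == 3 and self.intensities.shape[2] != 3:
            raise ValueError("color images must have exactly 3 channels")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.bit_depth not in (8, 16, "float"):
            raise ValueError("bit_depth must be 8, 16 or 'float'")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    def luminance(self) -> "RasterImage":
        """Collapse RGB to a single channel (mean of channels); no-op on
        grayscale input."""
        if self.intensities.ndim == 2:
            return self
        return replace(self, intensities=self.intensities.mean(axis=2))

    def copy(self) -> "RasterImage":
        return replace(self, intensities=self.intensities.copy(),
                       meta=dict(self.meta))


def _quantize(img: RasterImage) -> np.ndarray:
    if img.bit_depth == "float":
        return img.intensities.astype(np.float32)
    peak = 2 ** int(img.bit_depth) - 1
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    return np.clip(np.round(img.intensities * peak), 0, peak).astype(dtype)


def write_image(img: RasterImage, path: str | Path) -> None:
    """Write a 16-bit (or 8-bit) TIFF/PNG; pixel pitch is stored as TIFF
    resolution metadata where the format supports it."""
    path = Path(path)
    data = _quantize(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        # resolution in pixels per centimetre; pitch is in um
        ppcm = 1e4 / img.pixel_pitch
        tifffile.imwrite(path, data, resolution=(ppcm, ppcm),
                         resolutionunit="CENTIMETER")
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        if data.dtype == np.float32:
            data = np.clip(np.round(img.intensities * 65535), 0,
                           65535).astype(np.uint16)
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_image(path: str | Path, pixel_pitch: float | None = None) -> RasterImage:
    """Read a TIFF or PNG into a float RasterImage.

    Integer images are rescaled to [0, 1] by their dtype's full range.
    ``pixel_pitch`` overrides any pitch recoverable from TIFF metadata and is
    required for formats that carry none.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            if pixel_pitch is None:
                try:
                    xres = page.tags["XResolution"].value
                    unit = page.tags["ResolutionUnit"].value
                    per_cm = xres[0] / xres[1]
                    if int(unit) == 2:  # inch
                        per_cm /= 2.54
                    pixel_pitch = 1e4 / per_cm
                except (KeyError, ZeroDivisionError):
                    pass
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        data = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")

    if pixel_pitch is None:
        raise ValueError("pixel_pitch not in metadata; pass it explicitly")

    data = np.asarray(data)
    if data.dtype == np.uint8:
        arr, depth = data / 255.0, 8
    elif data.dtype == np.uint16:
        arr, depth = data / 65535.0, 16
    else:
        arr, depth = data.astype(float), "float"
    return RasterImage(arr, pixel_pitch=pixel_pitch, bit_depth=depth,
                       meta={"source": str(path)})
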