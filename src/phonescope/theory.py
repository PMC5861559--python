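"""Closed-form optics and resolution-chart geometry.

Three small results are used throughout the pipeline:

* the Rayleigh two-point resolution limit ``0.61 lambda / NA`` of an
  aberration-free lens,
* the USAF 1951 chart geometry, where element ``(group g, element e)`` has a
  spatial frequency of ``2**(g + (e-1)/6)`` line pairs per mm, so a single
  bar (half a line pair) is ``500 / frequency`` micrometres wide,
* a Nyquist-style sampling check: is the in-focus PSF peak covered by enough
  sensor pixels to be fitted and described?  The rule of thumb adopted here
  is that roughly 7 points across the central peak are required; the peak
  support is taken as twice the FWHM (``CENTRAL_PEAK_FWHM_FACTOR``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CENTRAL_PEAK_FWHM_FACTOR",
    "LensSpec",
    "TheoreticalResolution",
    "rayleigh_resolution",
    "usaf_bar_width",
    "sampling_assessment",
    "load_lens_table",
    "example_lens_table",
]

#: Support of the "central peak" of the PSF, in units of its FWHM, over which
#: sampling points are counted.  A full Gaussian central lobe spans roughly
#: twice its FWHM; the factor is exposed so users with a different convention
#: can override it.
CENTRAL_PEAK_FWHM_FACTOR: float = 2.0

#: Column headers expected in a lens-specification CSV.
LENS_TABLE_COLUMNS = [
    "Lens", "Supplier", "Cost ($)", "Material", "NA",
    "Focal length (mm)", "Working distance (mm)", "Diameter (mm)",
    "Clear aperture (mm)",
]


@dataclass(frozen=True)
class LensSpec:
    """Manufacturer specification of a single aspheric objective lens."""

    name: str
    supplier: str
    cost: float
    material: str
    na: float
    focal_length: float
    working_distance: float
    diameter: float
    clear_aperture: float

    def __post_init__(self):
        if not 0 < self.na < 1:
            raise ValueError("NA must lie in (0, 1) for a lens in air")


@dataclass(frozen=True)
class TheoreticalResolution:
    """Rayleigh-limit resolution ``delta = 0.61 * wavelength / na``.

    ``wavelength`` and ``delta`` share units (nm here)."""

    delta: float
    wavelength: float
    na: float


def rayleigh_resolution(wavelength: float, na: float) -> float:
    """Rayleigh two-point resolution limit, ``0.61 * wavelength / na``.

    Parameters
    ----------
    wavelength
        Imaging wavelength (nm).
    na
        Numerical aperture of the objective; must be positive.

    Returns
    -------
    float
        Minimum resolvable separation, in the same units as ``wavelength``.
    """
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    if wavelength < 0:
        raise ValueError("wavelength must be non-negative")
    return 0.61 * wavelength / na


def usaf_bar_width(group: int, element: int) -> tuple[float, float]:
    """Spatial frequency and bar width of a USAF 1951 chart element.

    Returns
    -------
    (resolution, bar_width)
        Resolution in line pairs per mm, ``2**(group + (element-1)/6)``, and
        the width of a single bar in micrometres, ``500 / resolution`` (one
        line pair = one bar + one gap = ``1000/resolution`` um).
    """
    if not 1 <= element <= 6:
        raise ValueError("element must be an integer in [1, 6]")
    resolution = 2.0 ** (group + (element - 1) / 6.0)
    return resolution, 500.0 / resolution


def sampling_assessment(
    fwhm_sample: float,
    magnification: float,
    pixel_pitch: float,
    required_points: int = 7,
    peak_fwhm_factor: float = CENTRAL_PEAK_FWHM_FACTOR,
) -> tuple[float, bool]:
    """Count sensor pixels across the PSF central peak and judge adequacy.

    The PSF of FWHM ``fwhm_sample`` (sample-plane um) appears on the sensor
    with width ``fwhm_sample * magnification``; its central peak, taken as
    ``peak_fwhm_factor`` FWHMs wide, is sampled every ``pixel_pitch`` um.

    Returns
    -------
    (points_per_peak, adequate)
        ``points_per_peak = peak_fwhm_factor * fwhm_sample * magnification /
        pixel_pitch``; ``adequate`` is True when it reaches
        ``required_points``.
    """
    if fwhm_sample <= 0 or magnification <= 0 or pixel_pitch <= 0:
        raise ValueError("fwhm, magnification and pixel_pitch must be positive")
    points = peak_fwhm_factor * fwhm_sample * magnification / pixel_pitch
    return points, points >= required_points


def _specs_from_frame(df: pd.DataFrame) -> list[LensSpec]:
    missing = [c for c in LENS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lens table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        cost = str(row["Cost ($)"]).lstrip("<>")
        out.append(LensSpec(
            name=str(row["Lens"]), supplier=str(row["Supplier"]),
            cost=float(cost), material=str(row["Material"]),
            na=float(row["NA"]), focal_length=float(row["Focal length (mm)"]),
            working_distance=float(row["Working distance (mm)"]),
            diameter=float(row["Diameter (mm)"]),
            clear_aperture=float(row["Clear aperture (mm)"]),
        ))
    return out


def load_lens_table(path: str | Path) -> list[LensSpec]:
    """Read lens specifications from a CSV or JSON table.

    The table must carry the standard headers (``Lens, Supplier, Cost ($),
    Material, NA, Focal length (mm), Working distance (mm), Diameter (mm),
    Clear aperture (mm)``).  A leading ``<`` in the cost column (``<1`` for
    a sub-dollar budget lens) is tolerated.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    return _specs_from_frame(df)


def example_lens_table() -> list[LensSpec]:
    """The bundled specification table for the five aspheric lenses the
    pipeline was developed around (four Thorlabs aspherics and one budget
    plastic lens)."""
    return load_lens_table(Path(__file__).parent / "data" / "lenses.csv")
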