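"""Per-lens characterization reports and the lens-comparison table.

``characterize_lens`` runs the full pipeline for one lens — magnification
from a grid-target image, PSF FWHM from a resolution-chart edge
cross-section, optional radial distortion, and the Rayleigh-limit prediction
from the lens NA — and collects everything, with provenance and warnings,
into a :class:`LensReport`.  ``compare_lenses`` tabulates several reports
side by side (magnification, resolution mean +/- SD, sampling, working
distance, cost).  No winner is declared: lens choice trades resolution
against field of view, working distance and cost, and stays a human
judgment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (DistortionEstimate, MagnificationEstimate,
                          estimate_distortion, estimate_magnification)
from .errors import PhonescopeError
from .image import RasterImage
from .resolution import PSFEstimate, measure_resolution
from .theory import LensSpec, TheoreticalResolution, rayleigh_resolution

__all__ = ["LensReport", "characterize_lens", "compare_lenses"]

logger = logging.getLogger("phonescope")

#: Default wavelength (nm) for Rayleigh-limit predictions: center of the
#: visible band under white-light LED illumination.
DEFAULT_WAVELENGTH_NM = 550.0


@dataclass
class LensReport:
    """Aggregate characterization of one lens."""

    lens: LensSpec
    magnification: MagnificationEstimate | None = None
    resolution: PSFEstimate | None = None
    distortion: DistortionEstimate | None = None
    theoretical_resolution: TheoreticalResolution | None = None
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    partial: bool = False

    @property
    def cost(self) -> float:
        return self.lens.cost

    @property
    def working_distance(self) -> float:
        return self.lens.working_distance

    def to_dict(self) -> dict:
        d = {
            "lens": self.lens.__dict__.copy(),
            "magnification": (self.magnification.to_dict()
                              if self.magnification else None),
            "resolution": self.resolution.to_dict() if self.resolution else None,
            "distortion": self.distortion.to_dict() if self.distortion else None,
            "theoretical_resolution": (
                self.theoretical_resolution.__dict__.copy()
                if self.theoretical_resolution else None),
            "warnings": list(self.warnings),
            "provenance": dict(self.provenance),
            "partial": self.partial,
        }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def characterize_lens(grid_image: RasterImage | None,
                      usaf_image: RasterImage,
                      lens: LensSpec,
                      roi,
                      known_period: float = 500.0,
                      pixel_pitch: float | None = None,
                      wavelength: float = DEFAULT_WAVELENGTH_NM,
                      required_points: int = 7,
                      expected_peaks: int | str = "auto",
                      with_distortion: bool = False) -> LensReport:
    """Run the full characterization pipeline for one lens.

    Parameters
    ----------
    grid_image
        Grid-target image for magnification (and optionally distortion).
        ``None`` degrades gracefully: the report is marked partial and the
        resolution is left in sensor-plane units (no magnification to
        divide by).
    usaf_image
        Resolution-chart image; ``roi`` selects one vertical-orientation
        three-bar element (pixel box ``(row0, col0, row1, col1)``).
    known_period
        Grid period in micrometres (500 for the standard distortion
        target, 100 for the fine variant).
    """
    report = LensReport(lens=lens)
    pitch = usaf_image.pixel_pitch if pixel_pitch is None else pixel_pitch
    report.provenance = {
        "grid_source": (grid_image.meta.get("source") or
                        grid_image.meta.get("config_hash")
                        if grid_image else None),
        "usaf_source": (usaf_image.meta.get("source") or
                        usaf_image.meta.get("config_hash")),
        "known_period_um": known_period,
        "pixel_pitch_um": pitch,
        "wavelength_nm": wavelength,
        "roi": list(np.asarray(roi, dtype=float)),
    }

    mag = None
    if grid_image is None:
        report.warnings.append(
            "no grid image: magnification unknown, resolution reported in "
            "sensor-plane units")
        report.partial = True
    else:
        try:
            mag = estimate_magnification(grid_image, known_period, pitch)
            report.magnification = mag
            logger.info("magnification: mx=%.3f my=%.3f", mag.mx, mag.my)
        except PhonescopeError as exc:
            report.warnings.append(f"magnification failed: {exc}")
            report.partial = True

    try:
        if mag is not None:
            m = 0.5 * (mag.mx + mag.my)
            report.resolution = measure_resolution(
                usaf_image, roi, magnification=m, pixel_pitch=pitch,
                required_points=required_points,
                expected_peaks=expected_peaks, plane="sample")
        else:
            report.resolution = measure_resolution(
                usaf_image, roi, magnification=1.0, pixel_pitch=pitch,
                required_points=required_points,
                expected_peaks=expected_peaks, plane="sensor")
        logger.info("resolution: %.3f +/- %.3f um (%s plane)",
                    report.resolution.fwhm_mean, report.resolution.fwhm_sd,
                    report.resolution.plane)
    except PhonescopeError as exc:
        report.warnings.append(f"resolution failed: {exc}")
        report.partial = True

    if with_distortion and grid_image is not None:
        try:
            report.distortion = estimate_distortion(grid_image, known_period,
                                                    pitch)
        except PhonescopeError as exc:
            report.warnings.append(f"distortion failed: {exc}")
            report.partial = True

    report.theoretical_resolution = TheoreticalResolution(
        delta=rayleigh_resolution(wavelength, lens.na),
        wavelength=wavelength, na=lens.na)
    return report


def compare_lenses(reports: list[LensReport],
                   sort_by: str | None = None,
                   ascending: bool = True) -> pd.DataFrame:
    """Side-by-side comparison table of lens reports.

    Columns: magnification (mean of axes), resolution mean +/- SD (um),
    points per PSF peak, Rayleigh prediction (um), working distance (mm)
    and unit cost.  Every numeric cell traces back to an estimator output
    or the manufacturer's specification sheet.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for r in reports:
        mag = (0.5 * (r.magnification.mx + r.magnification.my)
               if r.magnification else np.nan)
        rows.append({
            "lens": r.lens.name,
            "magnification": mag,
            "resolution_um": (r.resolution.fwhm_mean if r.resolution
                              else np.nan),
            "resolution_sd_um": (r.resolution.fwhm_sd if r.resolution
                                 else np.nan),
            "points_per_peak": (r.resolution.points_per_peak
                                if r.resolution else np.nan),
            "adequate_sampling": (r.resolution.adequate_sampling
                                  if r.resolution else None),
            "rayleigh_um": (r.theoretical_resolution.delta / 1000.0
                            if r.theoretical_resolution else np.nan),
            "working_distance_mm": r.working_distance,
            "cost": r.cost,
            "partial": r.partial,
        })
    df = pd.DataFrame(rows)
    if sort_by is not None:
        key = {"resolution": "resolution_um",
               "magnification": "magnification"}.get(sort_by, sort_by)
        df = df.sort_values(key, ascending=ascending).reset_index(drop=True)
    return df
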