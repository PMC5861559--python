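"""Magnification and radial-distortion calibration from grid-target images.

A grid target of known period imaged onto a sensor of known pixel pitch
gives the system magnification per axis:
``M = period_px * pixel_pitch / known_period``.
Line centers are located from intensity projections with sub-pixel parabolic
interpolation; the period is taken in the central region of the field, where
radial distortion bias is smallest.  Radial distortion itself is quantified
by fitting the Brown one-coefficient model ``r' = r (1 + k1 r^2)`` (radius
normalized by the half diagonal; k1 > 0 = pincushion) to the displacement of
detected grid intersections from an ideal lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .errors import InsufficientStructureError
from .image import RasterImage
from .targets import distort_points

__all__ = [
    "MagnificationEstimate",
    "DistortionEstimate",
    "estimate_grid_period",
    "estimate_magnification",
    "estimate_distortion",
]


@dataclass(frozen=True)
class MagnificationEstimate:
    """Per-axis magnification measured from a grid target."""

    mx: float
    my: float
    period_px_x: float
    period_px_y: float
    uncertainty: float  # 1 SD, dimensionless

    def to_dict(self) -> dict:
        return {"mx": self.mx, "my": self.my,
                "period_px_x": self.period_px_x,
                "period_px_y": self.period_px_y,
                "uncertainty": self.uncertainty}


@dataclass(frozen=True)
class DistortionEstimate:
    """Brown one-coefficient radial distortion fitted to a grid image."""

    k1: float
    center: tuple[float, float]  # (row, col), fixed at the image center
    residual: float  # RMS of the lattice fit, pixels
    n_points: int = 0

    def to_dict(self) -> dict:
        return {"k1": self.k1, "center": list(self.center),
                "residual": self.residual, "n_points": self.n_points}


def _line_centers(projection: np.ndarray) -> np.ndarray:
    """Locate periodic line centers in a 1-D intensity projection.

    Detects both dark and bright lines and keeps whichever polarity yields
    the stronger periodic structure.  Each center is the midpoint of the
    line's interpolated half-prominence crossings, which stays sub-pixel
    accurate for wide, flat-bottomed lines where a parabola through the
    extremum would not.
    """
    span = projection.max() - projection.min()
    if span <= 0:
        raise InsufficientStructureError("projection has no contrast")
    prom = 0.2 * span
    candidates = []
    for sign in (-1.0, 1.0):  # dark lines first
        p = sign * projection
        idx, props = signal.find_peaks(p, prominence=prom, width=1,
                                       rel_height=0.5)
        if len(idx):
            candidates.append((props["prominences"].sum(), props))
    if not candidates:
        raise InsufficientStructureError("no periodic lines detected")
    _, props = max(candidates, key=lambda t: t[0])
    return 0.5 * (props["left_ips"] + props["right_ips"])


def estimate_grid_period(image: RasterImage, axis: str = "x",
                         central_fraction: float = 1.0 / 3.0
                         ) -> tuple[float, float]:
    """Mean grid-line spacing along one axis, in pixels.

    The intensity is projected (averaged) across a central band
    perpendicular to ``axis`` and line centers are detected in the
    projection.  Centers inside the central ``central_fraction`` of the
    field are used (the region least affected by radial distortion); the
    window grows symmetrically if it holds fewer than three lines.

    Returns
    -------
    (period_px, uncertainty)
        Period as the slope of a linear fit of center position against line
        index, and its standard error.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    arr = image.luminance().intensities
    if axis == "y":
        arr = arr.T
    rows, cols = arr.shape
    band = slice(int(rows / 3), max(int(2 * rows / 3), int(rows / 3) + 1))
    projection = arr[band].mean(axis=0)
    centers = _line_centers(projection)
    if len(centers) < 3:
        raise InsufficientStructureError(
            f"only {len(centers)} grid lines detected; need >= 3")
    mid = (cols - 1) / 2.0
    frac = central_fraction
    sel = centers
    while frac <= 1.0:
        sel = centers[np.abs(centers - mid) <= frac * cols / 2.0]
        if len(sel) >= 3:
            break
        frac += 1.0 / 6.0
    if len(sel) < 3:
        sel = centers
    # mean of center-to-center spacings, robust to spurious or missed lines
    # (clipped half-lines at the border, drop-outs): spacings deviating more
    # than 30% from the median are discarded
    diffs = np.diff(np.sort(sel))
    med = float(np.median(diffs))
    good = diffs[np.abs(diffs - med) <= 0.3 * med]
    if len(good) < 2:
        raise InsufficientStructureError("no consistent line spacing found")
    sd = float(np.std(good, ddof=1)) if len(good) > 1 else 0.0
    return float(np.mean(good)), sd / np.sqrt(len(good))


def estimate_magnification(image: RasterImage, known_period: float,
                           pixel_pitch: float | None = None
                           ) -> MagnificationEstimate:
    """Per-axis magnification from a grid target of known period (um).

    ``M = period_px * pixel_pitch / known_period`` for each axis;
    ``pixel_pitch`` defaults to the image metadata.
    """
    if known_period <= 0:
        raise ValueError("known_period must be positive")
    pitch = image.pixel_pitch if pixel_pitch is None else pixel_pitch
    px, ux = estimate_grid_period(image, "x")
    py, uy = estimate_grid_period(image, "y")
    scale = pitch / known_period
    return MagnificationEstimate(
        mx=px * scale, my=py * scale, period_px_x=px, period_px_y=py,
        uncertainty=scale * float(np.sqrt((ux**2 + uy**2) / 2.0)))


# ----------------------------------------------------------------------
# distortion
# ----------------------------------------------------------------------

def _trough_center(values: np.ndarray) -> float:
    """Sub-pixel center of the single dark trough in a 1-D profile: midpoint
    of the interpolated half-depth crossings around the minimum."""
    p = values.max() - values
    i = int(np.argmax(p))
    level = 0.5 * p[i]
    left = right = np.nan
    for k in range(i, 0, -1):
        if p[k - 1] <= level <= p[k]:
            left = k - 1 + (level - p[k - 1]) / (p[k] - p[k - 1])
            break
    for k in range(i, len(p) - 1):
        if p[k + 1] <= level <= p[k]:
            right = k + (p[k] - level) / (p[k] - p[k + 1])
            break
    return 0.5 * (left + right)


def _grid_intersections(arr: np.ndarray, period_px: float) -> np.ndarray:
    """Detect grid-line crossings; returns (N, 2) array of (row, col).

    Dark lines are isolated by thresholding a lightly smoothed image;
    horizontal and vertical line masks are extracted by morphological
    opening with long thin structuring elements, and their intersection
    blobs are reduced to intensity-weighted centroids.
    """
    # enough smoothing that the trough flanks span several pixels: the
    # half-crossing linear interpolation is then sub-0.01 px accurate
    sm = ndimage.gaussian_filter(arr, max(1.5, period_px / 40.0))
    thr = 0.5 * (sm.min() + sm.max())
    dark = sm < thr
    if dark.mean() > 0.5:  # bright lines on dark background
        dark = ~dark
        sm = -sm
    L = max(int(round(0.6 * period_px)), 3)
    horiz = ndimage.binary_opening(dark, structure=np.ones((1, L)))
    vert = ndimage.binary_opening(dark, structure=np.ones((L, 1)))
    cross = horiz & vert
    labels, n = ndimage.label(cross)
    if n == 0:
        return np.empty((0, 2))
    # blobs touching the border are clipped and their centroids biased;
    # keep fully interior intersections only
    keep = [i + 1 for i, sl in enumerate(ndimage.find_objects(labels))
            if sl is not None
            and sl[0].start > 0 and sl[1].start > 0
            and sl[0].stop < arr.shape[0] and sl[1].stop < arr.shape[1]]
    if not keep:
        return np.empty((0, 2))
    coarse = np.asarray(ndimage.center_of_mass(cross, labels, index=keep),
                        dtype=float)
    # refine each coordinate separately: project the local cross arm and
    # take the midpoint of the trough's half-prominence crossings
    out = []
    W = max(int(round(0.35 * period_px)), 4)
    for r0, c0 in coarse:
        r, c = int(round(r0)), int(round(c0))
        rs = slice(max(r - W, 0), min(r + W + 1, arr.shape[0]))
        cs = slice(max(c - W, 0), min(c + W + 1, arr.shape[1]))
        row_c = _trough_center(sm[rs, cs].mean(axis=1))
        col_c = _trough_center(sm[rs, cs].mean(axis=0))
        if np.isnan(row_c) or np.isnan(col_c):
            continue
        out.append((rs.start + row_c, cs.start + col_c))
    return np.asarray(out, dtype=float)


def estimate_distortion(image: RasterImage, known_period: float | None = None,
                        pixel_pitch: float | None = None
                        ) -> DistortionEstimate:
    """Fit radial distortion ``r' = r (1 + k1 r^2)`` to a grid image.

    Grid intersections are detected over the whole field and matched to an
    ideal lattice (free per-axis period and offset); ``k1`` is then obtained
    by nonlinear least squares on the predicted, distorted lattice
    positions.  The distortion center is fixed at the geometric image
    center and the radius is normalized by the half diagonal, so ``k1`` is
    directly comparable with the forward model's ``distortion_k1``.
    """
    arr = image.luminance().intensities
    rows, cols = arr.shape
    period_px = estimate_grid_period(image, "x")[0]
    pts = _grid_intersections(arr, period_px)
    if len(pts) < 9:
        raise InsufficientStructureError(
            f"only {len(pts)} grid intersections detected; need >= 9")
    span_r = np.ptp(pts[:, 0]) / rows
    span_c = np.ptp(pts[:, 1]) / cols
    if span_r < 0.6 or span_c < 0.6:
        raise InsufficientStructureError(
            "grid intersections cover less than 60% of the field")
    period_py = estimate_grid_period(image, "y")[0]

    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    # lattice indices from the undistorted approximation
    ii = np.round((pts[:, 0] - cy) / period_py)
    jj = np.round((pts[:, 1] - cx) / period_px)

    def residuals(p):
        k1, Py, Px, r0, c0 = p
        ideal_r = r0 + ii * Py
        ideal_c = c0 + jj * Px
        pred_r, pred_c = distort_points(ideal_r, ideal_c, (rows, cols), k1)
        return np.concatenate([pred_r - pts[:, 0], pred_c - pts[:, 1]])

    p0 = [0.0, period_py, period_px, cy, cx]
    sol = optimize.least_squares(residuals, p0, method="lm")
    res = sol.fun.reshape(2, -1)
    rms = float(np.sqrt(np.mean(res[0] ** 2 + res[1] ** 2)))
    return DistortionEstimate(k1=float(sol.x[0]), center=(cy, cx),
                              residual=rms, n_points=len(pts))
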