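"""Edge-derivative PSF measurement: the pipeline's core analysis.

A chrome-on-glass resolution chart presents ideal step edges, so an
intensity cross-section through a three-bar element is a sequence of edge
spread functions (ESF).  Its first derivative is the line spread function
(LSF), which for a symmetric PSF profiles the PSF itself.  Each transition
in the derivative is fitted with a Gaussian as a first approximation to the
Airy profile; the mean and standard deviation of the fitted full widths at
half maximum (FWHM) give the practical resolution and its spread.  A
three-bar element contributes six transitions, hence six fitted widths.

Discretization handling
-----------------------
The derivative is formed by central finite differences on the sampled
profile.  That operator is a 2h-wide box average of the true LSF and, on
images, each sample additionally carries the pixel aperture (an h-wide box).
Fitting a bare Gaussian to such data overestimates sigma by up to several
percent at phone-sensor sampling, so by default each peak is modelled as the
exact central difference of a Gaussian ESF (a difference of Gaussian CDFs
sharing one sigma), and the pixel aperture is removed in quadrature
(``sigma^2 -> sigma^2 - pitch^2 / 12``).  Both refinements are switchable
(``discrete=False``, ``aperture_correction=False``) to recover the bare
Gaussian fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal
from scipy.special import erf

from .errors import FitError, GeometryError, PhonescopeError
from .image import RasterImage
from .targets import (FWHM_PER_SIGMA, USAFElementSpec,
                      fwhm_from_gaussian_sigma)
from .theory import sampling_assessment

__all__ = [
    "LineProfile",
    "GaussianPeak",
    "PSFEstimate",
    "ContrastResult",
    "extract_profile",
    "differentiate",
    "MultiGaussianModel",
    "MultiGaussianResult",
    "fit_multi_gaussian",
    "measure_resolution",
    "smallest_resolvable_element",
    "feature_contrast",
]


@dataclass(frozen=True)
class LineProfile:
    """Intensity samples along a straight segment.

    ``positions`` are micrometres on a strictly increasing uniform grid;
    ``plane`` records whether they are sensor-plane or sample-plane
    distances.
    """

    positions: np.ndarray
    intensities: np.ndarray
    plane: str = "sensor"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1-D")
        if len(pos) >= 2:
            d = np.diff(pos)
            if d.min() <= 0:
                raise ValueError("positions must be strictly increasing")
            if (d.max() - d.min()) > 1e-6 * abs(d.mean()):
                raise ValueError("positions must be uniformly spaced")
        if self.plane not in ("sensor", "sample"):
            raise ValueError("plane must be 'sensor' or 'sample'")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted transition of the derivative profile.

    ``amplitude`` is the signed peak height; ``fwhm = 2 sqrt(2 ln 2) sigma``.
    """

    center: float
    sigma: float
    amplitude: float
    fwhm: float = field(default=0.0)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "fwhm", fwhm_from_gaussian_sigma(self.sigma))


@dataclass(frozen=True)
class PSFEstimate:
    """Mean +/- SD PSF FWHM from the fitted edge-derivative Gaussians."""

    fwhm_mean: float
    fwhm_sd: float
    n_edges: int
    peaks: tuple
    points_per_peak: float
    adequate_sampling: bool
    plane: str = "sample"
    fwhm_mean_sensor: float = float("nan")

    def to_dict(self) -> dict:
        return {"fwhm_mean_um": self.fwhm_mean, "fwhm_sd_um": self.fwhm_sd,
                "n_edges": self.n_edges, "plane": self.plane,
                "points_per_peak": self.points_per_peak,
                "adequate_sampling": bool(self.adequate_sampling),
                "fwhm_mean_sensor_um": self.fwhm_mean_sensor}


@dataclass(frozen=True)
class ContrastResult:
    """Michelson modulation of a feature and whether it counts as resolved."""

    modulation: float
    resolved: bool


# ----------------------------------------------------------------------
# profile extraction and differentiation
# ----------------------------------------------------------------------

def extract_profile(image: RasterImage, p0, p1, width_px: int = 1,
                    spacing_px: float = 1.0) -> LineProfile:
    """Sample intensities along the segment p0 -> p1 (``(row, col)`` each).

    Samples every ``spacing_px`` pixels by bilinear interpolation, averaged
    over ``width_px`` parallel lines offset perpendicular to the segment.
    Positions are sensor-plane micrometres (``arc length * pixel_pitch``).
    """
    arr = image.luminance().intensities
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise GeometryError("profile endpoints coincide")
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)
    n = int(np.floor(length / spacing_px)) + 1
    t = np.arange(n) * spacing_px
    pts = p0[None, None, :] + t[None, :, None] * direction[None, None, :] \
        + offsets[:, None, None] * normal[None, None, :]
    lo = pts.reshape(-1, 2).min(axis=0)
    hi = pts.reshape(-1, 2).max(axis=0)
    if (lo < -0.5).any() or (hi > np.array(arr.shape) - 0.5).any():
        raise GeometryError("profile segment extends outside the image")
    vals = ndimage.map_coordinates(arr, [pts[..., 0].ravel(),
                                         pts[..., 1].ravel()],
                                   order=1, mode="nearest")
    inten = vals.reshape(width_px, n).mean(axis=0)
    return LineProfile(positions=t * image.pixel_pitch, intensities=inten,
                       plane="sensor")


def differentiate(profile: LineProfile) -> LineProfile:
    """First derivative of a profile by central finite differences.

    One-sided differences at the endpoints; no smoothing is applied, so the
    LSF estimate is unbiased (noise is left to the Gaussian fit).
    """
    if len(profile) < 3:
        raise PhonescopeError("need at least 3 samples to differentiate")
    y = profile.intensities
    h = profile.spacing
    d = np.empty_like(y)
    d[1:-1] = (y[2:] - y[:-2]) / (2 * h)
    d[0] = (y[1] - y[0]) / h
    d[-1] = (y[-1] - y[-2]) / h
    return LineProfile(positions=profile.positions.copy(), intensities=d,
                       plane=profile.plane)


# ----------------------------------------------------------------------
# multi-peak Gaussian model of the derivative
# ----------------------------------------------------------------------

def _phi(z):
    return 0.5 * (1.0 + erf(z / np.sqrt(2.0)))


def _robust_noise(d: np.ndarray, tail_fraction: float = 0.15) -> float:
    """1.4826 x median absolute deviation of the derivative tails."""
    k = max(int(round(tail_fraction * len(d))), 2)
    tails = np.concatenate([d[:k], d[-k:]])
    return float(1.4826 * np.median(np.abs(tails - np.median(tails))))


class MultiGaussianModel:
    """Sum of signed Gaussian peaks plus a constant baseline, fitted to a
    derivative (LSF) profile by nonlinear least squares.

    Peak locations are initialized at the alternating-sign local extrema of
    the derivative exceeding 5x a robust noise estimate; initial widths come
    from each extremum's half-height width and amplitudes from the extremum
    values.  The fit runs in two stages: first with a single width shared by
    all peaks (every transition samples the same PSF, and the shared-width
    problem is well conditioned), then with per-peak widths initialized from
    and bounded around the shared solution.  This prevents the classic
    degeneracy where two overlapping opposite-sign Gaussians collapse onto
    one center with huge cancelling amplitudes.

    Parameters
    ----------
    profile
        The differentiated line profile.
    expected_peaks
        ``"auto"`` keeps every detected extremum; an integer demands at
        least that many and keeps the strongest.
    discrete
        Model each peak as the exact central finite difference of a
        Gaussian ESF rather than a bare Gaussian (see module docstring).
    noise_factor
        Detection threshold in units of the robust noise estimate.
    """

    def __init__(self, profile: LineProfile,
                 expected_peaks: int | str = "auto",
                 discrete: bool = True, noise_factor: float = 5.0):
        self.profile = profile
        self.expected_peaks = expected_peaks
        self.discrete = discrete
        self.noise_factor = noise_factor

    # -- initialization ----------------------------------------------------
    def _find_extrema(self) -> tuple[np.ndarray, np.ndarray]:
        d = self.profile.intensities
        noise = _robust_noise(d)
        floor = max(self.noise_factor * noise, 0.02 * np.max(np.abs(d)))
        idx = []
        for sign in (1.0, -1.0):
            pk, _ = signal.find_peaks(sign * d, height=floor,
                                      prominence=0.5 * floor)
            idx.extend(pk.tolist())
        idx = np.array(sorted(idx), dtype=int)
        if len(idx) == 0:
            raise FitError("no derivative extrema above the noise floor",
                           {"noise": noise, "threshold": floor})
        if isinstance(self.expected_peaks, int):
            if len(idx) < self.expected_peaks:
                raise FitError(
                    f"found {len(idx)} extrema, expected "
                    f"{self.expected_peaks}", {"indices": idx.tolist()})
            order = np.argsort(np.abs(d[idx]))[::-1][:self.expected_peaks]
            idx = np.sort(idx[order])
        return idx, d[idx]

    def _model(self, params: np.ndarray, x: np.ndarray) -> np.ndarray:
        h = self.profile.spacing
        out = np.full_like(x, params[0])
        for a, c, s in params[1:].reshape(-1, 3):
            if self.discrete:
                norm = erf(h / (s * np.sqrt(2.0)))
                out = out + a * (_phi((x - c + h) / s)
                                 - _phi((x - c - h) / s)) / norm
            else:
                out = out + a * np.exp(-0.5 * ((x - c) / s) ** 2)
        return out

    # -- fitting -----------------------------------------------------------
    def fit(self, ftol: float = 1e-8, max_iter: int = 500
            ) -> "MultiGaussianResult":
        x = self.profile.positions
        d = self.profile.intensities
        h = self.profile.spacing
        idx, amp = self._find_extrema()
        centers = x[idx]
        if len(idx) > 1:
            gaps = np.diff(centers)
            near = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
        else:
            near = np.full(1, x[-1] - x[0])
        # initial sigma from each extremum's own half-height width, capped
        # at half the distance to its nearest neighbour
        sig0 = np.empty(len(idx))
        for j, (i, a) in enumerate(zip(idx, amp)):
            w = signal.peak_widths(np.sign(a) * d, [i], rel_height=0.5)[0][0]
            sig0[j] = w * h / FWHM_PER_SIGMA
        sig0 = np.clip(sig0, 0.5 * h, near / 2.0)
        npk = len(idx)
        # edges alternate direction: pin each amplitude to its detected sign
        amp_lo = np.where(amp > 0, 0.0, -np.inf)
        amp_hi = np.where(amp > 0, np.inf, 0.0)

        # stage 1: one width shared by all peaks
        span = x[-1] - x[0]
        shared0 = float(np.median(sig0))

        def shared_model(p):
            full = np.concatenate(
                [[p[0]], np.column_stack([p[2::2], p[3::2],
                                          np.full(npk, p[1])]).ravel()])
            return self._model(full, x)

        p0s = np.concatenate([[np.median(d), shared0],
                              np.column_stack([amp, centers]).ravel()])
        lo_s = np.concatenate([[-np.inf, 0.25 * h], np.column_stack(
            [amp_lo, np.full(npk, x[0])]).ravel()])
        hi_s = np.concatenate([[np.inf, span], np.column_stack(
            [amp_hi, np.full(npk, x[-1])]).ravel()])
        stage1 = optimize.least_squares(
            lambda p: shared_model(p) - d, p0s, bounds=(lo_s, hi_s),
            ftol=ftol, xtol=ftol, max_nfev=max_iter * (len(p0s) + 1))
        sig_shared = float(stage1.x[1])
        amp1 = stage1.x[2::2]
        cen1 = stage1.x[3::2]

        # stage 2: per-peak widths around the shared solution
        p0 = np.concatenate(
            [[stage1.x[0]], np.column_stack(
                [amp1, cen1, np.full(npk, sig_shared)]).ravel()])
        sig_lo = max(sig_shared / 2.5, 0.25 * h)
        sig_hi = min(sig_shared * 2.5, span)
        lo = np.concatenate([[-np.inf], np.column_stack(
            [amp_lo, np.full(npk, x[0]), np.full(npk, sig_lo)]).ravel()])
        hi = np.concatenate([[np.inf], np.column_stack(
            [amp_hi, np.full(npk, x[-1]), np.full(npk, sig_hi)]).ravel()])
        sol = optimize.least_squares(
            lambda p: self._model(p, x) - d, p0, bounds=(lo, hi),
            ftol=ftol, xtol=ftol, max_nfev=max_iter * (len(p0) + 1))
        if not sol.success:
            raise FitError("multi-Gaussian fit did not converge",
                           {"status": sol.status, "nfev": sol.nfev,
                            "cost": sol.cost})
        # parameter covariance from the Jacobian at the solution
        dof = max(len(x) - len(p0), 1)
        s2 = 2.0 * sol.cost / dof
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            perr = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0, None))
        except np.linalg.LinAlgError:
            perr = np.full(len(p0), np.nan)
        order = np.argsort(sol.x[2::3])  # centers at indices 2, 5, 8, ...
        peaks, errs = [], []
        for k in order:
            a, c, s = sol.x[1 + 3 * k: 4 + 3 * k]
            peaks.append(GaussianPeak(center=float(c), sigma=float(abs(s)),
                                      amplitude=float(a)))
            errs.append(tuple(perr[1 + 3 * k: 4 + 3 * k]))
        return MultiGaussianResult(
            model=self, peaks=tuple(peaks), baseline=float(sol.x[0]),
            baseline_stderr=float(perr[0]), peak_stderrs=tuple(errs),
            residual_norm=float(np.sqrt(2.0 * sol.cost)), nfev=sol.nfev,
            fitted=self._model(sol.x, x))


@dataclass(frozen=True)
class MultiGaussianResult:
    """Fit result: peaks sorted by center, uncertainties, diagnostics."""

    model: MultiGaussianModel
    peaks: tuple
    baseline: float
    baseline_stderr: float
    peak_stderrs: tuple
    residual_norm: float
    nfev: int
    fitted: np.ndarray

    @property
    def fwhms(self) -> np.ndarray:
        return np.array([p.fwhm for p in self.peaks])

    def summary(self) -> str:
        lines = ["Multi-peak Gaussian fit of the derivative (LSF) profile",
                 f"  peaks: {len(self.peaks)}   baseline: "
                 f"{self.baseline:.4g} +/- {self.baseline_stderr:.2g}",
                 f"  residual norm: {self.residual_norm:.4g}   "
                 f"function evals: {self.nfev}",
                 f"  {'center':>10} {'amplitude':>12} {'sigma':>9} "
                 f"{'fwhm':>9}  (um; +/- 1 SE)"]
        for p, (ea, ec, es) in zip(self.peaks, self.peak_stderrs):
            lines.append(f"  {p.center:10.3f} {p.amplitude:12.4g} "
                         f"{p.sigma:9.3f} {p.fwhm:9.3f}  "
                         f"(+/-{ec:.2g}, +/-{ea:.2g}, +/-{es:.2g})")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data, per-peak components and the full fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.profile.positions
        ax.plot(x, self.model.profile.intensities, color="0.5",
                label="derivative")
        ax.plot(x, self.fitted, color="crimson", label="multi-Gaussian fit")
        ax.set_xlabel(f"position ({self.model.profile.plane}-plane um)")
        ax.set_ylabel("dI/dx")
        ax.legend()
        return ax


def fit_multi_gaussian(deriv: LineProfile,
                       expected_peaks: int | str = "auto",
                       discrete: bool = True) -> list[GaussianPeak]:
    """Functional wrapper: fit and return the peaks sorted by center."""
    return list(MultiGaussianModel(deriv, expected_peaks=expected_peaks,
                                   discrete=discrete).fit().peaks)


# ----------------------------------------------------------------------
# resolution measurement
# ----------------------------------------------------------------------

def _aperture_corrected_fwhm(fwhm_sensor: np.ndarray, pitch: float
                             ) -> np.ndarray:
    """Remove the sensor pixel aperture (box of one pitch) in quadrature."""
    sig2 = (fwhm_sensor / FWHM_PER_SIGMA) ** 2 - pitch**2 / 12.0
    sig2 = np.clip(sig2, (0.05 * pitch) ** 2, None)
    return np.sqrt(sig2) * FWHM_PER_SIGMA


def measure_resolution(image: RasterImage, roi, magnification: float,
                       pixel_pitch: float | None = None,
                       required_points: int = 7,
                       expected_peaks: int | str = "auto",
                       width_px: int = 1,
                       aperture_correction: bool = True,
                       plane: str = "sample") -> PSFEstimate:
    """PSF FWHM from an edge cross-section through a three-bar element.

    Chains profile extraction (perpendicular to the bars, through their
    centers, padded beyond the element for baseline), differentiation and
    the multi-peak Gaussian fit; reports the mean and SD of the fitted
    FWHMs.  By default values are converted to sample-plane micrometres
    (sensor-plane FWHM divided by ``magnification``), which is the plane in
    which they compare against real feature sizes; ``plane="sensor"``
    reports sensor-plane values instead.

    Parameters
    ----------
    roi
        ``(row0, col0, row1, col1)`` box containing one full
        vertical-orientation 3-bar crossing (e.g. from the rendered element
        map).
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    pitch = image.pixel_pitch if pixel_pitch is None else pixel_pitch
    r0, c0, r1, c1 = roi
    rows, cols = image.luminance().intensities.shape
    pad = 0.3 * (c1 - c0)
    row_mid = (r0 + r1) / 2.0
    p0 = (row_mid, max(c0 - pad, 0.0))
    p1 = (row_mid, min(c1 + pad, cols - 1.0))
    profile = extract_profile(image, p0, p1, width_px=width_px)
    deriv = differentiate(profile)
    result = MultiGaussianModel(deriv, expected_peaks=expected_peaks,
                                discrete=True).fit()
    fwhm_sensor = result.fwhms
    if aperture_correction:
        fwhm_sensor = _aperture_corrected_fwhm(fwhm_sensor, pitch)
    mean_sensor = float(fwhm_sensor.mean())
    sd_sensor = float(fwhm_sensor.std(ddof=1)) if len(fwhm_sensor) > 1 else 0.0
    if plane == "sample":
        mean, sd = mean_sensor / magnification, sd_sensor / magnification
    else:
        mean, sd = mean_sensor, sd_sensor
    pts, ok = sampling_assessment(mean_sensor / magnification, magnification,
                                  pitch, required_points)
    return PSFEstimate(fwhm_mean=mean, fwhm_sd=sd,
                       n_edges=len(result.peaks), peaks=result.peaks,
                       points_per_peak=pts, adequate_sampling=ok,
                       plane=plane, fwhm_mean_sensor=mean_sensor)


def _element_modulation(image: RasterImage, box) -> tuple[float, int]:
    """Michelson modulation of a 3-bar element and its count of distinct
    bar minima."""
    r0, c0, r1, c1 = box
    row_mid = (r0 + r1) / 2.0
    profile = extract_profile(image, (row_mid, c0), (row_mid, c1))
    y = profile.intensities
    span = y.max() - y.min()
    if span <= 0:
        return 0.0, 0
    minima, _ = signal.find_peaks(-y, prominence=0.05 * span)
    if len(minima) < 3:
        return 0.0, len(minima)
    order = np.argsort(y[minima])[:3]
    mins = np.sort(minima[order])
    imin = float(y[mins].mean())
    gaps = [float(y[a:b + 1].max()) for a, b in zip(mins[:-1], mins[1:])]
    imax = float(np.mean(gaps))
    if imax + imin <= 0:
        return 0.0, 3
    return (imax - imin) / (imax + imin), 3


def smallest_resolvable_element(image: RasterImage, element_map: dict,
                                modulation_threshold: float = 0.1,
                                orientation: str = "vertical"
                                ) -> USAFElementSpec | None:
    """Finest chart element whose three bars remain distinct.

    Scans elements from coarse to fine; an element counts as resolved when
    its cross-section shows three distinct minima with Michelson modulation
    at or above ``modulation_threshold``.  Returns ``None`` when no element
    passes.
    """
    entries = [(USAFElementSpec.from_indices(g, e), box)
               for (g, e, orient), box in element_map.items()
               if orient == orientation]
    entries.sort(key=lambda t: -t[0].bar_width)  # coarse -> fine
    finest = None
    for spec, box in entries:
        modulation, n_min = _element_modulation(image, box)
        if n_min >= 3 and modulation >= modulation_threshold:
            finest = spec
    return finest


def feature_contrast(profile: LineProfile, feature_window,
                     threshold: float = 0.1) -> ContrastResult:
    """Michelson modulation ``(Imax - Imin) / (Imax + Imin)`` of the profile
    restricted to ``feature_window = (lo, hi)`` positions (um); the feature
    counts as resolved when modulation reaches ``threshold``."""
    lo, hi = feature_window
    mask = (profile.positions >= lo) & (profile.positions <= hi)
    if not mask.any():
        raise PhonescopeError("feature window contains no samples")
    y = profile.intensities[mask]
    imax, imin = float(y.max()), float(y.min())
    modulation = 0.0 if imax + imin <= 0 else (imax - imin) / (imax + imin)
    modulation = float(np.clip(modulation, 0.0, 1.0))
    return ContrastResult(modulation=modulation,
                          resolved=modulation >= threshold)
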