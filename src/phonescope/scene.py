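"""Forward imaging-model configuration.

A :class:`SceneConfig` fully determines how an ideal sample-plane target is
imaged onto the sensor: magnification, sensor pixel pitch, PSF blur, radial
distortion, vignetting and noise.  The same config (including seed) always
produces bit-identical images.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

__all__ = ["SceneConfig"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the forward imaging model.

    Parameters
    ----------
    magnification
        Sample-to-sensor scale M (dimensionless, > 0).  Smartphone-microscope
        systems built from two few-mm focal-length aspherics operate near
        unity (roughly 0.5-1.5).
    pixel_pitch
        Sensor pixel pitch in micrometres.  Default 1.2 um, typical of
        small-pixel phone sensors (e.g. the Sony IMX220's 1.2 x 1.2 um).
    psf_model
        ``"gaussian"`` (default; parameterized by ``psf_fwhm``) or ``"airy"``
        (parameterized by ``na`` and ``wavelength``).
    psf_fwhm
        Gaussian PSF full width at half maximum in sample-plane micrometres.
        0 disables blur.
    na, wavelength
        Numerical aperture and wavelength (nm) for the Airy PSF; the first
        dark ring falls at 0.61 * wavelength / na in the sample plane.
    distortion_k1
        Brown one-coefficient radial distortion, ``r' = r (1 + k1 r^2)``
        with radius normalized by half the image diagonal; positive values
        give pincushion distortion.
    vignette_strength
        Multiplicative edge falloff ``1 - strength * r^2`` with the same
        normalized radius; in [0, 1].
    read_noise_sd
        Additive Gaussian read-noise standard deviation (intensity units).
    photon_gain
        Full-scale photon count for shot noise (Poisson); 0 disables it.
    seed
        Integer seed for all randomness.
    image_size
        Sensor image size in pixels, ``(rows, cols)``.
    oversample
        Sub-pixel supersampling factor for rendering (anti-aliasing of bar
        edges and accurate sub-pixel PSF convolution).
    """

    magnification: float = 1.0
    pixel_pitch: float = 1.2
    psf_model: str = "gaussian"
    psf_fwhm: float = 3.2
    na: float = 0.4
    wavelength: float = 550.0
    distortion_k1: float = 0.0
    vignette_strength: float = 0.0
    read_noise_sd: float = 0.0
    photon_gain: float = 0.0
    seed: int = 0
    image_size: tuple[int, int] = (512, 512)
    oversample: int = 4

    def __post_init__(self):
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be non-negative")
        if self.psf_model not in ("gaussian", "airy"):
            raise ValueError("psf_model must be 'gaussian' or 'airy'")
        if not 0 <= self.vignette_strength <= 1:
            raise ValueError("vignette_strength must lie in [0, 1]")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        object.__setattr__(self, "image_size", tuple(self.image_size))

    # -- scale helpers -----------------------------------------------------
    @property
    def um_per_px(self) -> float:
        """Sample-plane micrometres spanned by one sensor pixel."""
        return self.pixel_pitch / self.magnification

    def replace(self, **kw) -> "SceneConfig":
        return replace(self, **kw)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_file(cls, path: str | Path) -> "SceneConfig":
        """Load from JSON or YAML, keyed on file extension."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
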