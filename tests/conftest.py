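import numpy as np
import pytest

import phonescope as ps

#: The five (lens, magnification, PSF FWHM um) study conditions used across
#: the round-trip suites.
LENS_SCENES = [
    ("CAY033", 1.5, 2.3),
    ("C170", 0.9, 2.9),
    ("CAY046", 1.2, 3.2),
    ("CAW110", 0.5, 4.3),
    ("Budget", 0.7, 9.2),
]

#: Read-noise SD giving SNR 50 on the 0.9 bar/background intensity range.
SNR50_NOISE = 0.9 / 50.0


def grid_scene(magnification, fwhm=3.2, seed=0, noise=SNR50_NOISE,
               size=360, **kw):
    return ps.SceneConfig(magnification=magnification, pixel_pitch=1.2,
                          psf_fwhm=fwhm, read_noise_sd=noise, seed=seed,
                          image_size=(size, size), **kw)


def render_grid_100um(scene):
    """100 um-period grid target (fine distortion-chart variant)."""
    return ps.render_grid(ps.GridTargetSpec(period=100.0, line_width=20.0),
                          scene)


def render_element_4_2(magnification, fwhm, seed=0, noise=SNR50_NOISE):
    """Chart element 4-2 (bar width 27.84 um), vertical bars only, in a
    field just large enough for the tile."""
    tile_px = int(np.ceil(222.7 * magnification / 1.2)) + 24
    scene = ps.SceneConfig(magnification=magnification, pixel_pitch=1.2,
                           psf_fwhm=fwhm, read_noise_sd=noise, seed=seed,
                           image_size=(tile_px, tile_px))
    img, emap = ps.render_usaf([4], scene, elements=[2],
                               orientations=("vertical",))
    return img, emap[(4, 2, "vertical")]


@pytest.fixture(scope="session")
def cay046_scene():
    """Noisy CAY046-like scene: M=1.2, PSF FWHM 3.2 um, SNR 50."""
    scene = grid_scene(1.2, 3.2, seed=1)
    grid = render_grid_100um(scene)
    usaf, roi = render_element_4_2(1.2, 3.2, seed=1)
    return {"scene": scene, "grid": grid, "usaf": usaf, "roi": roi}
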