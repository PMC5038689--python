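"""Raster scanning, image assembly, filtering, fusion and contrast.

A scan moves the focused beam over an (x, y) grid on the skin surface
and runs two transport simulations per pixel: one photon budget for the
confocal-reflectance image and a larger one, with importance splitting,
for the Doppler (perfusion) image.  Images are median filtered to remove
isolated Monte Carlo spikes, peak-normalised for display, and fused by
pixel-wise multiplication.  Contrast is quantified as a
signal-to-background ratio (SBR): the mean over the tumour disc divided
by the mean over the surrounding normal skin, with a one-pixel guard
ring excluded from both regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter as _nd_median

from .detection import LensModel
from .tissue import SkinModel, TumourSpec
from .transport import BeamSpec, TransportConfig, propagate_pixel

__all__ = [
    "ScanGrid",
    "ModalityImage",
    "RegionMask",
    "raster_scan",
    "median_filter",
    "normalize_peak",
    "multiply",
    "sbr",
    "default_mask",
    "diffusion_reflectance",
    "pixel_seed",
]


@dataclass(frozen=True)
class ScanGrid:
    """Raster-scan geometry: field extent (mm), pixel counts, focal depth."""

    extent_x: float = 10.0
    extent_y: float = 10.0
    nx: int = 30
    ny: int = 30
    focal_depth: float = 0.225

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid needs at least one pixel per side")
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ValueError("scan extent must be > 0")

    @property
    def pitch_x(self) -> float:
        return self.extent_x / self.nx

    @property
    def pitch_y(self) -> float:
        return self.extent_y / self.ny

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates, field centred on the origin."""
        cx = -self.extent_x / 2.0 + (np.arange(self.nx) + 0.5) * self.pitch_x
        cy = -self.extent_y / 2.0 + (np.arange(self.ny) + 0.5) * self.pitch_y
        return cx, cy


@dataclass
class ModalityImage:
    values: np.ndarray  # (ny, nx)
    modality: str  # doppler | reflectance | multiplication
    filtered: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("image values must be finite and >= 0")


@dataclass(frozen=True)
class RegionMask:
    """Disjoint tumour / background pixel index sets (boolean grids)."""

    tumour_pixels: np.ndarray
    background_pixels: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tumour_pixels, bool)
        b = np.asarray(self.background_pixels, bool)
        if t.shape != b.shape:
            raise ValueError("mask grids must have the same shape")
        if np.any(t & b):
            raise ValueError("tumour and background masks overlap")
        if not t.any() or not b.any():
            raise ValueError("both mask regions must be non-empty")


def pixel_seed(master_seed: int, ix: int, iy: int, modality: str) -> int:
    """Counter-based per-pixel substream seed (< 2^31), order-independent."""
    tag = {"doppler": 0, "reflectance": 1}[modality]
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(iy, ix, tag)
    )
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def raster_scan(
    model: SkinModel,
    beam: BeamSpec,
    grid: ScanGrid,
    config: TransportConfig,
    lens: LensModel | None = None,
    *,
    seed: int | None = None,
) -> tuple[ModalityImage, ModalityImage]:
    """Scan the beam over the grid; per pixel the Doppler value is the
    perfusion (first moment per launched photon) and the reflectance
    value the detected weight fraction."""
    beam = replace(beam, focal_depth=grid.focal_depth)
    master = int(config.rng_seed if seed is None else seed)
    # the reflectance estimator gains nothing from the Doppler-tail
    # importance sampling, so its runs use natural class probabilities
    config_refl = replace(config, class_bias=(1.0, 1.0, 1.0))
    cx, cy = grid.centers()
    dop = np.zeros((grid.ny, grid.nx))
    ref = np.zeros((grid.ny, grid.nx))
    for iy, y in enumerate(cy):
        for ix, x in enumerate(cx):
            try:
                rd = propagate_pixel(
                    model,
                    beam,
                    config,
                    lens,
                    n_photons=config.n_photons_doppler,
                    splitting=True,
                    seed=pixel_seed(master, ix, iy, "doppler"),
                    beam_xy=(x, y),
                )
                rr = propagate_pixel(
                    model,
                    beam,
                    config_refl,
                    lens,
                    n_photons=config.n_photons_reflectance,
                    splitting=False,
                    seed=pixel_seed(master, ix, iy, "reflectance"),
                    beam_xy=(x, y),
                )
            except Exception as err:
                raise RuntimeError(
                    f"transport failed at pixel (ix={ix}, iy={iy})"
                ) from err
            dop[iy, ix] = rd.perfusion_per_photon
            ref[iy, ix] = rr.reflectance
    return (
        ModalityImage(dop, "doppler"),
        ModalityImage(ref, "reflectance"),
    )


def median_filter(image: ModalityImage, kernel: int = 3) -> ModalityImage:
    """2-D median filter (odd kernel, nearest-edge replication)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be an odd integer >= 1")
    out = _nd_median(image.values, size=kernel, mode="nearest")
    return ModalityImage(out, image.modality, filtered=True, normalized=image.normalized)


def normalize_peak(image: ModalityImage) -> ModalityImage:
    """Divide by the image maximum (which becomes 1)."""
    peak = float(image.values.max())
    if peak <= 0:
        raise ValueError("cannot peak-normalise an all-zero image")
    return ModalityImage(
        image.values / peak, image.modality, filtered=image.filtered, normalized=True
    )


def multiply(a: ModalityImage, b: ModalityImage) -> ModalityImage:
    """Pixel-wise product of two modality images."""
    if a.values.shape != b.values.shape:
        raise ValueError("images must have the same shape")
    return ModalityImage(
        a.values * b.values,
        "multiplication",
        filtered=a.filtered and b.filtered,
        normalized=a.normalized and b.normalized,
    )


def sbr(image: ModalityImage, mask: RegionMask) -> float:
    """Signal-to-background ratio: mean over tumour pixels divided by
    mean over background pixels."""
    bg = image.values[np.asarray(mask.background_pixels, bool)]
    tm = image.values[np.asarray(mask.tumour_pixels, bool)]
    bg_mean = float(bg.mean())
    if bg_mean <= 0:
        raise ValueError("background mean must be > 0")
    return float(tm.mean()) / bg_mean


def default_mask(grid: ScanGrid, tumour: TumourSpec) -> RegionMask:
    """Tumour disc vs surrounding skin, one-pixel guard ring excluded.

    Tumour pixels: centres within the lateral disc.  Background pixels:
    centres beyond the disc dilated by one pixel pitch.
    """
    cx, cy = grid.centers()
    X, Y = np.meshgrid(cx, cy)
    dx = X - tumour.center_xy[0]
    dy = Y - tumour.center_xy[1]
    r2 = dx * dx + dy * dy
    guard = max(grid.pitch_x, grid.pitch_y)
    tum = r2 <= tumour.radius**2
    bg = r2 > (tumour.radius + guard) ** 2
    if not tum.any():
        raise ValueError("tumour footprint contains no pixel centres")
    if not bg.any():
        raise ValueError("tumour (plus guard ring) covers the whole grid")
    return RegionMask(tumour_pixels=tum, background_pixels=bg)


def diffusion_reflectance(
    mua: float, mus_prime: float, k1: float = 3.0, k2: float = 1.0
) -> float:
    """Diffusion-theory total reflectance of a semi-infinite medium,
    R = 1 / (k1 (1 + k2 mua/mus')).

    Monotonically increasing in mus'/mua and -> 1/k1 as mua -> 0.  k1 and
    k2 are empirical constants of the optical geometry.
    """
    if mus_prime <= 0:
        raise ValueError("reduced scattering coefficient must be > 0")
    return 1.0 / (k1 * (1.0 + k2 * mua / mus_prime))
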