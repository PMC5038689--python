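"""Photon-level Monte Carlo operations and the per-pixel transport driver.

The photon-level functions (`launch_photon`, `sample_step`, `interact`,
`sample_rbc_velocity`, `doppler_shift_for_event`, `split_photon`) define
the physics one event at a time and are what the unit and property tests
exercise.  `propagate_pixel` runs the whole launch/step/scatter/detect
loop for a pixel through the compiled kernel in `_kernel`; the scalar
deflection samplers are shared between the two paths, so both sides draw
from identical distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .detection import DetectionLedger, LensModel
from .phase_functions import gk_cos_from_u, hg_cos_from_u
from .tissue import LocalOptics, SkinModel, kernel_arrays

__all__ = [
    "Photon",
    "BeamSpec",
    "TransportConfig",
    "PixelResult",
    "launch_photon",
    "sample_step",
    "sample_rbc_velocity",
    "doppler_shift_for_event",
    "interact",
    "split_photon",
    "propagate_pixel",
    "gaussian_focal_spot_diameter",
]


@dataclass
class Photon:
    """Monte Carlo photon state (position mm, unit direction, weight,
    cumulative signed Doppler shift in Hz)."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    doppler_shift: float = 0.0
    n_scatters: int = 0
    alive: bool = True


@dataclass(frozen=True)
class BeamSpec:
    """Focused-beam geometry of the objective (Thorlabs C240TME-B-like)."""

    wavelength: float = 850.0  # nm
    focal_depth: float = 0.225  # mm below the surface
    spot_diameter_1e2: float = 4.0e-3  # mm (1/e^2 at focus)
    numerical_aperture: float = 0.5
    beam_diameter_at_lens: float = 1.96  # mm (1/e^2)
    focal_length: float = 8.0  # mm


def gaussian_focal_spot_diameter(
    wavelength_nm: float, beam_diameter_mm: float, focal_length_mm: float
) -> float:
    """Diffraction-limited 1/e^2 focal diameter 4*lambda*f/(pi*D), in mm."""
    lam_mm = wavelength_nm * 1.0e-6
    return 4.0 * lam_mm * focal_length_mm / (math.pi * beam_diameter_mm)


@dataclass(frozen=True)
class TransportConfig:
    """Per-pixel photon budgets and variance-reduction settings.

    Splitting is value-based: while a photon's prospective estimator
    contribution ``weight * |shift|`` exceeds ``split_value_threshold``
    it splits ``split_mult``-fold (weight conserved), with the cumulative
    split factor capped at ``max_split``.  ``class_bias`` importance-
    samples the RBC speed class of blood events (weight-corrected, so the
    estimators stay unbiased); ``importance_depth``/``importance_survival``
    roulette photons that dive below the given plane.
    """

    n_photons_reflectance: int = 320_000
    n_photons_doppler: int = 1_600_000
    max_split: int = 3200  # cap on the cumulative split factor per photon
    split_value_threshold: float = 300.0  # weight * Hz per photon
    split_mult: int = 4
    class_bias: tuple[float, float, float] = (1.0, 1.0, 100.0)
    roulette_threshold: float = 1.0e-4
    roulette_survival: float = 0.1
    importance_depth: float = 1.575  # mm; roulette below this plane
    importance_survival: float = 0.25
    escape_radius: float = 15.0  # mm, lateral truncation
    rng_seed: int = 0
    ledger_capacity: int = 1_000_000


@dataclass
class PixelResult:
    """Ledger plus exact energy bookkeeping for one pixel run."""

    ledger: DetectionLedger
    detected_weight: float
    detected_first_moment: float  # sum w |shift|, Hz
    absorbed: float
    escaped: float
    roulette_killed: float
    roulette_gained: float
    importance_reweight_net: float
    top_exit_weight: float

    @property
    def reflectance(self) -> float:
        return self.detected_weight / self.ledger.launched

    @property
    def perfusion_per_photon(self) -> float:
        return self.detected_first_moment / self.ledger.launched

    @property
    def total_reflectance(self) -> float:
        """All upward-exiting weight per launched photon (no confocal gate)."""
        return self.top_exit_weight / self.ledger.launched

    def energy_balance_error(self) -> float:
        lhs = (
            self.ledger.launched
            + self.roulette_gained
            + self.importance_reweight_net
        )
        rhs = (
            self.detected_weight
            + self.absorbed
            + self.escaped
            + self.roulette_killed
        )
        return abs(lhs - rhs) / self.ledger.launched


def launch_photon(beam: BeamSpec, rng: np.random.Generator) -> Photon:
    """Sample one photon of the hyperboloid (focused Gaussian) beam.

    A waist point is drawn from a Gaussian whose 1/e^2 diameter is the
    focal spot, a lens-plane point from the beam profile at the lens, and
    the ray runs from the lens point through the waist point; the photon
    starts where that ray crosses the surface.
    """
    if beam.numerical_aperture >= 1.0:
        raise ValueError("numerical aperture must be < 1")
    waist_sigma = beam.spot_diameter_1e2 / 4.0
    lens_sigma = beam.beam_diameter_at_lens / 4.0
    lens_h = beam.focal_length - beam.focal_depth
    lx, ly = rng.normal(0.0, lens_sigma, size=2)
    wx, wy = rng.normal(0.0, waist_sigma, size=2)
    v = np.array([wx - lx, wy - ly, beam.focal_depth + lens_h])
    v /= np.linalg.norm(v)
    t0 = lens_h / v[2]
    pos = np.array([lx + v[0] * t0, ly + v[1] * t0, 0.0])
    return Photon(position=pos, direction=v)


def sample_step(mut: float, rng: np.random.Generator) -> float:
    """Exponential free path s = -ln(u)/mu_t, u in (0, 1]."""
    if mut <= 0:
        raise ValueError("mu_t must be > 0")
    u = 1.0 - rng.random()  # (0, 1]
    return -math.log(u) / mut


def sample_rbc_velocity(mean_speed: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic direction; speed uniform on (0, 2 * mean_speed), mm/s."""
    if mean_speed < 0:
        raise ValueError("mean speed must be >= 0")
    cz = 2.0 * rng.random() - 1.0
    sz = math.sqrt(max(0.0, 1.0 - cz * cz))
    phi = 2.0 * math.pi * rng.random()
    speed = 2.0 * mean_speed * rng.random()
    return speed * np.array([sz * math.cos(phi), sz * math.sin(phi), cz])


def doppler_shift_for_event(
    incident_dir: np.ndarray,
    scattered_dir: np.ndarray,
    velocity: np.ndarray,
    n: float = 1.4,
    wavelength: float = 850.0,
) -> float:
    """Doppler shift (1/2pi)(k_s - k_i) . v in Hz, |k| = 2 pi n / lambda.

    Directions are unit vectors; velocity in mm/s; wavelength in nm.
    """
    lam_mm = wavelength * 1.0e-6
    diff = np.asarray(scattered_dir, float) - np.asarray(incident_dir, float)
    return float(n / lam_mm * diff @ np.asarray(velocity, float))


def _rotate(direction: np.ndarray, mu: float, phi: float) -> np.ndarray:
    dx, dy, dz = direction
    ndx, ndy, ndz = _kernel._scatter_dir(dx, dy, dz, mu, phi)
    return np.array([ndx, ndy, ndz])


def interact(
    photon: Photon, optics: LocalOptics, rng: np.random.Generator
) -> Photon:
    """One scattering interaction: albedo weighting, scatterer-class draw,
    HG or Gegenbauer deflection, Doppler accumulation on blood events."""
    if not photon.alive:
        raise ValueError("photon is dead")
    mus_parts = (optics.mus_static,) + optics.mus_blood_by_class
    mus_tot = sum(mus_parts)
    if mus_tot <= 0:
        raise ValueError("no scatterers at this point (all partial mus zero)")
    mut = mus_tot + optics.mua_total
    photon.weight *= mus_tot / mut
    r = rng.random() * mus_tot
    phi = 2.0 * math.pi * rng.random()
    old_dir = photon.direction.copy()
    if r < optics.mus_static:
        mu = hg_cos_from_u(rng.random(), optics.hg_g)
        photon.direction = _rotate(old_dir, mu, phi)
    else:
        r -= optics.mus_static
        cls = 0
        acc = optics.mus_blood_by_class[0]
        while r >= acc and cls < 2:
            cls += 1
            acc += optics.mus_blood_by_class[cls]
        mu = gk_cos_from_u(rng.random(), optics.gk_alpha, optics.gk_g)
        photon.direction = _rotate(old_dir, mu, phi)
        vel = sample_rbc_velocity(optics.mean_speed_by_class[cls], rng)
        photon.doppler_shift += doppler_shift_for_event(
            old_dir, photon.direction, vel
        )
    photon.n_scatters += 1
    return photon


def split_photon(photon: Photon, config: TransportConfig) -> list[Photon]:
    """Importance splitting of large-shift photons.

    While the photon's prospective estimator contribution
    ``weight * |doppler_shift|`` exceeds the configurable window, it is
    split ``split_mult``-fold (geometrically), so one photon can become
    up to ``max_split`` copies; total weight is conserved exactly.
    """
    n = 1
    while (
        (photon.weight / n) * abs(photon.doppler_shift)
        > config.split_value_threshold
        and n * config.split_mult <= config.max_split
    ):
        n *= config.split_mult
    if n <= 1:
        return [photon]
    out = []
    for _ in range(n):
        c = Photon(
            position=photon.position.copy(),
            direction=photon.direction.copy(),
            weight=photon.weight / n,
            doppler_shift=photon.doppler_shift,
            n_scatters=photon.n_scatters,
            alive=photon.alive,
        )
        out.append(c)
    return out


def propagate_pixel(
    model: SkinModel,
    beam: BeamSpec,
    config: TransportConfig,
    lens: LensModel | None = None,
    *,
    n_photons: int | None = None,
    splitting: bool = True,
    seed: int | None = None,
    beam_xy: tuple[float, float] = (0.0, 0.0),
) -> PixelResult:
    """Simulate all photons of one scan pixel and collect the ledger.

    ``beam_xy`` is the scan position on the skin; internally the beam
    stays on the pixel axis and the tumour is shifted by the opposite
    amount, which is equivalent.
    """
    if beam.numerical_aperture >= 1.0:
        raise ValueError("numerical aperture must be < 1")
    if beam.focal_depth <= 0 or beam.focal_depth >= model.total_depth:
        raise ValueError("focal depth must lie inside the medium")
    lens = lens or LensModel()
    n = int(n_photons if n_photons is not None else config.n_photons_doppler)
    the_seed = int(config.rng_seed if seed is None else seed) & 0x7FFFFFFF

    ka = kernel_arrays(model)
    cap = min(config.ledger_capacity, max(n, 1024))
    out_w = np.empty(cap)
    out_f = np.empty(cap)
    res = _kernel.run_pixel_kernel(
        the_seed,
        n,
        ka["layer_bot"],
        ka["mua_h"],
        ka["mus_static_h"],
        ka["musb_h"],
        ka["speeds_h"],
        ka["mua_t"],
        ka["mus_static_t"],
        ka["musb_t"],
        ka["speeds_t"],
        ka["has_tumour"],
        ka["tum_x"] - beam_xy[0],
        ka["tum_y"] - beam_xy[1],
        ka["tum_r"],
        ka["tum_z0"],
        ka["tum_z1"],
        ka["hg_g"],
        ka["gk_alpha"],
        ka["gk_g"],
        ka["n_ref"],
        ka["wavelength_nm"],
        beam.focal_depth,
        beam.spot_diameter_1e2 / 4.0,
        beam.beam_diameter_at_lens / 4.0,
        beam.focal_length - beam.focal_depth,
        beam.numerical_aperture,
        lens.clear_aperture_diameter / 2.0,
        lens.aperture_radius_mm / lens.magnification,
        splitting,
        config.split_value_threshold,
        config.split_mult,
        config.max_split,
        np.asarray(config.class_bias, dtype=np.float64),
        config.roulette_threshold,
        config.roulette_survival,
        config.importance_depth,
        config.importance_survival,
        config.escape_radius,
        out_w,
        out_f,
    )
    (
        n_out,
        detected_w,
        detected_moment,
        absorbed,
        escaped,
        rl_kill,
        rl_gain,
        bias_net,
        top_exit_w,
    ) = res
    if not np.isfinite(detected_w) or not np.isfinite(detected_moment):
        raise RuntimeError("non-finite transport state in pixel run")
    ledger = DetectionLedger(
        launched=n, weights=out_w[:n_out].copy(), shifts=out_f[:n_out].copy()
    )
    return PixelResult(
        ledger=ledger,
        detected_weight=detected_w,
        detected_first_moment=detected_moment,
        absorbed=absorbed,
        escaped=escaped,
        roulette_killed=rl_kill,
        roulette_gained=rl_gain,
        importance_reweight_net=bias_net,
        top_exit_weight=top_exit_w,
    )
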