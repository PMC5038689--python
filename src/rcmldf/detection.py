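"""Confocal detection: the lens/pinhole gate and the detection ledger.

A photon exiting the surface is detected when its ray (i) lies within
the numerical-aperture cone of the objective, (ii) passes inside the
clear aperture at the lens plane, and (iii), traced back into the
tissue, appears to originate within the aperture-conjugate disc around
the focal point.  With ideal thin-lens (paraxial) imaging of the focal
plane onto the pinhole plane, condition (iii) is equivalent to the
imaged ray hitting the physical pinhole of radius ``aperture_radius``
(the laser aperture acting as the confocal pinhole), divided by the
system magnification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel

__all__ = ["LensModel", "DetectionLedger", "accept", "detected_reflectance"]


@dataclass(frozen=True)
class LensModel:
    """Objective lens geometry and confocal pinhole.

    ``aperture_radius_um`` defaults to the enlarged 45 um gate (a
    speed-up approximation); the physical few-um laser aperture can be
    set instead.  ``magnification`` maps focal-plane offsets to the
    pinhole plane.
    """

    focal_length: float = 8.0  # mm
    clear_aperture_diameter: float = 8.0  # mm
    numerical_aperture: float = 0.5
    mode: str = "ideal-thin-lens"
    aperture_radius_um: float = 45.0
    magnification: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("ideal-thin-lens",):
            raise ValueError(f"unsupported lens mode {self.mode!r}")
        if self.aperture_radius_um <= 0 or self.magnification <= 0:
            raise ValueError("aperture radius and magnification must be > 0")

    @property
    def aperture_radius_mm(self) -> float:
        return self.aperture_radius_um * 1.0e-3


@dataclass
class DetectionLedger:
    """Per-pixel record of accepted photons: weights and Doppler shifts."""

    launched: int
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    shifts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.weights.shape != self.shifts.shape:
            raise ValueError("weights and shifts must have the same length")
        if np.any(self.weights <= 0):
            raise ValueError("ledger weights must be > 0")
        if self.launched <= 0:
            raise ValueError("launched count must be > 0")


def accept(
    exit_position,
    exit_direction,
    lens: LensModel,
    aperture_radius_um: float | None = None,
    *,
    focal_depth: float = 0.225,
) -> bool:
    """Deterministic confocal gate for one exiting ray.

    ``exit_position`` is (x, y) in mm at the surface; ``exit_direction``
    a unit vector in surface coordinates (z positive downward), so an
    upward-travelling photon has direction[2] < 0.
    """
    x, y = exit_position
    dx, dy, dz = np.asarray(exit_direction, dtype=float)
    if dz >= 0:
        raise ValueError("exit direction must have an upward component")
    ap_um = lens.aperture_radius_um if aperture_radius_um is None else aperture_radius_um
    ap_eff = ap_um * 1.0e-3 / lens.magnification
    lens_h = lens.focal_length - focal_depth
    clear_r = lens.clear_aperture_diameter / 2.0
    return bool(
        _kernel._accept_ray(
            x,
            y,
            dx,
            dy,
            dz,
            lens.numerical_aperture,
            lens_h,
            clear_r * clear_r,
            focal_depth,
            ap_eff * ap_eff,
        )
    )


def detected_reflectance(ledger: DetectionLedger) -> float:
    """Confocal reflectance: sum of accepted weights per launched photon."""
    if ledger.launched <= 0:
        raise ValueError("launched count must be > 0")
    if ledger.weights.size == 0:
        return 0.0
    return float(ledger.weights.sum() / ledger.launched)
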