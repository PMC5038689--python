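"""Single-scattering phase functions for skin tissue and red blood cells.

Static (non-blood) scatterers deflect photons according to the
Henyey-Greenstein (HG) phase function; red blood cells are sharply
forward-peaked and are modelled with the two-parameter Gegenbauer-kernel
(GK) phase function,

    p_GK(cos th) ~ (1 + g^2 - 2 g cos th)^-(alpha + 1).

Both admit closed-form inverse-CDF sampling (for the GK this holds for any
alpha > 0), which is what the Monte Carlo kernel uses.  The module also
provides the normalised densities in cos(theta) and a quadrature routine
for the anisotropy factor (mean deflection cosine), used as an independent
check on the samplers.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.integrate import quad

__all__ = [
    "hg_cos_from_u",
    "gk_cos_from_u",
    "sample_hg",
    "sample_gk",
    "hg_pdf",
    "gk_pdf",
    "anisotropy_by_quadrature",
]


@njit(cache=True)
def hg_cos_from_u(u: float, g: float) -> float:
    """Map a uniform deviate u in [0, 1) to an HG deflection cosine."""
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    mu = (1.0 + g * g - t * t) / (2.0 * g)
    if mu > 1.0:
        mu = 1.0
    elif mu < -1.0:
        mu = -1.0
    return mu


@njit(cache=True)
def gk_cos_from_u(u: float, alpha: float, g: float) -> float:
    """Map a uniform deviate to a Gegenbauer-kernel deflection cosine.

    Inverse CDF: with t = 1 + g^2 - 2 g mu, the CDF is linear in
    t^-alpha, so t^-alpha is uniform between (1+g)^-2alpha and
    (1-g)^-2alpha.
    """
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t_lo = (1.0 + g) ** (-2.0 * alpha)
    t_hi = (1.0 - g) ** (-2.0 * alpha)
    t = (t_lo + u * (t_hi - t_lo)) ** (-1.0 / alpha)
    mu = (1.0 + g * g - t) / (2.0 * g)
    if mu > 1.0:
        mu = 1.0
    elif mu < -1.0:
        mu = -1.0
    return mu


def sample_hg(g: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised HG deflection-cosine sampler (testing / analysis)."""
    u = rng.random(size)
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - t * t) / (2.0 * g), -1.0, 1.0)


def sample_gk(alpha: float, g: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised Gegenbauer-kernel deflection-cosine sampler."""
    u = rng.random(size)
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t_lo = (1.0 + g) ** (-2.0 * alpha)
    t_hi = (1.0 - g) ** (-2.0 * alpha)
    t = (t_lo + u * (t_hi - t_lo)) ** (-1.0 / alpha)
    return np.clip((1.0 + g * g - t) / (2.0 * g), -1.0, 1.0)


def hg_pdf(mu, g: float):
    """HG density in mu = cos(theta), normalised over [-1, 1]."""
    mu = np.asarray(mu, dtype=float)
    return 0.5 * (1.0 - g * g) / (1.0 + g * g - 2.0 * g * mu) ** 1.5


def gk_pdf(mu, alpha: float, g: float):
    """Gegenbauer-kernel density in mu = cos(theta), normalised over [-1, 1]."""
    mu = np.asarray(mu, dtype=float)
    if abs(g) < 1e-8:
        return np.full_like(mu, 0.5)
    # normalisation: integral of (1+g^2-2g mu)^-(a+1) dmu
    norm = ((1.0 - g) ** (-2.0 * alpha) - (1.0 + g) ** (-2.0 * alpha)) / (
        2.0 * g * alpha
    )
    return (1.0 + g * g - 2.0 * g * mu) ** (-(alpha + 1.0)) / norm


def anisotropy_by_quadrature(pdf, *args) -> float:
    """Mean deflection cosine <cos theta> of a density in mu over [-1, 1].

    ``pdf(mu, *args)`` need not be normalised; the moment is taken as a
    ratio of quadratures.
    """
    norm, _ = quad(lambda m: float(pdf(m, *args)), -1.0, 1.0, limit=200)
    num, _ = quad(lambda m: m * float(pdf(m, *args)), -1.0, 1.0, limit=200)
    return num / norm
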