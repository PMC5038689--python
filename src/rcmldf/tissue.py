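"""Layered optical skin model with blood, melanin and embedded tumours.

The medium is a stack of plane-parallel layers (z = 0 at the surface,
positive downward, lengths in mm).  Each layer carries a bloodless,
melanin-less baseline absorption and scattering coefficient plus volume
fractions of melanin and of three red-blood-cell (RBC) speed classes
(capillaries 0.3 mm/s, venules/arterioles 3.0 mm/s, larger vessels
30 mm/s).  In-vivo coefficients are composed by volume-fraction mixing:

    mu_in_vivo = V_blood * mu_blood + V_mel * mu_mel + (1 - V_blood - V_mel) * mu_base

Keratinocyte-skin-cancer-like tumours are thin cylinders that raise the
RBC concentration and speeds and scale the bloodless baseline
coefficients down before composition.  All refractive indices are equal
(1.4) so there are no internal Fresnel events, and the top surface is
index matched (anti-reflection plate), so photons cross it freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "ChromophoreConstants",
    "TumourSpec",
    "LocalOptics",
    "SkinModel",
    "default_skin_model",
    "compose_local_optics",
    "apply_tumour",
    "optics_at",
    "ksc1_tumour",
    "ksc2_tumour",
    "HG_G_DEFAULT",
    "GK_ALPHA_DEFAULT",
    "GK_G_DEFAULT",
    "BLOOD_SPEED_CLASSES",
]

# Anisotropy of static scatterers and Gegenbauer parameters of RBCs.
HG_G_DEFAULT = 0.85
GK_ALPHA_DEFAULT = 1.0
GK_G_DEFAULT = 0.948

# Mean speeds of the three blood velocity classes, mm/s.
BLOOD_SPEED_CLASSES = (0.3, 3.0, 30.0)


@dataclass(frozen=True)
class LayerSpec:
    """One plane-parallel skin layer.

    Blood fractions are volume fractions of the three RBC speed classes;
    ``mus_base`` / ``mua_base`` are the bloodless, melanin-less scattering
    and absorption coefficients in 1/mm.
    """

    name: str
    thickness: float
    blood_fraction_slow: float
    blood_fraction_mid: float
    blood_fraction_fast: float
    melanin_fraction: float
    mus_base: float
    mua_base: float
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        fracs = (
            self.blood_fraction_slow,
            self.blood_fraction_mid,
            self.blood_fraction_fast,
            self.melanin_fraction,
        )
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"layer {self.name!r}: fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError(f"layer {self.name!r}: fractions sum to more than 1")
        if self.mus_base < 0 or self.mua_base < 0:
            raise ValueError(f"layer {self.name!r}: coefficients must be >= 0")

    @property
    def blood_fraction_total(self) -> float:
        return (
            self.blood_fraction_slow
            + self.blood_fraction_mid
            + self.blood_fraction_fast
        )


@dataclass(frozen=True)
class ChromophoreConstants:
    """Optical properties of whole blood and melanin at the working wavelength."""

    mua_blood: float = 0.5  # 1/mm
    mus_blood: float = 222.0  # 1/mm
    mua_melanin: float = 15.0  # 1/mm
    mus_melanin: float = 0.0  # 1/mm (melanin does not scatter)
    wavelength: float = 850.0  # nm


@dataclass(frozen=True)
class TumourSpec:
    """Cylindrical tumour region.

    Inside the cylinder the blood fractions are multiplied by
    ``conc_multiplier``, the class mean speeds by ``velocity_multiplier``,
    and the bloodless baseline coefficients by ``mua_scale`` /
    ``mus_scale`` before in-vivo composition.
    """

    center_xy: tuple[float, float] = (0.0, 0.0)
    diameter: float = 5.0
    z_top: float = 0.075
    z_bottom: float = 0.375
    conc_multiplier: float = 1.0
    velocity_multiplier: float = 1.0
    mus_scale: float = 1.0
    mua_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.z_top < self.z_bottom:
            raise ValueError("tumour: z_top must be above z_bottom")
        if not self.diameter > 0:
            raise ValueError("tumour: diameter must be > 0")
        for m in (
            self.conc_multiplier,
            self.velocity_multiplier,
            self.mus_scale,
            self.mua_scale,
        ):
            if not m > 0:
                raise ValueError("tumour: multipliers must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def contains(self, x: float, y: float, z: float) -> bool:
        if not (self.z_top <= z < self.z_bottom):
            return False
        dx = x - self.center_xy[0]
        dy = y - self.center_xy[1]
        return dx * dx + dy * dy <= self.radius**2


def ksc1_tumour(**overrides) -> TumourSpec:
    """Mild keratinocyte-skin-cancer preset: RBC concentration x2, speeds x1.5,
    bloodless coefficients x0.6."""
    kw = dict(
        conc_multiplier=2.0, velocity_multiplier=1.5, mus_scale=0.6, mua_scale=0.6
    )
    kw.update(overrides)
    return TumourSpec(**kw)


def ksc2_tumour(**overrides) -> TumourSpec:
    """Severe keratinocyte-skin-cancer preset: RBC concentration x3, speeds x1.5,
    bloodless coefficients x0.6."""
    kw = dict(
        conc_multiplier=3.0, velocity_multiplier=1.5, mus_scale=0.6, mua_scale=0.6
    )
    kw.update(overrides)
    return TumourSpec(**kw)


@dataclass(frozen=True)
class LocalOptics:
    """In-vivo optical properties at a point.

    ``mus_blood_by_class`` are the partial scattering coefficients of the
    three RBC speed classes; ``mus_static`` is the non-blood remainder.
    """

    mua_total: float
    mus_total: float
    mus_static: float
    mus_blood_by_class: tuple[float, float, float]
    mean_speed_by_class: tuple[float, float, float]
    hg_g: float = HG_G_DEFAULT
    gk_alpha: float = GK_ALPHA_DEFAULT
    gk_g: float = GK_G_DEFAULT


@dataclass(frozen=True)
class SkinModel:
    """Ordered layer stack plus chromophore constants and optional tumour."""

    layers: tuple[LayerSpec, ...]
    constants: ChromophoreConstants = field(default_factory=ChromophoreConstants)
    tumour: TumourSpec | None = None
    hg_g: float = HG_G_DEFAULT
    gk_alpha: float = GK_ALPHA_DEFAULT
    gk_g: float = GK_G_DEFAULT

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("skin model needs at least one layer")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative layer bottom depths, mm (strictly increasing)."""
        return np.cumsum([la.thickness for la in self.layers])

    @property
    def total_depth(self) -> float:
        return float(self.boundaries[-1])

    def layer_index_at(self, z: float) -> int:
        """Half-open convention: depth z belongs to the layer whose
        [top, bottom) interval contains it."""
        if z < 0 or z > self.total_depth:
            raise ValueError(f"depth z={z} outside medium [0, {self.total_depth}]")
        bounds = self.boundaries
        for i, b in enumerate(bounds):
            if z < b:
                return i
        return len(self.layers) - 1  # z == total depth -> last layer


def default_skin_model() -> SkinModel:
    """The six-layer healthy skin model (blood fractions per speed class,
    melanin, bloodless baseline coefficients, thicknesses; all indices 1.4)."""
    layers = (
        LayerSpec("epidermis", 0.075, 0.0, 0.0, 0.0, 0.020, 23.0, 0.1),
        LayerSpec("papillary dermis", 0.15, 0.002, 0.0, 0.0, 0.0, 13.0, 0.1),
        LayerSpec("superior blood net", 0.15, 0.006, 0.0005, 0.00001, 0.0, 13.0, 0.1),
        LayerSpec("reticular dermis", 0.8, 0.001, 0.0001, 0.000006, 0.0, 13.0, 0.1),
        LayerSpec("inferior blood net", 0.4, 0.0025, 0.00035, 0.00006, 0.0, 13.0, 0.1),
        LayerSpec("subcutis", 2.0, 0.001, 0.0001, 0.00001, 0.0, 13.0, 0.1),
    )
    return SkinModel(layers=layers)


def compose_local_optics(
    layer: LayerSpec,
    constants: ChromophoreConstants,
    *,
    speed_multiplier: float = 1.0,
    hg_g: float = HG_G_DEFAULT,
    gk_alpha: float = GK_ALPHA_DEFAULT,
    gk_g: float = GK_G_DEFAULT,
) -> LocalOptics:
    """Volume-fraction mixing of blood, melanin and baseline tissue."""
    vb = layer.blood_fraction_total
    vm = layer.melanin_fraction
    rest = 1.0 - vb - vm
    mua = vb * constants.mua_blood + vm * constants.mua_melanin + rest * layer.mua_base
    mus_static = rest * layer.mus_base + vm * constants.mus_melanin
    musb = (
        layer.blood_fraction_slow * constants.mus_blood,
        layer.blood_fraction_mid * constants.mus_blood,
        layer.blood_fraction_fast * constants.mus_blood,
    )
    mus_total = mus_static + sum(musb)
    if mua < 0 or mus_total < 0:
        raise ValueError("composed optical coefficients must be non-negative")
    speeds = tuple(s * speed_multiplier for s in BLOOD_SPEED_CLASSES)
    return LocalOptics(
        mua_total=mua,
        mus_total=mus_total,
        mus_static=mus_static,
        mus_blood_by_class=musb,
        mean_speed_by_class=speeds,
        hg_g=hg_g,
        gk_alpha=gk_alpha,
        gk_g=gk_g,
    )


def tumour_modified_layer(layer: LayerSpec, tumour: TumourSpec) -> LayerSpec:
    """Layer properties inside the tumour cylinder: baseline coefficients
    scaled first, then blood fractions multiplied (speeds handled by the
    caller via ``speed_multiplier``)."""
    fracs = {
        "blood_fraction_slow": layer.blood_fraction_slow * tumour.conc_multiplier,
        "blood_fraction_mid": layer.blood_fraction_mid * tumour.conc_multiplier,
        "blood_fraction_fast": layer.blood_fraction_fast * tumour.conc_multiplier,
    }
    total = sum(fracs.values()) + layer.melanin_fraction
    if total > 1.0:
        raise ValueError(
            f"layer {layer.name!r}: tumour-scaled fractions exceed 1 ({total:.3f})"
        )
    return replace(
        layer,
        mus_base=layer.mus_base * tumour.mus_scale,
        mua_base=layer.mua_base * tumour.mua_scale,
        **fracs,
    )


def apply_tumour(model: SkinModel, tumour: TumourSpec) -> SkinModel:
    """Return a model with the tumour cylinder embedded.

    Validates the z-range and that the scaled blood fractions of every
    intersected layer stay physical.
    """
    if tumour.z_top < 0 or tumour.z_bottom > model.total_depth:
        raise ValueError("tumour z-range must lie within the medium")
    bounds = model.boundaries
    tops = np.concatenate([[0.0], bounds[:-1]])
    for layer, top, bot in zip(model.layers, tops, bounds):
        if top < tumour.z_bottom and bot > tumour.z_top:
            tumour_modified_layer(layer, tumour)  # raises if unphysical
    return replace(model, tumour=tumour)


def optics_at(model: SkinModel, position: Sequence[float]) -> LocalOptics:
    """Point query: LocalOptics of the containing layer, tumour-modified
    when the point lies inside the cylinder."""
    x, y, z = position
    idx = model.layer_index_at(z)
    layer = model.layers[idx]
    speed_mult = 1.0
    if model.tumour is not None and model.tumour.contains(x, y, z):
        layer = tumour_modified_layer(layer, model.tumour)
        speed_mult = model.tumour.velocity_multiplier
    return compose_local_optics(
        layer,
        model.constants,
        speed_multiplier=speed_mult,
        hg_g=model.hg_g,
        gk_alpha=model.gk_alpha,
        gk_g=model.gk_g,
    )


def kernel_arrays(model: SkinModel) -> dict[str, np.ndarray | float]:
    """Flatten a SkinModel into the arrays the Monte Carlo kernel consumes.

    Healthy and tumour-modified per-layer coefficient tables are both
    produced; the kernel switches on cylinder membership at run time.
    """
    n = len(model.layers)
    bot = model.boundaries.astype(np.float64)
    mua_h = np.empty(n)
    mus_static_h = np.empty(n)
    musb_h = np.empty((n, 3))
    speeds_h = np.empty((n, 3))
    mua_t = np.empty(n)
    mus_static_t = np.empty(n)
    musb_t = np.empty((n, 3))
    speeds_t = np.empty((n, 3))
    for i, layer in enumerate(model.layers):
        o = compose_local_optics(layer, model.constants)
        mua_h[i] = o.mua_total
        mus_static_h[i] = o.mus_static
        musb_h[i] = o.mus_blood_by_class
        speeds_h[i] = o.mean_speed_by_class
        if model.tumour is not None:
            tl = tumour_modified_layer(layer, model.tumour)
            ot = compose_local_optics(
                tl, model.constants, speed_multiplier=model.tumour.velocity_multiplier
            )
            mua_t[i] = ot.mua_total
            mus_static_t[i] = ot.mus_static
            musb_t[i] = ot.mus_blood_by_class
            speeds_t[i] = ot.mean_speed_by_class
        else:
            mua_t[i] = mua_h[i]
            mus_static_t[i] = mus_static_h[i]
            musb_t[i] = musb_h[i]
            speeds_t[i] = speeds_h[i]
    tum = model.tumour
    return dict(
        layer_bot=bot,
        mua_h=mua_h,
        mus_static_h=mus_static_h,
        musb_h=musb_h,
        speeds_h=speeds_h,
        mua_t=mua_t,
        mus_static_t=mus_static_t,
        musb_t=musb_t,
        speeds_t=speeds_t,
        has_tumour=tum is not None,
        tum_x=0.0 if tum is None else tum.center_xy[0],
        tum_y=0.0 if tum is None else tum.center_xy[1],
        tum_r=0.0 if tum is None else tum.radius,
        tum_z0=0.0 if tum is None else tum.z_top,
        tum_z1=0.0 if tum is None else tum.z_bottom,
        hg_g=model.hg_g,
        gk_alpha=model.gk_alpha,
        gk_g=model.gk_g,
        n_ref=model.layers[0].refractive_index,
        wavelength_nm=model.constants.wavelength,
    )
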