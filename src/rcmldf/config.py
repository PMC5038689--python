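"""Run configuration, presets, and the top-level scan entry point.

A run is described by a YAML file (every key optional; missing keys fall
back to the healthy six-layer defaults).  ``run_scan`` executes the full
pipeline — raster scan, median filtering, SBR, peak normalisation,
multiplicative fusion — and writes images (TIFF + CSV), an SBR report
and a reproducibility manifest.
"""

from __future__ import annotations

import csv
import json
import platform
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .detection import LensModel
from .imaging import (
    ModalityImage,
    RegionMask,
    ScanGrid,
    default_mask,
    median_filter,
    multiply,
    normalize_peak,
    raster_scan,
    sbr,
)
from .tissue import (
    ChromophoreConstants,
    LayerSpec,
    SkinModel,
    TumourSpec,
    apply_tumour,
    default_skin_model,
    ksc1_tumour,
    ksc2_tumour,
)
from .transport import BeamSpec, TransportConfig

__all__ = ["RunConfig", "RunManifest", "ScanResult", "load_config", "run_scan",
           "model_for_preset"]

TUMOUR_PRESETS = {"healthy": None, "ksc1": ksc1_tumour, "ksc2": ksc2_tumour}


@dataclass(frozen=True)
class RunConfig:
    model: SkinModel
    beam: BeamSpec
    lens: LensModel
    grid: ScanGrid
    transport: TransportConfig
    preset: str = "healthy"
    seed: int = 0


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    preset: str
    seed: int
    n_photons_doppler: int
    n_photons_reflectance: int
    grid: dict
    beam: dict
    lens: dict
    transport: dict
    code_version: str
    wall_time_s: float
    output_paths: dict
    platform: str = field(default_factory=platform.platform)

    def write(self, path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


@dataclass
class ScanResult:
    doppler: ModalityImage
    reflectance: ModalityImage
    multiplication: ModalityImage
    mask: RegionMask | None
    sbr_doppler: float | None
    sbr_reflectance: float | None
    sbr_multiplication: float | None


def model_for_preset(preset: str, **tumour_overrides) -> SkinModel:
    """Healthy six-layer model, or with the KSC1/KSC2 tumour embedded."""
    if preset not in TUMOUR_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of "
                         f"{sorted(TUMOUR_PRESETS)}")
    model = default_skin_model()
    maker = TUMOUR_PRESETS[preset]
    if maker is not None:
        model = apply_tumour(model, maker(**tumour_overrides))
    return model


def _build_layer(defaults: LayerSpec, raw: dict) -> LayerSpec:
    known = {
        "name", "thickness", "blood_fraction_slow", "blood_fraction_mid",
        "blood_fraction_fast", "melanin_fraction", "mus_base", "mua_base",
        "refractive_index",
    }
    bad = set(raw) - known
    if bad:
        raise ValueError(f"layer {raw.get('name', defaults.name)!r}: "
                         f"unknown keys {sorted(bad)}")
    try:
        return replace(defaults, **raw)
    except ValueError as err:
        raise ValueError(str(err)) from None


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields the full defaults (healthy Table-style model,
    standard beam/lens/scan).  Invalid values raise ValueError naming the
    offending key or layer.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")

    base = default_skin_model()
    layers = base.layers
    if "layers" in raw:
        entries = raw["layers"]
        if len(entries) != len(base.layers):
            raise ValueError(
                f"'layers' must list {len(base.layers)} layers, got {len(entries)}"
            )
        layers = tuple(
            _build_layer(d, e or {}) for d, e in zip(base.layers, entries)
        )
    constants = ChromophoreConstants(**raw.get("chromophores", {}))
    model = SkinModel(layers=layers, constants=constants)

    preset = str(raw.get("preset", "healthy")).lower()
    if preset not in TUMOUR_PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    tum_raw = raw.get("tumour", {})
    if preset != "healthy":
        maker = TUMOUR_PRESETS[preset]
        model = apply_tumour(model, maker(**tum_raw))
    elif tum_raw:
        model = apply_tumour(model, TumourSpec(**tum_raw))
        preset = "custom"

    beam = BeamSpec(**raw.get("beam", {}))
    lens = LensModel(**raw.get("lens", {}))
    grid = ScanGrid(**raw.get("scan", {}))
    transport = TransportConfig(**raw.get("transport", {}))
    seed = int(raw.get("seed", 0))
    return RunConfig(
        model=model, beam=beam, lens=lens, grid=grid,
        transport=transport, preset=preset, seed=seed,
    )


def _write_csv_grid(values: np.ndarray, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(
            [[f"{v:.8g}" for v in row] for row in values]
        )


def _export_image(img: ModalityImage, stem: Path) -> list[str]:
    import tifffile

    tif = stem.with_suffix(".tiff")
    tifffile.imwrite(tif, img.values.astype(np.float32))
    csv_path = stem.with_suffix(".csv")
    _write_csv_grid(img.values, csv_path)
    return [str(tif), str(csv_path)]


def run_scan(config: RunConfig, out_dir=None) -> tuple[ScanResult, RunManifest]:
    """Execute the full pipeline for one scene.

    SBR is computed on the median-filtered, pre-normalisation images
    (peak normalisation cannot change a ratio of means); the exported
    images are the filtered, normalised ones.
    """
    t0 = time.perf_counter()
    dop, ref = raster_scan(
        config.model, config.beam, config.grid, config.transport,
        config.lens, seed=config.seed,
    )
    dop_f = median_filter(dop)
    ref_f = median_filter(ref)

    mult_f = multiply(dop_f, ref_f)
    # healthy scenes use the nominal central-disc footprint, so their
    # SBRs are defined (and should be ~1: no contrast without a tumour)
    footprint = config.model.tumour or TumourSpec()
    mask = default_mask(config.grid, footprint)
    sbr_d = sbr(dop_f, mask)
    sbr_r = sbr(ref_f, mask)
    sbr_m = sbr(mult_f, mask)

    dop_n = normalize_peak(dop_f)
    ref_n = normalize_peak(ref_f)
    mult_n = multiply(dop_n, ref_n)
    result = ScanResult(
        doppler=dop_n, reflectance=ref_n, multiplication=mult_n,
        mask=mask, sbr_doppler=sbr_d, sbr_reflectance=sbr_r,
        sbr_multiplication=sbr_m,
    )

    paths: dict[str, list[str] | str] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["doppler"] = _export_image(dop_n, out / "doppler")
        paths["reflectance"] = _export_image(ref_n, out / "reflectance")
        paths["multiplication"] = _export_image(mult_n, out / "multiplication")
        report = {
            "preset": config.preset,
            "sbr_doppler": sbr_d,
            "sbr_reflectance": sbr_r,
            "sbr_multiplication": sbr_m,
        }
        with open(out / "sbr.json", "w") as fh:
            json.dump(report, fh, indent=2)
        paths["sbr"] = str(out / "sbr.json")

    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("rcmldf")
    except PackageNotFoundError:
        ver = "unknown"
    manifest = RunManifest(
        preset=config.preset,
        seed=config.seed,
        n_photons_doppler=config.transport.n_photons_doppler,
        n_photons_reflectance=config.transport.n_photons_reflectance,
        grid=asdict(config.grid),
        beam=asdict(config.beam),
        lens=asdict(config.lens),
        transport=asdict(config.transport),
        code_version=ver,
        wall_time_s=time.perf_counter() - t0,
        output_paths=paths,
    )
    if out_dir is not None:
        manifest.write(Path(out_dir) / "manifest.json")
    return result, manifest
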