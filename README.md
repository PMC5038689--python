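# rcmldf

Monte Carlo model of **concurrent reflectance confocal microscopy (RCM)
and laser Doppler flowmetry (LDF)** imaging of skin, for researchers in
biomedical optics studying dual-modality contrast of keratinocyte skin
cancers (KSC, i.e. BCC/SCC-like lesions).

A focused 850 nm beam raster-scans a six-layer skin model containing
moving red blood cells and, optionally, a cylindrical tumour with
elevated blood concentration and velocity and reduced baseline optical
coefficients.  Photons are tracked through exponential free paths,
Henyey–Greenstein scattering off static tissue (g = 0.85) and
Gegenbauer-kernel scattering off red blood cells (α = 1.0, g = 0.948,
anisotropy 0.991), accumulating Doppler shifts

    Δf = (1/2π)(k_s − k_i)·v,        |k| = 2πn/λ,

at each moving-scatterer event.  Photons that re-enter the confocal
aperture (paraxial thin-lens gate: NA cone, clear aperture, and the
aperture-conjugate disc at the focal plane) form, per pixel,

* the **confocal reflectance** signal — detected photon weight per
  launched photon, and
* the **Doppler perfusion** signal — the first moment of the detected
  Doppler power spectrum, Perf ∝ ∫₀^∞ ω P(ω) dω, computed bin-free as
  Σᵢ wᵢ |Δfᵢ|.

The two images are median filtered and fused by pixel-wise
multiplication; contrast is quantified by the signal-to-background ratio

    SBR = (1/N_T) Σ_{i∈T} Sig_i  /  (1/N_BG) Σ_{i∈BG} Sig_i

over the tumour disc T and the surrounding normal skin BG.  A separate
module (`rcmldf.lfi_signal`) implements the bench-style processing chain
(FFT spectrum, Savitzky–Golay smoothing, first-harmonic reflectance and
noise-subtracted spectral-moment perfusion) on synthetic
chopper-modulated records, so that signal-processing logic is testable
without hardware.

## Worked example

Single-pixel perfusion at the centre of a mild-KSC tumour versus healthy
skin (focal depth 0.225 mm, 8 × 5·10⁴ photons per arm, splitting on):

```python
import numpy as np
import rcmldf as r

beam, cfg = r.BeamSpec(), r.TransportConfig()
healthy = r.model_for_preset("healthy")
ksc1 = r.model_for_preset("ksc1")     # RBC conc x2, speeds x1.5, mus/mua x0.6

h = np.mean([r.propagate_pixel(healthy, beam, cfg, n_photons=50_000,
                               splitting=True, seed=s).perfusion_per_photon
             for s in range(8)])
t = np.mean([r.propagate_pixel(ksc1, beam, cfg, n_photons=50_000,
                               splitting=True, seed=100 + s).perfusion_per_photon
             for s in range(8)])
print(f"healthy perfusion/photon : {h:.4f} Hz")
print(f"KSC1 perfusion/photon    : {t:.4f} Hz")
print(f"tumour/healthy ratio     : {t/h:.2f}")
```

prints

```
healthy perfusion/photon : 0.0111 Hz
KSC1 perfusion/photon    : 0.0181 Hz
tumour/healthy ratio     : 1.63
```

i.e. the simulated tumour raises the Doppler perfusion signal by ~1.6×
at this photon budget (the statistic is heavy-tailed; the converged
ratio over more seeds is ≈ 2).  Healthy-skin confocal reflectance at the
default 45 µm detection gate is ≈ 3·10⁻³ per launched photon.

A full scene from the shell:

```sh
rcmldf scan --preset ksc1 --nx 9 --ny 9 \
    --photons-doppler 100000 --photons-reflectance 30000 \
    --seed 1 --out out/ksc1
```

writes Doppler / reflectance / multiplication images (TIFF + CSV), an
`sbr.json` report and a reproducibility manifest.  `rcmldf spectrum`
exports a single-pixel Doppler power spectrum, `rcmldf signal-demo` runs
the synthetic-record processing chain, and `rcmldf sbr` recomputes SBR
from a saved image.

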