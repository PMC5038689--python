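# Methods

`rcmldf` simulates a dual-modality optical scan of skin: reflectance
confocal microscopy (RCM, morphology) and laser Doppler flowmetry (LDF,
perfusion), acquired concurrently by one focused near-infrared beam whose
detection path doubles as a confocal pinhole and an interferometric
Doppler detector.  This note records the model, its assumptions, the
numerical choices, and what the test suite does and does not establish.

## Tissue model

Skin is a stack of six plane-parallel layers (z = 0 at the surface,
positive downward, all lengths in mm):

| layer              | thickness | blood 0.3 / 3 / 30 mm/s (vol %) | melanin | μs_base | μa_base |
|--------------------|-----------|---------------------------------|---------|---------|---------|
| epidermis          | 0.075     | 0 / 0 / 0                       | 2.0 %   | 23      | 0.1     |
| papillary dermis   | 0.15      | 0.2 / 0 / 0                     | 0       | 13      | 0.1     |
| superior blood net | 0.15      | 0.6 / 0.05 / 0.001              | 0       | 13      | 0.1     |
| reticular dermis   | 0.8       | 0.1 / 0.01 / 0.0006             | 0       | 13      | 0.1     |
| inferior blood net | 0.4       | 0.25 / 0.035 / 0.006            | 0       | 13      | 0.1     |
| subcutis           | 2.0       | 0.1 / 0.01 / 0.001              | 0       | 13      | 0.1     |

μs_base and μa_base (mm⁻¹) are bloodless, melanin-less baselines.  Blood
has μa = 0.5 mm⁻¹ and μs = 222 mm⁻¹; melanin absorbs at 15 mm⁻¹ and does
not scatter; the working wavelength is 850 nm.  In-vivo coefficients are
composed by volume-fraction mixing,

    μ_in_vivo = V_blood μ_blood + V_mel μ_mel + (1 − V_blood − V_mel) μ_base,

applied to absorption and scattering alike.  The three blood classes
(mean speeds 0.3, 3, 30 mm/s — capillaries, venules/arterioles, larger
vessels) keep separate partial scattering coefficients so the scatterer
class of each event can be drawn proportionally.  All refractive indices
are 1.4 and the surface is index-matched (anti-reflection plate), so
there are no Fresnel or refraction events anywhere.

Tumours are thin cylinders (default: 5 mm diameter, z = 0.075–0.375 mm,
spanning the papillary dermis and superior blood net).  Inside, blood
fractions are multiplied by a concentration factor, class speeds by a
velocity factor, and the *bloodless baseline* μs/μa by 0.6 before the
in-vivo composition — the baseline reduction represents ex-vivo tumour
optics, and the mixing formula converts them to in-vivo values.  Presets:
KSC1 (mild keratinocyte skin cancer): concentration ×2, speeds ×1.5;
KSC2 (severe): concentration ×3, speeds ×1.5.  The velocity factor is
applied to all three speed classes (configurable; the restriction to
capillary flow only would be an equally defensible reading).

## Scattering and Doppler physics

Static (non-blood) scatterers deflect photons by the Henyey–Greenstein
phase function with g = 0.85.  Red blood cells use the Gegenbauer-kernel
phase function with α = 1.0 and g_GK = 0.948; quadrature of that density
gives an anisotropy (mean deflection cosine) of 0.991.  Both are sampled
by closed-form CDF inversion (for the GK, t^(−α) is uniform between
(1+g)^(−2α) and (1−g)^(−2α), exact for any α > 0).

A blood event samples an RBC velocity — direction uniform on the sphere,
speed uniform on (0, 2·v_mean), a crude laminar-flow surrogate — and adds
the Doppler shift

    Δf = (1/2π)(k_s − k_i)·v,   |k| = 2πn/λ,

to the photon's running total.  The per-event bound |Δf| ≤ 2n|v|/λ
(≈ 98.8 kHz at the 30 mm/s class's 2× speed cap) is property-tested.

## Beam launch and confocal detection

The focused Gaussian beam (850 nm, 1/e² diameter 1.96 mm at the lens,
f = 8 mm, NA 0.5; diffraction-limited focal diameter 4λf/πD ≈ 4.4 µm) is
launched as a hyperboloid ray bundle: a waist point is drawn from a
Gaussian whose 1/e² diameter is the focal spot, a lens-plane point from
the beam profile, and the photon enters the surface along the line
joining them.  The ensemble therefore reproduces the waist exactly and
the NA cone approximately.

Detection is paraxial thin-lens conjugation.  An upward-exiting ray is
accepted iff (i) it lies within the NA cone, (ii) it passes the 8 mm
clear aperture at the lens plane, and (iii) its straight-line extension
back to the focal plane lands within the aperture-conjugate disc of
radius 45 µm / M around the axis.  The 45 µm radius is an enlarged,
statistics-friendly stand-in for the few-µm physical laser aperture; the
magnification M defaults to 1.  Tightening the gate (M up to 10, i.e.
effective radius down to 4.5 µm) moves the detected light from the
diffuse toward the ballistic regime — and flips the sign of the tumour's
confocal-reflectance contrast — but the acceptance probability falls to
~10⁻⁵, which is not statistically usable at desk-scale photon budgets.
With the default gate the confocal image is diffuse-dominated, and since
the tumour's reduced μs′ lowers diffuse reflectance (consistent with the
diffusion formula below), tumours appear slightly *darker* (~0.9×) here.
This is the main known regime limitation of the model.

## Transport kernel

Free paths are sampled as optical depths τ = −ln u and consumed region by
region (exact for piecewise-constant coefficients; no step truncation or
re-sampling is needed at layer or cylinder boundaries).  Absorption uses
weight attenuation by the single-event albedo.  Termination is by
surface exit (top: offered to the confocal gate; bottom and beyond a
15 mm lateral radius: discarded) or Russian roulette below weight 1e-4
(survival 0.1).  Energy is book-kept pathwise — launched + roulette
boosts + importance reweighting = detected + absorbed + escaped +
roulette kills — and asserted to 1e-9 per run.

Three unbiased variance-reduction devices shape the estimator:

* **Depth-importance roulette.**  Photons crossing below 1.575 mm (the
  subcutis) are rouletted with survival 0.25 (weight ×4 on survival).
  Deep wanderers dominate run time but contribute negligibly to the
  confocal gate; total reflectance is unchanged within MC error.
* **Speed-class importance sampling.**  The scatterer class of a blood
  event is drawn from bias-multiplied partial coefficients (default:
  fast 30 mm/s class ×100) with the exact weight correction p/q.  The
  perfusion first moment is tail-dominated by rare fast-class events;
  oversampling them populates the tail.  Reflectance-image runs use
  natural probabilities (bias 1) since their estimator has no such tail.
* **Value-based splitting.**  After each Doppler event a photon whose
  prospective contribution w·|Δf| exceeds a window (default 300
  weight·Hz) splits 4-fold repeatedly, up to a cumulative factor of
  3200, conserving weight exactly.  This bounds single-ledger-entry
  contributions instead of thresholding |Δf| alone; splitting on/off
  agreement of the perfusion estimate is property-tested.

Per-pixel RNG streams are derived from the master seed by counter-based
`SeedSequence` spawning (pixel index + modality), so results are
order-independent and bit-reproducible for a fixed seed.

## Signals and images

Per pixel, two quantities are estimated from the detection ledger:
confocal reflectance = Σ detected weights / photons launched, and
perfusion = Σ wᵢ|Δfᵢ| (the first moment of the one-sided Doppler power
spectrum, proportionality constant fixed at 1; only ratios are
meaningful).  Signed shifts are folded to |Δf| because the physical
flowmetry spectrum is a modulus beat spectrum.

A raster scan covers 10 × 10 mm; the full-scale protocol is 30 × 30
pixels with 1.6 M Doppler / 0.32 M reflectance photons per pixel, and the
package's scaled desk protocol is 9 × 9 pixels with 1e5 / 3e4 photons
per pixel over 3 seeds (chosen as the smallest scan that still resolves
the 5 mm tumour disc with ~21 tumour and ~44 background pixels).
Single-pixel perfusion-ratio arms (tumour centre vs healthy skin) use
16 seeds × 1e5 photons per arm with a tighter splitting window (50
weight·Hz): a lone pixel mean is skew-sensitive, so per-entry
contributions are capped harder than in the region-averaged scans.
Images are 3 × 3 median filtered (spike removal; kernel size is this
package's choice), peak-normalised for export, and fused by pixel-wise
multiplication.  Contrast is the signal-to-background ratio

    SBR = mean(signal over tumour disc) / mean(signal over background),

computed on the filtered, pre-normalisation images (normalisation cannot
change a ratio of means), with a one-pixel guard ring around the disc
excluded from both regions (edge pixels are mixed and would dilute both
means).

A diffusion-theory cross-check compares ungated MC total reflectance of
a homogeneous thick slab against R = 1/(k₁(1 + k₂ μa/μs′)) with k₁ = 3,
k₂ = 1 across a μs′ sweep; only the monotone trend (rank correlation) is
asserted, since the formula's constants are empirical and the published
comparison is qualitative.

## Synthetic interferometric records

`lfi_signal` implements the bench-style processing chain on records its
own generator produces: 60 kS/s, 3000 samples (50 ms), a 1 kHz chopper
gate (generated with exact integer-period arithmetic — trig-based square
waves jitter at transition samples and leak amplitude-dependent lines),
band-limited Gaussian "Doppler" fluctuation only on unblocked
half-cycles, and a white noise floor.  Reflectance is the first-harmonic
power above a blocked-beam reference; perfusion is the noise-subtracted
first moment with the DC line and chopper harmonics excluded ±5 bins
(the Savitzky–Golay window, default 11/order 3, smears lines that far).
The generator emulates the *structure* of such records, not laser
physics: no self-mixing nonlinearity, speckle, or 1/f noise.  Passing
the factor-separation and fusion-contrast tests therefore shows the
chain is correct, not that it is robust to real hardware noise.

## What the tests show, and known limitations

* Deterministic optics (anisotropy quadrature, focal-spot formula) and
  all estimator algebra are exact checks.
* The compiled kernel is cross-checked against a pure-Python reference
  propagation assembled from the photon-level operations on a
  homogeneous slab.
* Simulated tumour contrast: the KSC presets raise the Doppler image
  SBR (KSC2 > KSC1 > 1), and the tumour-centre perfusion ratios respond
  near-linearly to concentration × velocity with a partial-volume
  weight of ≈ 0.5 for the default focal geometry.  The confocal
  reflectance contrast is slightly negative in the diffuse detection
  regime (see above), so multiplicative fusion here sharpens the
  Doppler contrast only mildly rather than multiplying it.
* Single wavelength only; no polarisation, coherence, speckle or
  time-of-flight; no rough-surface or specular physics; melanoma-like
  lesions (pigmented, different geometry) are out of scope.
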