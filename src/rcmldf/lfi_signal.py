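"""Experimental-style signal chain on synthetic interferometric records.

In the bench implementation the confocal-reflectance and Doppler signals
are read from one voltage time series: the beam is chopper-modulated at
1 kHz, so reflectance appears as the first harmonic of the modulation in
the power spectrum, while perfusion appears as a Doppler-broadened
pedestal around DC whose first moment is taken after subtracting the
noise floor (a blocked-beam reference record) and excluding the chopper
harmonics.

The generator here is synthetic: it emulates the structure of such
records (square-wave modulation, band-limited stochastic Doppler
fluctuation only on unblocked half-cycles, white noise floor) so the
processing chain can be exercised and property-tested without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "SignalConfig",
    "Spectrum",
    "synth_signal",
    "power_spectrum",
    "smooth_spectrum",
    "extract_reflectance",
    "extract_perfusion",
]


@dataclass
class TimeSeries:
    samples: np.ndarray  # voltage, a.u.
    sample_rate: float = 60_000.0  # Hz

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class SignalConfig:
    """Synthetic record parameters (defaults: 60 kS/s, 3 kS = 50 ms,
    1 kHz chopper)."""

    sample_rate: float = 60_000.0
    n_samples: int = 3000
    chopper_freq: float = 1000.0
    reflectance_amplitude: float = 1.0
    doppler_bandwidth: float = 4000.0  # Hz
    doppler_power: float = 0.01  # variance of the fluctuation, a.u.^2
    noise_floor: float = 0.005  # white-noise std, a.u.
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.chopper_freq < self.sample_rate / 2:
            raise ValueError("chopper frequency must be below Nyquist")


@dataclass
class Spectrum:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # one-sided, power per bin

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def synth_signal(config: SignalConfig, rng: np.random.Generator) -> TimeSeries:
    """Square-wave-modulated record with Doppler-like fluctuation on the
    unblocked (high) half-cycles and an always-present white noise floor."""
    n = config.n_samples
    # exact gate: trig-based square waves jitter at transition samples
    # (float phase), which injects amplitude-dependent broadband lines
    period = config.sample_rate / config.chopper_freq
    if abs(period - round(period)) < 1e-9:
        ip = int(round(period))
        high = (np.arange(n) % ip) < ip / 2.0
    else:
        phase = (np.arange(n) * config.chopper_freq) / config.sample_rate
        high = phase % 1.0 < 0.5
    x = np.where(high, config.reflectance_amplitude, 0.0)
    if config.doppler_power > 0:
        white = rng.standard_normal(n)
        nyq = config.sample_rate / 2.0
        wn = min(config.doppler_bandwidth / nyq, 0.999)
        b, a = sps.butter(4, wn)
        fluct = sps.lfilter(b, a, white)
        std = fluct.std()
        if std > 0:
            fluct *= np.sqrt(config.doppler_power) / std
        x = x + fluct * high
    if config.noise_floor > 0:
        x = x + config.noise_floor * rng.standard_normal(n)
    return TimeSeries(samples=x, sample_rate=config.sample_rate)


def power_spectrum(ts: TimeSeries) -> Spectrum:
    """One-sided FFT power spectrum (power per bin; frequency resolution
    = sample_rate / n_samples)."""
    if ts.n_samples < 2:
        raise ValueError("need at least two samples")
    f, p = sps.periodogram(
        ts.samples, fs=ts.sample_rate, detrend=False, scaling="spectrum"
    )
    return Spectrum(frequencies=f, power=p)


def smooth_spectrum(spectrum: Spectrum, window: int = 11, order: int = 3) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing of the spectrum."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if order >= window:
        raise ValueError("polynomial order must be below the window length")
    sm = sps.savgol_filter(spectrum.power, window, order)
    return Spectrum(frequencies=spectrum.frequencies, power=sm)


def _nearest_bin(frequencies: np.ndarray, f: float) -> int:
    return int(np.argmin(np.abs(frequencies - f)))


def extract_reflectance(
    spectrum: Spectrum, noise_floor_spectrum: Spectrum, chopper_freq: float
) -> float:
    """First-harmonic power at the chopper frequency above the noise
    floor (clipped at zero)."""
    i = _nearest_bin(spectrum.frequencies, chopper_freq)
    j = _nearest_bin(noise_floor_spectrum.frequencies, chopper_freq)
    return float(max(spectrum.power[i] - noise_floor_spectrum.power[j], 0.0))


def extract_perfusion(
    spectrum: Spectrum,
    noise_floor_spectrum: Spectrum,
    chopper_freq: float,
    harmonic_exclusion_bins: int = 5,
) -> float:
    """Noise-subtracted first spectral moment over positive frequencies,
    with the chopper harmonics (+- ``harmonic_exclusion_bins`` bins)
    excluded so modulation power does not leak into perfusion.  The
    default half-width covers the smearing of the harmonic lines by the
    default Savitzky-Golay window (11 bins)."""
    f = spectrum.frequencies
    p = np.clip(spectrum.power - np.interp(
        f, noise_floor_spectrum.frequencies, noise_floor_spectrum.power
    ), 0.0, None)
    df = f[1] - f[0]
    # the DC line (record mean) smears like a harmonic; excluding the low
    # bins costs almost nothing since the moment weights them by f ~ 0
    keep = f > harmonic_exclusion_bins * df + 1e-9
    if chopper_freq > 0:
        nyquist = f[-1]
        k = 1
        while k * chopper_freq <= nyquist + df:
            keep &= np.abs(f - k * chopper_freq) > harmonic_exclusion_bins * df + 1e-9
            k += 1
    return float(np.sum(f[keep] * p[keep]))
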