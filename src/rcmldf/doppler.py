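"""Doppler power spectrum and perfusion from a detection ledger.

The Doppler power spectrum of a pixel is the weight-weighted histogram
of the detected photons' accumulated frequency shifts; perfusion (the
product of RBC concentration and speed, up to a fixed proportionality
constant taken as 1) is its first moment,

    Perf = sum_i w_i |df_i|,

computed bin-free directly from the ledger.  Signed shifts are folded to
|df| by default: the physical flowmetry spectrum is a one-sided beat
spectrum.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detection import DetectionLedger

__all__ = ["DopplerSpectrum", "build_spectrum", "perfusion"]


@dataclass
class DopplerSpectrum:
    bin_edges: np.ndarray  # Hz
    power: np.ndarray  # weight per bin
    folded: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def first_moment(self) -> float:
        """Sum over bins of |center frequency| x power."""
        return float(np.sum(np.abs(self.bin_centers) * self.power))

    def total_power(self) -> float:
        return float(self.power.sum())

    def to_csv(self, path) -> None:
        with open(Path(path), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frequency_hz", "power"])
            for c, p in zip(self.bin_centers, self.power):
                writer.writerow([f"{c:.6g}", f"{p:.10g}"])


def build_spectrum(
    ledger: DetectionLedger, bin_width: float, fold: bool = True
) -> DopplerSpectrum:
    """Weight-weighted histogram of the ledger's Doppler shifts."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    shifts = np.abs(ledger.shifts) if fold else ledger.shifts
    if shifts.size == 0:
        edges = np.array([0.0, bin_width])
        return DopplerSpectrum(edges, np.zeros(1), fold)
    lo = 0.0 if fold else min(shifts.min(), 0.0)
    hi = max(shifts.max(), lo + bin_width)
    # snap edges to multiples of the bin width so that zero is an edge
    first = np.floor(lo / bin_width)
    last = np.ceil(hi / bin_width + 1e-12)
    edges = np.arange(first, last + 1) * bin_width
    power, _ = np.histogram(shifts, bins=edges, weights=ledger.weights)
    return DopplerSpectrum(edges, power, fold)


def perfusion(ledger: DetectionLedger) -> float:
    """First spectral moment, bin-free: sum_i w_i |df_i| (weight x Hz)."""
    if ledger.weights.size == 0:
        return 0.0
    return float(np.sum(ledger.weights * np.abs(ledger.shifts)))
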