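"""Periodogram band-power features per lead.

A raw (unsmoothed) periodogram is computed on the demeaned epoch: ordinates
P_k = |FFT_k|^2 / N at the Fourier frequencies k fs/N, k = 1..floor(N/2).
Band power is the sum of ordinates whose frequency lies inside a closed
band [f_lo, f_hi]. The study bands are alpha 8-14 Hz, beta 16-31 Hz, delta
0.1-4 Hz, gamma 32-50 Hz and theta 4-7 Hz; the printed gaps between bands
(7-8, 14-16, 31-32 Hz) are deliberately left unassigned, and the shared
4 Hz edge belongs to both delta and theta, exactly as the bands are printed.

An optional split-cosine taper over a fraction of each end of the series is
provided (off by default) to mirror common periodogram routines. On a 30 s
epoch the Fourier spacing is 1/30 Hz, so the delta band's nominal 0.1 Hz
lower edge in practice starts at the first ordinate >= 0.1 Hz, i.e. 2/15 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Epoch


@dataclass(frozen=True)
class BandDefinition:
    """A named closed frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band {self.name}: "
                             f"[{self.f_lo}, {self.f_hi}]")


#: Study band definitions (Hz).
STUDY_BANDS = (
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 16.0, 31.0),
    BandDefinition("delta", 0.1, 4.0),
    BandDefinition("gamma", 32.0, 50.0),
    BandDefinition("theta", 4.0, 7.0),
)


@dataclass
class PeriodogramResult:
    """Periodogram ordinates (uV^2) at ascending Fourier frequencies."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs/power shape mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be ascending")
        if np.any(self.power < 0):
            raise ValueError("negative spectral power")

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


def _split_cosine_taper(n: int, p: float) -> np.ndarray:
    """Cosine bell over proportion p of each end of an n-point series."""
    w = np.ones(n)
    m = int(np.floor(n * p))
    if m > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(1, m + 1) - 0.5) / m))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
    return w


def periodogram(signal: np.ndarray, fs: float,
                taper_fraction: float = 0.0) -> PeriodogramResult:
    """Raw periodogram of a demeaned series, P_k = |FFT_k|^2 / N.

    ``taper_fraction`` applies a split-cosine bell to that proportion of
    each end of the series before the FFT (0 disables tapering).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise ValueError(f"series too short for a periodogram ({x.size})")
    if not 0 <= taper_fraction <= 0.5:
        raise ValueError("taper_fraction must lie in [0, 0.5]")
    n = x.size
    x = x - x.mean()
    if taper_fraction > 0:
        x = x * _split_cosine_taper(n, taper_fraction)
    spec = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    power = np.abs(spec[1: n // 2 + 1]) ** 2 / n
    freqs = k * fs / n
    return PeriodogramResult(freqs=freqs, power=power)


def band_power(pg: PeriodogramResult, band: BandDefinition) -> float:
    """Total power in the closed interval [f_lo, f_hi] (uV^2)."""
    mask = (pg.freqs >= band.f_lo) & (pg.freqs <= band.f_hi)
    if not mask.any():
        warnings.warn(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz contains no "
            "Fourier frequency; power reported as 0", UserWarning,
            stacklevel=2)
        return 0.0
    return float(pg.power[mask].sum())


def ft_features(epoch: Epoch, bands: Sequence[BandDefinition] = STUDY_BANDS,
                taper_fraction: float = 0.0) -> "pd.Series":
    """Band-power features "ft_<lead>_<band>" for every lead and band."""
    import pandas as pd

    nyq = epoch.fs / 2
    for b in bands:
        if b.f_hi > nyq:
            raise ValueError(f"band {b.name} exceeds Nyquist {nyq:g} Hz")
    values = {}
    for lab in epoch.lead_labels:
        pg = periodogram(epoch.lead(lab), epoch.fs, taper_fraction)
        for b in bands:
            values[f"ft_{lab}_{b.name}"] = band_power(pg, b)
    return pd.Series(values, dtype=float)


def parse_bands(spec: str) -> tuple:
    """Parse "name:lo:hi,name:lo:hi,..." into band definitions."""
    bands = []
    for part in spec.split(","):
        name, lo, hi = part.split(":")
        bands.append(BandDefinition(name.strip(), float(lo), float(hi)))
    return tuple(bands)
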