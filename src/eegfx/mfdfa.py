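"""Multifractal detrended fluctuation analysis (MF-DFA) of single leads.

The procedure is the standard one for nonstationary series: integrate the
demeaned signal into a profile, partition the profile into non-overlapping
windows of scale s from both ends, remove a least-squares polynomial trend
of order m in each window, and form the q-th order fluctuation function

    F_q(s) = { mean_v [F^2(v, s)]^(q/2) }^(1/q),        q != 0
    F_0(s) = exp( 0.5 * mean_v ln F^2(v, s) ),

where F^2(v, s) is the mean squared residual in window v. The generalized
Hurst exponent h(q) is the log-log slope of F_q(s) against s; the mass
exponent is tau(q) = q h(q) - 1, and the Legendre transform gives the
Hölder (singularity) spectrum alpha = dtau/dq, f(alpha) = q alpha - tau(q).

Four summary parameters are extracted per lead: the mean, minimum and
maximum Hölder exponent and the spectrum width alpha_max - alpha_min. A
wide spectrum indicates multifractal temporal structure; monofractal
signals (white noise, fractional Gaussian noise) give narrow spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .io import Epoch

#: floor applied to a window's mean squared residual when detrending is
#: exact (zero residual), in uV^2; keeps logs finite, always warned about
F2_FLOOR = 1e-20


class DegenerateWindowWarning(UserWarning):
    """A detrending window had zero residual variance and was floored."""


def default_q_grid() -> np.ndarray:
    """Integer moment orders -5..5 (11 points, includes 0 and 2)."""
    return np.arange(-5.0, 5.5, 1.0)


def default_scales(n: int, n_scales: int = 12, s_min: int = 16,
                   s_max: int | None = None) -> np.ndarray:
    """Log-spaced integer scales in [16, n/8], deduplicated after rounding."""
    if s_max is None:
        s_max = n // 8
    if s_max < s_min:
        raise ValueError(f"series of {n} samples too short for scale grid")
    scales = np.unique(np.round(np.geomspace(s_min, s_max, n_scales))
                       .astype(int))
    return scales


@dataclass
class MFDFAParams:
    """Moment orders, window scales and detrending order for MF-DFA."""

    q_grid: np.ndarray
    scales: np.ndarray
    detrend_order: int = 1

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.scales = np.asarray(self.scales, dtype=int)
        if not (np.any(self.q_grid == 0) and np.any(self.q_grid == 2)):
            raise ValueError("q_grid must contain 0 and 2")
        if len(self.q_grid) < 3:
            raise ValueError("q_grid needs >= 3 points for the transform")
        if np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q_grid must be strictly increasing")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if self.scales.min() < self.detrend_order + 2:
            raise ValueError("smallest scale must be >= detrend_order + 2")

    @classmethod
    def for_length(cls, n: int, detrend_order: int = 1,
                   n_scales: int = 12) -> "MFDFAParams":
        p = cls(q_grid=default_q_grid(),
                scales=default_scales(n, n_scales=n_scales),
                detrend_order=detrend_order)
        if p.scales.max() > n // 4:
            raise ValueError("largest scale exceeds length/4")
        return p


def profile(signal: np.ndarray) -> np.ndarray:
    """Cumulative sum of the demeaned signal, Y(i) = sum_{k<=i}(x_k - <x>)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 16:
        raise ValueError(f"series too short for MF-DFA ({x.size} < 16)")
    return np.cumsum(x - x.mean())


def _window_f2(Y: np.ndarray, s: int, m: int) -> np.ndarray:
    """Mean squared detrending residual in each of the 2*floor(N/s) windows.

    Windows are taken from both ends of the profile so the trailing
    N mod s samples are not discarded.
    """
    N = Y.size
    s = int(s)
    if s < m + 2:
        raise ValueError(f"scale {s} < detrend_order + 2 = {m + 2}")
    if s > N:
        raise ValueError(f"scale {s} exceeds profile length {N}")
    k = N // s
    segs = np.concatenate([
        Y[: k * s].reshape(k, s),
        Y[N - k * s:].reshape(k, s),
    ])
    # one design matrix per scale; residuals for all windows at once
    t = np.arange(s, dtype=float)
    A = np.vander(t, m + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(A, segs.T, rcond=None)
    resid = segs.T - A @ coef
    f2 = np.mean(resid ** 2, axis=0)
    if np.any(f2 <= F2_FLOOR):
        warnings.warn(
            f"{int(np.sum(f2 <= F2_FLOOR))} window(s) at scale {s} had "
            "(near-)zero residual variance; floored", DegenerateWindowWarning,
            stacklevel=2)
        f2 = np.maximum(f2, F2_FLOOR)
    return f2


def fluctuation_function(Y: np.ndarray, s: int, q: float,
                         m: int = 1) -> float:
    """q-th order fluctuation F_q(s) of a profile at a single scale."""
    f2 = _window_f2(np.asarray(Y, dtype=float), s, m)
    if q == 0:
        return float(np.exp(0.5 * np.mean(np.log(f2))))
    return float(np.mean(f2 ** (q / 2.0)) ** (1.0 / q))


@dataclass
class MFDFASpectrum:
    """h(q), tau(q), the singularity spectrum, and four summary parameters.

    ``alpha`` and ``f_alpha`` live on the interior of the q grid (central
    differences drop the two endpoints). ``summary`` holds the per-lead
    parameters used as features: alpha_mean, alpha_min, alpha_max and
    width = alpha_max - alpha_min.
    """

    q_grid: np.ndarray
    h_q: np.ndarray
    tau_q: np.ndarray
    q_interior: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    summary: Dict[str, float]
    scales: np.ndarray
    fq: np.ndarray          # F_q(s), shape (len(q_grid), len(scales))

    def h(self, q: float) -> float:
        idx = np.nonzero(np.isclose(self.q_grid, q))[0]
        if idx.size == 0:
            raise KeyError(f"q={q} not on the grid")
        return float(self.h_q[idx[0]])


def mfdfa_spectrum(signal: np.ndarray,
                   params: MFDFAParams | None = None) -> MFDFASpectrum:
    """Full MF-DFA of one series: fluctuation functions, h(q), spectrum."""
    x = np.asarray(signal, dtype=float)
    if params is None:
        params = MFDFAParams.for_length(x.size)
    Y = profile(x)
    q_grid = params.q_grid
    scales = params.scales
    m = params.detrend_order

    fq = np.empty((q_grid.size, scales.size))
    for j, s in enumerate(scales):
        f2 = _window_f2(Y, int(s), m)
        logf2 = np.log(f2)
        for i, q in enumerate(q_grid):
            if q == 0:
                fq[i, j] = np.exp(0.5 * logf2.mean())
            else:
                fq[i, j] = np.mean(f2 ** (q / 2.0)) ** (1.0 / q)

    log_s = np.log(scales.astype(float))
    h_q = np.empty(q_grid.size)
    for i, q in enumerate(q_grid):
        logf = np.log(fq[i])
        if not np.isfinite(logf).all():
            raise ValueError(f"non-finite fluctuation function at q={q:g}")
        h_q[i] = np.polyfit(log_s, logf, 1)[0]
        if not np.isfinite(h_q[i]):
            raise ValueError(f"non-finite scaling slope at q={q:g}")

    tau_q = q_grid * h_q - 1.0
    # Legendre transform via central differences on the q grid
    alpha = (tau_q[2:] - tau_q[:-2]) / (q_grid[2:] - q_grid[:-2])
    q_int = q_grid[1:-1]
    f_alpha = q_int * alpha - tau_q[1:-1]
    summary = {
        "mean": float(alpha.mean()),
        "min": float(alpha.min()),
        "max": float(alpha.max()),
        "width": float(alpha.max() - alpha.min()),
    }
    return MFDFASpectrum(q_grid=q_grid, h_q=h_q, tau_q=tau_q,
                         q_interior=q_int, alpha=alpha, f_alpha=f_alpha,
                         summary=summary, scales=scales, fq=fq)


def mfdfa_features(epoch: Epoch,
                   params: MFDFAParams | None = None) -> "pd.Series":
    """Four Hölder summary features per lead: mfdfa_<lead>_{mean|min|max|width}.

    A lead whose analysis fails (e.g. non-finite scaling) contributes NaN
    features and a warning rather than aborting the epoch.
    """
    import pandas as pd

    values = {}
    for lab in epoch.lead_labels:
        try:
            spec = mfdfa_spectrum(epoch.lead(lab), params)
            summ = spec.summary
        except (ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"MF-DFA failed on lead {lab}: {e}", UserWarning,
                          stacklevel=2)
            summ = {k: float("nan") for k in ("mean", "min", "max", "width")}
        for k in ("mean", "min", "max", "width"):
            values[f"mfdfa_{lab}_{k}"] = summ[k]
    return pd.Series(values, dtype=float)
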