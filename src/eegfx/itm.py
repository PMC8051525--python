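"""Information transfer modeling (ITM) of EEG voltage series.

ITM treats the EEG voltage trace as an information transfer device in which
voltage changes scale with the time interval over which they occur,
|dV| ~ dt^kappa. The per-instant information transfer constant is

    kappa(t) = log|V(t + dt) - V(t)| / log(dt),

with |dV| in microvolts and dt expressed in milliseconds (so the
denominator is finite and non-zero down to a one-sample lag at typical EEG
rates). Between two leads l1, l2 sampled at a common lag the information
transfer constant ratio

    kappa_itcr(t) = log|dV_l1(t)| / log|dV_l2(t)|

measures relative information flow; the lag cancels and only aligns the
differences. Segment features are means of these per-instant values over an
epoch, on a small grid of lags, for every lead (within-lead) and every
ordered lead pair (between-lead).

Timepoints where a voltage difference is exactly zero carry no defined
kappa and are excluded; for the ratio, |dV_l2| = 1 uV makes the denominator
zero and is likewise excluded (guard eps on |log|dV_l2||). Exclusions are
counted, and a mean over zero valid points is an NaN sentinel accompanied
by a warning, never a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .io import Epoch

#: guard on |log|dV_dest|| below which a ratio timepoint is excluded
DENOM_EPS = 1e-8


class UndefinedFeatureWarning(UserWarning):
    """A segment mean had no valid timepoints and is reported as NaN."""


@dataclass(frozen=True)
class DelayGrid:
    """Ascending positive integer sample lags plus the rate for ms units."""

    delays: tuple
    fs: float

    def __post_init__(self):
        delays = tuple(int(d) for d in self.delays)
        if len(delays) == 0:
            raise ValueError("empty delay grid")
        if any(d < 1 for d in delays):
            raise ValueError("delays must be >= 1 sample")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValueError("delays must be strictly increasing")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def delays_ms(self) -> tuple:
        return tuple(1000.0 * d / self.fs for d in self.delays)

    @classmethod
    def within_default(cls, fs: float = 250.0) -> "DelayGrid":
        """Five short lags, 1..16 samples (4..64 ms at 250 Hz)."""
        return cls((1, 2, 4, 8, 16), fs)

    @classmethod
    def between_default(cls, fs: float = 250.0) -> "DelayGrid":
        """Five lags log-spaced over 1..1000 samples (4 ms..4 s at 250 Hz)."""
        return cls((1, 6, 32, 178, 1000), fs)


@dataclass
class KappaSeries:
    """Per-instant kappa values surviving exclusion, with bookkeeping."""

    values: np.ndarray      # finite kappa(t) at the valid timepoints
    n_total: int            # candidate timepoints, n - delay
    n_valid: int            # timepoints surviving the exclusion rules
    delay: int              # sample lag

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n_valid != self.values.size:
            raise ValueError("n_valid inconsistent with stored values")
        if self.n_valid > self.n_total:
            raise ValueError("n_valid exceeds n_total")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("non-finite kappa values")


def _ms(delay: int, fs: float) -> float:
    return 1000.0 * delay / fs


def _fmt_ms(ms: float) -> str:
    return str(int(ms)) if float(ms).is_integer() else f"{ms:g}"


def kappa_series(signal: np.ndarray, delay: int, fs: float) -> KappaSeries:
    """Within-lead kappa(t) = log|dV| / log(dt_ms) over one lead.

    Parameters
    ----------
    signal : 1-D array of voltages, microvolts.
    delay : lag in samples (>= 1, < len(signal)).
    fs : sampling rate, Hz.
    """
    x = np.asarray(signal, dtype=float)
    delay = int(delay)
    if delay < 1:
        raise ValueError("delay must be >= 1 sample")
    if delay >= x.size:
        raise ValueError(f"delay {delay} >= series length {x.size}")
    dt_ms = _ms(delay, fs)
    log_dt = np.log(dt_ms)
    if abs(log_dt) < DENOM_EPS:
        raise ValueError(
            f"delay of {dt_ms:g} ms makes log(dt) vanish; "
            "choose a lag whose duration is not exactly 1 ms")
    dv = np.abs(x[delay:] - x[:-delay])
    valid = dv > 0
    values = np.log(dv[valid]) / log_dt
    return KappaSeries(values=values, n_total=dv.size,
                       n_valid=int(valid.sum()), delay=delay)


def mean_kappa(series: KappaSeries) -> float:
    """Mean kappa over valid timepoints (sum / n_valid, not / n_total)."""
    if series.n_valid == 0:
        warnings.warn(
            "segment mean undefined: no valid timepoints "
            f"(all {series.n_total} excluded)", UndefinedFeatureWarning,
            stacklevel=2)
        return float("nan")
    return float(series.values.mean())


def kappa_itcr_series(source: np.ndarray, dest: np.ndarray,
                      delay: int) -> KappaSeries:
    """Between-lead ratio kappa_itcr(t) = log|dV_src| / log|dV_dst|.

    ``source`` is the numerator lead l1 and ``dest`` the denominator lead
    l2. The lag only aligns the two difference series; its duration cancels
    out of the ratio. Excluded timepoints: either difference exactly zero,
    or |log|dV_dst|| < DENOM_EPS (|dV_dst| = 1 uV).
    """
    s = np.asarray(source, dtype=float)
    d = np.asarray(dest, dtype=float)
    if s.shape != d.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {d.shape}")
    delay = int(delay)
    if delay < 1:
        raise ValueError("delay must be >= 1 sample")
    if delay >= s.size:
        raise ValueError(f"delay {delay} >= series length {s.size}")
    dv1 = np.abs(s[delay:] - s[:-delay])
    dv2 = np.abs(d[delay:] - d[:-delay])
    with np.errstate(divide="ignore"):
        log1 = np.log(dv1)
        log2 = np.log(dv2)
    valid = (dv1 > 0) & (dv2 > 0) & (np.abs(log2) >= DENOM_EPS)
    values = log1[valid] / log2[valid]
    return KappaSeries(values=values, n_total=dv1.size,
                       n_valid=int(valid.sum()), delay=delay)


@dataclass
class ITMFeatureSet:
    """Segment-mean ITM features of one epoch.

    ``within`` maps (lead, delay_samples) -> mean kappa and ``between``
    maps (source_lead, dest_lead, delay_samples) -> mean kappa_itcr, over
    ordered pairs of distinct leads. ``valid_counts`` carries n_valid under
    the same keys. For L leads and D delays there are L*D within-lead and
    L*(L-1)*D between-lead features (64 leads, 5 delays: 20,480 in total).
    """

    within: Dict[Tuple[str, int], float]
    between: Dict[Tuple[str, str, int], float]
    valid_counts: Dict[tuple, int]
    fs: float

    def feature_names(self) -> list:
        names = [f"itm_w_{l}_{_fmt_ms(_ms(d, self.fs))}"
                 for (l, d) in self.within]
        names += [f"itm_b_{l1}_{l2}_{_fmt_ms(_ms(d, self.fs))}"
                  for (l1, l2, d) in self.between]
        return names

    def to_series(self):
        """Flatten into a name -> value pandas Series (NaN for undefined)."""
        import pandas as pd
        vals = list(self.within.values()) + list(self.between.values())
        return pd.Series(vals, index=self.feature_names(), dtype=float)

    def __len__(self) -> int:
        return len(self.within) + len(self.between)


def itm_features(epoch: Epoch, within_grid: DelayGrid | None = None,
                 between_grid: DelayGrid | None = None) -> ITMFeatureSet:
    """All within-lead and ordered-pair between-lead segment means.

    Defaults: within-lead lags {1,2,4,8,16} samples, between-lead lags
    {1,6,32,178,1000} samples (4 ms .. 4 s at 250 Hz).
    """
    fs = epoch.fs
    if within_grid is None:
        within_grid = DelayGrid.within_default(fs)
    if between_grid is None:
        between_grid = DelayGrid.between_default(fs)
    n = epoch.n_times
    for grid in (within_grid, between_grid):
        if max(grid.delays) >= n:
            raise ValueError(
                f"delay {max(grid.delays)} >= epoch length {n} samples")

    data = epoch.samples
    labels = epoch.lead_labels
    within: Dict[Tuple[str, int], float] = {}
    between: Dict[Tuple[str, str, int], float] = {}
    counts: Dict[tuple, int] = {}

    for i, lab in enumerate(labels):
        for d in within_grid.delays:
            ks = kappa_series(data[i], d, fs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UndefinedFeatureWarning)
                m = mean_kappa(ks)
            if np.isnan(m):
                warnings.warn(
                    f"undefined within-lead mean kappa: lead {lab}, "
                    f"lag {d} samples", UndefinedFeatureWarning,
                    stacklevel=2)
            within[(lab, d)] = m
            counts[(lab, d)] = ks.n_valid

    # precompute per-(lead, delay) log|dV| once; pairs then only divide
    for d in between_grid.delays:
        dv = np.abs(data[:, d:] - data[:, :-d])
        with np.errstate(divide="ignore"):
            logdv = np.log(dv)
        nz = dv > 0
        denom_ok = nz & (np.abs(logdv) >= DENOM_EPS)
        for i, l1 in enumerate(labels):
            for j, l2 in enumerate(labels):
                if i == j:
                    continue
                valid = nz[i] & denom_ok[j]
                nv = int(valid.sum())
                if nv == 0:
                    warnings.warn(
                        f"undefined between-lead mean: {l1}->{l2}, "
                        f"lag {d} samples", UndefinedFeatureWarning,
                        stacklevel=2)
                    m = float("nan")
                else:
                    m = float(np.mean(logdv[i, valid] / logdv[j, valid]))
                between[(l1, l2, d)] = m
                counts[(l1, l2, d)] = nv

    return ITMFeatureSet(within=within, between=between,
                         valid_counts=counts, fs=fs)
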