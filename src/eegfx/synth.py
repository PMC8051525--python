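"""Synthetic multichannel EEG cohorts with known ground truth.

Every upstream stage has a generator here whose true parameters are known,
so estimator behaviour can be checked without circularity:

* :func:`gen_powerlaw_noise` — spectral-synthesis noise with power ~ f^-beta
  (beta 0 white, ~1 pink/EEG-like, 2 Brownian-like).
* :func:`gen_fgn` — fractional Gaussian noise by Davies–Harte circulant
  embedding; a monofractal reference with known Hurst exponent H.
* :func:`gen_binomial_cascade` — dyadic multiplicative binomial measure, the
  classic multifractal reference with closed-form generalized Hurst
  exponent h(q) = 1/q - ln(p^q + (1-p)^q) / (q ln 2).
* :func:`gen_cohort` — a cohort of subjects: per-lead 1/f-like noise plus
  band-limited oscillations, optional lagged cross-lead coupling, and
  cognitive subscores generated from declared subject-level latent drivers.

Subject-level latents (e.g. a subject's alpha-oscillation amplitude)
persist across the whole recording, so features extracted from the early
(train) and late (test) windows of one recording share the subject's truth
— without that persistence an out-of-sample correlation would be impossible
by construction. All generators are bit-reproducible under a fixed seed and
return their ground truth alongside the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as eio
from .io import EEGRecord, ScoreTable, STUDY_SUBSCORES


def gen_powerlaw_noise(n: int, beta: float, seed) -> np.ndarray:
    """Zero-mean, unit-variance noise with mean spectral power ~ f^-beta."""
    if n < 16:
        raise ValueError("n must be >= 16")
    if not -1.0 <= beta <= 3.0:
        raise ValueError(f"beta {beta} outside [-1, 3]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    spec = spec * scale
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_fgn(n: int, hurst: float, seed, with_meta: bool = False):
    """Fractional Gaussian noise, unit variance, via circulant embedding.

    Exact Davies–Harte synthesis: the circulant embedding of the fGn
    autocovariance gamma(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2 is
    diagonalised by FFT; negative eigenvalues (numerically tiny for
    H in (0,1)) are clipped to zero.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst {hurst} outside (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst)
                   - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])        # length 2n - 2
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(eig / m) * z)[:n].real
    meta = {"method": "davies-harte circulant embedding", "hurst": hurst,
            "n": n}
    return (x, meta) if with_meta else x


def cascade_hq(q, p: float):
    """Closed-form generalized Hurst exponent of the binomial cascade.

    h(q) = 1/q - ln(p^q + (1-p)^q) / (q ln 2); defined for q != 0.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q == 0):
        raise ValueError("closed form is defined for q != 0")
    return 1.0 / q - np.log(p ** q + (1 - p) ** q) / (q * np.log(2.0))


def cascade_width(p: float) -> float:
    """Theoretical singularity-spectrum width, log2(p / (1-p))."""
    return float(np.log2(p / (1 - p)))


def gen_binomial_cascade(levels: int, p: float, seed,
                         with_meta: bool = False):
    """Random binomial multiplicative cascade of length 2^levels.

    At each dyadic split the mass multipliers (p, 1-p) are assigned to the
    two halves in a random order. Total mass is 1. The measure series is
    the standard multifractal oracle: its MF-DFA generalized Hurst exponent
    follows the closed form :func:`cascade_hq`.
    """
    if levels < 10:
        raise ValueError("need levels >= 10 for a usable cascade")
    if not 0.5 <= p < 1.0:
        raise ValueError(f"p {p} outside [0.5, 1)")
    if p == 0.5:
        warnings.warn("p = 0.5 gives a degenerate (monofractal) cascade",
                      UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    x = np.ones(1)
    for _ in range(levels):
        flips = rng.integers(0, 2, size=x.size)
        left = np.where(flips == 0, p, 1 - p)
        x = np.column_stack([x * left, x * (1 - left)]).ravel()
    meta = {"p": p, "levels": levels,
            "theoretical_width": cascade_width(p)}
    return (x, meta) if with_meta else x


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class Coupling:
    """dest = gain * source delayed by ``lag`` samples + independent noise."""

    source: str
    dest: str
    gain: float = 1.0
    lag: int = 0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class Driver:
    """Links a subject latent to a subscore: score = intercept +
    effect * latent + N(0, score_noise_sd).

    ``kind`` selects which signal property the latent controls:
    "alpha_power" scales the 10 Hz oscillation amplitude on ``lead`` (so
    the subject's alpha band power encodes the latent), "hurst" sets the
    lead's noise memory.
    """

    subscore: str = "TPM"
    lead: str = "3"
    kind: str = "alpha_power"
    effect: float = 4.0
    intercept: float = 10.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped synthetic cohort: 12 subjects, 250 Hz, 5 min records.

    Defaults emulate the study data shape with the ten-lead scalp subset;
    ``noise_beta`` = 1 gives the 1/f-like background typical of resting
    EEG, ``osc_amp_uv`` adds a common 10 Hz alpha rhythm of a few uV on a
    ~10 uV background, and the driven subscore's latent spreads alpha
    amplitude across subjects wide relative to ``score_noise_sd``.
    """

    n_subjects: int = 12
    n_leads: int = 10
    fs: float = 250.0
    duration_s: float = 300.0
    noise_beta: float = 1.0
    noise_amp_uv: float = 10.0
    osc_amp_uv: float = 2.0
    coupling: Tuple[Coupling, ...] = ()
    drivers: Tuple[Driver, ...] = (Driver(),)
    latent_range: Tuple[float, float] = (0.5, 2.5)
    score_noise_sd: float = 0.5
    seed: int = 0
    lead_labels: Optional[Tuple[str, ...]] = None

    def labels(self) -> Tuple[str, ...]:
        if self.lead_labels is not None:
            return tuple(str(l) for l in self.lead_labels)
        if self.n_leads == 10:
            return eio.STUDY_LEADS_10
        return tuple(str(i + 1) for i in range(self.n_leads))

    def validate(self):
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        labels = self.labels()
        if len(labels) != self.n_leads:
            raise ValueError("lead_labels count != n_leads")
        n = int(round(self.duration_s * self.fs))
        for c in self.coupling:
            if c.source not in labels or c.dest not in labels:
                raise ValueError(f"coupling references unknown lead: {c}")
            if c.lag >= n:
                raise ValueError("coupling lag exceeds recording length")
        # coupling graph must be acyclic (a zero-lag cycle is unbuildable;
        # cycles are rejected outright)
        edges = {}
        for c in self.coupling:
            edges.setdefault(c.source, []).append(c.dest)
        seen, done = set(), set()

        def dfs(u):
            seen.add(u)
            for v in edges.get(u, ()):
                if v in seen and v not in done:
                    raise ValueError("coupling graph contains a cycle")
                if v not in done:
                    dfs(v)
            done.add(u)

        for u in list(edges):
            if u not in done:
                dfs(u)


@dataclass
class Cohort:
    """Generated records + scores + the ground truth that produced them."""

    records: List[EEGRecord]
    scores: ScoreTable
    ground_truth: Dict
    spec: CohortSpec

    def write(self, out_dir, fmt: str = "edf") -> None:
        """Write per-subject recordings, the score CSV and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in self.records:
            if fmt == "edf":
                eio.write_edf(rec, out / f"{rec.subject_id}.edf")
            elif fmt == "csv":
                eio.write_matrix(rec, out / f"{rec.subject_id}.csv")
            else:
                raise ValueError(f"unknown format {fmt!r}")
        self.scores.to_csv(out / "scores.csv")
        manifest = {
            "seed": self.spec.seed,
            "spec": asdict(self.spec),
            "ground_truth": self.ground_truth,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate one cohort according to ``spec`` (bit-reproducible).

    Per subject, each lead is ``noise_amp_uv`` x f^-beta noise plus a 10 Hz
    oscillation; on a driver lead the oscillation amplitude is
    ``osc_amp_uv`` x the subject latent, elsewhere ``osc_amp_uv``. Coupled
    leads are rebuilt as gain x lagged source + their own noise. Scores:
    driven subscores follow their driver's linear model; the remaining
    study subscores are standard-normal noise.
    """
    spec.validate()
    labels = spec.labels()
    n = int(round(spec.duration_s * spec.fs))
    root = np.random.SeedSequence(spec.seed)
    subj_seeds = root.spawn(spec.n_subjects)
    t = np.arange(n) / spec.fs

    driver_leads = {}
    for d in spec.drivers:
        if d.lead not in labels:
            raise ValueError(f"driver lead {d.lead!r} not in the montage")
        driver_leads.setdefault(d.lead, []).append(d)

    records, truth_subjects = [], {}
    score_rows = {}
    lo, hi = spec.latent_range
    for si in range(spec.n_subjects):
        sid = f"S{si + 1:02d}"
        rng = np.random.default_rng(subj_seeds[si])
        latents = {d.subscore: float(rng.uniform(lo, hi))
                   for d in spec.drivers}
        phases = rng.uniform(0, 2 * np.pi, size=len(labels))
        data = np.empty((len(labels), n))
        for li, lab in enumerate(labels):
            hurst_drivers = [d for d in driver_leads.get(lab, [])
                             if d.kind == "hurst"]
            if hurst_drivers:
                h = min(max(latents[hurst_drivers[0].subscore] /
                            (hi + lo), 0.05), 0.95)
                base = spec.noise_amp_uv * gen_fgn(
                    n, h, rng.integers(2 ** 31))
            else:
                base = spec.noise_amp_uv * gen_powerlaw_noise(
                    n, spec.noise_beta, rng.integers(2 ** 31))
            amp = spec.osc_amp_uv
            for d in driver_leads.get(lab, []):
                if d.kind == "alpha_power":
                    amp = spec.osc_amp_uv * latents[d.subscore]
            data[li] = base + amp * np.sin(2 * np.pi * 10.0 * t + phases[li])

        # coupled leads overwrite their destination rows (topological order
        # guaranteed acyclic by validate(); process until stable)
        remaining = list(spec.coupling)
        built = set(labels) - {c.dest for c in remaining}
        while remaining:
            progress = False
            for c in list(remaining):
                if c.source in built:
                    i_src = labels.index(c.source)
                    i_dst = labels.index(c.dest)
                    shifted = np.roll(data[i_src], c.lag)
                    if c.lag > 0:
                        shifted[:c.lag] = data[i_src][:c.lag]
                    noise = (c.noise_sd * rng.standard_normal(n)
                             if c.noise_sd > 0 else 0.0)
                    data[i_dst] = c.gain * shifted + noise
                    built.add(c.dest)
                    remaining.remove(c)
                    progress = True
            if not progress:
                raise ValueError("unresolvable coupling ordering")

        records.append(EEGRecord(data, fs=spec.fs, lead_labels=labels,
                                 subject_id=sid))
        row = {}
        for sub in STUDY_SUBSCORES:
            driver = next((d for d in spec.drivers if d.subscore == sub),
                          None)
            if driver is not None:
                row[sub] = (driver.intercept
                            + driver.effect * latents[sub]
                            + rng.normal(0, spec.score_noise_sd))
            else:
                row[sub] = float(rng.normal(0, 1))
        score_rows[sid] = row
        truth_subjects[sid] = {"latents": latents,
                               "phases": phases.tolist()}

    scores = ScoreTable(pd.DataFrame.from_dict(score_rows, orient="index"))
    truth = {
        "subjects": truth_subjects,
        "drivers": [asdict(d) for d in spec.drivers],
        "coupling": [asdict(c) for c in spec.coupling],
    }
    return Cohort(records=records, scores=scores, ground_truth=truth,
                  spec=spec)
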