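"""Reading, validation, epoching and lead selection for multichannel EEG.

The central container is :class:`EEGRecord`: a leads x timepoints matrix of
voltages in microvolts with a single sampling rate and ordered, unique lead
labels. Two file formats are supported — EDF (European Data Format, read via
:mod:`mne`) and plain delimited numeric matrices (one row per timepoint, one
column per lead). Analysis operates on fixed-length :class:`Epoch` windows;
the study convention is two 30 s windows, 90–120 s and 210–240 s from
recording onset, used respectively to train and test downstream models.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _edf

#: Ten-lead scalp-covering subset used for between-lead analysis:
#: right frontal (3, 56), left frontal (9, 19), anterior / posterior
#: midline (6, 36), right parietal (40, 46), left parietal (26, 31).
STUDY_LEADS_10 = ("3", "56", "9", "19", "6", "36", "40", "46", "26", "31")

#: Tower-test subscore names carried by a ScoreTable.
STUDY_SUBSCORES = ("ACH", "FMT", "MAR", "RVPI", "TPM", "TRV")

#: Study train/test epoch windows, seconds from recording onset.
TRAIN_WINDOW = (90.0, 120.0)
TEST_WINDOW = (210.0, 240.0)


@dataclass(frozen=True)
class EEGRecord:
    """Multichannel voltage time series.

    Parameters
    ----------
    samples : ndarray, shape (n_leads, n_times)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    lead_labels : tuple of str
        Unique, ordered lead identifiers, one per row of ``samples``.
    subject_id : str
        Opaque subject identifier.
    """

    samples: np.ndarray
    fs: float
    lead_labels: tuple
    subject_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be 2-D (leads x timepoints)")
        if samples.shape[1] < 2:
            raise ValueError("each lead needs at least 2 timepoints")
        if not np.isfinite(samples).all():
            raise ValueError("non-finite voltage values in input")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        labels = tuple(str(l) for l in self.lead_labels)
        if len(labels) != samples.shape[0]:
            raise ValueError("lead_labels count does not match sample rows")
        if len(set(labels)) != len(labels):
            raise ValueError("lead_labels must be unique")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "lead_labels", labels)

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.fs

    def lead(self, label: str) -> np.ndarray:
        """Return the voltage series of one lead."""
        try:
            idx = self.lead_labels.index(str(label))
        except ValueError:
            raise KeyError(f"unknown lead label {label!r}") from None
        return self.samples[idx]


@dataclass(frozen=True)
class Epoch:
    """A half-open time window [start_s, end_s) of a parent record."""

    parent: EEGRecord
    start_s: float
    end_s: float

    def __post_init__(self):
        if not 0 <= self.start_s < self.end_s:
            raise ValueError("require 0 <= start_s < end_s")
        if self.end_s > self.parent.duration + 1e-9:
            raise ValueError(
                f"window ({self.start_s}, {self.end_s}) s exceeds the "
                f"{self.parent.duration:g} s recording")

    @property
    def _bounds(self):
        i0 = int(round(self.start_s * self.parent.fs))
        i1 = int(round(self.end_s * self.parent.fs))
        return i0, i1

    @property
    def samples(self) -> np.ndarray:
        i0, i1 = self._bounds
        return self.parent.samples[:, i0:i1]

    @property
    def n_times(self) -> int:
        i0, i1 = self._bounds
        return i1 - i0

    @property
    def fs(self) -> float:
        return self.parent.fs

    @property
    def lead_labels(self) -> tuple:
        return self.parent.lead_labels

    def lead(self, label: str) -> np.ndarray:
        i0, i1 = self._bounds
        return self.parent.lead(label)[i0:i1]


class ScoreTable:
    """Per-subject cognitive subscores (one row per subject).

    Backed by a :class:`pandas.DataFrame` indexed by subject id with one
    numeric column per subscore; every subject appears exactly once and
    column names are restricted to a declared subscore set.
    """

    def __init__(self, frame: pd.DataFrame,
                 subscores: Sequence[str] = STUDY_SUBSCORES):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dup}")
        unknown = set(frame.columns) - set(subscores)
        if unknown:
            raise ValueError(f"unknown subscore columns: {sorted(unknown)}")
        if not all(np.issubdtype(d, np.number) for d in frame.dtypes):
            raise ValueError("subscore values must be numeric")
        self.frame = frame
        self.subscores = tuple(frame.columns)

    @classmethod
    def from_csv(cls, path, subscores: Sequence[str] = STUDY_SUBSCORES,
                 subject_col: str = "subject_id") -> "ScoreTable":
        df = pd.read_csv(path)
        if subject_col not in df.columns:
            raise ValueError(f"score table needs a {subject_col!r} column")
        return cls(df.set_index(subject_col), subscores=subscores)

    def to_csv(self, path) -> None:
        self.frame.rename_axis("subject_id").to_csv(path)

    @property
    def subject_ids(self) -> tuple:
        return tuple(self.frame.index)

    def __getitem__(self, subject_id: str) -> Mapping[str, float]:
        return self.frame.loc[str(subject_id)].to_dict()

    def __len__(self) -> int:
        return len(self.frame)


def read_edf(path) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (voltages in microvolts).

    All signals must share one sampling rate; annotation channels are
    dropped. mne returns data in SI volts, which are converted to uV.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) == 0:
        raise ValueError("EDF file contains no signal channels")
    # mne resamples nothing: a genuine EDF with mixed rates either errors
    # out or exposes distinct rates through the underlying reader
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        ns = int(hdr[252:256])
        fh.seek(256 + ns * 216)
        spr = [int(fh.read(8)) for _ in range(ns)]
        rec_dur = float(hdr[244:252])
    rates = {s / rec_dur for s in spr}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates in EDF: {sorted(rates)}")
    data = raw.get_data() * 1e6  # V -> uV
    return EEGRecord(data, fs=float(raw.info["sfreq"]),
                     lead_labels=tuple(raw.ch_names),
                     subject_id=path.stem)


def write_edf(record: EEGRecord, path) -> None:
    """Serialise a record to 16-bit EDF (values quantised to the format)."""
    _edf.write_edf(path, record.samples, record.fs, record.lead_labels,
                   subject_id=record.subject_id or "X")


def read_matrix(path, fs: float, labels: Sequence[str] | None = None,
                subject_id: str | None = None) -> EEGRecord:
    """Read a delimited numeric matrix (rows = timepoints, cols = leads).

    A first row that does not parse as numbers is taken as a header of lead
    labels. Without a header (and no ``labels`` argument) leads are labelled
    "1".."L". Delimiters comma, semicolon, tab and whitespace are accepted.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = None
    for cand in (",", ";", "\t"):
        if cand in lines[0]:
            delim = cand
            break

    def tokens(line):
        return [t.strip() for t in
                (line.split(delim) if delim else line.split())]

    first = tokens(lines[0])
    header = None
    try:
        [float(t) for t in first]
    except ValueError:
        header = first
        lines = lines[1:]
        if not lines:
            raise ValueError(f"{path}: header but no data rows")

    ncol = len(tokens(lines[0]))
    rows = np.empty((len(lines), ncol))
    for i, ln in enumerate(lines):
        toks = tokens(ln)
        if len(toks) != ncol:
            raise ValueError(
                f"{path}: ragged row {i + 1}: {len(toks)} fields, "
                f"expected {ncol}")
        try:
            rows[i] = [float(t) for t in toks]
        except ValueError as e:
            raise ValueError(f"{path}: non-numeric cell in row {i + 1}: {e}")

    if labels is not None:
        lead_labels = tuple(str(l) for l in labels)
    elif header is not None:
        lead_labels = tuple(header)
    else:
        lead_labels = tuple(str(i + 1) for i in range(ncol))
    return EEGRecord(rows.T, fs=fs, lead_labels=lead_labels,
                     subject_id=subject_id or path.stem)


def write_matrix(record: EEGRecord, path, header: bool = True) -> None:
    """Write a record as CSV, one row per timepoint, full float precision."""
    buf = _stdio.StringIO()
    if header:
        buf.write(",".join(record.lead_labels) + "\n")
    np.savetxt(buf, record.samples.T, delimiter=",", fmt="%.17g")
    Path(path).write_text(buf.getvalue())


def extract_epoch(record: EEGRecord, start_s: float, end_s: float) -> Epoch:
    """Cut the half-open window [start_s, end_s) from a record."""
    return Epoch(record, float(start_s), float(end_s))


def select_leads(record: EEGRecord, labels: Sequence[str]) -> EEGRecord:
    """Restrict a record to the requested leads, in the requested order."""
    labels = [str(l) for l in labels]
    missing = [l for l in labels if l not in record.lead_labels]
    if missing:
        raise KeyError(f"unknown lead label(s): {missing}")
    idx = [record.lead_labels.index(l) for l in labels]
    return EEGRecord(record.samples[idx], fs=record.fs,
                     lead_labels=tuple(labels),
                     subject_id=record.subject_id)
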