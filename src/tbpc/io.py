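"""Readers and writers for recordings, montages, subject tables and profiles.

The on-disk formats are deliberately plain:

* recordings — EDF (read through :mod:`mne`, written by a small built-in
  16-bit EDF writer) or a whitespace-delimited text matrix with an
  ``fs=<Hz>`` header line;
* montage, subject table, TBPC profiles and prediction reports — TSV,
  optionally prefixed by ``#`` provenance comment lines.

All channel-pair indices are stored in canonical form: the two labels of an
unordered pair sorted lexicographically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "Montage",
    "read_recording",
    "write_recording",
    "read_montage",
    "write_montage",
    "read_subjects",
    "write_subjects",
    "canonical_pair",
]

GROUPS = ("PD", "HC")
SCORE_RANGE = (0.0, 30.0)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered electrode pair in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"pair must consist of two distinct labels, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass
class EEGRecording:
    """A multichannel EEG block: channels x samples, in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel identifiers, one per row of ``data``, unique.
    bad : set of str
        Labels flagged as bad channels; always a subset of ``labels``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    bad: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = [str(l) for l in self.labels]
        self.bad = set(self.bad)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.bad <= set(self.labels):
            raise ValueError(f"bad channels {self.bad - set(self.labels)} not in labels")
        bad_mask = ~np.isfinite(self.data).all(axis=1)
        if bad_mask.any():
            culprits = [l for l, m in zip(self.labels, bad_mask) if m]
            raise ValueError(f"non-finite samples in channel(s): {', '.join(culprits)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def good_labels(self) -> list[str]:
        """Labels not flagged bad, in recording order."""
        return [l for l in self.labels if l not in self.bad]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data, self.fs, list(self.labels), set(self.bad))


@dataclass
class Montage:
    """Sensor layout: channel labels with 3-D Cartesian positions."""

    labels: list[str]
    pos: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.pos = np.asarray(self.pos, dtype=float).reshape(len(self.labels), 3)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if not np.isfinite(self.pos).all():
            raise ValueError("montage positions must be finite")
        self._index = {l: i for i, l in enumerate(self.labels)}

    def position(self, label: str) -> np.ndarray:
        try:
            return self.pos[self._index[label]]
        except KeyError:
            raise KeyError(f"label {label!r} not in montage") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Load an EEG recording from EDF or the plain text matrix format.

    The matrix format is one header line ``fs=<Hz>`` (optionally followed by a
    ``labels=<comma-separated>`` line), then one whitespace-delimited row per
    channel, samples in microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "matrix":
        _write_matrix(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")


def _read_matrix(path: Path) -> EEGRecording:
    fs = None
    labels = None
    data_start = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("fs="):
            fs = float(stripped[3:])
            data_start += 1
        elif stripped.startswith("labels="):
            labels = [l.strip() for l in stripped[7:].split(",")]
            data_start += 1
        elif stripped.startswith("#") or not stripped:
            data_start += 1
        else:
            break
    if fs is None:
        raise ValueError(f"{path}: matrix format requires an 'fs=<Hz>' header line")
    data = np.loadtxt(lines[data_start:], ndmin=2)
    if labels is None:
        labels = [f"ch{i + 1:03d}" for i in range(data.shape[0])]
    return EEGRecording(data, fs, labels)


def _write_matrix(rec: EEGRecording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"fs={rec.fs:.12g}\n")
        fh.write("labels=" + ",".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.10g")


# -- EDF ---------------------------------------------------------------------
# Plain EDF: one 256-byte global header, one 256-byte header per signal,
# then data records of little-endian int16 samples scaled by the per-signal
# physical/digital ranges.  Reading goes through mne.

def _read_edf(path: Path) -> EEGRecording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate; use matrix format")
    fs = int(round(fs))
    n_ch = rec.n_channels
    # one record per second; pad the tail record with the final sample value
    n_rec = int(np.ceil(rec.n_samples / fs))
    padded = np.empty((n_ch, n_rec * fs))
    padded[:, : rec.n_samples] = rec.data
    padded[:, rec.n_samples:] = rec.data[:, -1:]

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))          # patient id
        fh.write(_edf_field("Startdate X X X X", 80))  # recording id
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_rec, 8))
        fh.write(_edf_field(1, 8))                    # record duration, s
        fh.write(_edf_field(n_ch, 4))
        for label in rec.labels:
            fh.write(_edf_field(label, 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))              # transducer
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for v in pmin:
            fh.write(_edf_field(f"{v:.7g}"[:8], 8))
        for v in pmax:
            fh.write(_edf_field(f"{v:.7g}"[:8], 8))
        fh.write(_edf_field(dmin, 8) * n_ch)
        fh.write(_edf_field(dmax, 8) * n_ch)
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))              # prefiltering
        fh.write(_edf_field(fs, 8) * n_ch)
        fh.write(_edf_field("", 32) * n_ch)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def read_montage(path: str | Path) -> Montage:
    """Read a TSV montage with columns ``label``, ``x``, ``y``, ``z``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str},
                     float_precision="round_trip")
    required = {"label", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"montage file must have columns {sorted(required)}")
    if df["label"].duplicated().any():
        dups = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate montage label(s): {dups}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return Montage(df["label"].tolist(), coords)


def write_montage(montage: Montage, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("label\tx\ty\tz\n")
        for label, (x, y, z) in zip(montage.labels, montage.pos):
            fh.write(f"{label}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")


# ---------------------------------------------------------------------------
# subject table
# ---------------------------------------------------------------------------

def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read the subject table (TSV): subject_id, group, score_bl, score_fu.

    Missing follow-up scores are empty fields and load as NaN.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"subject_id": str})
    return validate_subjects(df)


def validate_subjects(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    required = {"subject_id", "group", "score_bl", "score_fu"}
    if not required <= set(df.columns):
        raise ValueError(f"subject table must have columns {sorted(required)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in subject table")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group label(s) {bad_groups}; expected {GROUPS}")
    lo, hi = SCORE_RANGE
    for col in ("score_bl", "score_fu"):
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.dropna()
        if ((present < lo) | (present > hi)).any():
            raise ValueError(f"{col} outside instrument range [{lo}, {hi}]")
        df[col] = vals
    return df


def write_subjects(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    df = validate_subjects(df)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
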