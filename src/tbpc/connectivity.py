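"""Phase-lag index, phase-crossing trains, and the TBPC coefficient profile.

The chain, per band-limited channel pair, is:

1. instantaneous (analytic) phase of each channel via the Hilbert transform;
2. the phase-difference series ``dphi(t)`` and its sign series
   ``s(t) = sign(sin dphi(t))``;
3. the phase-lag index ``PLI = |sum_t s(t)| / T``, which is 0 for zero-lag
   (volume-conducted) synchrony and 1 for a constant nonzero lag;
4. the crossing train: the times at which ``s(t)`` flips, i.e. the phase
   difference crosses 0 or pi.

The time-between-phase-crossing (TBPC) coefficient compares the crossing
trains of two connections that share a common electrode ``k`` lying near the
midpoint of the outer pair ``(i, j)``: crossings of (i,k) are matched to the
nearest crossings of (k,j) (and vice versa) and the matched absolute lags are
summed per second of recording, in ms/s.  Two connections whose phase
dynamics flip synchronously score near 0; independent flip dynamics score
high.  One coefficient per unordered outer pair and band gives the TBPC
profile: ``C(n, 2)`` coefficients per band (22,578 for a 213-channel net).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io import EEGRecording, Montage, canonical_pair

__all__ = [
    "PhaseDiffSeries",
    "SignSeries",
    "CrossingTrain",
    "TripletMap",
    "TBPCProfile",
    "analytic_phase",
    "analytic_signal",
    "phase_difference",
    "pli",
    "pli_matrix",
    "sign_series",
    "crossings",
    "build_triplet_map",
    "tbpc_coefficient",
    "tbpc_profile",
    "write_profile",
    "read_profile",
]

MATCHING_RULES = ("nearest", "next")


@dataclass
class PhaseDiffSeries:
    """Analytic phase difference between two channels, one value per sample."""

    dphi: np.ndarray  # radians
    fs: float

    def __post_init__(self) -> None:
        self.dphi = np.asarray(self.dphi, dtype=float).ravel()
        if self.dphi.size == 0:
            raise ValueError("empty phase-difference series")
        if not np.isfinite(self.dphi).all():
            raise ValueError("phase-difference series must be finite")


@dataclass
class SignSeries:
    """sign(sin dphi) per sample with zeros resolved; degenerate if all-zero."""

    s: np.ndarray  # values in {-1, +1} (all 0 only when degenerate)
    fs: float
    degenerate: bool = False


@dataclass
class CrossingTrain:
    """Ordered times (s) at which a pair's phase-difference sign flips."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size:
            if not (np.diff(self.times) > 0).all():
                raise ValueError("crossing times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("crossing times must lie in [0, duration)")

    @property
    def n_crossings(self) -> int:
        return len(self.times)

    @property
    def n_episodes(self) -> int:
        """Constant-sign episodes delimited by the crossings (and boundaries)."""
        return len(self.times) + 1

    def episode_durations(self) -> np.ndarray:
        edges = np.concatenate(([0.0], self.times, [self.duration]))
        return np.diff(edges)


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic (complex) representation of a real signal along the last axis."""
    return hilbert(np.asarray(x, dtype=float), axis=-1)


def analytic_phase(x: np.ndarray, fs: float) -> np.ndarray:
    """Instantaneous phase of a band-limited signal, in (-pi, pi] per sample."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("signal must be finite")
    if x.ndim != 1:
        raise ValueError("analytic_phase expects a single channel")
    if np.ptp(x) == 0:
        raise ValueError("constant (zero-amplitude) signal has no defined phase")
    return np.angle(analytic_signal(x))


def phase_difference(x: np.ndarray, y: np.ndarray, fs: float) -> PhaseDiffSeries:
    """dphi(t) = phase(x) - phase(y), wrapped to (-pi, pi]."""
    d = analytic_phase(x, fs) - analytic_phase(y, fs)
    d = np.mod(d + np.pi, 2 * np.pi) - np.pi
    return PhaseDiffSeries(d, fs)


def pli(d: PhaseDiffSeries) -> float:
    """Phase-lag index: |mean over time of sign(sin dphi)|, in [0, 1].

    Exact zeros of sin(dphi) contribute 0, so identical signals score 0 —
    the volume-conduction robustness the index is built for.
    """
    s = np.sign(np.sin(d.dphi))
    return float(abs(s.sum()) / len(s))


def _resolve_zero_signs(s: np.ndarray, fs: float) -> SignSeries:
    """Raw {-1, 0, +1} samples -> SignSeries with zeros carried over."""
    nz = np.nonzero(s)[0]
    if nz.size == 0:
        return SignSeries(s, fs, degenerate=True)
    # forward-fill zeros with the previous nonzero sign; leading zeros take
    # the first nonzero sign
    idx = np.maximum.accumulate(np.where(s != 0, np.arange(len(s)), -1))
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], s[nz[0]])
    return SignSeries(filled, fs)


def sign_series(d: PhaseDiffSeries) -> SignSeries:
    """Sign of sin(dphi) with exact zeros carried over from the last nonzero.

    Leading zeros take the first nonzero sign.  An all-zero series (identical
    signals) is returned with ``degenerate=True``.
    """
    return _resolve_zero_signs(np.sign(np.sin(d.dphi)), d.fs)


def crossings(s: SignSeries, fs: float | None = None) -> CrossingTrain:
    """Times of adjacent-sample sign flips, at the midpoint of the two samples.

    With samples at t = i/fs, a flip between samples i and i+1 is placed at
    (i + 0.5)/fs.  A constant-sign series yields an empty train.
    """
    if s.degenerate:
        raise ValueError("degenerate (all-zero) sign series has no crossings")
    fs = fs if fs is not None else s.fs
    flips = np.nonzero(np.diff(s.s))[0]
    return CrossingTrain((flips + 0.5) / fs, len(s.s) / fs)


# ---------------------------------------------------------------------------
# triplet geometry
# ---------------------------------------------------------------------------

@dataclass
class TripletMap:
    """Outer pair (i, j) -> common electrode k near the pair's midpoint."""

    mapping: dict[tuple[str, str], str]

    def common(self, i: str, j: str) -> str:
        return self.mapping[canonical_pair(i, j)]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)


def build_triplet_map(montage: Montage, good: list[str] | None = None) -> TripletMap:
    """Assign each outer pair the good electrode closest to its 3-D midpoint.

    Distance is Euclidean in sensor space; exact ties go to the
    lexicographically smallest label.
    """
    labels = sorted(good if good is not None else montage.labels)
    if len(labels) < 3:
        raise ValueError("triplet construction needs at least 3 good channels")
    pos = np.array([montage.position(l) for l in labels])
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    midpoints = (pos[iu] + pos[ju]) / 2.0
    # (n_pairs, n_labels) distances; exclude the pair's own electrodes
    d = np.linalg.norm(midpoints[:, None, :] - pos[None, :, :], axis=2)
    d[np.arange(len(iu)), iu] = np.inf
    d[np.arange(len(ju)), ju] = np.inf
    # labels are sorted, so argmin's first-minimum rule is the lexicographic tie-break
    k = np.argmin(d, axis=1)
    mapping = {(labels[a], labels[b]): labels[c] for a, b, c in zip(iu, ju, k)}
    return TripletMap(mapping)


# ---------------------------------------------------------------------------
# TBPC
# ---------------------------------------------------------------------------

def _directed_lag_sum(a: np.ndarray, b: np.ndarray, rule: str) -> float:
    """Sum over crossings of `a` of the (absolute) lag to its match in `b`, s."""
    if rule == "nearest":
        pos = np.searchsorted(b, a)
        left = b[np.clip(pos - 1, 0, len(b) - 1)]
        right = b[np.clip(pos, 0, len(b) - 1)]
        return float(np.minimum(np.abs(a - left), np.abs(right - a)).sum())
    if rule == "next":
        pos = np.searchsorted(b, a)
        nxt = b[np.clip(pos, 0, len(b) - 1)]  # last crossing stands in when none follows
        return float(np.abs(nxt - a).sum())
    raise ValueError(f"unknown matching rule {rule!r}; expected one of {MATCHING_RULES}")


def tbpc_coefficient(a: CrossingTrain, b: CrossingTrain, rule: str = "nearest") -> float:
    """Symmetric summed crossing lag between two trains, in ms per second.

    Each crossing of one train is matched to its nearest crossing in the
    other; the two directed absolute-lag sums are averaged and normalised by
    the recording duration.  Identical trains score 0; an empty train on
    either side is degenerate and scores 0.
    """
    if abs(a.duration - b.duration) > 1e-9:
        raise ValueError(f"duration mismatch: {a.duration} vs {b.duration}")
    if a.n_crossings == 0 or b.n_crossings == 0:
        return 0.0
    l_ab = _directed_lag_sum(a.times, b.times, rule)
    l_ba = _directed_lag_sum(b.times, a.times, rule)
    return (l_ab + l_ba) * 1000.0 / (2.0 * a.duration)


@dataclass
class TBPCProfile:
    """One TBPC coefficient (ms/s) per band and unordered outer pair.

    ``coeff[b, p]`` is the coefficient for ``bands[b]`` and ``pairs[p]``;
    pairs are canonical (lexicographically sorted labels) and listed in
    lexicographic order, so profiles from the same montage align feature-wise
    regardless of input channel order.
    """

    bands: list[str]
    pairs: list[tuple[str, str]]
    common: dict[tuple[str, str], str]
    coeff: np.ndarray  # (n_bands, n_pairs)
    duration: float
    degenerate_pairs: set[tuple[str, tuple[str, str]]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coeff = np.asarray(self.coeff, dtype=float).reshape(
            len(self.bands), len(self.pairs))
        if (self.coeff < 0).any():
            raise ValueError("TBPC coefficients must be non-negative")

    def value(self, band: str, i: str, j: str) -> float:
        return float(self.coeff[self.bands.index(band),
                                self.pairs.index(canonical_pair(i, j))])

    @property
    def n_coefficients_per_band(self) -> int:
        return len(self.pairs)

    def to_vector(self) -> np.ndarray:
        """Band-major flattening: the per-subject CPM feature vector."""
        return self.coeff.ravel()

    def feature_bands(self) -> np.ndarray:
        """Band label of each entry of :meth:`to_vector`."""
        return np.repeat(self.bands, len(self.pairs))


def _pair_crossings(z: np.ndarray, i: int, k: int, fs: float) -> CrossingTrain | None:
    """Crossing train of the (i, k) connection from analytic signals.

    sign(sin(phi_i - phi_k)) equals sign(Im(z_i * conj(z_k))); returns None
    when the series is degenerate (identical signals).
    """
    cross = np.imag(z[i] * np.conj(z[k]))
    s = _resolve_zero_signs(np.sign(cross), fs)
    if s.degenerate:
        return None
    return crossings(s, fs)


def tbpc_profile(band_recs: dict[str, EEGRecording], montage: Montage,
                 rule: str = "nearest") -> TBPCProfile:
    """TBPC coefficients for every unordered good-channel pair, per band.

    ``band_recs`` maps band name to the band-limited recording; all bands must
    share channels, sampling rate and duration.  Bad channels are excluded.
    For each outer pair (i, j) the common electrode k comes from the triplet
    map and the coefficient compares the crossing trains of connections (i,k)
    and (k,j).
    """
    first = next(iter(band_recs.values()))
    good = sorted(first.good_labels)
    missing = [l for l in good if l not in montage]
    if missing:
        raise ValueError(f"montage missing channel(s): {missing}")
    if len(good) < 3:
        raise ValueError("TBPC needs at least 3 good channels")
    for name, rec in band_recs.items():
        if sorted(rec.good_labels) != good or rec.n_samples != first.n_samples \
                or rec.fs != first.fs:
            raise ValueError(f"band {name!r} inconsistent with other bands")

    tmap = build_triplet_map(montage, good)
    pairs = sorted(tmap.mapping)
    bands = list(band_recs)
    fs = first.fs
    duration = first.duration
    coeff = np.zeros((len(bands), len(pairs)))
    degenerate: set[tuple[str, tuple[str, str]]] = set()

    for bi, band in enumerate(bands):
        rec = band_recs[band]
        order = [rec.labels.index(l) for l in good]
        z = analytic_signal(rec.data[order])
        idx = {l: i for i, l in enumerate(good)}
        train_cache: dict[tuple[str, str], CrossingTrain | None] = {}

        def train(a: str, b: str) -> CrossingTrain | None:
            key = canonical_pair(a, b)
            if key not in train_cache:
                train_cache[key] = _pair_crossings(z, idx[key[0]], idx[key[1]], fs)
            return train_cache[key]

        for pi, (i, j) in enumerate(pairs):
            k = tmap.mapping[(i, j)]
            ta, tb = train(i, k), train(k, j)
            if ta is None or tb is None or ta.n_crossings == 0 or tb.n_crossings == 0:
                degenerate.add((band, (i, j)))
                coeff[bi, pi] = 0.0
            else:
                coeff[bi, pi] = tbpc_coefficient(ta, tb, rule)

    return TBPCProfile(bands, pairs, dict(tmap.mapping), coeff, duration, degenerate)


def pli_matrix(band_recs: dict[str, EEGRecording]) -> dict[str, pd.DataFrame]:
    """Symmetric PLI matrix per band over the good channels (labels sorted)."""
    out = {}
    for band, rec in band_recs.items():
        good = sorted(rec.good_labels)
        order = [rec.labels.index(l) for l in good]
        z = analytic_signal(rec.data[order])
        n = len(good)
        m = np.zeros((n, n))
        for i in range(n):
            cross = np.imag(z[i] * np.conj(z[i + 1:]))
            if len(cross):
                m[i, i + 1:] = np.abs(np.sign(cross).sum(axis=1)) / cross.shape[1]
        m = m + m.T
        out[band] = pd.DataFrame(m, index=good, columns=good)
    return out


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

def write_profile(profile: TBPCProfile, path: str | Path, header: str | None = None) -> None:
    """Long-format TSV: band, elec_i, elec_j, common_elec, coefficient."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# duration_s={profile.duration:.17g}\n")
        fh.write("band\telec_i\telec_j\tcommon_elec\tcoefficient\n")
        for bi, band in enumerate(profile.bands):
            for pi, (i, j) in enumerate(profile.pairs):
                fh.write(f"{band}\t{i}\t{j}\t{profile.common[(i, j)]}\t"
                         f"{profile.coeff[bi, pi]:.17g}\n")


def read_profile(path: str | Path) -> TBPCProfile:
    """Exact inverse of :func:`write_profile`."""
    duration = np.nan
    with open(path) as fh:
        for line in fh:
            if line.startswith("# duration_s="):
                duration = float(line.split("=", 1)[1])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                     dtype={"band": str, "elec_i": str, "elec_j": str, "common_elec": str})
    required = {"band", "elec_i", "elec_j", "common_elec", "coefficient"}
    if not required <= set(df.columns):
        raise ValueError(f"profile file must have columns {sorted(required)}")
    if df.duplicated(subset=["band", "elec_i", "elec_j"]).any():
        raise ValueError("duplicated (band, pair) row in profile file")
    bands = list(dict.fromkeys(df["band"]))
    pairs = sorted({canonical_pair(i, j) for i, j in zip(df["elec_i"], df["elec_j"])})
    pair_idx = {p: i for i, p in enumerate(pairs)}
    coeff = np.full((len(bands), len(pairs)), np.nan)
    common: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        p = canonical_pair(row.elec_i, row.elec_j)
        coeff[bands.index(row.band), pair_idx[p]] = row.coefficient
        common[p] = row.common_elec
    if np.isnan(coeff).any():
        raise ValueError("profile file incomplete: some (band, pair) entries missing")
    return TBPCProfile(bands, pairs, common, coeff, duration)
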