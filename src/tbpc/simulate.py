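"""Synthetic phase-coupled EEG cohorts with planted group and outcome effects.

Each channel is a sum of band-limited oscillators (filtered Gaussian noise,
one independent component per channel and band) plus broadband white noise.
A coupling edge makes two channels share one narrowband oscillator at a fixed
phase lag; a positive ``switch_rate`` flips the sign of that lag as a Poisson
process, which is what manufactures phase crossings at a controllable rate —
the object the TBPC coefficient measures.

A cohort plants a group effect by shifting the switch rate (or coupling
strength) of a fixed subset of pairs in one band for PD subjects, scaled by a
per-subject severity, and generates the follow-up cognitive score as a linear
function of that severity plus Gaussian noise.  Everything is reproducible
from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal

from .connectivity import analytic_signal
from .io import EEGRecording, Montage, canonical_pair
from .preprocessing import DEFAULT_BANDS, BandSpec

__all__ = [
    "CouplingEdge",
    "CouplingSpec",
    "CohortSpec",
    "Cohort",
    "spherical_cap_montage",
    "gen_recording",
    "gen_cohort",
]

#: Per-band oscillator amplitude (uV RMS): a coarse resting-state spectrum.
DEFAULT_BAND_AMP: dict[str, float] = {
    "delta": 8.0, "theta": 7.0, "alpha1": 6.0, "alpha2": 5.0, "beta": 4.0,
}


@dataclass(frozen=True)
class CouplingEdge:
    """One phase-coupled channel pair in one band."""

    i: str
    j: str
    band: str
    lag: float              # radians, |lag| < pi
    strength: float         # in [0, 1]: share of the channel's band power
    switch_rate: float = 0.0  # Hz; Poisson rate of lag sign flips

    def __post_init__(self) -> None:
        if not abs(self.lag) < np.pi:
            raise ValueError(f"|lag| must be < pi, got {self.lag}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"strength must be in [0, 1], got {self.strength}")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")


@dataclass
class CouplingSpec:
    """Edges plus additive white-noise level and the recording seed."""

    edges: list[CouplingEdge] = field(default_factory=list)
    noise_sd: float = 5.0  # uV
    seed: int = 0


def _channel_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"E{i + 1:0{width}d}" for i in range(n)]


def spherical_cap_montage(n_channels: int, radius: float = 0.09,
                          cap_min_z: float = 0.3) -> Montage:
    """Quasi-uniform (Fibonacci spiral) sensor positions on a spherical cap.

    ``radius`` is the head radius in metres; channels cover the cap with
    z/radius in [cap_min_z, 1] (vertex at the top, none below the ears).
    """
    labels = _channel_labels(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_channels)
    z = 1.0 - (1.0 - cap_min_z) * (k + 0.5) / n_channels
    r = np.sqrt(1.0 - z ** 2)
    theta = golden * k
    pos = radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return Montage(labels, pos)


def _narrowband_noise(rng: np.random.Generator, band: BandSpec, fs: float,
                      n_rows: int, n_samples: int) -> np.ndarray:
    """Rows of unit-RMS band-limited Gaussian noise (Butterworth order 4)."""
    sos = signal.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    # burn-in pad so the filter transient does not colour the start
    pad = int(2 * fs)
    white = rng.standard_normal((n_rows, n_samples + pad))
    x = signal.sosfilt(sos, white, axis=1)[:, pad:]
    rms = np.sqrt((x ** 2).mean(axis=1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def _switch_sign_series(rng: np.random.Generator, rate: float, n_samples: int,
                        fs: float) -> np.ndarray:
    """+-1 series starting at +1, flipping at Poisson(rate) event times."""
    if rate <= 0:
        return np.ones(n_samples)
    n_flips = rng.poisson(rate * n_samples / fs)
    flip_idx = np.sort(rng.integers(0, n_samples, size=n_flips))
    ind = np.zeros(n_samples)
    np.add.at(ind, flip_idx, 1.0)
    return (-1.0) ** np.cumsum(ind)


def gen_recording(spec: CouplingSpec, n_channels: int, fs: float, duration: float,
                  bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                  band_amp: dict[str, float] | None = None,
                  montage: Montage | None = None) -> tuple[EEGRecording, Montage]:
    """Simulate one multichannel recording from a coupling specification.

    Coupled pairs share a narrowband oscillator: the first channel carries it
    as is, the second carries it rotated by ``lag`` times the +-1 switching
    series, so the pair's analytic phase difference sits at the requested lag
    and flips sign at the Poisson switch times.  Per band, a channel's
    independent component is scaled down so its total band power stays
    roughly constant regardless of how many edges it participates in.
    """
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    hi_edge = max(b.hi for b in bands)
    if fs < 4 * hi_edge:
        raise ValueError(f"fs={fs} too low for band edge {hi_edge} Hz (need >= {4 * hi_edge})")
    band_amp = band_amp or DEFAULT_BAND_AMP
    band_names = {b.name for b in bands}
    for e in spec.edges:
        if e.band not in band_names:
            raise ValueError(f"edge band {e.band!r} not in band set")

    labels = _channel_labels(n_channels)
    if montage is None:
        montage = spherical_cap_montage(n_channels)
    index = {l: i for i, l in enumerate(labels)}
    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(spec.seed)
    data = np.zeros((n_channels, n_samples))

    for band in bands:
        amp = band_amp.get(band.name, 5.0)
        edges = [e for e in spec.edges if e.band == band.name]
        indep = _narrowband_noise(rng, band, fs, n_channels, n_samples)
        shared = _narrowband_noise(rng, band, fs, len(edges), n_samples)
        # exact per-channel band-power normalisation: with unit-RMS components
        # the band content of a channel is (w*indep + sum_e s_e*shared_e) /
        # sqrt(w^2 + sum_e s_e^2); strength is a power share, channels stay
        # homogeneous in variance no matter how many edges they join
        strength_sq = np.zeros(n_channels)
        for e in edges:
            strength_sq[index[e.i]] += e.strength ** 2
            strength_sq[index[e.j]] += e.strength ** 2
        w_indep = np.sqrt(np.clip(1.0 - strength_sq, 0.0, 1.0))
        norm = np.sqrt(w_indep ** 2 + strength_sq)
        band_sum = w_indep[:, None] * indep
        if edges:
            z_all = analytic_signal(shared)
            for ei, e in enumerate(edges):
                s = _switch_sign_series(rng, e.switch_rate, n_samples, fs)
                # s is +-1, so each rotation takes only two values; the lag is
                # split symmetrically so a flip kicks both channels' phases
                rot_i = np.where(s > 0, np.exp(1j * e.lag / 2), np.exp(-1j * e.lag / 2))
                rot_j = np.conj(rot_i)
                band_sum[index[e.i]] += e.strength * np.real(z_all[ei] * rot_i)
                band_sum[index[e.j]] += e.strength * np.real(z_all[ei] * rot_j)
        data += amp * band_sum / norm[:, None]

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return EEGRecording(data, fs, labels), montage


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic PD/HC cohort.

    The planted group effect shifts ``effect_on`` (switch rate in Hz, or
    coupling strength) on ``effect_fraction`` of all channel pairs in
    ``effect_band``, scaled per PD subject by a severity drawn uniformly
    from ``severity_range``.  The follow-up score is
    ``outcome_intercept + outcome_slope * severity + N(0, outcome_noise_sd)``,
    clipped to the instrument range; healthy controls keep severity 0 and no
    follow-up score.
    """

    n_pd: int = 20
    n_hc: int = 20
    effect_band: str = "theta"
    effect_fraction: float = 0.05
    effect_size: float = 2.0
    effect_on: str = "switch_rate"  # or "strength"
    outcome_intercept: float = 29.0
    outcome_slope: float = -3.0
    outcome_noise_sd: float = 1.0
    base_switch_rate: float = 0.5
    strength_range: tuple[float, float] = (0.8, 0.95)
    severity_range: tuple[float, float] = (0.7, 1.3)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in (0, 1]")
        if self.effect_on not in ("switch_rate", "strength"):
            raise ValueError("effect_on must be 'switch_rate' or 'strength'")
        if self.n_pd < 5 or self.n_hc < 5:
            raise ValueError("need at least 5 subjects per group")


@dataclass
class Cohort:
    """Generated recordings plus montage, subject table, and provenance."""

    recordings: dict[str, EEGRecording]
    montage: Montage
    subjects: pd.DataFrame
    spec: CohortSpec
    effect_pairs: list[tuple[str, str]]
    base_edges: list[CouplingEdge]


def gen_cohort(spec: CohortSpec, n_channels: int = 16, fs: float = 250.0,
               duration: float = 60.0,
               bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> Cohort:
    """Generate a full synthetic cohort with a planted group/outcome effect.

    Baseline coupling (shared by both groups) is a random perfect matching
    per band: each channel shares one oscillator with exactly one partner, so
    every edge keeps an undiluted power share.  Lags are U(0.5, 1.3) radians
    of random sign, strengths U over ``strength_range``, switch rate
    ``base_switch_rate``.  The effect pairs are a fixed random subset of the
    effect band's coupled pairs (extended with disjoint extra edges if the
    matching is too small).
    """
    master = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    labels = _channel_labels(n_channels)
    montage = spherical_cap_montage(n_channels)
    all_pairs = [canonical_pair(a, b) for a, b in combinations(labels, 2)]
    n_pairs = len(all_pairs)

    n_effect = int(round(spec.effect_fraction * n_pairs))
    if n_effect < 1:
        raise ValueError(
            f"effect_fraction {spec.effect_fraction} selects no pair out of {n_pairs}")

    band_names = [b.name for b in bands]
    if spec.effect_band not in band_names:
        raise ValueError(f"effect band {spec.effect_band!r} not in band set")

    def _new_edge(pair: tuple[str, str], band: str) -> CouplingEdge:
        lag = rng.uniform(0.5, 1.3) * rng.choice([-1.0, 1.0])
        return CouplingEdge(pair[0], pair[1], band, lag,
                            rng.uniform(*spec.strength_range),
                            spec.base_switch_rate)

    # couple spatial neighbours: a greedy minimum-distance matching, since
    # short-range synchrony dominates scalp EEG and short pairs are the ones
    # the triplet decomposition actually reads out as connections
    dists = {p: float(np.linalg.norm(montage.position(p[0]) - montage.position(p[1])))
             for p in all_pairs}
    matching: list[tuple[str, str]] = []
    unmatched = set(labels)
    for p in sorted(all_pairs, key=dists.__getitem__):
        if p[0] in unmatched and p[1] in unmatched:
            matching.append(p)
            unmatched -= set(p)

    base_edges: list[CouplingEdge] = []
    coupled_by_band: dict[str, list[tuple[str, str]]] = {}
    for band in band_names:
        coupled_by_band[band] = list(matching)
        base_edges.extend(_new_edge(p, band) for p in matching)

    pool = coupled_by_band[spec.effect_band]
    if n_effect > len(pool):
        extra = [p for p in all_pairs if p not in pool]
        add = [extra[k] for k in
               rng.choice(len(extra), size=n_effect - len(pool), replace=False)]
        base_edges.extend(_new_edge(p, spec.effect_band) for p in add)
        pool = pool + add
    effect_pairs = sorted(pool[k] for k in
                          rng.choice(len(pool), size=n_effect, replace=False))
    effect_set = set(effect_pairs)

    ids = [f"PD{i + 1:03d}" for i in range(spec.n_pd)] + \
          [f"HC{i + 1:03d}" for i in range(spec.n_hc)]
    groups = ["PD"] * spec.n_pd + ["HC"] * spec.n_hc
    severities = np.where(np.array(groups) == "PD",
                          rng.uniform(*spec.severity_range, size=len(ids)), 0.0)
    score_bl = np.clip(rng.normal(28.7, 1.0, size=len(ids)), 24.0, 30.0).round(1)
    fu_noise = rng.normal(0.0, spec.outcome_noise_sd, size=len(ids))
    score_fu = np.clip(spec.outcome_intercept + spec.outcome_slope * severities
                       + fu_noise, 0.0, 30.0).round(2)
    score_fu = np.where(np.array(groups) == "PD", score_fu, np.nan)

    child_seeds = master.spawn(len(ids))
    recordings: dict[str, EEGRecording] = {}
    for sid, sev, child in zip(ids, severities, child_seeds):
        edges = []
        for e in base_edges:
            if sev > 0 and e.band == spec.effect_band \
                    and canonical_pair(e.i, e.j) in effect_set:
                if spec.effect_on == "switch_rate":
                    e = replace(e, switch_rate=e.switch_rate + spec.effect_size * sev)
                else:
                    e = replace(e, strength=float(np.clip(
                        e.strength + spec.effect_size * sev, 0.0, 1.0)))
            edges.append(e)
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rec, _ = gen_recording(CouplingSpec(edges, spec.noise_sd, sub_seed),
                               n_channels, fs, duration, bands, montage=montage)
        recordings[sid] = rec

    subjects = pd.DataFrame({
        "subject_id": ids,
        "group": groups,
        "score_bl": score_bl,
        "score_fu": score_fu,
        "planted_severity": severities,
    })
    return Cohort(recordings, montage, subjects, spec, effect_pairs, base_edges)
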