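"""End-to-end orchestration: preprocess -> TBPC profiles -> CPM -> report.

A single :class:`RunConfig` (serialisable to YAML, hashed into every output
header) drives both the PD/HC classification run and the follow-up score
prediction run.  TBPC profiles are the cost centre, so they are cached on
disk keyed by a content hash of the recording and the profile-relevant
configuration; re-running CPM with a different threshold grid reuses them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import TBPCProfile, read_profile, tbpc_profile, write_profile
from .cpm import (DEFAULT_THRESHOLDS, PredictionReport, loocv,
                  profiles_to_features, spearman_ci)
from .io import EEGRecording, Montage, read_montage, read_recording, read_subjects
from .preprocessing import DEFAULT_BANDS, BandSpec, FilterSpec

__all__ = ["RunConfig", "compute_profiles", "run_classification", "run_prediction"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; YAML-serialisable and content-hashable."""

    recordings_dir: str = "."
    montage: str = "montage.tsv"
    subjects: str = "subjects.tsv"
    out_dir: str = "out"
    cache_dir: str | None = None
    broadband_lo: float = 0.5
    broadband_hi: float = 70.0
    notch: float | None = 50.0
    butter_order: int = 4
    bands: list[list] = field(default_factory=lambda: [
        [b.name, b.lo, b.hi] for b in DEFAULT_BANDS])
    detect_bad: bool = True
    tbpc_matching: str = "nearest"
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    family: str = "logistic"
    restrict: list[str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def band_specs(self) -> tuple[BandSpec, ...]:
        return tuple(BandSpec(str(n), float(lo), float(hi)) for n, lo, hi in self.bands)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.broadband_lo, self.broadband_hi, self.notch,
                          butter_order=self.butter_order)

    _PATH_KEYS = ("recordings_dir", "montage", "subjects", "out_dir", "cache_dir")

    def config_hash(self) -> str:
        """Hash of the analysis configuration (paths excluded): two runs of
        the same analysis hash identically wherever their files live."""
        d = {k: v for k, v in asdict(self).items() if k not in self._PATH_KEYS}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def _profile_config_hash(self) -> str:
        """Hash of only the keys that change TBPC profiles (cache key part)."""
        keys = ("broadband_lo", "broadband_hi", "notch", "butter_order",
                "bands", "detect_bad", "tbpc_matching")
        d = asdict(self)
        blob = json.dumps({k: d[k] for k in keys}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return (f"tbpc {__version__}\nconfig_hash={self.config_hash()}\n"
                f"seed={self.seed}")


def compute_profiles(recordings: dict[str, EEGRecording], montage: Montage,
                     cfg: RunConfig) -> dict[str, TBPCProfile]:
    """Preprocess and profile every subject, using the cache when present.

    Bad channels are detected per subject but pooled so all profiles share
    one feature space: a channel is excluded cohort-wide when it is flagged
    in at least a quarter of the subjects (sporadic single-subject flags at
    these SNRs are overwhelmingly statistical, not hardware, events).
    """
    from collections import Counter

    from .preprocessing import (broadband_filter, decompose_bands,
                                detect_bad_channels, rereference_common_average)

    fspec = cfg.filter_spec()
    bands = cfg.band_specs()
    broad: dict[str, EEGRecording] = {}
    flag_counts: Counter[str] = Counter()
    for sid, rec in recordings.items():
        b = broadband_filter(rec, fspec)
        if cfg.detect_bad and b.n_channels >= 8:
            b.bad |= detect_bad_channels(b)
        flag_counts.update(b.bad)
        broad[sid] = b
    min_count = max(1, int(np.ceil(0.25 * len(recordings))))
    common_bad = {l for l, c in flag_counts.items() if c >= min_count}
    if common_bad:
        logger.info("cohort-wide bad channels: %s", sorted(common_bad))

    cache = Path(cfg.cache_dir) if cfg.cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    pch = cfg._profile_config_hash()
    out: dict[str, TBPCProfile] = {}
    for sid, b in broad.items():
        t0 = time.perf_counter()
        b.bad = common_bad & set(b.labels)
        cached = None
        if cache:
            rec = recordings[sid]
            data_hash = hashlib.sha256(
                np.ascontiguousarray(rec.data).tobytes()
                + f"{rec.fs}{rec.labels}{sorted(b.bad)}".encode()).hexdigest()[:16]
            cached = cache / f"{sid}.{data_hash}.{pch}.profile.tsv"
        if cached is not None and cached.exists():
            out[sid] = read_profile(cached)
            logger.debug("profile %s: cache hit", sid)
            continue
        band_recs = decompose_bands(rereference_common_average(b), bands, fspec)
        out[sid] = tbpc_profile(band_recs, montage, rule=cfg.tbpc_matching)
        if cached is not None:
            write_profile(out[sid], cached, header=cfg.provenance())
        logger.info("profile %s: %d pairs x %d bands in %.2f s", sid,
                    len(out[sid].pairs), len(out[sid].bands),
                    time.perf_counter() - t0)
    return out


def _load_inputs(cfg: RunConfig) -> tuple[dict[str, EEGRecording], Montage, pd.DataFrame, list[str]]:
    montage = read_montage(cfg.montage)
    subjects = read_subjects(cfg.subjects)
    rec_dir = Path(cfg.recordings_dir)
    recordings: dict[str, EEGRecording] = {}
    excluded: list[str] = []
    for sid in subjects["subject_id"]:
        for ext in (".edf", ".txt", ".mat.txt"):
            path = rec_dir / f"{sid}{ext}"
            if path.exists():
                recordings[sid] = read_recording(path)
                break
        else:
            excluded.append(f"{sid}\tno recording file found in {rec_dir}")
    return recordings, montage, subjects, excluded


def _write_report(report: PredictionReport, cfg: RunConfig, stem: str,
                  excluded: list[str]) -> None:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = "".join(f"# {l}\n" for l in cfg.provenance().splitlines())
    with open(out_dir / f"{stem}_report.tsv", "w") as fh:
        fh.write(header)
        report.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")
    with open(out_dir / f"{stem}_summary.tsv", "w") as fh:
        fh.write(header)
        fh.write("metric\tvalue\n")
        if report.auc is not None:
            fh.write(f"auc_mean_score\t{report.auc:.6f}\n")
            for thr, auc in (report.auc_per_threshold or {}).items():
                fh.write(f"auc_p{thr:g}\t{auc:.6f}\n")
        if report.spearman_r is not None:
            lo, hi = report.spearman_ci95
            fh.write(f"spearman_r\t{report.spearman_r:.6f}\n")
            fh.write(f"spearman_ci_low\t{lo:.6f}\n")
            fh.write(f"spearman_ci_high\t{hi:.6f}\n")
    if excluded:
        with open(out_dir / f"{stem}_excluded.tsv", "w") as fh:
            fh.write(header + "subject_id\treason\n")
            for line in excluded:
                fh.write(line + "\n")


def run_classification(cfg: RunConfig,
                       recordings: dict[str, EEGRecording] | None = None,
                       montage: Montage | None = None,
                       subjects: pd.DataFrame | None = None) -> PredictionReport:
    """PD-vs-HC CPM classification with LOOCV; writes report + summary TSVs.

    Inputs may be passed in memory (tests, simulations); otherwise they are
    loaded from the paths in the config.  Subjects without a recording are
    listed in an exclusion log rather than silently dropped.
    """
    excluded: list[str] = []
    if recordings is None:
        recordings, montage, subjects, excluded = _load_inputs(cfg)
    assert montage is not None and subjects is not None
    profiles = compute_profiles(recordings, montage, cfg)
    present = subjects[subjects["subject_id"].isin(profiles)]
    y = (present.set_index("subject_id")["group"] == "PD").astype(float)
    fm = profiles_to_features({sid: profiles[sid] for sid in present["subject_id"]}, y)
    report = loocv(fm, tuple(cfg.thresholds), family="logistic", mode="group",
                   restrict=cfg.restrict)
    _write_report(report, cfg, "classify", excluded)
    return report


def run_prediction(cfg: RunConfig,
                   recordings: dict[str, EEGRecording] | None = None,
                   montage: Montage | None = None,
                   subjects: pd.DataFrame | None = None) -> PredictionReport:
    """LOOCV prediction of the follow-up score from baseline TBPC profiles.

    Restricted to subjects with a follow-up score present (>= 10 required).
    """
    excluded: list[str] = []
    if recordings is None:
        recordings, montage, subjects, excluded = _load_inputs(cfg)
    assert montage is not None and subjects is not None
    with_fu = subjects[subjects["score_fu"].notna()]
    dropped = subjects[subjects["score_fu"].isna()]
    excluded += [f"{sid}\tno follow-up score" for sid in dropped["subject_id"]]
    if len(with_fu) < 10:
        raise ValueError(f"only {len(with_fu)} subjects with follow-up scores (need >= 10)")
    profiles = compute_profiles(
        {sid: recordings[sid] for sid in with_fu["subject_id"] if sid in recordings},
        montage, cfg)
    present = with_fu[with_fu["subject_id"].isin(profiles)]
    y = present.set_index("subject_id")["score_fu"].astype(float)
    fm = profiles_to_features({sid: profiles[sid] for sid in present["subject_id"]}, y)
    report = loocv(fm, tuple(cfg.thresholds), family="linear", mode="correlation",
                   restrict=cfg.restrict)
    _write_report(report, cfg, "predict", excluded)
    return report
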