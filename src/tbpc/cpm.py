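"""Connectome-based predictive modeling over TBPC profiles.

CPM compresses a high-dimensional connectivity profile into a handful of
network strengths and fits a small regression on those:

1. univariate test of every feature against the outcome on the *training*
   subjects only (Welch t-test for PD/HC, Spearman for a continuous score);
2. keep features with p below a threshold, split by direction of effect
   into a positive (PD > HC, or r > 0) and a negative set per band;
3. z-score features using training mean/SD;
4. average the z-scored selected features into one positive and one negative
   network strength per band (five bands -> ten candidate predictors);
5. fit a logistic (classification) or ordinary least-squares (score
   prediction) regression on the strengths;
6. evaluate out of sample with leave-one-subject-out cross-validation,
   repeating steps 1-5 inside every fold, and average the held-out scores
   over the threshold grid.

Evaluation is ROC/AUC for classification and Spearman rank correlation with
a Fisher-z confidence interval for score prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import TBPCProfile

__all__ = [
    "FeatureMatrix",
    "SelectionMasks",
    "CPMModel",
    "PredictionReport",
    "DEFAULT_THRESHOLDS",
    "profiles_to_features",
    "univariate_select",
    "zscore_fit_apply",
    "network_strengths",
    "strength_names",
    "fit_cpm",
    "predict_cpm",
    "loocv",
    "roc_auc",
    "spearman_ci",
    "fisher_confidence_interval",
]

logger = logging.getLogger(__name__)

#: Feature-selection p-value grid evaluated (and averaged over) by default.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.0001, 0.001, 0.005, 0.01, 0.05)


@dataclass
class FeatureMatrix:
    """Subjects x features block with per-feature band labels and an outcome.

    ``y`` is a binary group indicator (1 = PD, 0 = HC) in classification
    mode or a continuous score in prediction mode.
    """

    X: np.ndarray
    band_of: np.ndarray  # band label per column
    y: np.ndarray
    subject_ids: list[str]
    bands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.band_of = np.asarray(self.band_of)
        self.y = np.asarray(self.y, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        if self.X.shape != (len(self.subject_ids), len(self.band_of)):
            raise ValueError("inconsistent feature-matrix shapes")
        if len(self.y) != len(self.subject_ids):
            raise ValueError("outcome length does not match subject count")
        if not self.bands:
            self.bands = list(dict.fromkeys(self.band_of))
        counts = {b: int((self.band_of == b).sum()) for b in self.bands}
        if len(set(counts.values())) > 1:
            raise ValueError(f"unequal feature count per band: {counts}")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def profiles_to_features(profiles: dict[str, TBPCProfile],
                         y: dict[str, float] | pd.Series) -> FeatureMatrix:
    """Stack per-subject TBPC profiles into a FeatureMatrix.

    All profiles must share bands and pairs (same montage / good-channel
    set); subjects are taken in the order of ``profiles``.
    """
    ids = list(profiles)
    first = profiles[ids[0]]
    for sid in ids[1:]:
        p = profiles[sid]
        if p.bands != first.bands or p.pairs != first.pairs:
            raise ValueError(f"profile for {sid!r} has different bands/pairs")
    X = np.stack([profiles[sid].to_vector() for sid in ids])
    yv = np.array([float(y[sid]) for sid in ids])
    return FeatureMatrix(X, first.feature_bands(), yv, ids, list(first.bands))


# ---------------------------------------------------------------------------
# selection and strengths
# ---------------------------------------------------------------------------

@dataclass
class SelectionMasks:
    """Boolean feature masks split by effect direction, plus the p cutoff."""

    pos: np.ndarray
    neg: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if (self.pos & self.neg).any():
            raise ValueError("a feature cannot be both positive and negative")


def _feature_stats(X: np.ndarray, y: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature p-value and effect direction (+1/-1/0), vectorised.

    Group mode: Welch two-sample t-test, direction = sign(mean PD - mean HC).
    Correlation mode: Spearman r against the outcome, p from the usual
    t-approximation, direction = sign(r).  Constant features get p = 1.
    """
    n, m = X.shape
    if mode == "group":
        g1 = X[y == 1]
        g0 = X[y == 0]
        if len(g1) < 3 or len(g0) < 3:
            raise ValueError("group mode needs at least 3 subjects per group")
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(g1, g0, axis=0, equal_var=False)
        direction = np.sign(g1.mean(axis=0) - g0.mean(axis=0))
    elif mode == "correlation":
        if n < 4:
            raise ValueError("correlation mode needs at least 4 subjects")
        rx = stats.rankdata(X, axis=0)
        ry = stats.rankdata(y)
        rx = rx - rx.mean(axis=0)
        ry = ry - ry.mean()
        denom = np.sqrt((rx ** 2).sum(axis=0) * (ry ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rx * ry[:, None]).sum(axis=0) / denom
            r = np.clip(r, -1.0, 1.0)
            t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        direction = np.sign(r)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    constant = X.std(axis=0) == 0
    if constant.any():
        logger.debug("excluding %d constant feature(s) from selection", constant.sum())
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    direction = np.where(constant, 0.0, direction)
    return p, direction


def univariate_select(X: np.ndarray, y: np.ndarray, threshold: float,
                      mode: str = "group") -> SelectionMasks:
    """Features with univariate p < threshold, split by effect direction."""
    p, direction = _feature_stats(np.asarray(X, float), np.asarray(y, float), mode)
    keep = p < threshold
    return SelectionMasks(keep & (direction > 0), keep & (direction < 0), threshold)


def zscore_fit_apply(X_train: np.ndarray, X_test: np.ndarray,
                     masks: SelectionMasks) -> tuple[np.ndarray, np.ndarray, SelectionMasks]:
    """Standardise both splits with training mean/SD per feature.

    Features with zero training SD are dropped from the masks (they carry no
    training information) and logged.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.atleast_2d(np.asarray(X_test, float))
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    dead = sd == 0
    if (dead & (masks.pos | masks.neg)).any():
        logger.debug("dropping %d zero-SD feature(s) from masks",
                     int((dead & (masks.pos | masks.neg)).sum()))
    masks = SelectionMasks(masks.pos & ~dead, masks.neg & ~dead, masks.threshold)
    sd_safe = np.where(dead, 1.0, sd)
    return (X_train - mu) / sd_safe, (X_test - mu) / sd_safe, masks


def strength_names(bands: list[str]) -> list[str]:
    """Canonical predictor order: <band>_pos, <band>_neg per band."""
    return [f"{b}_{s}" for b in bands for s in ("pos", "neg")]


def network_strengths(Z: np.ndarray, masks: SelectionMasks, band_of: np.ndarray,
                      bands: list[str]) -> np.ndarray:
    """Mean z-scored selected feature per (band, direction): 2 per band.

    An empty mask contributes a strength of exactly 0, keeping the design
    matrix shape fixed across folds and thresholds.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    out = np.zeros((Z.shape[0], 2 * len(bands)))
    for bi, band in enumerate(bands):
        in_band = band_of == band
        for si, mask in enumerate((masks.pos, masks.neg)):
            sel = mask & in_band
            if sel.any():
                out[:, 2 * bi + si] = Z[:, sel].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass
class CPMModel:
    """Fitted regression over network strengths.

    ``coef`` holds the intercept followed by one weight per *used* predictor
    (the ``restrict`` subset of the canonical strength order).
    """

    family: str  # {"logistic", "linear"}
    coef: np.ndarray
    predictor_names: list[str]
    used: np.ndarray  # boolean over the canonical predictors
    regularized: bool = False
    masks: SelectionMasks | None = None


def _restrict_mask(names: list[str], restrict: list[str] | None) -> np.ndarray:
    if restrict is None:
        return np.ones(len(names), dtype=bool)
    unknown = set(restrict) - set(names)
    if unknown:
        raise ValueError(f"unknown predictor(s) {sorted(unknown)}; have {names}")
    return np.array([n in restrict for n in names])


def fit_cpm(strengths: np.ndarray, y: np.ndarray, family: str = "logistic",
            predictor_names: list[str] | None = None,
            restrict: list[str] | None = None) -> CPMModel:
    """Fit logistic (P_PD) or linear (score) regression on network strengths.

    ``restrict`` names a predictor subset (e.g. ``["theta_neg", "delta_pos",
    "beta_pos"]``); others are excluded from the design.  Perfectly separable
    logistic problems fall back to a ridge-penalised fit, which is logged and
    flagged on the returned model.
    """
    S = np.atleast_2d(np.asarray(strengths, float))
    y = np.asarray(y, float)
    names = predictor_names or [f"s{i}" for i in range(S.shape[1])]
    used = _restrict_mask(names, restrict)
    Xd = S[:, used]
    if family == "linear":
        A = np.column_stack([np.ones(len(Xd)), Xd])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return CPMModel("linear", coef, names, used)
    if family != "logistic":
        raise ValueError(f"unknown family {family!r}")

    import statsmodels.api as sm

    # constant columns (e.g. empty masks at strict thresholds) carry no
    # information and make the design singular; fit without them, weight 0
    live = np.ptp(Xd, axis=0) > 0
    Xl = Xd[:, live]
    A = sm.add_constant(Xl, has_constant="add")
    regularized = False
    try:
        if not live.any():
            raise np.linalg.LinAlgError("no informative predictors")
        import warnings as _warnings
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, A).fit(disp=0, maxiter=200)
        fitted = np.asarray(res.params)
        # detect (quasi-)separation: unbounded likelihood blows the weights up
        if not np.isfinite(fitted).all() or np.abs(fitted).max() > 50:
            raise np.linalg.LinAlgError("separation suspected")
    except Exception:
        logger.debug("logistic fit unstable (separation?); ridge fall-back")
        regularized = True
        from sklearn.linear_model import LogisticRegression
        if live.any():
            clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)  # ridge (L2)
            clf.fit(Xl, y)
            fitted = np.r_[clf.intercept_, clf.coef_.ravel()]
        else:
            # no informative predictor: return the uninformative P = 0.5.
            # The training-fold base rate would be anti-correlated with the
            # held-out label under LOOCV (its mean is 0.5 - y/(2n)), which
            # would bias null AUC far below chance at strict thresholds.
            fitted = np.array([0.0])
    coef = np.zeros(Xd.shape[1] + 1)
    coef[0] = fitted[0]
    coef[1:][live] = fitted[1:]
    return CPMModel("logistic", coef, names, used, regularized=regularized)


def predict_cpm(model: CPMModel, strengths: np.ndarray) -> np.ndarray:
    """Predicted P_PD (logistic) or score in outcome units (linear)."""
    S = np.atleast_2d(np.asarray(strengths, float))
    lin = model.coef[0] + S[:, model.used] @ model.coef[1:]
    if model.family == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(lin, -500, 500)))
    return lin


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (ties counted 1/2) plus the ROC curve points (fpr, tpr)."""
    from sklearn.metrics import roc_auc_score, roc_curve
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, fpr, tpr


def fisher_confidence_interval(r: float, n: int, level: float = 0.95
                               ) -> tuple[float, float]:
    """Fisher-z interval for a correlation: tanh(atanh(r) -+ z_crit/sqrt(n-3))."""
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    halfwidth = zcrit / np.sqrt(n - 3)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return float(np.tanh(zr - halfwidth)), float(np.tanh(zr + halfwidth))


def spearman_ci(x: np.ndarray, y: np.ndarray, level: float = 0.95
                ) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Average ranks for ties; see :func:`fisher_confidence_interval`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("spearman_ci needs paired vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined rank correlation")
    r = float(stats.spearmanr(x, y).statistic)
    return r, fisher_confidence_interval(r, len(x), level)


@dataclass
class PredictionReport:
    """LOOCV output: per-subject held-out scores and summary metrics.

    ``scores`` is subjects x thresholds; ``mean_scores`` averages over the
    threshold grid (the per-subject P_PD or predicted score reported).
    """

    subject_ids: list[str]
    thresholds: list[float]
    scores: np.ndarray
    mean_scores: np.ndarray
    y: np.ndarray
    family: str
    auc: float | None = None
    auc_per_threshold: dict[float, float] | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None
    spearman_r: float | None = None
    spearman_ci95: tuple[float, float] | None = None
    aborted_folds: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids, "y": self.y})
        for ti, thr in enumerate(self.thresholds):
            df[f"score_p{thr:g}"] = self.scores[:, ti]
        df["score_mean"] = self.mean_scores
        return df


def loocv(fm: FeatureMatrix, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
          family: str = "logistic", mode: str | None = None,
          restrict: list[str] | None = None) -> PredictionReport:
    """Leave-one-subject-out CPM with all data-dependent steps inside folds.

    For each held-out subject, feature statistics, selection masks, z-scoring
    parameters and the regression are recomputed from the remaining subjects
    only; the held-out score is predicted per threshold and then averaged
    over the grid.  Classification reports ROC/AUC on the averaged scores
    (and per threshold); prediction reports Spearman r with a 95% CI.
    """
    if fm.n_subjects < 10:
        raise ValueError("LOOCV needs at least 10 subjects")
    if mode is None:
        mode = "group" if family == "logistic" else "correlation"
    names = strength_names(fm.bands)
    n = fm.n_subjects
    scores = np.full((n, len(thresholds)), np.nan)
    live = np.zeros((n, len(thresholds)), dtype=bool)
    aborted: list[str] = []

    for i in range(n):
        tr = np.arange(n) != i
        X_tr, y_tr = fm.X[tr], fm.y[tr]
        if mode == "group" and len(np.unique(y_tr)) < 2:
            aborted.append(fm.subject_ids[i])
            continue
        p, direction = _feature_stats(X_tr, y_tr, mode)
        for ti, thr in enumerate(thresholds):
            keep = p < thr
            masks = SelectionMasks(keep & (direction > 0), keep & (direction < 0), thr)
            Z_tr, Z_te, masks = zscore_fit_apply(X_tr, fm.X[i:i + 1], masks)
            S_tr = network_strengths(Z_tr, masks, fm.band_of, fm.bands)
            S_te = network_strengths(Z_te, masks, fm.band_of, fm.bands)
            model = fit_cpm(S_tr, y_tr, family, names, restrict)
            scores[i, ti] = predict_cpm(model, S_te)[0]
            live[i, ti] = bool(np.ptp(S_tr[:, model.used], axis=0).any())

    ok = ~np.isnan(scores).any(axis=1)
    # average only thresholds at which at least one fold had an informative
    # model: a threshold whose every fold is intercept-only carries no signal
    # but, in the linear family, its fold-mean predictions are exactly
    # anti-monotone in the held-out outcome and would poison the average
    live_thr = live.any(axis=0)
    if not live_thr.any():
        live_thr[:] = True
    mean_scores = scores[:, live_thr].mean(axis=1)
    report = PredictionReport(fm.subject_ids, list(thresholds), scores,
                              mean_scores, fm.y, family, aborted_folds=aborted)
    if family == "logistic" and len(np.unique(fm.y[ok])) == 2:
        auc, fpr, tpr = roc_auc(mean_scores[ok], fm.y[ok])
        report.auc = auc
        report.roc = (fpr, tpr)
        report.auc_per_threshold = {
            thr: roc_auc(scores[ok, ti], fm.y[ok])[0]
            for ti, thr in enumerate(thresholds)
        }
    elif family == "linear" and ok.sum() >= 4:
        r, ci = spearman_ci(mean_scores[ok], fm.y[ok])
        report.spearman_r = r
        report.spearman_ci95 = ci
    return report
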