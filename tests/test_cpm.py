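import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbpc.cpm import (DEFAULT_THRESHOLDS, FeatureMatrix, SelectionMasks,
                      fisher_confidence_interval, fit_cpm, loocv,
                      network_strengths, predict_cpm, roc_auc, spearman_ci,
                      strength_names, univariate_select, zscore_fit_apply)

BANDS = ["delta", "theta", "alpha1", "alpha2", "beta"]


def make_fm(n_per_group=20, n_per_band=40, effect_band=None, effect_sd=0.0,
            seed=0, continuous=False):
    """Gaussian feature matrix, optionally with a planted effect in one band
    (group shift, or correlation with a continuous outcome)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    band_of = np.repeat(BANDS, n_per_band)
    X = rng.normal(size=(n, len(band_of)))
    if continuous:
        y = rng.normal(size=n)
    else:
        y = np.r_[np.ones(n_per_group), np.zeros(n_per_group)]
    if effect_band is not None:
        cols = np.nonzero(band_of == effect_band)[0][: n_per_band // 4]
        if continuous:
            X[:, cols] += effect_sd * y[:, None]
        else:
            X[:, cols] += effect_sd * y[:, None]
    ids = [f"s{i:03d}" for i in range(n)]
    return FeatureMatrix(X, band_of, y, ids, BANDS)


class TestUnivariateSelect:
    def test_identical_feature_never_selected(self):
        fm = make_fm(seed=1)
        fm.X[:, 0] = 1.23  # constant
        masks = univariate_select(fm.X, fm.y, 0.999, "group")
        assert not masks.pos[0] and not masks.neg[0]

    def test_threshold_one_selects_every_nonconstant_feature(self):
        fm = make_fm(seed=2)
        fm.X[:, 0] = 0.0
        masks = univariate_select(fm.X, fm.y, 1.0, "group")
        sel = masks.pos | masks.neg
        assert not sel[0] and sel[1:].all()

    def test_five_sd_separation_always_selected(self):
        hits = 0
        for seed in range(50):
            fm = make_fm(n_per_band=10, seed=seed)
            fm.X[fm.y == 1, 0] += 5.0
            masks = univariate_select(fm.X, fm.y, 0.001, "group")
            hits += bool(masks.pos[0])
        assert hits >= 50 * 0.99

    def test_direction_split_is_disjoint_and_correct(self):
        fm = make_fm(seed=3)
        fm.X[fm.y == 1, 0] += 5.0
        fm.X[fm.y == 1, 1] -= 5.0
        masks = univariate_select(fm.X, fm.y, 0.001, "group")
        assert masks.pos[0] and masks.neg[1]
        assert not (masks.pos & masks.neg).any()

    def test_correlation_mode_finds_planted_feature(self):
        fm = make_fm(seed=4, continuous=True)
        fm.X[:, 2] = 2.0 * fm.y + 0.1 * np.random.default_rng(4).normal(size=len(fm.y))
        masks = univariate_select(fm.X, fm.y, 0.001, "correlation")
        assert masks.pos[2]

    def test_group_mode_needs_three_per_group(self):
        fm = make_fm(n_per_group=2, n_per_band=2)
        with pytest.raises(ValueError, match="3 subjects"):
            univariate_select(fm.X, fm.y, 0.05, "group")


class TestZScore:
    def test_training_zscores_are_standardised(self):
        fm = make_fm(seed=5)
        masks = univariate_select(fm.X, fm.y, 1.0, "group")
        Z, Zt, _ = zscore_fit_apply(fm.X, fm.X, masks)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_array_equal(Z, Zt)

    def test_test_subject_at_training_mean_maps_to_zero(self):
        fm = make_fm(seed=6)
        masks = univariate_select(fm.X, fm.y, 1.0, "group")
        _, Zt, _ = zscore_fit_apply(fm.X, fm.X.mean(axis=0)[None, :], masks)
        np.testing.assert_allclose(Zt, 0.0, atol=1e-12)

    def test_affine_shift_contract(self):
        fm = make_fm(seed=7)
        masks = univariate_select(fm.X, fm.y, 1.0, "group")
        _, z0, _ = zscore_fit_apply(fm.X, fm.X[:3], masks)
        _, z1, _ = zscore_fit_apply(fm.X, fm.X[:3] + 2.0, masks)
        sd = fm.X.std(axis=0, ddof=0)
        np.testing.assert_allclose(z1 - z0, np.broadcast_to(2.0 / sd, z0.shape),
                                   rtol=1e-9)

    def test_zero_sd_feature_dropped_from_masks(self):
        fm = make_fm(seed=8)
        fm.X[:, 0] = 5.0
        masks = SelectionMasks(np.eye(1, fm.n_features, 0, dtype=bool).ravel(),
                               np.zeros(fm.n_features, bool), 0.05)
        _, _, out = zscore_fit_apply(fm.X, fm.X, masks)
        assert not out.pos[0]


class TestNetworkStrengths:
    def test_five_bands_give_ten_predictors(self):
        fm = make_fm(seed=9)
        masks = univariate_select(fm.X, fm.y, 1.0, "group")
        Z, _, masks = zscore_fit_apply(fm.X, fm.X, masks)
        S = network_strengths(Z, masks, fm.band_of, fm.bands)
        assert S.shape == (fm.n_subjects, 10)
        assert len(strength_names(fm.bands)) == 10

    def test_all_zero_features_give_zero_strengths(self):
        band_of = np.repeat(BANDS, 2)
        masks = SelectionMasks(np.ones(10, bool), np.zeros(10, bool), 1.0)
        S = network_strengths(np.zeros((4, 10)), masks, band_of, BANDS)
        np.testing.assert_array_equal(S, 0.0)

    def test_singleton_mask_passes_value_through(self):
        band_of = np.repeat(BANDS, 2)
        pos = np.zeros(10, bool)
        pos[2] = True  # a theta feature
        masks = SelectionMasks(pos, np.zeros(10, bool), 1.0)
        Z = np.zeros((1, 10))
        Z[0, 2] = 2.0
        S = network_strengths(Z, masks, band_of, BANDS)
        assert S[0, strength_names(BANDS).index("theta_pos")] == 2.0

    def test_empty_mask_contributes_zero(self):
        band_of = np.repeat(BANDS, 2)
        masks = SelectionMasks(np.zeros(10, bool), np.zeros(10, bool), 0.001)
        S = network_strengths(np.random.default_rng(0).normal(size=(3, 10)),
                              masks, band_of, BANDS)
        np.testing.assert_array_equal(S, 0.0)


class TestFitPredict:
    def test_separable_strengths_give_training_auc_one(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        S = np.zeros((20, 10))
        S[:, 0] = np.r_[np.ones(10), -np.ones(10)]
        model = fit_cpm(S, y, "logistic", strength_names(BANDS))
        auc, *_ = roc_auc(predict_cpm(model, S), y)
        assert auc == 1.0

    def test_permuted_labels_training_auc_shows_only_fitting_optimism(self):
        """With permuted labels the only signal a training-set AUC can show
        is in-sample fitting optimism, which for k predictors scales like
        sqrt(k/n); at k=4, n=60 that is ~0.64, and importantly it vanishes
        out of sample (the LOOCV permutation tests)."""
        rng = np.random.default_rng(10)
        S = rng.normal(size=(60, 4))
        y = np.r_[np.ones(30), np.zeros(30)]
        aucs = []
        for _ in range(200):
            yp = rng.permutation(y)
            model = fit_cpm(S, yp, "logistic")
            aucs.append(roc_auc(predict_cpm(model, S), yp)[0])
        assert 0.5 <= np.mean(aucs) < 0.75
        # a single noise predictor has far less room to overfit
        aucs1 = []
        for _ in range(200):
            yp = rng.permutation(y)
            model = fit_cpm(S[:, :1], yp, "logistic")
            aucs1.append(roc_auc(predict_cpm(model, S[:, :1]), yp)[0])
        assert np.mean(aucs1) < np.mean(aucs)

    def test_linear_family_recovers_noiseless_outcome(self):
        rng = np.random.default_rng(11)
        S = rng.normal(size=(30, 5))
        beta = np.array([2.0, -1.0, 0.5, 0.0, 3.0])
        y = 1.5 + S @ beta
        model = fit_cpm(S, y, "linear")
        np.testing.assert_allclose(predict_cpm(model, S), y, rtol=1e-9)

    def test_restriction_uses_named_subset_only(self):
        rng = np.random.default_rng(12)
        S = rng.normal(size=(40, 10))
        y = (S[:, 3] > 0).astype(float)  # theta_neg informative
        names = strength_names(BANDS)
        model = fit_cpm(S, y, "logistic", names, restrict=["delta_pos"])
        assert model.used.sum() == 1
        # predictions ignore the excluded informative column entirely
        S2 = S.copy()
        S2[:, 3] += 100.0
        np.testing.assert_array_equal(predict_cpm(model, S),
                                      predict_cpm(model, S2))

    def test_unknown_restriction_rejected(self):
        with pytest.raises(ValueError, match="unknown predictor"):
            fit_cpm(np.zeros((10, 10)), np.r_[np.ones(5), np.zeros(5)],
                    "logistic", strength_names(BANDS), restrict=["gamma_pos"])


class TestROCAUC:
    def test_perfectly_ordered_scores(self):
        auc, *_ = roc_auc(np.arange(10, dtype=float), np.r_[np.zeros(5), np.ones(5)])
        assert auc == 1.0

    def test_all_equal_scores_give_half(self):
        auc, *_ = roc_auc(np.ones(10), np.r_[np.zeros(5), np.ones(5)])
        assert auc == 0.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 50))
        n0 = int(rng.integers(2, 50))
        scores = np.round(rng.normal(size=n1 + n0), 1)  # force some ties
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, labels)[0] == pytest.approx(conc / (n1 * n0), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(5.0), np.ones(5))


class TestSpearmanCI:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        r, _ = spearman_ci(x, x ** 3)
        assert r == pytest.approx(1.0)
        r, _ = spearman_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_fisher_interval_matches_closed_form(self):
        r, (lo, hi) = spearman_ci(np.arange(20.0),
                                  np.arange(20.0) + np.random.default_rng(1).normal(0, 5, 20))
        zr = np.arctanh(r)
        se = 1 / np.sqrt(20 - 3)
        assert lo == pytest.approx(np.tanh(zr - 1.959963985 * se))
        assert hi == pytest.approx(np.tanh(zr + 1.959963985 * se))

    def test_fisher_ci_at_published_operating_point(self):
        lo, hi = fisher_confidence_interval(-0.41, 54)
        assert round(lo, 2) == -0.61
        assert round(hi, 2) == -0.16

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci(np.ones(10), np.arange(10.0))


class TestLOOCV:
    def test_one_heldout_score_per_subject(self):
        fm = make_fm(n_per_group=8, n_per_band=10, seed=13)
        rep = loocv(fm, thresholds=(0.01, 0.05), family="logistic")
        assert len(rep.mean_scores) == fm.n_subjects
        assert rep.scores.shape == (fm.n_subjects, 2)
        assert np.isfinite(rep.mean_scores).all()
        assert ((rep.mean_scores >= 0) & (rep.mean_scores <= 1)).all()

    def test_no_leakage_under_label_permutation(self):
        """Permuted outcomes must never give above-chance held-out AUC: any
        systematic excess means selection leaked outside the folds.  (LOOCV
        with in-fold selection is actually *pessimistically* biased on pure
        noise — training-fold selections anti-match the held-out subject —
        so the distribution sits at or below 0.5, never above.)"""
        rng = np.random.default_rng(14)
        aucs = []
        for rep_i in range(20):
            fm = make_fm(n_per_group=20, n_per_band=40, seed=100 + rep_i)
            fm.y[:] = rng.permutation(fm.y)
            aucs.append(loocv(fm, family="logistic").auc)
        assert np.median(aucs) <= 0.55
        assert np.mean(aucs) <= 0.55

    def test_planted_group_effect_is_recovered(self):
        """A 2-SD shift on a quarter of the theta features should push
        held-out AUC near 1 and concentrate selection in theta."""
        aucs = []
        frac = []
        for seed in range(20):
            fm = make_fm(n_per_group=20, n_per_band=40, effect_band="theta",
                         effect_sd=2.0, seed=200 + seed)
            rep = loocv(fm, family="logistic")
            aucs.append(rep.auc)
            masks = univariate_select(fm.X, fm.y, 0.01, "group")
            sel = masks.pos | masks.neg
            frac.append((fm.band_of[sel] == "theta").mean())
        assert np.median(aucs) >= 0.9
        assert np.median(frac) > 0.8

    def test_restriction_preserves_subject_count_and_order(self):
        fm = make_fm(n_per_group=10, n_per_band=10, effect_band="theta",
                     effect_sd=2.0, seed=15)
        full = loocv(fm, thresholds=(0.05,), family="logistic")
        restricted = loocv(fm, thresholds=(0.05,), family="logistic",
                           restrict=["theta_pos", "theta_neg"])
        assert full.subject_ids == restricted.subject_ids
        assert len(full.mean_scores) == len(restricted.mean_scores)

    def test_band_restriction_prefers_informative_band(self):
        """theta-restricted prediction should do at least as well as the
        all-band model when the outcome correlation lives in theta."""
        diffs = []
        for seed in range(12):
            fm = make_fm(n_per_group=20, n_per_band=40, effect_band="theta",
                         effect_sd=1.0, seed=300 + seed, continuous=True)
            all_r = loocv(fm, family="linear", mode="correlation").spearman_r
            th_r = loocv(fm, family="linear", mode="correlation",
                         restrict=["theta_pos", "theta_neg"]).spearman_r
            diffs.append(th_r - all_r)
        assert np.median(diffs) >= -0.05

    def test_fewer_than_ten_subjects_rejected(self):
        fm = make_fm(n_per_group=4, n_per_band=4)
        with pytest.raises(ValueError, match="10 subjects"):
            loocv(fm)
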