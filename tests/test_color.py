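import colorsys
import warnings

import numpy as np
import pytest

from otoaudit.color import (
    CollinearityError,
    SeparationWarning,
    color_audit,
    fit_logistic,
    hsv_stats,
    odds_ratios,
    rgb_to_hsv_channels,
)
from otoaudit.roc import auc_mann_whitney
from conftest import provider_for


def _uniform(r, g, b, shape=(8, 8)):
    return np.full(shape + (3,), (r, g, b), dtype=np.uint8)


class TestHsvStats:
    @pytest.mark.parametrize(
        "img,expected",
        [
            (_uniform(255, 0, 0), (0, 0, 255, 0, 255, 0)),
            (_uniform(128, 128, 128), (0, 0, 0, 0, 128, 0)),
        ],
    )
    def test_uniform_closed_forms(self, img, expected):
        fv = hsv_stats(img)
        got = (fv.hue_mean, fv.hue_std, fv.sat_mean, fv.sat_std, fv.val_mean, fv.val_std)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_half_red_half_green(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:4, :, 0] = 255
        img[4:, :, 1] = 255
        fv = hsv_stats(img)
        # hues {0, 120} in equal number: linear mean 60, population std 60
        assert fv.hue_mean == pytest.approx(60.0)
        assert fv.hue_std == pytest.approx(60.0)
        assert (fv.sat_mean, fv.sat_std) == (255.0, 0.0)
        assert (fv.val_mean, fv.val_std) == (255.0, 0.0)

    def test_matches_colorsys_on_random_colors(self):
        rng = np.random.default_rng(0)
        cols = rng.integers(0, 256, (1000, 3)).astype(np.uint8)
        h, s, v = rgb_to_hsv_channels(cols.reshape(1, -1, 3))
        for i, (r, g, b) in enumerate(cols):
            hh, ss, vv = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
            assert h[0, i] == pytest.approx((hh * 360) % 360, abs=1e-9)
            assert s[0, i] == pytest.approx(ss * 255, abs=1e-9)
            assert v[0, i] == pytest.approx(vv * 255, abs=1e-9)

    def test_mask_restricts_statistics(self):
        img = _uniform(10, 10, 10, (8, 8)).copy()
        img[:4] = (200, 0, 0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        fv = hsv_stats(img, pixel_mask=mask)
        assert fv.val_mean == 200.0
        assert fv.val_std == 0.0

    def test_empty_mask_rejected(self, sample_image):
        with pytest.raises(ValueError, match="no pixels"):
            hsv_stats(sample_image, pixel_mask=np.zeros(sample_image.shape[:2], bool))


class TestFitLogistic:
    def test_symmetric_feature_gives_null_association(self):
        x = np.array([-1.0, 1.0] * 20)[:, None]
        y = np.array([0, 0, 1, 1] * 10)
        model = fit_logistic(x, y)
        assert model.converged
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert odds_ratios(model)[0].odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_matches_newton_oracle_on_random_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 5:
            X = rng.normal(0, 1, (50, 3)) * np.array([1.0, 10.0, 100.0])
            beta = rng.normal(0, 0.5, 3) / np.array([1.0, 10.0, 100.0])
            y = (rng.random(50) < 1 / (1 + np.exp(-(0.3 + X @ beta)))).astype(int)
            if y.sum() in (0, 50):
                continue
            model = fit_logistic(X, y)
            ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-10)
            assert model.intercept == pytest.approx(ref.params[0], abs=1e-6)
            np.testing.assert_allclose(model.coefficients, ref.params[1:], atol=1e-6)
            ci_ref = np.exp(ref.conf_int())
            for i, row in enumerate(odds_ratios(model)):
                assert row.ci_low == pytest.approx(ci_ref[i + 1][0], rel=1e-6)
                assert row.ci_high == pytest.approx(ci_ref[i + 1][1], rel=1e-6)
            checked += 1

    def test_separation_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        with pytest.warns(SeparationWarning):
            model = fit_logistic(x[:, None], (x > 0).astype(int))
        assert not model.converged
        with pytest.raises(ValueError, match="non-converged"):
            odds_ratios(model)

    def test_collinear_features_named(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        with pytest.raises(CollinearityError, match="sat"):
            fit_logistic(X, y, feature_names=("sat_a", "sat_b"))

    def test_loglik_never_decreases(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (80, 4))
        y = (rng.random(80) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        model = fit_logistic(X, y)
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-10).all()
        # final gradient essentially zero
        from scipy.special import expit

        Xd = np.column_stack([np.ones(80), X])
        beta = np.r_[model.intercept, model.coefficients]
        grad = Xd.T @ (y - expit(Xd @ beta))
        assert np.linalg.norm(grad) < 1e-6


class TestOddsRatios:
    def test_closed_form_null_feature(self):
        # beta = 0, SE = 0.5 -> OR 1, CI = exp(+/- z*0.5)
        from otoaudit.color import LogisticModel
        from scipy.stats import norm

        cov = np.diag([0.1, 0.25])
        model = LogisticModel(
            feature_names=("f",),
            coefficients=np.array([0.0]),
            intercept=0.0,
            covariance=cov,
            converged=True,
            n_iterations=3,
        )
        row = odds_ratios(model)[0]
        z = norm.ppf(0.975)
        assert row.odds_ratio == 1.0
        assert row.ci_low == pytest.approx(np.exp(-z * 0.5))
        assert row.ci_high == pytest.approx(np.exp(z * 0.5))
        assert (row.ci_low, row.ci_high) == pytest.approx((0.375, 2.664), abs=5e-3)

    def test_vanishing_se_collapses_ci(self):
        from otoaudit.color import LogisticModel

        model = LogisticModel(
            feature_names=("f",),
            coefficients=np.array([np.log(2.0)]),
            intercept=0.0,
            covariance=np.diag([0.1, 1e-20]),
            converged=True,
            n_iterations=3,
        )
        row = odds_ratios(model)[0]
        assert row.odds_ratio == pytest.approx(2.0)
        assert row.ci_low == pytest.approx(2.0, abs=1e-6)
        assert row.ci_high == pytest.approx(2.0, abs=1e-6)

    def test_wald_ci_coverage(self):
        """95% Wald CI covers the true odds ratio at close to nominal rate."""
        rng = np.random.default_rng(17)
        true_beta = 0.8
        covered = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0, 1, 200)
            y = (rng.random(200) < 1 / (1 + np.exp(-(0.2 + true_beta * x)))).astype(int)
            model = fit_logistic(x[:, None], y)
            row = odds_ratios(model)[0]
            covered += row.ci_low <= np.exp(true_beta) <= row.ci_high
        assert 0.93 <= covered / reps <= 0.97


class TestColorAudit:
    def test_planted_saturation_bias_recovered(self, small_biased_dataset):
        manifest, _, images = small_biased_dataset
        res = color_audit(
            manifest, feature_set="sat_std_only",
            image_provider=provider_for(manifest, images),
        )
        internal = res.auc_rows[0]
        assert internal["eval_set"] == "internal_val"
        assert internal["auc"] >= 0.8
        assert res.odds_ratio_rows[0].odds_ratio > 1.0
        assert res.odds_ratio_rows[0].p_value < 0.01

    def test_hsv6_emits_six_odds_ratio_rows(self, small_biased_dataset):
        manifest, _, images = small_biased_dataset
        res = color_audit(
            manifest, feature_set="hsv6",
            image_provider=provider_for(manifest, images),
        )
        assert [r.feature for r in res.odds_ratio_rows] == [
            "hue_mean", "hue_std", "sat_mean", "sat_std", "val_mean", "val_std",
        ]

    def test_one_class_eval_reported_not_raised(self, small_biased_dataset):
        from otoaudit.data_model import Manifest

        manifest, _, images = small_biased_dataset
        one_class = Manifest(
            records=tuple(r for r in manifest.records if r.label == 1)[:10],
            dataset_id="oneclass",
        )
        res = color_audit(
            manifest, [one_class], feature_set="sat_std_only",
            image_provider=provider_for(manifest, images),
        )
        bad = [r for r in res.auc_rows if r["eval_set"] == "oneclass"][0]
        assert "error" in bad and "auc" not in bad

    def test_label_permutation_centres_on_chance(self, small_biased_dataset):
        """Permuting labels destroys the planted association."""
        from dataclasses import replace

        from otoaudit.data_model import Manifest

        manifest, _, images = small_biased_dataset
        provider = provider_for(manifest, images)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(10):
            labels = np.array([r.label for r in manifest.records])
            rng.shuffle(labels)
            permuted = Manifest(
                records=tuple(
                    replace(r, label=int(lab))
                    for r, lab in zip(manifest.records, labels)
                ),
                dataset_id=manifest.dataset_id,
            )
            try:
                res = color_audit(
                    permuted, feature_set="sat_std_only", image_provider=provider
                )
            except ValueError:
                continue
            aucs.append(res.auc_rows[0]["auc"])
        assert 0.4 < np.mean(aucs) < 0.6
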