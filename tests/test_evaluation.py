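import numpy as np
import pandas as pd
import pytest
from scipy import stats

import leapd
from leapd.evaluation import (
    BANDS,
    CVScheme,
    band_powers,
    classification_metrics,
    compare_dependent_correlations,
    cross_validate,
    randomization_test,
    regression_linear_quadratic,
    roc_auc,
    spearman_partial,
    spectral_baselines,
)
from leapd.preprocess import Band
from leapd.training import IMPAIRED, NORMAL, TrainingSettings

TINY = TrainingSettings(grid=[(Band(4, 14), 6, 2, 2)], n_electrodes=2)


class TestSpearmanPartial:
    def test_identical_ranks_give_one(self, rng):
        x = rng.normal(size=12)
        y = np.argsort(np.argsort(x)).astype(float)  # same ranks as x
        rho, p = spearman_partial(x, y, rng.normal(size=12))
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, rng):
        x = rng.normal(size=12)
        rho, _ = spearman_partial(x, -x, rng.normal(size=12))
        assert rho == pytest.approx(-1.0)

    def test_matches_explicit_formula(self, rng):
        for _ in range(25):
            x, y, z = rng.normal(size=(3, 10))
            rho, _ = spearman_partial(x, y, z)
            rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
            r = lambda a, b: stats.pearsonr(a, b).statistic
            expect = (r(rx, ry) - r(rx, rz) * r(ry, rz)) / np.sqrt(
                (1 - r(rx, rz) ** 2) * (1 - r(ry, rz) ** 2)
            )
            assert rho == pytest.approx(expect, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, z = rng.normal(size=(3, 30))
        rho, p = spearman_partial(x, y, z)
        out = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman",
        )
        assert rho == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), rel=1e-6)

    def test_constant_inputs_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError):
            spearman_partial(np.ones(10), x, x)
        with pytest.raises(ValueError):
            spearman_partial(x, x, np.ones(10))


class TestDependentCorrelations:
    def test_identical_predictors_give_zero(self, rng):
        x = rng.normal(size=20)
        assert compare_dependent_correlations(x, x.copy(), rng.normal(size=20)) == 0.0

    def test_matches_published_formula(self, rng):
        x1, x2, y = rng.normal(size=(3, 40))
        x2 = x2 + 0.5 * x1
        z = compare_dependent_correlations(x1, x2, y)
        r1 = stats.pearsonr(x1, y).statistic
        r2 = stats.pearsonr(x2, y).statistic
        r12 = stats.pearsonr(x1, x2).statistic
        rbar2 = (r1**2 + r2**2) / 2
        f = min((1 - r12) / (2 * (1 - rbar2)), 1.0)
        h = (1 - f * rbar2) / (1 - rbar2)
        expect = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt(
            (40 - 3) / (2 * (1 - r12) * h)
        )
        assert z == pytest.approx(expect, abs=1e-8)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_dependent_correlations(*rng.normal(size=(3, 9)))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_pairwise_example(self):
        auc, _ = roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == 0.75

    def test_label_flip_symmetry(self, rng):
        s = rng.normal(size=30)
        lab = rng.integers(0, 2, 30).astype(bool)
        lab[:2] = [True, False]
        a1, _ = roc_auc(s, lab)
        a2, _ = roc_auc(s, ~lab)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            s = np.round(rng.normal(size=n), 1)  # ties likely
            lab = rng.integers(0, 2, n).astype(bool)
            if lab.all() or not lab.any():
                continue
            auc, _ = roc_auc(s, lab)
            pos, neg = s[lab], s[~lab]
            brute = np.mean([
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            ])
            assert auc == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestClassificationMetrics:
    def test_arithmetic(self):
        truth = [IMPAIRED, IMPAIRED, NORMAL, NORMAL]
        pred = [IMPAIRED, IMPAIRED, NORMAL, IMPAIRED]
        m = classification_metrics(pred, truth, [0.1, 0.2, 0.9, 0.4])
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 50.0
        assert m["accuracy"] == 75.0
        assert m["confusion"].sum() == 4

    def test_all_correct(self):
        truth = [IMPAIRED, NORMAL, NORMAL]
        m = classification_metrics(truth, truth, [0.1, 0.8, 0.9])
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 100.0

    def test_exact_ranksum_p(self):
        truth = [NORMAL] * 3 + [IMPAIRED] * 3
        scores = [0.9, 0.85, 0.8, 0.1, 0.15, 0.2]
        m = classification_metrics(
            np.where(np.array(scores) > 0.5, NORMAL, IMPAIRED), truth, scores
        )
        assert m["ranksum_p"] == pytest.approx(0.1, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([NORMAL], [NORMAL, IMPAIRED], [0.5, 0.4])


class TestRegression:
    def test_pure_quadratic(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        fit1, fit2, _ = regression_linear_quadratic(x, x**2)
        assert fit2.rsquared == pytest.approx(1.0, abs=1e-10)
        assert fit1.rsquared == pytest.approx(0.0, abs=1e-10)

    def test_linear_data_has_no_quadratic_term(self, rng):
        x = rng.normal(size=40)
        y = 2.0 * x + 1.0 + 0.01 * rng.normal(size=40)
        _, fit2, lr_p = regression_linear_quadratic(x, y)
        assert abs(fit2.params[2]) < 0.01
        assert lr_p > 0.01

    def test_r2_matches_residual_oracle(self, rng):
        x, y = rng.normal(size=(2, 20))
        fit1, fit2, _ = regression_linear_quadratic(x, y)
        for fit, deg in ((fit1, 1), (fit2, 2)):
            coef = np.polyfit(x, y, deg)
            sse = np.sum((y - np.polyval(coef, x)) ** 2)
            sst = np.sum((y - y.mean()) ** 2)
            assert fit.rsquared == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            regression_linear_quadratic(np.ones(10), np.arange(10.0))


@pytest.fixture(scope="module")
def mini_ds():
    spec = leapd.SyntheticSpec(n_subjects=20, duration=10.0, seed=5)
    return leapd.generate_cohort(spec).to_dataset()


class TestCrossValidate:
    def test_loocv_covers_every_subject_once(self, mini_ds):
        res = cross_validate(mini_ds, settings=TINY)
        df = res.report.indices
        assert len(df) == 20 and df["index"].notna().all()
        assert set(df["id"]) == set(mini_ds.ids)

    def test_kfold_partition(self, mini_ds):
        res = cross_validate(
            mini_ds, settings=TINY, scheme=CVScheme("kfold", k=5, repeats=2)
        )
        assert len(res.reports) == 2
        for r in res.reports:
            assert r.indices["index"].notna().all()

    def test_balanced_subsampling_equalizes_classes(self, mini_ds):
        res = cross_validate(mini_ds, settings=TINY, balanced=True)
        counts = res.report.indices["truth"].value_counts()
        assert counts[NORMAL] == counts[IMPAIRED]

    def test_metrics_consistent_with_confusion(self, mini_ds):
        r = cross_validate(mini_ds, settings=TINY).report
        cm = r.confusion
        assert cm.sum() == len(r.indices)
        assert r.accuracy == pytest.approx(100.0 * np.trace(cm) / cm.sum())


class TestRandomization:
    def test_shuffle_preserves_score_multiset_and_determinism(self, mini_ds):
        t1 = randomization_test(mini_ds, settings=TINY, n_shuffles=2, seed=4)
        t2 = randomization_test(mini_ds, settings=TINY, n_shuffles=2, seed=4)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 2


class TestSpectralBaselines:
    def test_band_edges(self):
        assert BANDS == {
            "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0), "gamma": (31.0, 100.0),
        }

    def test_pure_alpha_tone(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t) + 1e-6 * np.random.default_rng(0).normal(
            size=5000
        )
        bp = band_powers(x, 500.0)
        assert bp["alpha"] == max(bp[b] for b in BANDS)
        assert bp["alpha_theta_ratio"] > 0

    def test_theta_tone_flips_ratio(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 6.0 * t) + 1e-6 * np.random.default_rng(0).normal(
            size=5000
        )
        assert band_powers(x, 500.0)["alpha_theta_ratio"] < 0

    def test_summary_structure(self, mini_ds):
        summary, feats = spectral_baselines(mini_ds)
        assert {"channel", "feature", "rho", "rho_p", "auc"} <= set(summary.columns)
        assert set(summary["feature"]) <= set(BANDS) | {"alpha_theta_ratio"}
        assert len(feats) == 20 * 16
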