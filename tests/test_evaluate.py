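"""Evaluation statistics: errors, confusion metrics, ICC, ANOVA, folds."""

import numpy as np
import pytest

from aclloc import evaluate as ev
from aclloc.phantom import make_dataset
from aclloc.pipeline import oracle_fit_predict

TABLE_3D = [[37, 9, 0], [6, 25, 2], [0, 1, 5]]


class TestErrors:
    def test_three_four_five(self):
        assert ev.euclidean_error((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_identical_points(self):
        assert ev.euclidean_error((1, 2, 3), (1, 2, 3)) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 3))
            assert ev.euclidean_error(a, b) == pytest.approx(ev.euclidean_error(b, a))

    @pytest.mark.parametrize(
        "error,expected", [(10.1, True), (9.9, False), (10.0, False)]
    )
    def test_failure_strictly_above_threshold(self, error, expected):
        assert ev.failure_flag(error) is expected

    def test_localization_stats_error_rate(self):
        errors = [1.0] * 82 + [11.0, 12.0, 15.0]
        stats = ev.localization_stats(errors)
        assert stats.failures == 3
        assert stats.error_rate == pytest.approx(3 / 85)

    def test_localization_stats_hand_arithmetic(self):
        stats = ev.localization_stats([1.0, 2.0, 3.0])
        assert stats.mean == pytest.approx(2.0)
        assert stats.sd == pytest.approx(1.0)  # sample sd
        assert stats.failures == 0

    def test_all_zero(self):
        stats = ev.localization_stats([0.0, 0.0, 0.0])
        assert stats.mean == 0.0 and stats.sd == 0.0 and stats.error_rate == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.localization_stats([])


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        sides = ["femoral", "middle", "tibial", "middle", "femoral"]
        cm = ev.confusion(sides, sides)
        assert np.trace(cm.counts) == 5
        assert cm.counts.sum() == 5

    def test_single_misclassification(self):
        cm = ev.confusion(["middle"], ["femoral"])
        assert cm.counts[1, 0] == 1

    def test_column_sums_of_study_matrix(self):
        """The 3D-CNN matrix columns sum to the true class sizes 43/35/7."""
        cm = ev.ConfusionMatrix3(np.array(TABLE_3D))
        np.testing.assert_array_equal(cm.counts.sum(axis=0), [43, 35, 7])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.confusion(["femoral"], ["femoral", "middle"])


class TestClassMetrics:
    def test_study_3d_matrix(self):
        report = ev.class_metrics(ev.ConfusionMatrix3(np.array(TABLE_3D)))
        assert report.per_class["femoral"]["sensitivity"] == pytest.approx(37 / 43)
        assert report.overall_accuracy == pytest.approx(67 / 85)

    def test_perfect_matrix(self):
        report = ev.class_metrics(ev.ConfusionMatrix3(np.diag([10, 10, 10])))
        for side in ("femoral", "middle", "tibial"):
            for metric in ("sensitivity", "specificity", "precision", "f1"):
                assert report.per_class[side][metric] == 1.0
        assert report.overall_accuracy == 1.0

    def test_tibial_f1_study_2d_matrix(self):
        cm = ev.ConfusionMatrix3(np.array([[28, 10, 1], [13, 23, 5], [2, 2, 1]]))
        report = ev.class_metrics(cm)
        assert report.per_class["tibial"]["f1"] == pytest.approx(1 / 6, abs=1e-9)

    def test_undefined_metrics_are_nan_not_zero(self):
        # never predicts tibial and no true tibial cases
        cm = ev.ConfusionMatrix3(np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]]))
        report = ev.class_metrics(cm)
        assert np.isnan(report.per_class["tibial"]["sensitivity"])
        assert np.isnan(report.per_class["tibial"]["precision"])

    def test_f1_equals_harmonic_mean_identity(self):
        """TP/(TP+0.5(FP+FN)) == 2PR/(P+R) wherever both are defined."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            counts = rng.integers(0, 30, (3, 3))
            if counts.sum() == 0:
                continue
            report = ev.class_metrics(ev.ConfusionMatrix3(counts))
            for side in ("femoral", "middle", "tibial"):
                m = report.per_class[side]
                p, r, f1 = m["precision"], m["sensitivity"], m["f1"]
                if np.isnan(p) or np.isnan(r) or (p + r) == 0:
                    continue
                assert f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)
            checked += 1

    def test_accuracy_invariant_under_class_permutation(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 20, (3, 3))
        base = ev.class_metrics(ev.ConfusionMatrix3(counts)).overall_accuracy
        perm = np.array([2, 0, 1])
        permuted = counts[np.ix_(perm, perm)]
        assert ev.class_metrics(ev.ConfusionMatrix3(permuted)).overall_accuracy == pytest.approx(base)


class TestIcc:
    def _brute_force_icc21(self, x):
        """Explicit two-way ANOVA sums-of-squares oracle."""
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    def test_perfect_agreement(self):
        x = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        res = ev.icc_single_absolute(x)
        assert res.icc == pytest.approx(1.0)

    def test_fixed_matrix_matches_brute_force(self):
        x = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]], dtype=float
        )
        res = ev.icc_single_absolute(x)
        assert res.icc == pytest.approx(self._brute_force_icc21(x), abs=1e-9)

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            x = rng.normal(size=(rng.integers(3, 12), rng.integers(2, 5)))
            res = ev.icc_single_absolute(x)
            assert res.icc == pytest.approx(self._brute_force_icc21(x), abs=1e-9)

    def test_matches_pingouin(self):
        """Cross-check estimate and CI against an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        res = ev.icc_single_absolute(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        icc_tab = pingouin.intraclass_corr(long, "subject", "rater", "score")
        ci_col = "CI95%" if "CI95%" in icc_tab.columns else "CI95"
        mask = icc_tab["Type"].isin(["ICC2", "ICC(A,1)"])
        row = icc_tab[mask].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-6)
        np.testing.assert_allclose(res.ci95, list(row[ci_col]), atol=0.02)

    def test_pure_noise_icc_near_zero(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=(200, 3))
        res = ev.icc_single_absolute(x)
        assert abs(res.icc) < 0.1

    def test_degenerate_flagged(self):
        res = ev.icc_single_absolute(np.full((5, 3), 2.0))
        assert not res.defined and np.isnan(res.icc)


class TestAnova:
    def test_identical_groups(self):
        f, p = ev.anova_oneway([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_clear_separation(self):
        rng = np.random.default_rng(1)
        a = np.zeros(4) + rng.normal(0, 1e-6, 4)
        b = np.ones(4) + rng.normal(0, 1e-6, 4)
        _, p = ev.anova_oneway(a, b)
        assert p < 1e-6

    def test_matches_explicit_sums_of_squares(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=6), rng.normal(1.0, 1.0, 8), rng.normal(size=5)]
        f, _ = ev.anova_oneway(*groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = len(groups), sum(len(g) for g in groups)
        f_oracle = (ssb / (k - 1)) / (ssw / (n - k))
        assert f == pytest.approx(f_oracle, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ev.anova_oneway([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            ev.anova_oneway([1.0], [2.0, 3.0])


class TestFolds:
    def test_85_cases_five_folds_of_17(self):
        ids = [f"c{i}" for i in range(85)]
        split = ev.fivefold_split(ids, k=5, seed=3)
        sizes = [len(split.fold_ids(f)) for f in range(5)]
        assert sizes == [17, 17, 17, 17, 17]

    def test_partition_properties(self):
        ids = [f"c{i}" for i in range(23)]
        split = ev.fivefold_split(ids, k=5, seed=1)
        folds = [set(split.fold_ids(f)) for f in range(5)]
        assert set().union(*folds) == set(ids)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not folds[i] & folds[j]
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(20)]
        assert ev.fivefold_split(ids, 5, seed=7).assignments == ev.fivefold_split(
            ids, 5, seed=7
        ).assignments

    def test_stratified_balances_sides(self):
        ids = [f"c{i}" for i in range(20)]
        sides = ["femoral"] * 10 + ["middle"] * 10
        split = ev.fivefold_split(ids, k=5, seed=2, stratify=sides)
        for f in range(5):
            fold = split.fold_ids(f)
            fem = sum(1 for cid in fold if int(cid[1:]) < 10)
            assert fem == 2

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ev.fivefold_split(["a", "b"], k=5, seed=0)


class TestCrossValidate:
    def test_exact_oracle_full_marks(self, small_spec):
        """A perfect localizer scores zero pooled error and accuracy 1.0."""
        cases = make_dataset(10, small_spec, seed=17)
        exact = lambda tr, te: [c.gt.rupture_point for c in te]  # noqa: E731
        result = ev.cross_validate(cases, exact, k=5, seed=17)
        assert result.pooled_stats.mean == 0.0
        assert result.pooled_stats.error_rate == 0.0
        assert result.metrics.overall_accuracy == 1.0
        assert len(result.fold_stats) == 5

    def test_decoding_oracle_subvoxel(self, small_spec):
        """The decoding oracle stays far under the 10 mm failure bar."""
        cases = make_dataset(10, small_spec, seed=17)
        result = ev.cross_validate(cases, oracle_fit_predict, k=5, seed=17)
        assert result.pooled_stats.error_rate == 0.0
        assert result.pooled_stats.mean < 0.5 * 3.0

    def test_leave_one_out_structure(self, small_spec):
        cases = make_dataset(5, small_spec, seed=19)
        result = ev.cross_validate(cases, oracle_fit_predict, k=5, seed=19)
        assert [len(result.split.fold_ids(f)) for f in range(5)] == [1] * 5

    def test_fold_failure_recorded(self, small_spec):
        cases = make_dataset(6, small_spec, seed=23)
        calls = {"n": 0}

        def flaky(train_cases, test_cases):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("synthetic training failure")
            return oracle_fit_predict(train_cases, test_cases)

        result = ev.cross_validate(cases, flaky, k=3, seed=23)
        assert len(result.fold_failures) == 1
        assert len(result.fold_stats) == 2


def test_format_p():
    assert ev.format_p(0.004) == "<0.01"
    assert ev.format_p(0.0321) == "0.0321"
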