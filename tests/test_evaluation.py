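import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from omicsnmf.evaluation import (
    CoxConfig,
    PhenotypeLabels,
    SurvivalData,
    baseline_knn_impute,
    baseline_mean_impute,
    baseline_regression_impute,
    compare_methods,
    cox_fit,
    logrank_pvalue,
    median_risk_split,
    overall_auc,
    prognostic_index,
    test_set_auc as imputed_test_auc,
    validation_mse,
)
from omicsnmf.io import OmicsMatrix, align_samples, make_split
from omicsnmf.training import CompletedMatrix


def completed(values, prefix="s", provenance=None):
    n, q = values.shape
    return CompletedMatrix(
        np.asarray(values, float),
        [f"{prefix}{i}" for i in range(n)],
        [f"f{j}" for j in range(q)],
        provenance or ["observed"] * n,
    )


class TestValidationMse:
    def test_identity_is_zero(self):
        Y = np.random.default_rng(0).uniform(0, 1, (4, 3))
        assert validation_mse(Y, Y) == 0.0

    def test_unit_offset(self):
        assert validation_mse(np.ones((3, 3)), np.zeros((3, 3))) == 1.0

    def test_hand_instance(self):
        truth = np.array([[1.0, 2.0], [3.0, 4.0]])
        gen = np.array([[1.0, 2.0], [3.0, 0.0]])
        assert validation_mse(gen, truth) == 4.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            validation_mse(np.ones((2, 2)), np.ones((3, 2)))


class TestClassificationAUC:
    def test_separable_labels_reach_perfect_auc(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (60, 5))
        X[:30, 0] += 5.0
        cm = completed(X)
        labels = PhenotypeLabels(list(cm.sample_ids), (X[:, 0] > 2.5).astype(int))
        assert overall_auc(cm, labels, seed=0) == 1.0

    def test_permuted_labels_near_chance(self):
        """Null AUC stays inside the permutation-derived band on 200 samples."""
        rng = np.random.default_rng(2)
        cm = completed(rng.uniform(0, 1, (200, 20)))
        y = rng.permutation(np.repeat([0, 1], 100))
        labels = PhenotypeLabels(list(cm.sample_ids), y)
        assert 0.35 <= overall_auc(cm, labels, seed=0) <= 0.65

    def test_feature_scaling_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (60, 5))
        y = (X[:, 1] + 0.2 * rng.normal(size=60) > 0.5).astype(int)
        labels = PhenotypeLabels([f"s{i}" for i in range(60)], y)
        a = overall_auc(completed(X), labels, seed=0)
        b = overall_auc(completed(X * 7.3), labels, seed=0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_test_set_auc_consistency(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (50, 4))
        X[::2, 0] += 5.0  # class signal present in both observed and imputed rows
        prov = ["observed"] * 40 + ["imputed"] * 10
        cm = completed(X, provenance=prov)
        labels = PhenotypeLabels(list(cm.sample_ids), (X[:, 0] > 2.5).astype(int))
        plan = _plan_from(cm)
        assert imputed_test_auc(cm, labels, plan, seed=0) == 1.0

    def test_single_class_test_set_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (20, 3))
        prov = ["observed"] * 18 + ["imputed"] * 2
        cm = completed(X, provenance=prov)
        y = np.ones(20, int)
        y[:9] = 0  # both imputed samples end up labeled 1
        labels = PhenotypeLabels(list(cm.sample_ids), y)
        with pytest.raises(ValueError, match="one class"):
            imputed_test_auc(cm, labels, _plan_from(cm), seed=0)


def _plan_from(cm):
    from omicsnmf.io import SplitPlan

    observed = [s for s, p in zip(cm.sample_ids, cm.provenance) if p == "observed"]
    missing = [s for s, p in zip(cm.sample_ids, cm.provenance) if p == "imputed"]
    n_tr = int(round(0.8 * len(observed)))
    return SplitPlan(observed[:n_tr], observed[n_tr:], missing, 0, 0.8)


class TestCox:
    def _cohort(self, seed=0, n=40, hr=2.0):
        rng = np.random.default_rng(seed)
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1.0 / np.exp(np.log(hr) * x))
        surv = SurvivalData([f"s{i}" for i in range(n)], t, np.ones(n, int))
        return x[:, None], surv

    def test_heavy_shrinkage_zeroes_coefficients(self):
        X, surv = self._cohort()
        beta = cox_fit(X, surv, CoxConfig(shrinkage=1e6, l1_ratio=0.5))
        np.testing.assert_allclose(beta, 0.0, atol=1e-8)

    def test_hazard_ratio_two_recovered_on_average(self):
        """Mean coefficient over 50 cohorts falls in the recovery band of log 2."""
        betas = []
        for seed in range(50):
            X, surv = self._cohort(seed=seed)
            betas.append(cox_fit(X, surv, CoxConfig(shrinkage=1e-4, l1_ratio=0.5))[0])
        assert 0.4 <= np.mean(betas) <= 1.0

    def test_ridge_endpoint_runs(self):
        X, surv = self._cohort()
        beta = cox_fit(X, surv, CoxConfig(shrinkage=0.1, l1_ratio=0.0))
        assert beta.shape == (1,) and np.isfinite(beta).all()

    def test_lasso_endpoint_runs(self):
        X, surv = self._cohort()
        beta = cox_fit(X, surv, CoxConfig(shrinkage=1e-3, l1_ratio=1.0))
        assert np.isfinite(beta).all()

    def test_no_events_rejected(self):
        X, surv = self._cohort()
        surv.event[:] = False
        with pytest.raises(ValueError, match="event"):
            cox_fit(X, surv)


class TestPrognosticIndex:
    def test_zero_coefficients_zero_scores(self):
        assert (prognostic_index(np.zeros(3), np.ones((4, 3))) == 0).all()

    def test_one_hot_selects_column(self):
        Y = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(
            prognostic_index(np.array([0.0, 1.0, 0.0]), Y), Y[:, 1]
        )

    def test_hand_dot_product(self):
        assert prognostic_index(np.array([1.0, -2.0]), np.array([[3.0, 1.0]]))[0] == 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prognostic_index(np.ones(2), np.ones((3, 3)))


class TestMedianSplit:
    def test_even_count_balanced(self):
        g = median_risk_split(np.arange(10.0))
        assert len(g["low"]) == len(g["high"]) == 5
        assert set(g["low"]) == set(range(5))

    def test_odd_count_extra_goes_low(self):
        g = median_risk_split(np.arange(11.0))
        assert (len(g["low"]), len(g["high"])) == (6, 5)

    def test_all_equal_scores_warn_but_balance(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            g = median_risk_split(np.ones(7))
        assert abs(len(g["low"]) - len(g["high"])) <= 1

    @pytest.mark.parametrize("n", [2, 5, 8, 13])
    def test_always_balanced_within_one(self, n):
        scores = np.random.default_rng(n).normal(size=n)
        g = median_risk_split(scores)
        assert abs(len(g["low"]) - len(g["high"])) <= 1


def brute_force_logrank(time, event, group):
    """Independent observed-minus-expected log-rank computation."""
    from scipy.stats import chi2

    times = np.sort(np.unique(time[event.astype(bool)]))
    O = E = Vr = 0.0
    for t in times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & event.astype(bool)).sum()
        d1 = ((time == t) & event.astype(bool) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            Vr += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if Vr == 0:
        return 1.0
    stat = (O - E) ** 2 / Vr
    return float(chi2.sf(stat, 1))


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.ones(8, int)
        surv = SurvivalData([f"s{i}" for i in range(8)], t, e)
        p = logrank_pvalue({"a": np.arange(4), "b": np.arange(4, 8)}, surv)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_on_hand_table(self):
        t = np.arange(1.0, 7.0)
        e = np.ones(6, int)
        grp = np.array([0, 1, 0, 1, 0, 1])
        surv = SurvivalData([f"s{i}" for i in range(6)], t, e)
        p = logrank_pvalue(
            {"a": np.flatnonzero(grp == 0), "b": np.flatnonzero(grp == 1)}, surv
        )
        assert p == pytest.approx(brute_force_logrank(t, e, grp), rel=1e-6)

    def test_matches_brute_force_on_small_censored_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(4, 9)
            t = rng.exponential(1.0, n).round(2) + 0.01
            e = rng.integers(0, 2, n)
            grp = rng.integers(0, 2, n)
            if e.sum() == 0 or (grp == 0).sum() == 0 or (grp == 1).sum() == 0:
                continue
            surv = SurvivalData([f"s{i}" for i in range(n)], t, e)
            p = logrank_pvalue(
                {"a": np.flatnonzero(grp == 0), "b": np.flatnonzero(grp == 1)}, surv
            )
            assert p == pytest.approx(brute_force_logrank(t, e, grp), rel=1e-6)

    def test_null_pvalues_approximately_uniform(self):
        ps = []
        for rep in range(300):
            rng = np.random.default_rng(10_000 + rep)
            t = rng.exponential(1.0, 40)
            surv = SurvivalData([f"s{i}" for i in range(40)], t, np.ones(40, int))
            ps.append(
                logrank_pvalue({"a": np.arange(20), "b": np.arange(20, 40)}, surv)
            )
        assert kstest(ps, "uniform").statistic < 0.1

    def test_empty_group_rejected(self):
        surv = SurvivalData(["s0", "s1"], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            logrank_pvalue({"a": np.array([0, 1]), "b": np.array([], int)}, surv)


def _pair(seed=7, n=20, m=14, p=4, q=3):
    rng = np.random.default_rng(seed)
    source = OmicsMatrix(
        [f"s{i}" for i in range(n)], [f"x{j}" for j in range(p)],
        rng.uniform(0, 2, (n, p)),
    )
    target = OmicsMatrix(
        [f"s{i}" for i in range(m)], [f"y{j}" for j in range(q)],
        rng.uniform(0, 2, (m, q)),
    )
    return align_samples(source, target)


class TestKnnBaseline:
    def test_exact_duplicate_neighbor(self):
        ds = _pair()
        # make missing sample s14's source row equal observed s3's
        ds.source.values[14] = ds.source.values[3]
        cm = baseline_knn_impute(ds, k_neighbors=1)
        np.testing.assert_array_equal(cm.rows(["s14"])[0], ds.target.values[3])

    def test_full_neighborhood_weighted_mean(self):
        ds = _pair()
        cm = baseline_knn_impute(ds, k_neighbors=ds.m)
        d = np.linalg.norm(
            ds.source_rows(ds.observed_ids) - ds.source_rows(["s14"])[0], axis=1
        )
        w = 1.0 / d
        w /= w.sum()
        np.testing.assert_allclose(cm.rows(["s14"])[0], w @ ds.target.values)

    def test_hand_weights(self):
        # distances from the missing sample m (at 2.0): a->2, b->1, c->98
        source = OmicsMatrix(
            ["a", "b", "c", "m"], ["x"], np.array([[0.0], [1.0], [100.0], [2.0]])
        )
        target = OmicsMatrix(["a", "b", "c"], ["y"], np.array([[10.0], [40.0], [0.0]]))
        ds = align_samples(source, target)
        cm = baseline_knn_impute(ds, k_neighbors=2)
        # neighbors b (d=1) and a (d=2); weights 2/3, 1/3
        assert cm.rows(["m"])[0][0] == pytest.approx(2 / 3 * 40.0 + 1 / 3 * 10.0)

    def test_k_exceeding_m_rejected(self):
        with pytest.raises(ValueError):
            baseline_knn_impute(_pair(), k_neighbors=99)


class TestRegressionBaseline:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 2, (30, 4))
        ids = [f"s{i}" for i in range(30)]
        source = OmicsMatrix(ids, [f"x{j}" for j in range(4)], X)
        target = OmicsMatrix(ids[:22], ["y0"], 2.0 * X[:22, [1]])
        ds = align_samples(source, target)
        plan = make_split(ds, 0.8, seed=0)
        cm = baseline_regression_impute(ds, plan)
        truth = 2.0 * X[22:, [1]]
        assert np.mean((cm.rows(ds.missing_ids) - truth) ** 2) <= 1e-10

    def test_constant_target_fit_exactly(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 2, (20, 3))
        ids = [f"s{i}" for i in range(20)]
        source = OmicsMatrix(ids, [f"x{j}" for j in range(3)], X)
        target = OmicsMatrix(ids[:15], ["y0"], np.full((15, 1), 3.7))
        ds = align_samples(source, target)
        cm = baseline_regression_impute(ds, make_split(ds, 0.8, seed=0))
        np.testing.assert_allclose(cm.rows(ds.missing_ids), 3.7, atol=1e-9)

    def test_independent_target_mse_near_variance(self):
        rng = np.random.default_rng(10)
        n = 400
        X = rng.uniform(0, 1, (n, 2))
        Y = rng.uniform(0, 1, (n, 1))  # independent of X
        ids = [f"s{i}" for i in range(n)]
        source = OmicsMatrix(ids, ["x0", "x1"], X)
        target = OmicsMatrix(ids[:300], ["y0"], Y[:300])
        ds = align_samples(source, target)
        cm = baseline_regression_impute(ds, make_split(ds, 0.8, seed=0))
        mse = np.mean((cm.rows(ds.missing_ids) - Y[300:]) ** 2)
        var = Y.var()
        assert abs(mse - var) <= 0.2 * var

    def test_mean_baseline_rows_are_column_means(self):
        ds = _pair()
        cm = baseline_mean_impute(ds)
        expected = np.tile(ds.target.values.mean(axis=0), (ds.k, 1))
        np.testing.assert_allclose(cm.rows(ds.missing_ids), expected)


class TestCompareMethods:
    def test_self_comparison_p_one(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0.7, 0.9, 20)
        df = pd.DataFrame({"m1": a, "m2": a})
        out = compare_methods(df)
        assert out["p_raw"].iloc[0] == 1.0

    def test_constant_dominance_is_significant(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0.7, 0.9, 100)
        df = pd.DataFrame({"A": a, "B": a + 0.05})
        out = compare_methods(df)
        assert out["p_holm"].iloc[0] < 1e-10

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_comp = 200
        for _ in range(n_comp):
            df = pd.DataFrame(
                {"A": rng.uniform(0.7, 0.9, 20), "B": rng.uniform(0.7, 0.9, 20)}
            )
            if compare_methods(df)["p_raw"].iloc[0] < 0.05:
                rejections += 1
        assert rejections / n_comp <= 0.10

    def test_too_few_splits_rejected(self):
        df = pd.DataFrame({"A": np.arange(5.0), "B": np.arange(5.0)})
        with pytest.raises(ValueError, match="10"):
            compare_methods(df)
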