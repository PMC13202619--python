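"""Age regressors, CV protocol, model comparison, cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from bwage.agemodel import (
    CVPlan,
    cohort_stats,
    kfold_cv,
    make_model,
    mae,
    monte_carlo_cv,
    pooled_mean,
    ridge_fit,
    select_hyperparameters,
    stratified_split,
    svr_fit,
    two_sample_stats,
    wilcoxon_compare,
)


class TestStratifiedSplit:
    def test_floor_rule_tiny_cell(self):
        df = pd.DataFrame({"study": ["A"] * 19, "sex": [0] * 19, "age": 50.0})
        ps, mv = stratified_split(df, fraction=0.1, seed=0)
        assert len(ps) == 1 and len(mv) == 18

    def test_partition_covers_all_rows(self, small_cohort):
        ps, mv = stratified_split(small_cohort, seed=1)
        assert len(ps) + len(mv) == len(small_cohort)
        assert len(ps.intersection(mv)) == 0

    def test_seeded_and_stratified(self, small_cohort):
        ps1, _ = stratified_split(small_cohort, seed=4)
        ps2, _ = stratified_split(small_cohort, seed=4)
        assert ps1.sort_values().equals(ps2.sort_values())
        # per-cell PS sizes follow floor(0.1 * n)
        for (study, sex), cell in small_cohort.groupby(["study", "sex"]):
            got = small_cohort.loc[ps1].query("study == @study and sex == @sex")
            assert len(got) == int(np.floor(0.1 * len(cell)))


class TestRidge:
    def test_lambda_zero_matches_ols_oracle(self, rng):
        X = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        m = ridge_fit(X, y, lam=0.0)
        Xa = np.hstack([np.ones((50, 1)), X])
        oracle = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        np.testing.assert_allclose(m.beta, oracle, atol=1e-8)

    def test_huge_penalty_shrinks_weights(self, rng):
        X = rng.standard_normal((100, 4))
        y = rng.standard_normal(100)
        m = ridge_fit(X, y, lam=1e6)
        assert np.linalg.norm(m.beta) < 1e-3

    def test_three_point_hand_system(self):
        # X = [1;2;3] with intercept, Y = [2;4;6], lambda = 1
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        Xa = np.hstack([np.ones((3, 1)), X])
        expected = np.linalg.solve(Xa.T @ Xa + np.eye(2), Xa.T @ y)
        m = ridge_fit(X, y, lam=1.0)
        np.testing.assert_allclose(m.beta, expected, atol=1e-12)
        np.testing.assert_allclose(m.predict(X), Xa @ expected, atol=1e-12)

    def test_singular_at_zero_warns_and_uses_pseudo_solution(self, rng):
        X = rng.standard_normal((5, 10))  # p > n
        y = rng.standard_normal(5)
        with pytest.warns(UserWarning, match="pseudo-solution"):
            m = ridge_fit(X, y, lam=0.0)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)  # interpolates

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            ridge_fit(np.ones((3, 1)), np.ones(3), lam=-1.0)


class TestSVR:
    def test_linear_kernel_fits_linear_data(self, rng):
        X = rng.standard_normal((200, 2))
        y = 50 + 3 * X[:, 0] - 2 * X[:, 1]
        m = svr_fit(X, y, "linear-svr", inverse_c=1e-4)  # large C
        assert mae(m.predict(X), y) < 0.1
        assert m.beta is not None and m.beta.shape == (3,)

    def test_duplicated_rows_with_compensating_c_identical(self, rng):
        """Duplicating every row doubles the data-fidelity term of the C-SVR
        objective; halving C restores the exact same optimization problem,
        so predictions must match."""
        X = rng.standard_normal((80, 3))
        y = rng.uniform(40, 80, 80)
        m1 = svr_fit(X, y, "rbf-svr", inverse_c=0.01)
        m2 = svr_fit(np.vstack([X, X]), np.concatenate([y, y]), "rbf-svr", 0.02)
        # equal up to the solver's convergence tolerance
        np.testing.assert_allclose(m1.predict(X), m2.predict(X), atol=5e-3)

    def test_refit_is_deterministic(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.uniform(40, 80, 60)
        for kind in ("rbf-svr", "linear-svr"):
            a = svr_fit(X, y, kind, 0.01).predict(X)
            b = svr_fit(X, y, kind, 0.01).predict(X)
            np.testing.assert_array_equal(a, b)

    def test_rbf_beats_ridge_on_nonlinear_signal(self, rng):
        n = 2000
        x = rng.uniform(-2, 2, (n, 2))
        y = 60 + 10 * np.sin(2 * x[:, 0]) * np.cos(x[:, 1]) + 0.5 * rng.standard_normal(n)
        tr, te = slice(0, 1500), slice(1500, None)
        rbf = svr_fit(x[tr], y[tr], "rbf-svr", inverse_c=0.001)
        ridge = ridge_fit(x[tr], y[tr], lam=10.0)
        assert mae(rbf.predict(x[te]), y[te]) < mae(ridge.predict(x[te]), y[te])

    def test_invalid_inverse_c(self):
        with pytest.raises(ValueError):
            svr_fit(np.ones((5, 1)), np.ones(5), "rbf-svr", inverse_c=0.0)


class TestMAE:
    def test_hand_values(self):
        assert mae([60, 70], [62, 66]) == pytest.approx(3.0)
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        assert mae(a, b) == pytest.approx(mae(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


def linear_cohort(rng, n=240):
    age = rng.uniform(40, 80, n)
    X = np.column_stack([age + rng.standard_normal(n), rng.standard_normal((n, 2))])
    strata = np.repeat(["A", "B"], n // 2)
    return X, age, strata


class TestMonteCarloCV:
    def test_row_count_and_pairing(self, rng):
        X, y, strata = linear_cohort(rng)
        plan = CVPlan(stage="parameter-setting", n_repeats=25, seed=0)
        res = monte_carlo_cv(X, y, strata, plan, models={"ridge": (0.0, 10.0)})
        assert len(res) == 25 * 2
        assert set(res["repeat"]) == set(range(25))

    def test_folds_shared_across_grid_points_and_runs(self, rng):
        """Effectively identical models (lambda differing by 1e-12) must see
        the same folds and produce identical MAE columns; a second run with
        the same plan reproduces them."""
        X, y, strata = linear_cohort(rng)
        plan = CVPlan(stage="parameter-setting", n_repeats=5, seed=1)
        res = monte_carlo_cv(X, y, strata, plan, models={"ridge": (10.0, 10.0 + 1e-12)})
        wide = res.pivot_table(index="repeat", columns="hyper", values="mae")
        np.testing.assert_allclose(wide.iloc[:, 0], wide.iloc[:, 1], rtol=1e-9)
        res2 = monte_carlo_cv(X, y, strata, plan, models={"ridge": (10.0,)})
        np.testing.assert_allclose(
            res.loc[res.hyper == 10.0, "mae"].to_numpy(), res2["mae"].to_numpy()
        )

    def test_planted_signal_selects_finite_penalty_with_useful_error(self, rng):
        X, y, strata = linear_cohort(rng, n=400)
        plan = CVPlan(stage="parameter-setting", n_repeats=10, seed=2)
        res = monte_carlo_cv(X, y, strata, plan)
        best = select_hyperparameters(res)
        assert np.isfinite(best["ridge"])
        best_mae = res.groupby(["model", "hyper"])["mae"].mean().loc["ridge"].min()
        assert best_mae < np.std(y)

    def test_wrong_stage_rejected(self, rng):
        X, y, strata = linear_cohort(rng)
        with pytest.raises(ValueError):
            monte_carlo_cv(X, y, strata, CVPlan(stage="method-validation"))


class TestKFoldCV:
    def test_ten_maes_per_model_and_balanced_folds(self, rng):
        X, y, strata = linear_cohort(rng, n=400)
        plan = CVPlan(stage="method-validation", n_folds=10, seed=3, subsample={})
        res = kfold_cv(X, y, strata, plan, {"ridge": 10.0})
        assert len(res) == 10
        folds = CVPlan(stage="method-validation", seed=3)
        # same plan seed -> identical folds on a second run
        res2 = kfold_cv(X, y, strata, plan, {"ridge": 10.0})
        np.testing.assert_allclose(res["mae"], res2["mae"])

    def test_rbf_trains_on_subsample_by_default(self, rng):
        X, y, strata = linear_cohort(rng, n=300)
        plan = CVPlan(stage="method-validation", n_folds=5, seed=4)
        res = kfold_cv(X, y, strata, plan, {"rbf-svr": 0.01, "ridge": 10.0})
        assert set(res["model"]) == {"rbf-svr", "ridge"}
        assert (res.groupby("model").size() == 5).all()


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        assert wilcoxon_compare(np.ones(10), np.ones(10)) == 1.0

    def test_exact_p_for_ten_consistent_differences(self, rng):
        b = rng.standard_normal(10)
        a = b + rng.uniform(0.1, 1.0, 10)  # all-positive differences
        # exact two-sided p: 2 / 2^10 sign assignments
        assert wilcoxon_compare(a, b) == pytest.approx(2 / 1024)

    def test_symmetric_in_argument_order(self, rng):
        a = rng.standard_normal(12)
        b = a + rng.standard_normal(12)
        assert wilcoxon_compare(a, b) == pytest.approx(wilcoxon_compare(b, a))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0, 2.0], [2.0, 1.0])


class TestCohortStats:
    def test_identical_groups_zero_effect(self):
        st = two_sample_stats(50, 60.0, 5.0, 80, 60.0, 5.0)
        assert st["cohen_d"] == 0.0 and st["mean_diff"] == 0.0

    def test_pooled_mean_weighting(self):
        assert pooled_mean([1, 3], [10.0, 20.0]) == pytest.approx(17.5)

    def test_records_level_report(self, small_cohort):
        rep = cohort_stats(small_cohort)
        assert set(rep["comparison"]) == {
            "men_vs_women", "study_vs_all", "sex_composition_fisher",
        }
        assert (rep.loc[rep.comparison != "sex_composition_fisher", "cohen_d"] >= 0).all()
        assert rep["p"].between(0, 1).all()
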