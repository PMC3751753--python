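import numpy as np
import pytest

from motorcap.regress import (
    CapacityRegressor,
    evaluate,
    loso_cv,
    minmax_apply,
    minmax_fit_transform,
    pooled_generalization,
)
from motorcap.types import TaskClass
from tests.conftest import make_instances


class TestMinMax:
    def test_train_columns_map_onto_unit_interval(self):
        X = np.array([[2.0], [4.0], [6.0]])
        Xs, scaler = minmax_fit_transform(X)
        np.testing.assert_allclose(Xs[:, 0], [0.0, 0.5, 1.0])

    def test_apply_extrapolates_beyond_train_bounds(self):
        _, scaler = minmax_fit_transform(np.array([[2.0], [4.0], [6.0]]))
        assert minmax_apply(scaler, np.array([[8.0]]))[0, 0] == pytest.approx(1.5)

    def test_round_trip_inverts(self, rng):
        X = rng.normal(size=(20, 3))
        Xs, (lo, hi) = minmax_fit_transform(X)
        np.testing.assert_allclose(lo + Xs * (hi - lo), X, atol=1e-12)

    def test_constant_column_rejected_by_name(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="RANG"):
            minmax_fit_transform(X, feature_names=["TIME", "RANG"])


class TestFit:
    def test_noiseless_line_recovered(self):
        x = np.arange(1.0, 11.0).reshape(-1, 1)
        t = 0.3 + 0.05 * x[:, 0]
        model = CapacityRegressor(gate=False).fit(x, t)
        w0, w = model.raw_coefficients()
        assert w0 == pytest.approx(0.3, abs=1e-9)
        assert w[0] == pytest.approx(0.05, abs=1e-10)
        np.testing.assert_allclose(model.predict(x), t, atol=1e-9)

    def test_weights_match_normal_equations_oracle(self, rng):
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        model = CapacityRegressor(gate=False, scale_target=False).fit(X, y)
        w0, w = model.raw_coefficients()
        A = np.column_stack([np.ones(25), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert w0 == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(w, beta[1:], atol=1e-8)

    def test_needs_more_rows_than_features(self, rng):
        X = rng.normal(size=(5, 5))
        with pytest.raises(ValueError, match="rows"):
            CapacityRegressor().fit(X, rng.normal(size=5))

    def test_rank_deficiency_names_collinear_columns(self, rng):
        a = rng.normal(size=20)
        X = np.column_stack([a, 2 * a, rng.normal(size=20)])
        with pytest.raises(ValueError, match="collinear.*x0.*x1"):
            CapacityRegressor().fit(X, rng.normal(size=20), feature_names=["x0", "x1", "x2"])


class TestSelection:
    def test_noise_column_dropped_predictor_kept(self):
        kept_pred = kept_noise = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 40)
            noise = rng.normal(size=40)
            y = 0.2 + 0.6 * x + rng.normal(0, 0.05, 40)
            m = CapacityRegressor(alpha=0.05).fit(
                np.column_stack([x, noise]), y, feature_names=["pred", "noise"]
            )
            kept_pred += m.support_[0]
            kept_noise += m.support_[1]
        assert kept_pred >= 18  # >= 90% of seeds
        assert kept_noise <= 5

    def test_all_noise_design_flags_intercept_only(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        m = CapacityRegressor(alpha=0.05).fit(X, y)
        assert m.intercept_only_
        assert not m.support_.any()
        assert np.allclose(m.coef_, 0.0)

    def test_all_significant_model_unchanged(self, rng):
        X = rng.uniform(0, 1, size=(60, 2))
        y = 0.1 + 0.5 * X[:, 0] - 0.4 * X[:, 1] + rng.normal(0, 0.02, 60)
        gated = CapacityRegressor(alpha=0.05).fit(X, y)
        ungated = CapacityRegressor(gate=False).fit(X, y)
        assert gated.support_.all()
        np.testing.assert_allclose(gated.coef_, ungated.coef_, atol=1e-12)

    def test_backward_elimination_rescues_shared_signal(self):
        # two nearly collinear informative columns: the one-shot test can
        # drop both, stepwise keeps at least one
        rng = np.random.default_rng(42)
        z = rng.uniform(0, 1, 25)
        X = np.column_stack([z + rng.normal(0, 0.02, 25), z + rng.normal(0, 0.02, 25)])
        y = 0.2 + 0.6 * z + rng.normal(0, 0.05, 25)
        m = CapacityRegressor(alpha=0.05, selection="backward").fit(X, y)
        assert m.support_.any()


class TestEvaluate:
    def test_perfect_prediction(self):
        rmse, r, p = evaluate([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert rmse == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_anti_prediction(self):
        rmse, r, _ = evaluate([0.0, 1.0], [1.0, 0.0])
        assert rmse == pytest.approx(1.0)
        assert r == pytest.approx(-1.0)

    def test_matches_naive_formula(self, rng):
        t = rng.normal(size=50)
        p = rng.normal(size=50)
        rmse, r, _ = evaluate(t, p)
        assert rmse == pytest.approx(np.sqrt(np.mean((t - p) ** 2)), rel=1e-12)
        num = np.sum((t - t.mean()) * (p - p.mean()))
        den = np.sqrt(np.sum((t - t.mean()) ** 2) * np.sum((p - p.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_degenerate_correlation_flagged_not_silent(self):
        rmse, r, p = evaluate([0.1, 0.5, 0.9], [0.4, 0.4, 0.4])
        assert rmse > 0
        assert np.isnan(r) and np.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            evaluate([1.0, 2.0], [1.0])


class TestLoso:
    def test_too_few_sessions_is_explicit(self, manual_task_list):
        instances = make_instances(manual_task_list, 0.0, seed=1, n_subjects=2, weeks=1)
        with pytest.raises(ValueError, match="3 distinct sessions"):
            loso_cv(instances, TaskClass.CARDS)

    def test_instance_order_does_not_change_results(self, manual_task_list):
        instances = make_instances(manual_task_list, 0.02, seed=2, n_subjects=3, weeks=2)
        res = loso_cv(instances, TaskClass.CARDS)
        rng = np.random.default_rng(0)
        shuffled = list(instances)
        rng.shuffle(shuffled)
        res2 = loso_cv(shuffled, TaskClass.CARDS)
        assert res.rmse == pytest.approx(res2.rmse, rel=1e-12)
        assert res.r == pytest.approx(res2.r, rel=1e-12)

    def test_fold_scalers_use_training_bounds_only(self, manual_task_list):
        instances = make_instances(manual_task_list, 0.02, seed=3, n_subjects=3, weeks=2)
        res = loso_cv(instances, TaskClass.CARDS)
        X = np.array(
            [i.features.as_array() for i in instances if i.task_class == TaskClass.CARDS]
        )
        for model, key in zip(res.models, res.fold_keys):
            train_rows = [
                i
                for i in instances
                if i.task_class == TaskClass.CARDS and i.session_key != key
            ]
            Xt = np.array([i.features.as_array() for i in train_rows])
            np.testing.assert_allclose(model.x_min_, Xt.min(axis=0))
            np.testing.assert_allclose(model.x_max_, Xt.max(axis=0))


class TestPooledGeneralization:
    def test_single_instance_means_equal_values(self, manual_task_list):
        instances = make_instances(
            manual_task_list[:1], 0.0, seed=4, n_subjects=1, weeks=1
        )
        out = pooled_generalization(instances)
        assert len(out) == 1
        row = out.iloc[0]
        inst = instances[0]
        for name in ("SM", "ARE", "RANG"):
            assert row[name] == pytest.approx(inst.features.values[name])

    def test_time_and_df_excluded(self, manual_task_list):
        instances = make_instances(manual_task_list, 0.0, seed=5, n_subjects=1, weeks=1)
        out = pooled_generalization(instances)
        assert {"TIME", "DF"}.isdisjoint(out.columns)

    def test_impairment_levels_separate_in_feature_space(self, manual_task_list):
        from motorcap.synth import simulate_session
        from motorcap.types import ImpairmentProfile

        rows = {}
        for lvl in (0.1, 0.9):
            result = simulate_session(
                ImpairmentProfile(level=lvl),
                task_list=manual_task_list,
                seed=6,
                subject_id=f"L{lvl}",
            )
            rows[lvl] = pooled_generalization(result.instances).iloc[0]
        for name in ("SM", "ARE", "RANG"):
            assert rows[0.1][name] > rows[0.9][name]
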