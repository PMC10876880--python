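"""Calibration models: metrics, splits, NIPALS PLS, SVR/GPR/baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrocal import (
    GPREnsemble,
    NipalsPLS,
    SplitSpec,
    evaluate_all,
    fit_baseline,
    fit_svr,
    r_squared,
    rmse,
    select_n_latent,
    split_dataset,
)
from pyrocal.models import results_from_frame, results_to_frame


class TestMetrics:
    def test_worked_four_point_example(self):
        y = [1.0, 2.0, 3.0, 4.0]
        yh = [1.1, 1.9, 3.2, 3.8]
        assert rmse(y, yh) == pytest.approx(np.sqrt(0.10 / 4), abs=1e-12)
        assert r_squared(y, yh) == pytest.approx(0.98, abs=1e-12)

    def test_trivial_identities(self):
        y = np.array([2.0, 4.0, 5.0])
        assert rmse(y, y) == 0.0
        assert r_squared(y, y) == 1.0
        assert rmse(y, y + 0.7) == pytest.approx(0.7)
        assert r_squared(y, np.full_like(y, y.mean())) == pytest.approx(0.0)

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            r_squared([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_r2_rmse_identity(self, seed):
        # r² = 1 − n·rmse² / Σ(y−ȳ)²
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        y = rng.normal(0, 1, n)
        if np.allclose(y, y[0]):
            return
        yh = y + rng.normal(0, 0.5, n)
        lhs = r_squared(y, yh)
        rhs = 1 - n * rmse(y, yh) ** 2 / np.sum((y - y.mean()) ** 2)
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestSplit:
    def test_study_scale_split_sizes(self):
        s = split_dataset(157, SplitSpec(test_fraction=0.25, seed=0))
        assert len(s.train_idx) == 118
        assert len(s.test_idx) == 39

    def test_reproducible_disjoint_exhaustive(self):
        a = split_dataset(50, SplitSpec(seed=7))
        b = split_dataset(50, SplitSpec(seed=7))
        assert np.array_equal(a.train_idx, b.train_idx)
        combined = np.sort(np.concatenate([a.train_idx, a.test_idx]))
        assert np.array_equal(combined, np.arange(50))

    def test_degenerate_fractions_rejected(self):
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                SplitSpec(test_fraction=frac)
        with pytest.raises(ValueError):
            split_dataset(3, SplitSpec())


class TestNipalsPLS:
    def test_exact_linear_recovery(self, rng):
        X = rng.normal(0, 1, (40, 5))
        b = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X @ b + 1.7
        m = NipalsPLS(5).fit(X, y)
        assert r_squared(y, m.predict(X)) == pytest.approx(1.0, abs=1e-8)

    def test_scores_orthogonal_and_weights_unit_norm(self, rng):
        X = rng.normal(0, 1, (30, 12))
        y = rng.normal(0, 1, 30)
        m = NipalsPLS(6).fit(X, y)
        G = m.x_scores_.T @ m.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8
        assert np.allclose(np.linalg.norm(m.x_weights_, axis=0), 1.0)

    def test_training_residuals_orthogonal_to_scores(self, rng):
        X = rng.normal(0, 1, (25, 8))
        y = rng.normal(0, 1, 25)
        m = NipalsPLS(4).fit(X, y)
        resid = y - m.predict(X)
        assert np.max(np.abs(m.x_scores_.T @ resid)) < 1e-8

    def test_single_component_on_orthonormal_design(self):
        # y depends on variable 2 only → w aligns with that axis
        X = np.eye(8)
        y = np.zeros(8)
        y[2] = 1.0
        m = NipalsPLS(1).fit(X, y)
        w = np.abs(m.x_weights_[:, 0])
        assert w[2] == pytest.approx(max(w))
        assert w[2] > 0.9

    def test_matches_reference_pls_implementation(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(0, 1, (20, 50))
        y = rng.normal(0, 1, 20)
        Xq = rng.normal(0, 1, (10, 50))
        for A in (1, 4, 8):
            ours = NipalsPLS(A).fit(X, y)
            ref = PLSRegression(n_components=A, scale=False).fit(X, y.reshape(-1, 1))
            assert np.allclose(ours.predict(Xq), ref.predict(Xq).ravel(), atol=1e-6)

    def test_nested_predictions_consistent(self, rng):
        X = rng.normal(0, 1, (30, 10))
        y = rng.normal(0, 1, 30)
        m = NipalsPLS(5).fit(X, y)
        nested = m.predict_components(X)
        assert nested.shape == (30, 5)
        assert np.allclose(nested[:, -1], m.predict(X), atol=1e-10)
        sub = NipalsPLS(2).fit(X, y)
        assert np.allclose(nested[:, 1], sub.predict(X), atol=1e-10)

    def test_component_count_validated(self, rng):
        X = rng.normal(0, 1, (10, 4))
        y = rng.normal(0, 1, 10)
        with pytest.raises(ValueError):
            NipalsPLS(5).fit(X, y)
        with pytest.raises(ValueError):
            NipalsPLS(0).fit(X, y)


class TestSelectNLatent:
    def test_recovers_known_latent_dimension(self, rng):
        # three independent factors drive y noiselessly
        n, p, k = 80, 40, 3
        S = rng.normal(0, 1, (n, k))
        load = rng.normal(0, 1, (k, p))
        X = S @ load
        y = S @ np.array([1.0, -1.0, 0.5])
        A = select_n_latent(X, y, max_components=8, cv_folds=5, seed=0)
        assert 2 <= A <= 4

    def test_single_candidate_returns_one(self, rng):
        X = rng.normal(0, 1, (20, 5))
        y = rng.normal(0, 1, 20)
        assert select_n_latent(X, y, max_components=1) == 1

    def test_arguments_validated(self, rng):
        X = rng.normal(0, 1, (20, 5))
        y = rng.normal(0, 1, 20)
        with pytest.raises(ValueError):
            select_n_latent(X, y, 0)
        with pytest.raises(ValueError):
            select_n_latent(X, y, 3, cv_folds=1)


class TestSVR:
    def test_learns_linear_signal(self, rng):
        X = rng.normal(0, 1, (260, 2))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.05, 260)
        m, params = fit_svr(X[:200], y[:200], cv_folds=3, seed=1)
        assert r_squared(y[200:], m.predict(X[200:])) >= 0.9
        assert "C" in params

    def test_reproducible_and_tolerates_duplicates(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 3))] * 2)  # duplicated rows
        y = np.concatenate([np.arange(10.0)] * 2)
        m1, p1 = fit_svr(X, y, cv_folds=3, seed=5)
        m2, p2 = fit_svr(X, y, cv_folds=3, seed=5)
        assert p1 == p2
        assert np.allclose(m1.predict(X), m2.predict(X))


class TestGPREnsemble:
    def test_reported_metrics_are_kernel_means(self, rng):
        X = rng.normal(0, 1, (40, 3))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        m = GPREnsemble(random_state=0).fit(X, y)
        r2s, rmses = [], []
        for pred in m.predict_all(X).values():
            r2s.append(r_squared(y, pred))
            rmses.append(rmse(y, pred))
        mean_r2, mean_rmse = m.mean_metrics(X, y)
        assert mean_r2 == pytest.approx(np.mean(r2s))
        assert mean_rmse == pytest.approx(np.mean(rmses))

    def test_interpolates_smooth_noiseless_target(self, rng):
        X = np.linspace(-2, 2, 30).reshape(-1, 1)
        y = np.tanh(X).ravel()
        m = GPREnsemble(random_state=0).fit(X, y)
        for pred in m.predict_all(X).values():
            assert r_squared(y, pred) >= 0.99

    def test_constant_response_predicted_flat(self):
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        y = np.full(10, 2.5)
        m = GPREnsemble(random_state=0).fit(X, y)
        assert rmse(y, m.predict(X)) == pytest.approx(0.0, abs=1e-6)

    def test_three_kernels_fitted(self, rng):
        X = rng.normal(0, 1, (20, 2))
        y = rng.normal(0, 1, 20)
        m = GPREnsemble(random_state=0).fit(X, y)
        assert set(m.models_) == {"SE", "Exp", "RQ"}


class TestBaselines:
    def test_mlr_exact_on_overdetermined_linear_data(self, rng):
        X = rng.normal(0, 1, (50, 4))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5]) + 3.0
        m, _ = fit_baseline(X, y, "MLR")
        assert r_squared(y, m.predict(X)) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("kind", ["RF", "SNN"])
    def test_stochastic_baselines_reproducible(self, kind, rng):
        X = rng.normal(0, 1, (60, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        m1, _ = fit_baseline(X, y, kind, seed=11)
        m2, _ = fit_baseline(X, y, kind, seed=11)
        assert np.allclose(m1.predict(X), m2.predict(X))

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_baseline(np.ones((5, 2)), np.ones(5), "XGB")


class TestEvaluateAll:
    def test_cardinality_and_serialization(self, small_study):
        study = small_study
        # restrict grid columns for speed; contracts are size-independent
        X = study["X"][:, ::4]
        split = split_dataset(study["spec"].n_samples, SplitSpec(seed=1))
        comps = ["Total phytoaloids", "Reducing sugar", "Total nitrogen"]
        results = evaluate_all(
            X, study["measured"], split, components=comps,
            max_components=8, cv_folds=4, seed=1,
        )
        assert len(results) == len(comps) * 6
        assert {r.model for r in results} == {"PLS", "SVR", "GPR", "MLR", "RF", "SNN"}
        for r in results:
            assert r.rmse_train >= 0 and r.rmse_test >= 0
            assert r.r2_train <= 1 and r.r2_test <= 1
        frame = results_to_frame(results)
        back = results_from_frame(frame)
        assert [r.to_dict() for r in back] == [r.to_dict() for r in results]
        pls_rows = [r for r in results if r.model == "PLS"]
        assert all(r.n_latent is not None for r in pls_rows)

    def test_missing_component_warns_and_skips(self, small_study):
        study = small_study
        X = study["X"][:, ::8]
        split = split_dataset(study["spec"].n_samples, SplitSpec(seed=1))
        with pytest.warns(UserWarning, match="missing"):
            results = evaluate_all(
                X, study["measured"], split,
                components=["Unobtainium", "Total nitrogen"],
                models=["PLS"], max_components=4, cv_folds=3,
            )
        assert len(results) == 1
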