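import numpy as np
import pytest

from chemdiv.models import (
    ENModel,
    ModelSpec,
    fit_en,
    fit_krr,
    grid_search_en_alpha,
    grid_search_width,
    kernel_matrix,
    learning_curve,
    predict_en,
    predict_krr,
    shuffle_evaluate,
    width_grid,
)


class TestKRRClosedForm:
    def test_single_point_closed_form(self):
        # one training point (y=2): w = 2/(1+lam); query at L1 distance d
        gamma, lam, d = 1.5, 1e-3, 0.7
        model = fit_krr(np.array([[0.0]]), np.array([2.0]), "laplacian", gamma, lam)
        pred = predict_krr(model, np.array([[d]]))[0]
        assert pred == pytest.approx(2.0 * np.exp(-d / gamma) / (1.0 + lam), abs=1e-12)

    def test_interpolation_limit(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        model = fit_krr(X, y, "laplacian", gamma=1.0, lam=1e-9)
        np.testing.assert_allclose(predict_krr(model, X), y, atol=1e-6)

    @pytest.mark.parametrize("kernel", ["laplacian", "rbf"])
    def test_matches_dense_solve_oracle(self, kernel, rng):
        for n in (5, 17, 50):
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            Xq = rng.normal(size=(7, 3))
            lam = 1e-6
            model = fit_krr(X, y, kernel, gamma=2.0, lam=lam)
            K = kernel_matrix(X, X, kernel, 2.0)
            w = np.linalg.solve(K + lam * np.eye(n), y)
            expected = kernel_matrix(Xq, X, kernel, 2.0) @ w
            np.testing.assert_allclose(predict_krr(model, Xq), expected, atol=1e-8)

    def test_training_row_order_irrelevant(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        Xq = rng.normal(size=(5, 3))
        perm = rng.permutation(25)
        p1 = predict_krr(fit_krr(X, y, gamma=1.0), Xq)
        p2 = predict_krr(fit_krr(X[perm], y[perm], gamma=1.0), Xq)
        np.testing.assert_allclose(p1, p2, atol=1e-7)

    def test_feature_mismatch_error(self, rng):
        model = fit_krr(rng.normal(size=(5, 3)), rng.normal(size=5))
        with pytest.raises(ValueError, match="mismatch"):
            predict_krr(model, rng.normal(size=(2, 4)))


class TestWidthSearch:
    def test_grids_match_protocol(self):
        lap = width_grid("laplacian")
        rbf = width_grid("rbf")
        assert lap[0] == 0.1 and lap[-1] <= 16384 and lap[-1] * 2 > 16384
        assert rbf[0] == 0.25 and rbf[-1] == 8192.0
        np.testing.assert_allclose(np.diff(np.log2(lap)), 1.0)

    def test_single_candidate_returned(self, rng):
        X, y = rng.normal(size=(40, 2)), rng.normal(size=40)
        g, _ = grid_search_width(X, y, candidates=np.array([3.0]), subsample_fraction=1.0)
        assert g == 3.0

    def test_returned_gamma_minimizes_trace(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.sin(X[:, 0])
        g, trace = grid_search_width(X, y, subsample_fraction=1.0, seed=4)
        assert g == trace.loc[trace["cv_mae"].idxmin(), "gamma"]

    def test_within_factor_four_of_fine_grid_oracle(self, rng):
        # 1-D smooth target with known scale
        X = rng.uniform(-3, 3, size=(120, 1))
        y = np.sin(2 * X[:, 0])
        g, _ = grid_search_width(X, y, kernel="rbf", subsample_fraction=1.0, seed=0)
        fine = np.exp(np.linspace(np.log(0.01), np.log(100), 60))
        g_fine, _ = grid_search_width(
            X, y, kernel="rbf", subsample_fraction=1.0, seed=0, candidates=fine
        )
        assert g_fine / 4 <= g <= g_fine * 4


class TestElasticNet:
    def test_unpenalized_limit_recovers_coefficients(self, rng):
        X = rng.normal(size=(200, 5))
        beta = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
        y = X @ beta + 0.7
        model = fit_en(X, y, alpha=1e-10)
        np.testing.assert_allclose(model.estimator.coef_, beta, atol=1e-4)

    def test_total_shrinkage_predicts_mean(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100) + 5.0
        model = fit_en(X, y, alpha=1e6)
        np.testing.assert_allclose(model.estimator.coef_, 0.0, atol=1e-8)
        np.testing.assert_allclose(predict_en(model, X), y.mean(), atol=1e-6)

    def test_alpha_search_trace_minimal_at_choice(self, rng):
        X = rng.normal(size=(80, 4))
        y = X @ np.array([1.0, 0.5, 0.0, -1.0]) + rng.normal(0, 0.1, 80)
        a, trace = grid_search_en_alpha(X, y, n_folds=5)
        assert a == trace.loc[trace["cv_mae"].idxmin(), "alpha"]


class TestShuffleEvaluate:
    def test_oracle_predictor_zero_mae(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.zeros(50)
        rep = shuffle_evaluate(
            X, y, ModelSpec("krr"), n_repeats=3, predictor=lambda Xq: np.zeros(len(Xq))
        )
        assert rep.mae == 0.0

    def test_constant_predictor_equals_mad_oracle(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        seed = 9
        rep = shuffle_evaluate(
            X, y, ModelSpec("krr"), n_repeats=4, seed=seed,
            predictor=lambda Xq: np.zeros(len(Xq)),
        )
        # recompute the splits independently
        gen = np.random.default_rng(seed)
        expected = []
        for _ in range(4):
            perm = gen.permutation(60)
            te = perm[54:]
            expected.append(np.abs(y[te]).mean())
        np.testing.assert_allclose(rep.per_repeat_mae, expected, atol=1e-12)
        assert rep.mae == pytest.approx(np.mean(expected))

    def test_determinism(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 0] ** 2
        spec = ModelSpec("krr", gamma=0.5)
        r1 = shuffle_evaluate(X, y, spec, n_repeats=3, seed=7)
        r2 = shuffle_evaluate(X, y, spec, n_repeats=3, seed=7)
        assert r1.per_repeat_mae == r2.per_repeat_mae


class TestLearningCurve:
    def test_empty_sizes_empty_table(self, rng):
        table = learning_curve(rng.normal(size=(30, 2)), rng.normal(size=30),
                               ModelSpec("krr"), sizes=[])
        assert len(table) == 0

    def test_same_seed_same_result(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.sin(X[:, 0])
        spec = ModelSpec("krr", gamma=1.0)
        t1 = learning_curve(X, y, spec, sizes=[20], n_folds=3, seed=5)
        t2 = learning_curve(X, y, spec, sizes=[20], n_folds=3, seed=5)
        assert t1.equals(t2)

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValueError):
            learning_curve(rng.normal(size=(30, 2)), rng.normal(size=30),
                           ModelSpec("krr"), sizes=[29])


def test_krr_beats_en_on_synthetic_energies(energy_spec):
    """Kernel model outperforms the linear one on additive synthetic energies."""
    from chemdiv import energetics
    from chemdiv.descriptors import raw_features
    from chemdiv.synthetic import GeneratorSpec, atom_ref_table, generate_dataset

    ds = generate_dataset(
        GeneratorSpec(n_molecules=400, seed=21, multiplet_fraction=0.0), energy_spec
    )
    y = energetics.atomization_energies(ds, atom_ref_table(energy_spec))
    X_raw = raw_features(ds)
    krr = shuffle_evaluate(X_raw, y, ModelSpec("krr", gamma=0.8), n_repeats=3, seed=1)
    en = shuffle_evaluate(X_raw, y, ModelSpec("en", alpha=1e-3), n_repeats=3, seed=1)
    assert krr.mae < en.mae
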