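import numpy as np
import pytest

from chemdiv.generalization import (
    cross_predict,
    extract_outliers,
    fit_affine_correction,
    group_mae,
    subset_mae,
)
from chemdiv.models import ModelSpec, fit_krr


class TestCrossPredict:
    def test_own_training_set_matches_predict(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        spec = ModelSpec("krr", gamma=1.0)
        model = spec.fit(X, y)
        np.testing.assert_array_equal(cross_predict(model, spec, X), spec.predict(model, X))

    def test_mismatched_descriptor_length_refused(self, rng):
        spec = ModelSpec("krr", gamma=1.0)
        model = fit_krr(rng.normal(size=(10, 6)), rng.normal(size=10), gamma=1.0)
        with pytest.raises(ValueError, match="mismatch"):
            cross_predict(model, spec, rng.normal(size=(4, 10)))

    def test_pure_offset_shift_appears_as_bias(self, energy_spec):
        """A noiseless affine energy shift shows up as ~|b| MAE before correction."""
        from chemdiv import energetics
        from chemdiv.constants import HARTREE_TO_KCALMOL
        from chemdiv.descriptors import featurize_matrix, raw_features
        from chemdiv.synthetic import (
            EnergyModelSpec, GeneratorSpec, apply_theory_shift, atom_ref_table,
            generate_dataset,
        )

        espec = EnergyModelSpec(noise_sd=0.0, orbital_noise_sd=0.0)
        ds = generate_dataset(
            GeneratorSpec(n_molecules=80, seed=13, multiplet_fraction=0.0,
                          coordinate_jitter_sd=0.005),
            espec,
        )
        shifted = apply_theory_shift(ds, a=1.0, b=-0.02, noise_sd=0.0)
        refs = atom_ref_table(espec)
        y = energetics.atomization_energies(ds, refs)
        y_shift = energetics.atomization_energies(shifted, refs)
        n_max = ds.max_atoms()
        X = featurize_matrix(raw_features(ds, n_max), n_max, mode="normalize_l1").X
        spec = ModelSpec("krr", gamma=0.5)
        model = spec.fit(X, y)
        pred = cross_predict(model, spec, X)
        mae = np.abs(pred - y_shift).mean()
        assert mae == pytest.approx(0.02 * HARTREE_TO_KCALMOL, rel=0.15)


class TestAffineCorrection:
    def test_identity_recovered(self, rng):
        pred = rng.normal(size=(100,))
        corr = fit_affine_correction(pred, pred)
        assert corr.slope == pytest.approx(1.0, abs=1e-8)
        assert corr.intercept == pytest.approx(0.0, abs=1e-8)

    def test_exact_affine_recovered(self, rng):
        pred = rng.normal(size=(200,))
        ref = 2.0 * pred + 3.0
        corr = fit_affine_correction(pred, ref)
        assert corr.slope == pytest.approx(2.0, abs=1e-6)
        assert corr.intercept == pytest.approx(3.0, abs=1e-6)
        np.testing.assert_allclose(corr.apply(pred), ref, atol=1e-5)

    def test_robust_to_gross_outliers_where_ols_fails(self):
        gen = np.random.default_rng(77)
        pred = gen.normal(size=(300,))
        ref = 2.0 * pred + 3.0
        n_out = 30
        ref_contam = ref.copy()
        ref_contam[:n_out] += 100.0
        corr = fit_affine_correction(pred, ref_contam)
        assert corr.slope == pytest.approx(2.0, abs=1e-2)
        assert corr.intercept == pytest.approx(3.0, abs=1e-2)
        # the least-squares oracle is dragged far off by the contamination
        ols = np.polyfit(pred, ref_contam, 1)
        assert abs(ols[1] - 3.0) > 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_affine_correction(np.ones(10), np.arange(10.0))

    def test_correction_never_hurts_on_fitting_pairs(self, rng):
        pred = rng.normal(size=(150,))
        ref = 1.3 * pred - 0.4 + rng.normal(0, 0.1, 150)
        corr = fit_affine_correction(pred, ref)
        def huber_loss(resid, delta):
            a = np.abs(resid)
            return np.where(a <= delta, 0.5 * a**2, delta * (a - 0.5 * delta)).sum()
        delta = corr.epsilon * max(corr.residual_scale, 1e-12)
        assert huber_loss(ref - corr.apply(pred), delta) <= huber_loss(ref - pred, delta) + 1e-9


class TestSubsetMae:
    def test_perfect_predictions(self):
        y = np.arange(10.0)
        out = subset_mae(y, y, [0, 1, 2], [3, 4])
        assert out["mae_common"] == 0.0 and out["mae_exclusive"] == 0.0

    def test_constructed_errors(self):
        ref = np.zeros(6)
        corrected = np.array([1.0, 1, 1, 3, 3, 3])
        out = subset_mae(corrected, ref, [0, 1, 2], [3, 4, 5])
        assert out["mae_common"] == pytest.approx(1.0)
        assert out["mae_exclusive"] == pytest.approx(3.0)

    def test_pooled_is_weighted_mean(self, rng):
        ref = rng.normal(size=20)
        corrected = ref + rng.normal(size=20)
        common, exclusive = list(range(8)), list(range(8, 20))
        out = subset_mae(corrected, ref, common, exclusive)
        weighted = (8 * out["mae_common"] + 12 * out["mae_exclusive"]) / 20
        assert out["mae_pooled"] == pytest.approx(weighted)

    def test_empty_subset_marked_na(self):
        out = subset_mae(np.ones(3), np.zeros(3), [], [0, 1, 2])
        assert out["mae_common"] is None


class TestOutliers:
    def test_strict_threshold(self):
        ref = np.zeros(3)
        corrected = np.array([31.0, 29.0, 30.0])
        rep = extract_outliers(corrected, ref, "E", threshold=30.0)
        assert list(rep.outlier_index) == [0]

    def test_triplet_class_tally(self):
        # every triplet gets +50 error; the multiplicity class captures all of them
        n = 40
        ref = np.zeros(n)
        mult = np.ones(n, dtype=int)
        mult[::8] = 3
        corrected = np.where(mult > 1, 50.0, 1.0)
        rep = extract_outliers(corrected, ref, "E", multiplicities=mult)
        assert rep.n_multiplet == (mult > 1).sum()
        assert rep.n_outliers == (mult > 1).sum()

    def test_unclassified_counted(self):
        rep = extract_outliers(
            np.array([40.0]), np.zeros(1), "E",
            multiplicities=np.array([1]), group_table=[set()],
        )
        assert rep.n_unclassified == 1


class TestGroupMae:
    def test_single_group_constant_error(self):
        table = group_mae(np.full(5, 2.0), np.zeros(5), [{"alcohol"}] * 5)
        row = table.iloc[0]
        assert row["group"] == "alcohol" and row["occurrences"] == 5
        assert row["mae"] == pytest.approx(2.0)

    def test_empty_group_omitted(self):
        table = group_mae(np.ones(2), np.zeros(2), [{"ether"}, {"ether"}])
        assert list(table["group"]) == ["ether"]

    def test_overlapping_groups_count_twice(self):
        table = group_mae(
            np.array([1.0, 2.0]), np.zeros(2), [{"a", "b"}, {"a"}]
        ).set_index("group")
        assert table.loc["a", "occurrences"] == 2
        assert table.loc["b", "occurrences"] == 1
        assert table.loc["a", "mae"] == pytest.approx(1.5)
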