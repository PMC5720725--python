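import numpy as np
import pytest

from toothssm.cohort import RegisteredCohort, ShapeVector
from toothssm.errors import InvalidInputError
from toothssm.model import (PCWeights, choose_c, fit_model, generate_instance,
                            project, reconstruction_error_test,
                            reconstruction_error_vectorspace, sigma_sweep,
                            variance_report)


def _cohort(matrix, has_material=False):
    matrix = np.asarray(matrix, dtype=float)
    return RegisteredCohort(
        faces=np.zeros((0, 3), int),
        vectors=[ShapeVector(row, has_material=has_material) for row in matrix],
        ids=[f"s{i}" for i in range(len(matrix))],
        groups=["g"] * len(matrix),
    )


@pytest.fixture(scope="module")
def random_cohort():
    rng = np.random.default_rng(10)
    return _cohort(rng.normal(size=(10, 6)) * np.array([1, 2, 5, 0.1, 3, 1]))


@pytest.fixture(scope="module")
def random_model(random_cohort):
    return fit_model(random_cohort)


class TestFitModel:
    def test_identical_specimens_zero_pcs(self):
        cohort = _cohort(np.tile(np.arange(6.0), (4, 1)))
        model = fit_model(cohort)
        assert model.n_components == 0
        assert np.allclose(model.mean, np.arange(6.0))

    def test_rank_bound_three_specimens(self):
        rng = np.random.default_rng(1)
        model = fit_model(_cohort(rng.normal(size=(3, 9))))
        assert model.n_components <= 2

    def test_eigenvalues_match_dense_correlation_oracle(self, random_cohort, random_model):
        x = random_cohort.matrix()
        corr = np.corrcoef(x.T)
        oracle = np.sort(np.linalg.eigvalsh(corr))[::-1]
        k = random_model.n_components
        assert np.allclose(random_model.eigenvalues, oracle[:k], atol=1e-9)

    def test_matches_sklearn_on_standardised_data(self, random_cohort):
        sklearn = pytest.importorskip("sklearn.decomposition")
        x = random_cohort.matrix()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        pca = sklearn.PCA()
        pca.fit(z)
        model = fit_model(random_cohort)
        # sklearn uses the same 1/(N-1) convention
        assert np.allclose(model.eigenvalues,
                           pca.explained_variance_[:model.n_components], atol=1e-9)

    def test_scores_zero_mean(self, random_cohort, random_model):
        scores = np.vstack([project(random_model, v).coefficients
                            for v in random_cohort.vectors])
        assert np.allclose(scores.mean(axis=0), 0, atol=1e-10)

    def test_score_variance_equals_eigenvalues(self, random_cohort, random_model):
        scores = np.vstack([project(random_model, v).coefficients
                            for v in random_cohort.vectors])
        assert np.allclose(scores.var(axis=0, ddof=1), random_model.eigenvalues, atol=1e-9)

    def test_orthonormal_eigenvectors(self, random_model):
        phi = random_model.eigenvectors
        assert np.allclose(phi.T @ phi, np.eye(phi.shape[1]), atol=1e-9)

    def test_needs_two_specimens(self):
        with pytest.raises(InvalidInputError):
            fit_model(_cohort(np.ones((1, 6))))

    def test_constant_variable_masked(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 6))
        x[:, 2] = 7.0
        model = fit_model(_cohort(x))
        assert model.constant_mask[2]
        assert model.n_components <= 5
        inst = generate_instance(model, PCWeights(np.ones(model.n_components)))
        assert inst.values[2] == pytest.approx(7.0)


class TestGenerateProject:
    def test_zero_weights_give_mean(self, random_model):
        inst = generate_instance(random_model, PCWeights(np.zeros(3)), c=3)
        assert np.allclose(inst.values, random_model.mean, atol=1e-12)

    def test_training_round_trip_all_pcs(self, random_cohort, random_model):
        for vec in random_cohort.vectors:
            w = project(random_model, vec)
            recon = generate_instance(random_model, w)
            assert np.allclose(recon.values, vec.values, rtol=1e-9, atol=1e-9)

    def test_project_generate_round_trip(self, random_model):
        rng = np.random.default_rng(3)
        w = rng.normal(size=random_model.n_components)
        inst = generate_instance(random_model, PCWeights(w))
        back = project(random_model, inst)
        assert np.allclose(back.coefficients, w, atol=1e-9)

    def test_linearity_symmetry(self, random_model):
        w = np.ones(random_model.n_components)
        plus = generate_instance(random_model, PCWeights(w))
        minus = generate_instance(random_model, PCWeights(-w))
        assert np.allclose((plus.values + minus.values) / 2, random_model.mean, atol=1e-10)

    def test_project_mean_is_zero(self, random_model):
        w = project(random_model, ShapeVector(random_model.mean))
        assert np.allclose(w.coefficients, 0, atol=1e-10)

    def test_c_too_large_rejected(self, random_model):
        with pytest.raises(InvalidInputError):
            generate_instance(random_model, PCWeights(np.zeros(99)), c=99)

    def test_sigma_unit_conversion(self, random_model):
        ev = random_model.eigenvalues
        w = PCWeights(np.ones(len(ev)), sigma_units=True)
        assert np.allclose(w.raw(ev), np.sqrt(ev))

    def test_material_clamped(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(6, 8 * 3))
        mats = rng.uniform(0, 1, size=(6, 8)).round()
        x = np.hstack([np.column_stack([coords[:, 3 * i:3 * i + 3], mats[:, i]])
                       for i in range(8)])
        model = fit_model(_cohort(x, has_material=True))
        inst = generate_instance(model, PCWeights(5 * np.ones(model.n_components),
                                                  sigma_units=True))
        m = inst.materials()
        assert np.all((m >= 0) & (m <= 1))


class TestVarianceAndC:
    def test_fractions_sum_to_one(self, random_model):
        frac, cum = variance_report(random_model)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)

    def test_single_pc_fraction_one(self):
        base = np.arange(6.0)
        rows = [base + t * np.array([1, 2, 0, -1, 0.5, 3]) for t in (-1, 0, 1, 2)]
        model = fit_model(_cohort(rows))
        frac, _ = variance_report(model)
        assert len(frac) == 1
        assert frac[0] == pytest.approx(1.0)

    def test_choose_c_hand_case(self):
        # fractions (0.4, 0.3, 0.2, 0.1): cumulative 0.4, 0.7, 0.9, 1.0
        class Fake:
            eigenvalues = np.array([0.4, 0.3, 0.2, 0.1])

            def variance_fractions(self):
                return self.eigenvalues / self.eigenvalues.sum()

        assert choose_c(Fake(), 0.75) == 3
        assert choose_c(Fake(), 1.0) == 4
        assert choose_c(Fake(), 0.4) == 1
        assert choose_c(Fake(), 0.1) == 1

    def test_choose_c_invalid_target(self, random_model):
        with pytest.raises(InvalidInputError):
            choose_c(random_model, 0.0)


class TestSigmaSweep:
    def test_level_zero_is_mean(self, random_model):
        sweep = sigma_sweep(random_model, pc=1, levels=(0,))
        assert np.allclose(sweep[0].values, random_model.mean, atol=1e-12)

    def test_symmetry_about_mean(self, random_model):
        sweep = sigma_sweep(random_model, pc=1, levels=(-2, 2))
        assert np.allclose(sweep[0].values + sweep[1].values,
                           2 * random_model.mean, atol=1e-9)

    def test_seven_default_levels(self, random_model):
        assert len(sigma_sweep(random_model, pc=1)) == 7


class TestReconstructionError:
    def test_all_pcs_reconstructs_exactly(self, mode_cohort, mode_model):
        errs = reconstruction_error_test(mode_model, mode_cohort,
                                         k_range=[mode_model.n_components])
        assert np.all(errs <= 1e-6)

    def test_k0_positive_for_nondegenerate(self, mode_cohort, mode_model):
        errs = reconstruction_error_test(mode_model, mode_cohort, k_range=[0])
        assert np.all(errs > 0)

    def test_vectorspace_monotone_nonincreasing(self, mode_cohort, mode_model):
        errs = reconstruction_error_vectorspace(mode_model, mode_cohort)
        assert np.all(np.diff(errs, axis=0) <= 1e-9)


class TestModeRecovery:
    def test_two_modes_two_distinct_leading_pcs(self, mode_population, mode_cohort, mode_model):
        scores = np.vstack([project(mode_model, v).coefficients
                            for v in mode_cohort.vectors])
        true_scale = np.log([s.modes["scale"] for s in mode_population])
        true_ratio = np.log([s.modes["ratio"] for s in mode_population])
        best = {}
        for name, truth in (("scale", true_scale), ("ratio", true_ratio)):
            rs = [abs(np.corrcoef(truth, scores[:, j])[0, 1]) for j in range(4)]
            best[name] = (int(np.argmax(rs)), max(rs))
        assert best["scale"][1] > 0.9
        assert best["ratio"][1] > 0.9
        assert best["scale"][0] != best["ratio"][0]
        assert {best["scale"][0], best["ratio"][0]} <= {0, 1}
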