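"""Unit tests for sparse functional PCA (mean/covariance smoothing, eigenanalysis, BLUP scores)."""

import numpy as np
import pytest

from spatent import (
    DegenerateInputError,
    FPCAConfig,
    FPCAModel,
    FunctionalSample,
    ValidationError,
    eigendecompose,
    estimate_covariance,
    estimate_mean,
    estimate_scores_conditional,
    fit_fpca,
    select_n_components,
)
from conftest import sine_cohort


def _sample(ids, absc, vals):
    return FunctionalSample(tuple(ids), tuple(absc), tuple(vals))


class TestMean:
    def test_constant_curves_give_constant_mean(self, rng):
        absc = [np.sort(rng.uniform(0, 1, 8)) for _ in range(10)]
        sample = _sample(range(10), absc, [np.full(8, 3.5) for _ in range(10)])
        _, mu, _ = estimate_mean(sample, bandwidth=0.3)
        np.testing.assert_allclose(mu, 3.5, atol=1e-10)

    def test_known_mean_recovered_from_noisy_cohort(self):
        rng = np.random.default_rng(3)
        truth = lambda s: np.sin(np.pi * s) + 0.5 * s
        absc, vals = [], []
        for _ in range(200):
            s = np.sort(rng.uniform(0, 1, 20))
            vals.append(truth(s) + rng.normal(0, 0.1, 20))
            absc.append(s)
        sample = _sample(range(200), absc, vals)
        grid, mu, _ = estimate_mean(sample)
        assert np.max(np.abs(mu - truth(grid))) < 0.05

    def test_too_few_observations_rejected(self):
        sample = _sample(["a"], [np.array([0.1, 0.5])], [np.array([1.0, 2.0])])
        with pytest.raises(DegenerateInputError):
            estimate_mean(sample)


class TestCovariance:
    def test_one_factor_model_recovered_noiseless(self):
        _, absc, vals, truth = sine_cohort(250, seed=4, noise_sd=0.0, eigenvalues=(2.0,), )
        sample = _sample(range(250), absc, vals)
        grid, G, sigma2, _ = estimate_covariance(sample)
        target = 2.0 * np.outer(truth["phi"][0](grid), truth["phi"][0](grid))
        rel_l2 = np.linalg.norm(G - target) / np.linalg.norm(target)
        assert rel_l2 < 0.15
        assert sigma2 < 0.15

    def test_pure_noise_gives_flat_surface_and_noise_variance(self):
        rng = np.random.default_rng(5)
        absc, vals = [], []
        for _ in range(300):
            s = np.sort(rng.uniform(0, 1, 15))
            absc.append(s)
            vals.append(rng.normal(0, 0.5, 15))
        sample = _sample(range(300), absc, vals)
        _, G, sigma2, _ = estimate_covariance(sample)
        assert np.max(np.abs(G)) < 0.08
        assert sigma2 == pytest.approx(0.25, rel=0.3)

    def test_symmetry_exact(self):
        _, absc, vals, _ = sine_cohort(50, seed=6)
        _, G, _, _ = estimate_covariance(_sample(range(50), absc, vals))
        np.testing.assert_array_equal(G, G.T)

    def test_all_singletons_rejected(self):
        sample = _sample(
            range(12), [np.array([0.1 * i]) for i in range(12)], [np.array([float(i)]) for i in range(12)]
        )
        with pytest.raises(DegenerateInputError):
            estimate_covariance(sample)


class TestEigendecomposition:
    def test_rank_two_surface_recovered(self):
        grid = np.linspace(0, 1, 51)
        phi1 = np.sqrt(2) * np.sin(np.pi * grid)
        phi2 = np.sqrt(2) * np.sin(3 * np.pi * grid)
        G = 3.0 * np.outer(phi1, phi1) + 0.5 * np.outer(phi2, phi2)
        lam, phi = eigendecompose(G, grid)
        assert lam[0] == pytest.approx(3.0, rel=1e-3)
        assert lam[1] == pytest.approx(0.5, rel=1e-3)
        assert np.all(lam[2:] < 1e-8)
        assert abs(np.trapezoid(phi[:, 0] * phi1, grid)) > 0.999

    def test_orthonormality_and_sign_convention(self, rng):
        grid = np.linspace(0, 2, 41)
        A = rng.normal(size=(41, 41))
        lam, phi = eigendecompose(A @ A.T / 41, grid)
        for l in range(min(4, lam.size)):
            assert np.trapezoid(phi[:, l] ** 2, grid) == pytest.approx(1.0, abs=1e-6)
            integral = np.trapezoid(phi[:, l], grid)
            if abs(integral) > 1e-10:
                assert integral > 0
            for m in range(l):
                assert abs(np.trapezoid(phi[:, l] * phi[:, m], grid)) < 1e-6

    def test_nonfinite_surface_rejected(self):
        grid = np.linspace(0, 1, 5)
        G = np.full((5, 5), np.nan)
        with pytest.raises(ValidationError):
            eigendecompose(G, grid)


class TestComponentSelection:
    @pytest.mark.parametrize(
        "lam, threshold, expected",
        [
            ((0.9, 0.1), 0.92, 2),
            ((0.95, 0.05), 0.92, 1),
            ((0.80, 0.13, 0.07), 0.92, 2),
        ],
    )
    def test_fve_rule(self, lam, threshold, expected):
        assert select_n_components(np.array(lam), threshold) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            select_n_components(np.zeros(3))


def _manual_model(grid, lam, phis, sigma2=0.0, mean=None):
    mean = np.zeros_like(grid) if mean is None else mean
    phi = np.column_stack(phis)
    return FPCAModel(
        grid=grid,
        mean=mean,
        covariance=phi @ np.diag(lam) @ phi.T,
        sigma2=sigma2,
        eigenvalues=np.asarray(lam, dtype=float),
        eigenfunctions=phi,
        fve=np.cumsum(lam) / np.sum(lam),
        n_selected=len(lam),
        scores=np.zeros((0, len(lam))),
        ids=(),
    )


class TestScores:
    def _two_factor_model(self):
        grid = np.linspace(0, 1, 51)
        phi1 = np.sqrt(2) * np.sin(np.pi * grid)
        phi2 = np.sqrt(2) * np.sin(3 * np.pi * grid)
        return grid, _manual_model(grid, (4.0, 1.0), (phi1, phi2), sigma2=1e-4)

    def test_subject_on_the_mean_has_zero_scores(self):
        grid, model = self._two_factor_model()
        sample = _sample(["a"], [grid], [model.mean.copy()])
        scores = estimate_scores_conditional(sample, model)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_dense_noiseless_scores_recovered(self, rng):
        grid, model = self._two_factor_model()
        xi = rng.normal(0, 1, size=(20, 2)) * np.sqrt([4.0, 1.0])
        ys = [model.mean + model.eigenfunctions @ x for x in xi]
        sample = _sample(range(20), [grid] * 20, ys)
        scores = estimate_scores_conditional(sample, model)
        assert np.max(np.abs(scores - xi) / np.maximum(np.abs(xi), 1e-6)) < 1e-3

    def test_estimator_is_linear_in_observations(self, rng):
        grid, model = self._two_factor_model()
        y1 = rng.normal(size=grid.size)
        y2 = rng.normal(size=grid.size)
        f = lambda y: estimate_scores_conditional(_sample(["x"], [grid], [y]), model)[0]
        np.testing.assert_allclose(
            f(model.mean + 0.3 * y1 + 0.7 * y2 - model.mean * 0)  # affine in y around mean
            - f(model.mean),
            0.3 * (f(model.mean + y1) - f(model.mean)) + 0.7 * (f(model.mean + y2) - f(model.mean)),
            atol=1e-9,
        )

    def test_scores_shrink_to_zero_as_noise_dominates(self, rng):
        grid = np.linspace(0, 1, 51)
        phi1 = np.sqrt(2) * np.sin(np.pi * grid)
        y = 2.0 * phi1
        small = _manual_model(grid, (1.0,), (phi1,), sigma2=1e-6)
        huge = _manual_model(grid, (1.0,), (phi1,), sigma2=1e6)
        s_small = estimate_scores_conditional(_sample(["a"], [grid], [y]), small)[0, 0]
        s_huge = estimate_scores_conditional(_sample(["a"], [grid], [y]), huge)[0, 0]
        assert abs(s_small - 2.0) < 1e-3
        assert abs(s_huge) < 1e-3


class TestFitFPCA:
    def test_sparse_two_factor_recovery(self):
        ids, absc, vals, truth = sine_cohort(200, seed=9, noise_sd=0.2)
        model = fit_fpca(_sample(ids, absc, vals))
        g = model.grid
        for l in range(2):
            align = abs(np.trapezoid(model.eigenfunctions[:, l] * truth["phi"][l](g), g))
            assert align > 0.9
        assert model.eigenvalues[0] == pytest.approx(4.0, rel=0.25)
        assert model.n_selected == 2

    def test_dense_limit_matches_matrix_pca(self, rng):
        ids, absc, vals, truth = sine_cohort(150, seed=10, sparse=False, noise_sd=0.0)
        Y = np.vstack(vals)
        grid = absc[0]
        step = grid[1] - grid[0]
        cfg = FPCAConfig(mean_bandwidth=0.55 * step, cov_bandwidth=0.55 * step)
        with pytest.warns(UserWarning):  # local bandwidth widening at the excluded diagonal
            model = fit_fpca(_sample(ids, absc, vals), cfg)
        lam_o, phi_o = eigendecompose(np.cov(Y, rowvar=False, bias=True), grid)
        np.testing.assert_allclose(model.eigenvalues[:2], lam_o[:2], rtol=0.01)
        for l in range(2):
            assert abs(np.trapezoid(model.eigenfunctions[:, l] * phi_o[:, l], grid)) > 0.99

    def test_subject_order_invariance(self):
        ids, absc, vals, _ = sine_cohort(40, seed=11)
        model = fit_fpca(_sample(ids, absc, vals))
        perm = np.random.default_rng(0).permutation(40)
        model_p = fit_fpca(_sample([ids[i] for i in perm], [absc[i] for i in perm], [vals[i] for i in perm]))
        np.testing.assert_allclose(model.eigenvalues, model_p.eigenvalues, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(model.scores[perm], model_p.scores, atol=1e-8)

    def test_reconstruction_error_nonincreasing_in_components(self):
        ids, absc, vals, _ = sine_cohort(80, seed=12, noise_sd=0.1)
        sample = _sample(ids, absc, vals)
        model = fit_fpca(sample)
        errors = []
        for L in range(1, model.n_components + 1):
            scores = estimate_scores_conditional(sample, model, n_components=L)
            sse = 0.0
            for i, (s, y) in enumerate(zip(sample.abscissae, sample.values)):
                fitted = model.mean_at(s) + model.eigenfunctions_at(s)[:, :L] @ scores[i]
                sse += float(np.sum((y - fitted) ** 2))
            errors.append(sse)
        assert all(b <= a + 1e-8 for a, b in zip(errors, errors[1:]))
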