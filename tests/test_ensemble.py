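import numpy as np
import pytest

import saxsensemble as sx
from saxsensemble.ensemble import nnls_solve, scale_and_chi2


def _profiles_from_matrix(q, mat):
    return [sx.IntensityProfile(q_grid=q, intensity=mat[:, k])
            for k in range(mat.shape[1])]


class TestNnlsSolve:
    def test_single_column_scaling(self):
        c = np.array([1.0, 2.0, 3.0])
        x = nnls_solve([c], 2 * c)
        assert x == pytest.approx([2.0])

    def test_orthogonal_design_exact(self):
        c1 = np.array([1.0, 0.0, 0.0, 0.0])
        c2 = np.array([0.0, 0.0, 1.0, 0.0])
        x = nnls_solve([c1, c2], 0.3 * c1 + 0.7 * c2)
        assert x == pytest.approx([0.3, 0.7], abs=1e-12)

    def test_kkt_optimality_random_problems(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            a = rng.uniform(0, 1, (40, 12))
            b = rng.uniform(0, 1, 40)
            x = nnls_solve(list(a.T), b)
            grad = a.T @ (a @ x - b)
            assert np.all(grad[x == 0] >= -1e-8)
            assert np.all(np.abs(grad[x > 0]) <= 1e-8)

    def test_beats_random_nonnegative_trials(self):
        rng = np.random.default_rng(37)
        a = rng.uniform(0, 1, (30, 20))
        b = rng.uniform(0, 1, 30)
        x = nnls_solve(list(a.T), b)
        best = np.linalg.norm(a @ x - b)
        trials = rng.uniform(0, 1, (10_000, 20)) * np.abs(x).max() * 2
        residuals = np.linalg.norm(trials @ a.T - b, axis=1)
        assert best <= residuals.min() + 1e-12

    def test_nested_design_monotonicity(self):
        rng = np.random.default_rng(41)
        a = rng.uniform(0, 1, (50, 25))
        b = rng.uniform(0, 1, 50)
        prev = np.inf
        for ncols in (5, 10, 15, 25):
            x = nnls_solve(list(a[:, :ncols].T), b)
            res = np.linalg.norm(a[:, :ncols] @ x - b)
            assert res <= prev + 1e-10
            prev = res

    def test_grid_mismatch_and_zero_target(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            nnls_solve([np.ones(3)], np.ones(4))
        with pytest.raises(ValueError, match="all-zero"):
            nnls_solve([np.ones(3)], np.zeros(3))


class TestScaleAndChi2:
    def _pair(self, model_scale=1.0):
        q = np.linspace(0.01, 0.3, 100)
        intensity = 50 * np.exp(-q**2 * 30**2 / 3)
        expt = sx.IntensityProfile(q_grid=q, intensity=intensity,
                                   sigma=0.02 * intensity)
        model = sx.IntensityProfile(q_grid=q, intensity=model_scale * intensity)
        return model, expt

    def test_identical_curves(self):
        model, expt = self._pair()
        scale, chi2, resid = scale_and_chi2(model, expt)
        assert scale == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-20)

    def test_doubled_model_halved_scale(self):
        model, expt = self._pair(model_scale=2.0)
        scale, chi2, _ = scale_and_chi2(model, expt)
        assert scale == pytest.approx(0.5)
        assert chi2 == pytest.approx(0.0, abs=1e-20)

    def test_chi2_calibrated_for_known_noise(self):
        rng = np.random.default_rng(43)
        q = np.linspace(0.01, 0.4, 1000)
        truth = 100 * np.exp(-q**2 * 25**2 / 3)
        sigma = 0.02 * truth
        chis = []
        for _ in range(20):
            noisy = truth + rng.standard_normal(len(q)) * sigma
            expt = sx.IntensityProfile(q_grid=q, intensity=noisy, sigma=sigma)
            model = sx.IntensityProfile(q_grid=q, intensity=truth)
            _, chi2, _ = scale_and_chi2(model, expt)
            chis.append(chi2)
        assert 0.86 <= np.mean(chis) <= 1.14

    def test_requires_sigma_and_points(self):
        q = np.linspace(0.01, 0.1, 10)
        a = sx.IntensityProfile(q_grid=q, intensity=np.ones(10))
        with pytest.raises(ValueError, match="sigma"):
            scale_and_chi2(a, a)


class TestComposite:
    def test_single_profile_identity(self):
        q = np.linspace(0.01, 0.2, 30)
        p = sx.IntensityProfile(q_grid=q, intensity=np.exp(-q))
        out = sx.composite_profile([p], [1.0])
        assert np.allclose(out.intensity, p.intensity)

    def test_two_constants(self):
        q = np.linspace(0.01, 0.2, 10)
        a = sx.IntensityProfile(q_grid=q, intensity=np.full(10, 1.0))
        b = sx.IntensityProfile(q_grid=q, intensity=np.full(10, 3.0))
        out = sx.composite_profile([a, b], [0.5, 0.5])
        assert np.allclose(out.intensity, 2.0)

    def test_matches_matrix_vector_product(self):
        rng = np.random.default_rng(47)
        q = np.linspace(0.01, 0.3, 40)
        mat = rng.uniform(0, 5, (40, 8))
        f = rng.dirichlet(np.ones(8))
        out = sx.composite_profile(_profiles_from_matrix(q, mat), f)
        assert np.allclose(out.intensity, mat @ f)


class TestFitEnsemble:
    def test_pool_of_target_itself(self):
        q = np.linspace(0.01, 0.3, 60)
        intensity = 40 * np.exp(-q**2 * 20**2 / 3)
        target = sx.IntensityProfile(q_grid=q, intensity=intensity,
                                     sigma=0.01 * intensity)
        pool = [sx.IntensityProfile(q_grid=q, intensity=intensity)]
        res = sx.fit_ensemble(pool, target)
        assert res.n_members == 1
        assert res.fractions[0] == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-15)

    def test_noise_free_two_member_recovery(self):
        rng = np.random.default_rng(53)
        # overdetermined: full column rank makes the exact solution unique
        q = np.linspace(0.01, 0.4, 400)
        pool_mat = rng.uniform(0.0, 1.0, (400, 200)) + 1.0
        truth = 0.6 * pool_mat[:, 17] + 0.4 * pool_mat[:, 140]
        target = sx.IntensityProfile(q_grid=q, intensity=truth,
                                     sigma=np.full(400, 1e-3))
        res = sx.fit_ensemble(_profiles_from_matrix(q, pool_mat), target)
        rec = dict(zip(res.member_ids, res.fractions))
        assert rec.get(17, 0) == pytest.approx(0.6, abs=1e-6)
        assert rec.get(140, 0) == pytest.approx(0.4, abs=1e-6)

    def test_constant_sigma_matches_unweighted(self):
        rng = np.random.default_rng(59)
        q = np.linspace(0.01, 0.3, 80)
        mat = rng.uniform(0.5, 2.0, (80, 15))
        target_i = mat @ rng.dirichlet(np.ones(15)) + rng.normal(0, 0.01, 80)
        target = sx.IntensityProfile(q_grid=q, intensity=target_i,
                                     sigma=np.full(80, 0.37))
        pool = _profiles_from_matrix(q, mat)
        uw = sx.fit_ensemble(pool, target, error_weighted=False)
        w = sx.fit_ensemble(pool, target, error_weighted=True)
        assert np.array_equal(uw.member_ids, w.member_ids)
        assert np.allclose(uw.fractions, w.fractions, atol=1e-10)

    def test_fractions_invariant_to_pool_rescaling(self):
        rng = np.random.default_rng(61)
        q = np.linspace(0.01, 0.3, 50)
        mat = rng.uniform(0.5, 2.0, (50, 10))
        target_i = mat @ rng.dirichlet(np.ones(10))
        target = sx.IntensityProfile(q_grid=q, intensity=target_i,
                                     sigma=0.01 * target_i)
        r1 = sx.fit_ensemble(_profiles_from_matrix(q, mat), target)
        r2 = sx.fit_ensemble(_profiles_from_matrix(q, 7.3 * mat), target)
        assert np.array_equal(r1.member_ids, r2.member_ids)
        assert np.allclose(r1.fractions, r2.fractions, atol=1e-9)

    def test_error_weighting_without_sigma_rejected(self):
        q = np.linspace(0.01, 0.2, 20)
        p = sx.IntensityProfile(q_grid=q, intensity=np.ones(20))
        with pytest.raises(ValueError, match="no errors"):
            sx.fit_ensemble([p], sx.IntensityProfile(q_grid=q, intensity=np.ones(20)),
                            error_weighted=True)


class TestEnsembleStats:
    def test_single_member(self):
        rg_rms, dm, dmx, hist = sx.ensemble_stats([1.0], [33.0], [90.0])
        assert rg_rms == 33.0
        assert dm == 90.0
        assert dmx == (90.0, 1.0)

    def test_two_member_rms(self):
        rg_rms, *_ = sx.ensemble_stats([0.5, 0.5], [30.0, 40.0], [100.0, 150.0])
        assert rg_rms == pytest.approx(np.sqrt((900 + 1600) / 2))
        assert rg_rms == pytest.approx(35.355, abs=1e-3)

    def test_rms_bounded_by_members(self):
        rng = np.random.default_rng(67)
        for _ in range(20):
            n = rng.integers(2, 8)
            f = rng.dirichlet(np.ones(n))
            rg = rng.uniform(20, 60, n)
            rg_rms, *_ = sx.ensemble_stats(f, rg)
            assert rg.min() <= rg_rms <= rg.max()


class TestRefitUnion:
    def _setup(self):
        rng = np.random.default_rng(71)
        q = np.linspace(0.01, 0.4, 100)
        mat = rng.uniform(0.5, 2.0, (100, 30))
        truth = mat @ rng.dirichlet(np.ones(30) * 0.2)
        target = sx.IntensityProfile(q_grid=q, intensity=truth, sigma=0.01 * truth)
        pool = _profiles_from_matrix(q, mat)
        return q, mat, pool, target

    def test_union_with_itself_idempotent(self):
        _, _, pool, target = self._setup()
        fit = sx.fit_ensemble(pool, target)
        again = sx.refit_union([fit], pool, target)
        assert sorted(again.member_ids) == sorted(fit.member_ids)
        f1 = dict(zip(fit.member_ids, fit.fractions))
        f2 = dict(zip(again.member_ids, again.fractions))
        for k in f1:
            assert f2[k] == pytest.approx(f1[k], abs=1e-9)

    def test_union_residual_not_worse_than_members(self):
        q, mat, pool, target = self._setup()
        fit_a = sx.fit_ensemble(pool[:15], target)
        fit_b = sx.fit_ensemble(pool, target)
        union = sx.refit_union([fit_a, fit_b], pool, target)
        assert union.residual_norm <= min(fit_a.residual_norm,
                                          fit_b.residual_norm) + 1e-9

    def test_empty_union_rejected(self):
        _, _, pool, target = self._setup()
        with pytest.raises(ValueError, match="empty union"):
            sx.refit_union([], pool, target)
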