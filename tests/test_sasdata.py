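import numpy as np
import pytest

import saxsensemble as sx
from saxsensemble.sasdata import mass_from_sequence

from conftest import sphere_pr_shape


class TestReadIq:
    def test_header_and_count(self, tmp_path):
        path = tmp_path / "data.dat"
        path.write_text(
            "# synthetic sample\nSample description line\n"
            "0.01 100.0 1.0\n0.02 90.0 1.0\n0.03 80.0 1.0\n"
            "0.04 70.0 1.0\n0.05 60.0 1.0\n")
        p = sx.read_iq(path)
        assert p.n_points == 5
        assert p.sigma is not None

    def test_negative_sigma_rejected(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.01 100.0 1.0\n0.02 90.0 -1.0\n")
        with pytest.raises(ValueError, match="negative sigma"):
            sx.read_iq(path)

    def test_non_monotonic_q_rejected(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.02 100.0\n0.01 90.0\n")
        with pytest.raises(ValueError, match="increasing"):
            sx.read_iq(path)

    def test_no_numeric_rows(self, tmp_path):
        path = tmp_path / "empty.dat"
        path.write_text("# nothing here\n")
        with pytest.raises(ValueError, match="no numeric"):
            sx.read_iq(path)


class TestGnomOut:
    def _pr(self, spacing=1.0):
        r = np.arange(0, 60 + spacing / 2, spacing)
        p = np.sin(np.pi * r / 60.0) ** 2 * r
        p[-1] = 0.0
        return sx.DistanceDistribution(r_grid=r, p=p, errors=0.05 * p + 0.1,
                                       dmax=60.0)

    def test_round_trip(self, tmp_path):
        pr = self._pr()
        path = tmp_path / "test.out"
        sx.write_gnom_out(pr, path)
        back, fit, meta = sx.read_gnom_out(path)
        assert np.allclose(back.r_grid, pr.r_grid, atol=1e-3)
        assert np.allclose(back.p, pr.p, rtol=1e-4)
        assert np.allclose(back.errors, pr.errors, rtol=1e-4, atol=1e-4)

    def test_spacing_detected(self, tmp_path):
        pr = self._pr(spacing=0.5)
        path = tmp_path / "half.out"
        sx.write_gnom_out(pr, path)
        _, _, meta = sx.read_gnom_out(path)
        assert meta["spacing"] == pytest.approx(0.5, abs=1e-3)

    def test_fit_block_round_trip(self, tmp_path):
        pr = self._pr()
        q = np.linspace(0.01, 0.3, 20)
        fit = sx.IntensityProfile(q_grid=q, intensity=np.exp(-q * 10))
        path = tmp_path / "with_fit.out"
        sx.write_gnom_out(pr, path, fit=fit)
        _, fit_back, _ = sx.read_gnom_out(path)
        assert fit_back is not None
        assert np.allclose(fit_back.intensity, fit.intensity, rtol=1e-4)

    def test_missing_block_raises(self, tmp_path):
        path = tmp_path / "trunc.out"
        path.write_text("some header\nno distance block here\n")
        with pytest.raises(ValueError, match="no distance-distribution"):
            sx.read_gnom_out(path)


class TestRebin:
    def test_identity_on_one_angstrom_grid(self):
        r = np.arange(0, 51.0)
        pr = sx.DistanceDistribution(r_grid=r, p=np.sin(r / 8), dmax=50.0)
        out = sx.rebin_pr(pr, 1.0)
        assert np.allclose(out.p, pr.p)

    def test_triangle_peak_preserved(self):
        r = np.arange(0, 40.5, 0.5)
        p = np.maximum(0, 1 - np.abs(r - 20.0) / 20.0)
        pr = sx.DistanceDistribution(r_grid=r, p=p, dmax=40.0)
        out = sx.rebin_pr(pr, 1.0)
        assert out.p.max() == pytest.approx(1.0, abs=1e-9)
        # integral preserved on the piecewise-linear profile
        assert np.trapezoid(out.p, out.r_grid) == pytest.approx(
            np.trapezoid(p, r), rel=0.01)

    def test_error_midpoint_is_neighbour_mean(self):
        rng = np.random.default_rng(4)
        r = np.arange(0, 41.0, 2.0)
        e = rng.uniform(0.5, 2.0, len(r))
        pr = sx.DistanceDistribution(r_grid=r, p=np.ones_like(r), errors=e, dmax=40.0)
        out = sx.rebin_pr(pr, 1.0)
        # odd target nodes fall midway between source nodes
        mids = out.errors[1::2]
        expected = (e[:-1] + e[1:]) / 2
        assert np.allclose(mids, expected)

    def test_too_coarse_rejected(self):
        r = np.arange(0, 21.0)
        pr = sx.DistanceDistribution(r_grid=r, p=np.ones_like(r), dmax=20.0)
        with pytest.raises(ValueError, match="too coarse"):
            sx.rebin_pr(pr, 6.0)


class TestGuinier:
    def test_exact_on_guinier_law(self):
        for rg_true, max_qrg in ((40.0, 1.0), (22.0, 1.3)):
            q = np.linspace(0.002, 0.2, 500)
            prof = sx.IntensityProfile(
                q_grid=q, intensity=100 * np.exp(-q**2 * rg_true**2 / 3))
            res = sx.guinier_fit(prof, max_qrg=max_qrg)
            assert abs(res.rg / rg_true - 1) < 1e-6
            assert res.i0 == pytest.approx(100.0, rel=1e-6)
            assert res.max_qrg <= max_qrg + 1e-9

    def test_skip_low_q(self):
        q = np.linspace(0.002, 0.2, 300)
        intensity = 100 * np.exp(-q**2 * 30**2 / 3)
        intensity[:25] *= 10  # parasitic upturn
        prof = sx.IntensityProfile(q_grid=q, intensity=intensity)
        res = sx.guinier_fit(prof, max_qrg=1.0, n_skip_low_q=25)
        assert res.n_skipped_low_q == 25
        assert abs(res.rg - 30.0) < 1e-6

    def test_negative_intensity_in_window(self):
        q = np.linspace(0.01, 0.1, 50)
        intensity = 10 * np.exp(-q**2 * 30**2 / 3)
        intensity[3] = -1.0
        prof = sx.IntensityProfile(q_grid=q, intensity=intensity)
        with pytest.raises(ValueError, match="non-positive"):
            sx.guinier_fit(prof, max_qrg=1.3)


class TestIFT:
    def test_sphere_rg_and_shape(self, sphere_profile):
        res = sx.ift(sphere_profile, dmax=100.0)
        rg_true = np.sqrt(3.0 / 5.0) * 50.0
        assert abs(res.rg / rg_true - 1) < 0.01
        shape = sphere_pr_shape(res.pr.r_grid, 100.0)
        dev = np.abs(res.pr.p / res.pr.p.max() - shape / shape.max())
        assert dev.max() < 0.02
        assert res.pr.p[0] == 0.0 and res.pr.p[-1] == 0.0

    def test_oversized_dmax_leaves_tail_empty(self, sphere_profile):
        res = sx.ift(sphere_profile, dmax=120.0)
        tail = res.pr.p[res.pr.r_grid > 100.0]
        assert tail.max() < 0.01 * res.pr.p.max()

    def test_linearity_in_data(self, sphere_profile):
        res1 = sx.ift(sphere_profile, dmax=100.0, alpha=0.1, error_samples=0)
        scaled = sx.IntensityProfile(q_grid=sphere_profile.q_grid,
                                     intensity=3.0 * sphere_profile.intensity,
                                     sigma=sphere_profile.sigma)
        res3 = sx.ift(scaled, dmax=100.0, alpha=0.1, error_samples=0)
        assert np.allclose(res3.pr.p, 3.0 * res1.pr.p, rtol=1e-6, atol=1e-9)

    def test_invalid_inputs(self, sphere_profile):
        with pytest.raises(ValueError):
            sx.ift(sphere_profile, dmax=5.0)
        with pytest.raises(ValueError):
            sx.ift(sphere_profile, dmax=100.0, alpha=-1.0)
        no_sigma = sx.IntensityProfile(q_grid=sphere_profile.q_grid,
                                       intensity=sphere_profile.intensity)
        with pytest.raises(ValueError):
            sx.ift(no_sigma, dmax=100.0)

    def test_monte_carlo_errors_present(self, sphere_profile):
        res = sx.ift(sphere_profile, dmax=100.0, error_samples=8)
        assert res.pr.errors is not None
        assert res.pr.errors.max() > 0


class TestSelectDmax:
    def test_sphere_diameter_recovered(self, sphere_profile):
        dmax, diag = sx.select_dmax(sphere_profile, dmax_range=(80, 130))
        assert 96 <= dmax <= 106

    def test_two_gaussian_extent(self):
        # synthetic ensemble P(r): two Gaussian humps, max extent 150 A
        r = np.arange(0, 151.0)
        p = (np.exp(-0.5 * ((r - 55) / 16) ** 2)
             + 0.5 * np.exp(-0.5 * ((r - 105) / 14) ** 2))
        p *= np.sin(np.pi * r / 150.0) ** 0.5  # force endpoints to zero
        pr = sx.DistanceDistribution(r_grid=r, p=p, dmax=150.0)
        q = np.linspace(0.008, 0.4, 400)
        iq = sx.pr_to_iq(pr, q, self_term=0.0)
        prof = sx.IntensityProfile(q_grid=q, intensity=iq.intensity,
                                   sigma=0.002 * np.abs(iq.intensity)
                                   + 2e-5 * iq.intensity[0])
        dmax, _ = sx.select_dmax(prof, dmax_range=(100, 200))
        assert abs(dmax - 150.0) <= 15.0

    def test_scale_invariance(self, sphere_profile):
        d1, _ = sx.select_dmax(sphere_profile, dmax_range=(80, 130))
        scaled = sx.IntensityProfile(q_grid=sphere_profile.q_grid,
                                     intensity=100 * sphere_profile.intensity,
                                     sigma=100 * sphere_profile.sigma)
        d2, _ = sx.select_dmax(scaled, dmax_range=(80, 130))
        assert d1 == d2

    def test_released_endpoint_shrinks_with_dmax(self, sphere_profile):
        _, diag = sx.select_dmax(sphere_profile, dmax_range=(80, 130),
                                 released_fraction=-1.0)  # force full scan
        rel = [d["released_endpoint_fraction"] for d in diag]
        # noise-free data: endpoint release decays once dmax covers the particle
        assert rel[-1] < rel[0]


class TestQualityAndMass:
    def test_dmax_limit_arithmetic(self):
        q = np.linspace(0.0141, 0.3, 200)
        prof = sx.IntensityProfile(q_grid=q, intensity=np.exp(-q))
        rep = sx.data_quality(prof, rg_hint=40.0)
        assert rep.dmax_limit == pytest.approx(np.pi / 0.0141, rel=1e-6)
        assert rep.dmax_limit == pytest.approx(222.8, abs=0.1)

    def test_guinier_count_matches_bruteforce(self):
        q = np.linspace(0.005, 0.2, 150)
        prof = sx.IntensityProfile(q_grid=q, intensity=np.exp(-q))
        rg = 35.0
        rep = sx.data_quality(prof, rg_hint=rg, max_qrg=1.3, n_skip=10)
        brute = sum(1 for k, qq in enumerate(q) if k >= 10 and qq * rg <= 1.3)
        assert rep.n_guinier_points == brute

    def test_mass_of_gg(self):
        assert mass_from_sequence("GG") == pytest.approx(132.12, abs=0.01)

    def test_mass_errors(self):
        with pytest.raises(ValueError):
            mass_from_sequence("")
        with pytest.raises(ValueError, match="unknown residue"):
            mass_from_sequence("GXZ1")
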