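"""Gradient scheme generation, standard-model kernels, multi-fascicle
signal synthesis and noise models."""
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erf, eval_legendre

from shardtest import ShardModel, simulate as sim
from shardtest.decomposition import build_matrices, decompose
from shardtest.sh import SHFitter, band_slice, n_coeffs


class TestSchemeGeneration:
    def test_reference_protocol_layout(self, scheme6):
        assert scheme6.n_measurements == 450
        assert scheme6.k == 6
        assert scheme6.n_dw == 420
        np.testing.assert_allclose(
            scheme6.shell_bvals, [900, 1600, 2500, 3600, 4900, 6400]
        )
        assert len(scheme6.b0_indices) == 30

    def test_directions_distinct_across_shells(self, scheme6):
        d0 = scheme6.shell_directions(0)
        d1 = scheme6.shell_directions(1)
        assert np.abs(d0 - d1).max() > 1e-3

    def test_reproducible_under_seed(self):
        a = sim.make_directions(20, seed=7)
        b = sim.make_directions(20, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_single_direction_accepted_with_warning(self):
        with pytest.warns(UserWarning, match="lmax=8"):
            s = sim.make_scheme(bvalues=(1000.0,), dirs_per_shell=1, n_b0=0, seed=0)
        assert s.n_dw == 1

    def test_repulsion_beats_random_min_angle(self, scheme6):
        """The 70-direction set's minimum pairwise angle exceeds that of
        uniformly random 70-point sets in >= 95% of trials."""
        opt = scheme6.min_angle_deg(0)
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(100):
            x = rng.normal(size=(70, 3))
            x /= np.linalg.norm(x, axis=1, keepdims=True)
            c = np.abs(x @ x.T)
            np.fill_diagonal(c, 0)
            rand_angle = np.degrees(np.arccos(np.clip(c.max(), 0, 1)))
            wins += opt > rand_angle
        assert wins >= 95

    def test_repulsion_lowers_energy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        assert sim.repulsion_energy(sim.make_directions(30, seed=1)) < (
            sim.repulsion_energy(x)
        )


class TestStandardModelKernel:
    def test_unit_signal_at_b0(self):
        for kern in (sim.DEFAULT_KERNEL, sim.StandardModelKernel(1.0, 2.0, 0, 0)):
            assert sim.stm_signal(kern, 0.0, 0.3) == pytest.approx(1.0)

    def test_pure_stick_perpendicular(self):
        stick = sim.StandardModelKernel(f=1.0, d_i=2.0, d_e=0.0, d_r=0.0)
        assert sim.stm_signal(stick, 6400.0, 0.0) == pytest.approx(1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="f"):
            sim.StandardModelKernel(1.2, 2.0, 2.0, 0.5)
        with pytest.raises(ValueError, match="d_e"):
            sim.StandardModelKernel(0.5, 2.0, 0.5, 1.0)

    def test_stick_l0_closed_form(self):
        """The l=0 zonal coefficient of a pure stick has the closed form
        sqrt(pi) * sqrt(pi/a) * erf(sqrt(a)), a = b D."""
        stick = sim.StandardModelKernel(f=1.0, d_i=2.0, d_e=0.0, d_r=0.0)
        b = 6400.0
        a = b * 1e-3 * 2.0
        expected = np.sqrt(np.pi) * np.sqrt(np.pi / a) * erf(np.sqrt(a))
        hbar = sim.kernel_to_zonal(stick, [b], 0)
        assert hbar[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_zonal_matches_adaptive_quadrature(self):
        """Gauss-Legendre zonal projections match adaptive quadrature of
        the projection integral for a high-b stick kernel."""
        stick = sim.StandardModelKernel(f=1.0, d_i=2.0, d_e=0.0, d_r=0.0)
        b = 6400.0
        hbar = sim.kernel_to_zonal(stick, [b], 8)
        for j, l in enumerate([0, 2, 4, 6, 8]):
            ref = 2 * np.pi * np.sqrt((2 * l + 1) / (4 * np.pi)) * quad(
                lambda xi: np.exp(-b * 1e-3 * 2.0 * xi**2) * eval_legendre(l, xi),
                -1, 1, epsabs=1e-12,
            )[0]
            assert hbar[0, j] == pytest.approx(ref, abs=1e-8)

    def test_isotropic_kernel_has_no_angular_content(self):
        iso = sim.StandardModelKernel(f=0.0, d_i=0.0, d_e=1.5, d_r=1.5)
        hbar = sim.kernel_to_zonal(iso, [3000.0], 8)
        np.testing.assert_allclose(hbar[0, 1:], 0.0, atol=1e-12)
        assert hbar[0, 0] > 0

    def test_b_to_zero_limit_is_flat(self):
        hbar = sim.kernel_to_zonal(sim.DEFAULT_KERNEL, [1e-9], 8)
        # hbar_0 = 2 sqrt(pi) * spherical mean; mean -> 1 as b -> 0
        assert hbar[0, 0] == pytest.approx(2 * np.sqrt(np.pi), rel=1e-6)
        np.testing.assert_allclose(hbar[0, 1:], 0.0, atol=1e-6)

    def test_perturbed_pair(self):
        k1, k2 = sim.DEFAULT_KERNEL.perturbed("f", 0.3)
        assert (k1.f, k2.f) == (0.35, 0.65)


class TestVoxelSimulation:
    def test_same_kernel_crossing_is_rank_one(self, scheme6, fitter8):
        config = [
            sim.Fascicle(sim.DEFAULT_KERNEL, np.array([0, 0, 1.0]), 0.5),
            sim.Fascicle(sim.DEFAULT_KERNEL, np.array([1.0, 0, 0]), 0.5),
        ]
        y = sim.simulate_voxel(config, scheme6, band_limit=8)
        dec = decompose(build_matrices(fitter8.fit(y), 8))
        assert dec.R == pytest.approx(100.0, abs=1e-10)

    def test_equal_kernel_random_geometry_rank_one(self, scheme6, fitter8):
        """The reduction to a single convolution holds for any geometry
        when all kernels are equal up to scale (100 random draws)."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            kern = sim.StandardModelKernel(
                f=rng.uniform(0, 1), d_i=rng.uniform(0.5, 3),
                d_e=rng.uniform(1, 3), d_r=rng.uniform(0, 1),
            )
            n_fas = rng.integers(2, 5)
            dirs = rng.normal(size=(n_fas, 3))
            config = [
                sim.Fascicle(kern, d, w, dispersion=rng.uniform(0, 0.4))
                for d, w in zip(dirs, rng.uniform(0.2, 2.0, n_fas))
            ]
            y = sim.simulate_voxel(config, scheme6, band_limit=8)
            dec = decompose(build_matrices(fitter8.fit(y), 8))
            assert dec.R == pytest.approx(100.0, abs=1e-9)

    def test_crossing_with_kernel_difference_raises_rank(self, scheme6, fitter8):
        """A 90-degree crossing with delta f = 0.3 yields sigma_2 > 0,
        matching an independent construction from analytic per-order
        outer products."""
        config = sim.crossing_config("f", 0.3, dispersion=0.0)
        y = sim.simulate_voxel(config, scheme6, band_limit=8)
        dec = decompose(build_matrices(fitter8.fit(y), 8))
        ratio = dec.sigmas[1] / dec.sigmas[0]
        assert ratio > 1e-4

        # oracle: S_l built directly from the analytic kernel and delta-ODF
        # coefficients of the two fascicles, bypassing signal space
        from shardtest.sh import convolve_sh, eval_sh_basis

        C = np.zeros((6, n_coeffs(8)))
        for fas in config:
            hbar = sim.kernel_to_zonal(fas.kernel, scheme6.shell_bvals, 8)
            p = fas.weight * eval_sh_basis(fas.direction[None, :], 8)[0]
            C += convolve_sh(hbar, p, 8)
        ref = decompose(build_matrices(C, 8))
        assert dec.sigmas[1] / dec.sigmas[0] == pytest.approx(
            ref.sigmas[1] / ref.sigmas[0], rel=1e-6
        )

    def test_truncation_error_grows_with_b(self, scheme6, fitter8):
        """Kernels sharpen with b, so the lmax=8 truncation error of an
        exact delta-fascicle signal is larger at b=6400 than at b=900."""
        fas = [sim.Fascicle(sim.DEFAULT_KERNEL, np.array([0, 0, 1.0]),
                            dispersion=0.0)]
        y = sim.simulate_voxel(fas, scheme6)  # exact evaluation
        C = fitter8.fit(y)
        err = []
        for i in (0, 5):
            resid = y[scheme6.shells[i]] - fitter8.designs[i] @ C[i]
            err.append(np.sqrt(np.mean(resid**2)))
        assert err[0] < err[1]

    def test_gaussian_residual_std_matches_leverage(self, scheme6):
        """Residual std after the rank-1 fit is sqrt(1-h)/snr."""
        fas = [sim.Fascicle(sim.DEFAULT_KERNEL, np.array([0, 0, 1.0]))]
        snr = 50.0
        y = sim.simulate_voxels(10_000, fas, scheme6,
                                sim.NoiseSpec("gaussian", snr), seed=3)
        res = ShardModel(y, scheme6).fit()
        h = res.leverage.h
        # band-sparse voxels absorb slightly more than kappa/nu; allow 4%
        assert np.sqrt(np.mean(res.residuals**2)) == pytest.approx(
            np.sqrt(1 - h) / snr, rel=0.04
        )

    def test_rician_close_to_gaussian_at_snr30(self, scheme6):
        fas = [sim.Fascicle(sim.DEFAULT_KERNEL, np.array([0, 0, 1.0]))]
        yg = sim.simulate_voxels(3000, fas, scheme6,
                                 sim.NoiseSpec("gaussian", 30), seed=4)
        yr = sim.simulate_voxels(3000, fas, scheme6,
                                 sim.NoiseSpec("rician", 30), seed=4)
        # mean-signal bias across the acquisition stays below 2% of b0;
        # per-measurement the Rician floor (sigma sqrt(pi/2), ~4% of b0 at
        # SNR 30) is reached only where the signal is fully attenuated
        assert np.abs(yg.mean(axis=0) - yr.mean(axis=0)).mean() < 0.02

    def test_reproducible_under_seed(self, scheme6):
        fas = [sim.Fascicle(sim.DEFAULT_KERNEL, np.array([0, 0, 1.0]))]
        a = sim.simulate_voxels(5, fas, scheme6, sim.NoiseSpec("gaussian", 20), seed=9)
        b = sim.simulate_voxels(5, fas, scheme6, sim.NoiseSpec("gaussian", 20), seed=9)
        np.testing.assert_array_equal(a, b)

    def test_empty_config_rejected(self, scheme6):
        with pytest.raises(ValueError, match="fascicle"):
            sim.simulate_voxel([], scheme6)

    def test_b0_signal_is_total_weight(self, scheme6):
        config = sim.crossing_config("f", 0.2)
        y = sim.simulate_voxel(config, scheme6)
        np.testing.assert_allclose(y[scheme6.b0_indices], 1.0, rtol=1e-12)


class TestPowerSurface:
    def test_null_column_rejects_at_alpha(self, power_grid):
        """At delta = 0 the detection rate stays within binomial error of
        the significance level (100 voxels per cell)."""
        null_rows = power_grid[power_grid["delta"] == 0.0]
        half = 2.576 * np.sqrt(0.05 * 0.95 / 100)
        assert (null_rows["rate_0.05"] <= 0.05 + half).all()

    def test_contours_nested_in_snr(self, power_grid):
        """The 50% detection contour at p < 0.001 sits at higher SNR than
        at p < 0.05 wherever both exist."""
        c05 = sim.contour_snr(power_grid, 0.05).set_index("delta")
        c001 = sim.contour_snr(power_grid, 0.001).set_index("delta")
        both = c05.join(c001, lsuffix="_05", rsuffix="_001").dropna()
        assert len(both) >= 1
        assert (both["snr_crossing_001"] > both["snr_crossing_05"]).all()

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            sim.power_surface(deltas=(), snrs=(10,), n_voxels=1, n_perm=9)
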