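"""Shared fixtures: the reference 6-shell scheme, precomputed fitters,
and the expensive null-calibration / power-grid simulations reused by
several tests."""
import numpy as np
import pytest

from shardtest import ShardModel, simulate as sim
from shardtest.sh import SHFitter, convolve_sh, n_coeffs


@pytest.fixture(scope="session")
def scheme6():
    """Reference protocol: 6 shells x 70 directions + 30 b=0."""
    return sim.make_scheme(seed=0)


@pytest.fixture(scope="session")
def fitter8(scheme6):
    return SHFitter(scheme6, 8)


@pytest.fixture(scope="session")
def small_scheme():
    """Cheap 3-shell scheme usable at lmax=4 (15 coefficients)."""
    return sim.make_scheme(bvalues=(1000.0, 2500.0, 5000.0), dirs_per_shell=24,
                           n_b0=3, seed=0)


def fullband_voxel(scheme, fitter, rng, amp=1.0, offset=2.0):
    """Noise-free single-kernel voxel whose random ODF carries power in
    every fitted band (the regime where the leverage count is exact)."""
    p = rng.normal(size=n_coeffs(fitter.lmax)) * amp
    p[0] = abs(p[0]) + offset
    hbar = sim.kernel_to_zonal(sim.DEFAULT_KERNEL, scheme.shell_bvals, fitter.lmax)
    C = convolve_sh(hbar, p, fitter.lmax)
    y = np.zeros(scheme.n_measurements)
    for i, idx in enumerate(scheme.shells):
        y[idx] = fitter.designs[i] @ C[i]
    y[scheme.b0_indices] = p[0] * 2 * np.sqrt(np.pi)
    return y, p, hbar


@pytest.fixture(scope="session")
def wm_voxels_snr80(scheme6):
    """1000 white-matter-like rank-1 voxels (dispersed single fascicle)
    with Gaussian noise at SNR 80, plus their fitted results."""
    fas = [sim.Fascicle(sim.DEFAULT_KERNEL, np.array([0.0, 0.0, 1.0]))]
    y = sim.simulate_voxels(1000, fas, scheme6, sim.NoiseSpec("gaussian", 80),
                            seed=np.random.SeedSequence(0))
    res = ShardModel(y, scheme6).fit()
    return res


@pytest.fixture(scope="session")
def null_test_wm(scheme6):
    """Permutation test of 500 rank-1 null voxels (dispersed fascicle,
    SNR 30, 999 permutations): the type-I calibration experiment."""
    fas = [sim.Fascicle(sim.DEFAULT_KERNEL, np.array([0.0, 0.0, 1.0]))]
    y = sim.simulate_voxels(500, fas, scheme6, sim.NoiseSpec("gaussian", 30),
                            seed=np.random.SeedSequence(0))
    res = ShardModel(y, scheme6).fit()
    test = res.rank_test(n_perm=999, seed=0)
    return res, test


@pytest.fixture(scope="session")
def null_test_fullband(scheme6, fitter8):
    """Permutation test of 500 rank-1 null voxels whose ODFs occupy all
    fitted bands (SNR 30, 999 permutations)."""
    rng = np.random.default_rng(0)
    Y = np.empty((500, scheme6.n_measurements))
    for v in range(500):
        Y[v] = fullband_voxel(scheme6, fitter8, rng, amp=0.3, offset=0.3)[0]
    Y += rng.normal(0, 1 / 30, size=Y.shape)
    res = ShardModel(Y, scheme6).fit()
    test = res.rank_test(n_perm=999, seed=0)
    return res, test


@pytest.fixture(scope="session")
def power_grid(scheme6):
    """Detection-rate grid of the two-kernel 90-degree crossing over
    (delta f) x SNR, 100 voxels per cell, 999 permutations."""
    return sim.power_surface(param="f", deltas=(0.0, 0.25, 0.5),
                             snrs=(15.0, 40.0, 100.0), n_voxels=100,
                             n_perm=999, seed=0, scheme=scheme6)
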