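"""Independent quadrature oracles used by the tests.

A Gauss-Legendre (polar) x trapezoid (azimuth) product grid integrates
band-limited spherical functions exactly, giving brute-force references
for basis orthonormality, Parseval, zonal projections and the spherical
convolution integral — all computed without the package's SH-multiplication
path.
"""
import numpy as np
from numpy.polynomial.legendre import leggauss


def sphere_grid(n_polar=64, n_azimuth=129):
    """Product quadrature nodes (m, 3) and weights (m,) integrating over
    the unit sphere (sum of weights = 4 pi)."""
    xi, w = leggauss(n_polar)
    phi = np.arange(n_azimuth) * 2 * np.pi / n_azimuth
    theta = np.arccos(xi)
    st = np.sin(theta)
    dirs = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.outer(np.cos(theta), np.ones_like(phi)).ravel(),
        ],
        axis=1,
    )
    weights = np.outer(w, np.full(n_azimuth, 2 * np.pi / n_azimuth)).ravel()
    return dirs, weights


def sphere_integral(values, weights):
    return np.tensordot(values, weights, axes=([0], [0]))


def convolve_bruteforce(kernel_func, odf_values, grid_dirs, grid_weights, out_dirs):
    """Direct numerical evaluation of the spherical convolution integral
    S(g) = int H(g . n) P(n) dn over the quadrature grid, for each output
    direction g."""
    out = np.empty(len(out_dirs))
    for j, g in enumerate(np.atleast_2d(out_dirs)):
        ct = grid_dirs @ g
        out[j] = np.sum(grid_weights * kernel_func(ct) * odf_values)
    return out
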