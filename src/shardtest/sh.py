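"""Real symmetric spherical harmonics: basis evaluation, per-shell
least-squares fitting, and spherical convolution as SH multiplication.

Convention
----------
The basis is real, orthonormal, and restricted to even orders
(antipodally symmetric signals).  With ``Y_l^m`` the complex spherical
harmonic of scipy (Condon--Shortley phase included), the real basis is

    Y_{l,m} = sqrt(2) * (-1)^m * Im(Y_l^|m|)   for m < 0
    Y_{l,0} = Y_l^0                            for m = 0
    Y_{l,m} = sqrt(2) * (-1)^m * Re(Y_l^m)     for m > 0

The ``(-1)^m`` factor cancels the Condon--Shortley phase, so all zonal
and tesseral functions carry the plain associated-Legendre sign.
Coefficients are ordered with l ascending and, within each order, m
ascending from -l to +l.

Spherical convolution of an axially symmetric kernel (zonal coefficients
``hbar_{l,b}``) with an ODF (coefficients ``p_l^m``) multiplies per
coefficient:

    s_{l,b}^m = sqrt(4 pi / (2 l + 1)) * hbar_{l,b} * p_l^m = h_{l,b} p_l^m
"""
from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

from .scheme import GradientScheme

__all__ = [
    "n_coeffs",
    "even_orders",
    "band_slice",
    "coeff_orders",
    "convolution_scale",
    "eval_sh_basis",
    "fit_sh_per_shell",
    "convolve_sh",
    "zonal_to_scaled",
    "SHFitter",
]

UNIT_NORM_ATOL = 1e-3  # directions further from unit norm than this are rejected


def n_coeffs(lmax: int) -> int:
    """Number of even-order basis functions up to lmax: (lmax+1)(lmax+2)/2."""
    _check_even(lmax)
    return (lmax + 1) * (lmax + 2) // 2


def even_orders(lmax: int) -> np.ndarray:
    _check_even(lmax)
    return np.arange(0, lmax + 1, 2)


def band_slice(l: int) -> slice:
    """Column slice of order l in the even-order coefficient layout."""
    _check_even(l)
    start = l * (l - 1) // 2
    return slice(start, start + 2 * l + 1)


def coeff_orders(lmax: int) -> np.ndarray:
    """Order l of every coefficient column, length n_coeffs(lmax)."""
    return np.concatenate([np.full(2 * l + 1, l) for l in even_orders(lmax)])


def convolution_scale(l) -> np.ndarray:
    """Per-order factor sqrt(4 pi / (2l+1)) mapping zonal kernel coefficients
    to the scaled form that multiplies the ODF coefficients."""
    l = np.asarray(l)
    return np.sqrt(4 * np.pi / (2 * l + 1))


def _check_even(l: int) -> None:
    if l < 0 or l % 2:
        raise ValueError(f"spherical harmonic order must be even and >= 0, got {l}")


def _to_angles(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise ValueError(f"directions must be (n, 3), got {directions.shape}")
    norms = np.linalg.norm(directions, axis=-1)
    if np.any(np.abs(norms - 1.0) > UNIT_NORM_ATOL):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(
            f"direction vectors must have unit norm (worst deviation {worst:.2e}); "
            "normalize them, e.g. v / np.linalg.norm(v)"
        )
    directions = directions / norms[:, None]
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    return theta, phi


def eval_sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the real even-order SH basis at unit direction vectors.

    Parameters
    ----------
    directions : (n, 3) array of unit vectors.
    lmax : even int
        Maximum harmonic order.

    Returns
    -------
    (n, n_coeffs(lmax)) design matrix, columns ordered (l asc, m asc).
    """
    _check_even(lmax)
    theta, phi = _to_angles(directions)
    out = np.empty((theta.size, n_coeffs(lmax)))
    for l in even_orders(lmax):
        sl = band_slice(l)
        block = out[:, sl]
        block[:, l] = sph_harm_y(l, 0, theta, phi).real
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            sign = (-1) ** m
            block[:, l + m] = np.sqrt(2.0) * sign * y.real
            block[:, l - m] = np.sqrt(2.0) * sign * y.imag
    return out


def fit_sh_per_shell(
    signal: np.ndarray, scheme: GradientScheme, lmax: int = 8
) -> np.ndarray:
    """Ordinary least-squares SH fit of one voxel's signal, per shell.

    Parameters
    ----------
    signal : (n_measurements,) array
        Voxel signal ordered as the scheme (b=0 entries, if present, are
        ignored by the fit).
    scheme : GradientScheme
    lmax : even int

    Returns
    -------
    (k, n_coeffs(lmax)) array of SH coefficients, one row per shell in
    scheme order.
    """
    return SHFitter(scheme, lmax).fit(signal)


def zonal_to_scaled(hbar: np.ndarray, lmax: int) -> np.ndarray:
    """Scaled kernel coefficients h_{l,b} = sqrt(4pi/(2l+1)) hbar_{l,b}.

    `hbar` has shape (k, n_bands) with bands l = 0, 2, ..., lmax.
    """
    ls = even_orders(lmax)
    hbar = np.atleast_2d(np.asarray(hbar, dtype=float))
    if hbar.shape[1] != ls.size:
        raise ValueError(
            f"expected {ls.size} zonal bands for lmax={lmax}, got {hbar.shape[1]}"
        )
    return hbar * convolution_scale(ls)


def convolve_sh(hbar: np.ndarray, odf: np.ndarray, lmax: int) -> np.ndarray:
    """Spherical convolution in the SH domain (per-coefficient product).

    Parameters
    ----------
    hbar : (k, n_bands) array
        Zonal SH coefficients of the axially symmetric kernel per shell,
        bands l = 0, 2, ..., lmax.
    odf : (n_coeffs(lmax),) array
        SH coefficients of the ODF.
    lmax : even int

    Returns
    -------
    (k, n_coeffs(lmax)) array of signal SH coefficients per shell.
    """
    odf = np.asarray(odf, dtype=float)
    if odf.shape[-1] != n_coeffs(lmax):
        raise ValueError(
            f"ODF has {odf.shape[-1]} coefficients; lmax={lmax} requires "
            f"{n_coeffs(lmax)} — kernel and ODF must share lmax"
        )
    h = zonal_to_scaled(hbar, lmax)
    out = np.empty((h.shape[0], odf.shape[-1]))
    for j, l in enumerate(even_orders(lmax)):
        out[:, band_slice(l)] = h[:, j, None] * odf[band_slice(l)]
    return out


class SHFitter:
    """Precomputed per-shell design matrices and pseudoinverses for one
    scheme + lmax, reused across voxels and bootstrap instances.

    Attributes
    ----------
    designs : list of (m_i, n_coeffs) design matrices, one per shell.
    pinvs : list of (n_coeffs, m_i) pseudoinverses.
    """

    def __init__(self, scheme: GradientScheme, lmax: int = 8):
        _check_even(lmax)
        self.scheme = scheme
        self.lmax = lmax
        self.nc = n_coeffs(lmax)
        self.designs = []
        self.pinvs = []
        for i, idx in enumerate(scheme.shells):
            if len(idx) < self.nc:
                raise ValueError(
                    f"shell {i} (b={scheme.shell_bvals[i]:.0f} s/mm^2) has only "
                    f"{len(idx)} directions but the lmax={lmax} basis needs "
                    f">= {self.nc}; the fit is under-determined"
                )
            B = eval_sh_basis(scheme.bvecs[idx], lmax)
            self.designs.append(B)
            self.pinvs.append(np.linalg.pinv(B))

    def fit(self, signal: np.ndarray) -> np.ndarray:
        """OLS coefficients (k, n_coeffs) of one voxel's signal."""
        signal = np.asarray(signal, dtype=float)
        if signal.shape[-1] != self.scheme.n_measurements:
            raise ValueError(
                f"signal has {signal.shape[-1]} entries; scheme expects "
                f"{self.scheme.n_measurements}"
            )
        return np.stack(
            [signal[..., idx] @ P.T for P, idx in zip(self.pinvs, self.scheme.shells)],
            axis=-2,
        )

    def fit_dw(self, dw_signal: np.ndarray) -> np.ndarray:
        """OLS coefficients from signals holding only the nu diffusion-weighted
        entries, concatenated shell by shell.  Accepts (..., nu) batches."""
        dw_signal = np.asarray(dw_signal, dtype=float)
        out = []
        start = 0
        for P, idx in zip(self.pinvs, self.scheme.shells):
            stop = start + len(idx)
            out.append(dw_signal[..., start:stop] @ P.T)
            start = stop
        return np.stack(out, axis=-2)

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """Signal-space evaluation (..., nu) of per-shell coefficients
        (..., k, n_coeffs), concatenated shell by shell."""
        coeffs = np.asarray(coeffs, dtype=float)
        return np.concatenate(
            [coeffs[..., i, :] @ B.T for i, B in enumerate(self.designs)], axis=-1
        )
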