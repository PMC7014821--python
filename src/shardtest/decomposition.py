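"""Voxel-wise SHARD decomposition.

For one voxel, the per-shell SH coefficients of order l are arranged in a
matrix S_l with the k shells in rows and the 2l+1 coefficients (m
ascending) in columns.  Under a single spherical convolution (one kernel,
one ODF) each S_l is the outer product h_l p_l^T and hence exactly rank
1; additional kernels with distinct orientation structure raise the rank.

The SVD of every S_l yields singular triplets (u_{l,i}, sigma_{l,i},
v_{l,i}).  Components are pooled across orders purely by singular-value
index:

    sigma_i^2 = sum_l sigma_{l,i}^2

and the fraction of total signal power captured by the leading component
is

    R = sigma_1^2 / sum_i sigma_i^2 * 100  (percent).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import GradientScheme
from .sh import SHFitter, band_slice, even_orders, n_coeffs

__all__ = [
    "build_matrices",
    "decompose",
    "pooled_sigmas",
    "rank1_reconstruct",
    "ShardDecomposition",
    "Rank1Fit",
]


def build_matrices(coeffs: np.ndarray, lmax: int) -> dict[int, np.ndarray]:
    """Slice a (k, n_coeffs) per-shell coefficient array into the per-order
    matrices {l: S_l of shape (k, 2l+1)}.

    The views share memory with `coeffs`.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.ndim != 2 or coeffs.shape[1] != n_coeffs(lmax):
        raise ValueError(
            f"expected coefficient array of shape (k, {n_coeffs(lmax)}) for "
            f"lmax={lmax}, got {coeffs.shape}"
        )
    return {int(l): coeffs[:, band_slice(int(l))] for l in even_orders(lmax)}


def _fix_svd_signs(u: np.ndarray, vt: np.ndarray) -> None:
    # reproducible sign convention: largest-|entry| of each u column positive
    for i in range(u.shape[1]):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] *= -1
            vt[i, :] *= -1


@dataclass(frozen=True)
class ShardDecomposition:
    """Per-order singular triplets of one voxel and their pooled summaries.

    Attributes
    ----------
    lmax : even int
    U, s, Vt : dicts keyed by order l
        ``U[l]`` is (k, r_l), ``s[l]`` is (r_l,) descending, ``Vt[l]`` is
        (r_l, 2l+1), with r_l = min(k, 2l+1).
    sigmas : (n_components,) array
        Pooled effect sizes sigma_i (RMS signal units), index-aligned
        across orders; n_components = max_l r_l.
    R : float
        Signal power explained by the leading component, in percent.
        Defined as 100 for an all-zero voxel (see ``degenerate``).
    degenerate : bool
        True when the voxel had no signal power at all.
    """

    lmax: int
    U: dict[int, np.ndarray]
    s: dict[int, np.ndarray]
    Vt: dict[int, np.ndarray]
    sigmas: np.ndarray
    R: float
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.sigmas.shape[0]

    def total_power(self) -> float:
        """Sum_i sigma_i^2 = sum_l ||S_l||_F^2."""
        return float(np.sum(self.sigmas**2))

    def rms_beyond_leading(self) -> float:
        """sqrt(sum_{i>1} sigma_i^2): RMS signal in components 2..r."""
        return float(np.sqrt(np.sum(self.sigmas[1:] ** 2)))


def decompose(matrices: dict[int, np.ndarray]) -> ShardDecomposition:
    """Full SVD of every S_l plus pooled effect sizes and the ratio R."""
    orders = sorted(matrices)
    lmax = orders[-1]
    k = matrices[orders[0]].shape[0]
    U, s, Vt = {}, {}, {}
    n_comp = 0
    for l in orders:
        S = np.asarray(matrices[l], dtype=float)
        if S.shape != (k, 2 * l + 1):
            raise ValueError(
                f"S_{l} must have shape ({k}, {2 * l + 1}), got {S.shape}"
            )
        u, sv, vt = np.linalg.svd(S, full_matrices=False)
        _fix_svd_signs(u, vt)
        U[l], s[l], Vt[l] = u, sv, vt
        n_comp = max(n_comp, sv.size)

    sig2 = np.zeros(n_comp)
    for l in orders:
        sig2[: s[l].size] += s[l] ** 2
    total = sig2.sum()
    if total == 0.0:
        return ShardDecomposition(
            lmax=lmax, U=U, s=s, Vt=Vt, sigmas=np.sqrt(sig2), R=100.0, degenerate=True
        )
    R = float(sig2[0] / total * 100.0)
    return ShardDecomposition(lmax=lmax, U=U, s=s, Vt=Vt, sigmas=np.sqrt(sig2), R=R)


def pooled_sigmas(coeffs: np.ndarray, k: int, lmax: int) -> np.ndarray:
    """Pooled effect sizes sigma_i for batches of coefficient arrays.

    Fast path for permutation sampling: singular values only, computed as
    eigenvalues of the small k x k Gram matrices S_l S_l^T.

    Parameters
    ----------
    coeffs : (..., k, n_coeffs) array
    k : number of shells
    lmax : even int

    Returns
    -------
    (..., n_components) array of sigma_i, descending in i.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    n_comp = max(min(k, 2 * int(l) + 1) for l in even_orders(lmax))
    sig2 = np.zeros(coeffs.shape[:-2] + (n_comp,))
    for l in even_orders(lmax):
        S = coeffs[..., band_slice(int(l))]
        r = min(k, 2 * int(l) + 1)
        if r == 1:
            sig2[..., 0] += np.sum(S**2, axis=(-2, -1))
            continue
        G = S @ np.swapaxes(S, -2, -1)
        ev = np.linalg.eigvalsh(G)  # ascending
        ev = np.clip(ev[..., ::-1], 0.0, None)  # descending, non-negative
        sig2[..., :r] += ev[..., :r]
    return np.sqrt(sig2)


@dataclass(frozen=True)
class Rank1Fit:
    """Rank-1 signal reconstruction of one voxel.

    ``yhat`` and ``residuals`` hold the nu diffusion-weighted entries,
    concatenated shell by shell in scheme order.
    """

    yhat: np.ndarray
    residuals: np.ndarray
    coeffs_rank1: np.ndarray  # (k, n_coeffs) truncated coefficients


def rank1_reconstruct(
    dec: ShardDecomposition,
    fitter: SHFitter,
    signal: np.ndarray,
) -> Rank1Fit:
    """Signal-space rank-1 representation yhat and residuals e = y - yhat.

    Parameters
    ----------
    dec : decomposition of this voxel's coefficients under `fitter`.
    fitter : SHFitter for the same scheme and lmax.
    signal : the voxel's measurements ordered as the scheme (full length;
        b=0 entries are ignored).
    """
    if dec.lmax != fitter.lmax:
        raise ValueError(
            f"decomposition lmax={dec.lmax} does not match fitter lmax={fitter.lmax}"
        )
    k = fitter.scheme.k
    c1 = np.zeros((k, fitter.nc))
    for l in even_orders(dec.lmax):
        l = int(l)
        u, sv, vt = dec.U[l], dec.s[l], dec.Vt[l]
        c1[:, band_slice(l)] = sv[0] * np.outer(u[:, 0], vt[0, :])
    yhat = fitter.synthesize(c1)
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] == fitter.scheme.n_measurements:
        y_dw = signal[..., fitter.scheme.dw_indices]
    elif signal.shape[-1] == fitter.scheme.n_dw:
        y_dw = signal
    else:
        raise ValueError(
            f"signal length {signal.shape[-1]} matches neither the full scheme "
            f"({fitter.scheme.n_measurements}) nor its diffusion-weighted part "
            f"({fitter.scheme.n_dw})"
        )
    return Rank1Fit(yhat=yhat, residuals=y_dw - yhat, coeffs_rank1=c1)
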