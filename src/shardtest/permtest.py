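"""Permutation test of the single-convolution (rank-1) null hypothesis.

The null distribution of the effect sizes sigma_i (i > 1) is sampled by
residual bootstrapping: permute the rank-1 residuals, rescale them for
the leverage of the least-squares fit, add them back onto the rank-1
representation, refit, and re-measure the effect sizes.  The one-sided
p-value of component i is

    P_i = 1 - (N_i+ + 1) / (N + 1)

with N_i+ the number of bootstrap instances whose sigma'_i lies strictly
below the measured sigma_i.  Voxel maps of P_i are corrected with the
Benjamini-Hochberg FDR step-up procedure.

Leverage
--------
An OLS fit with kappa model degrees of freedom to nu data points leaves
residuals whose mean square is (nu - kappa)/nu times the noise variance,
so permuted residuals are scaled up before reuse.  With the voxel-wise
decomposition, kappa = sum_l [k + (2l+1) - 1] over even orders
(each rank-1 factorization of the k x (2l+1) matrix S_l has
k + (2l+1) - 1 free parameters) and nu = k x directions-per-shell.  The
default rescaling is 1/sqrt(1 - h), which restores the residual variance
to the noise variance; the factor 1/(1 - h) is available as
``leverage_mode="linear"``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .decomposition import Rank1Fit, pooled_sigmas
from .sh import SHFitter, even_orders

__all__ = [
    "LeverageSpec",
    "leverage_factor",
    "leverage_scale",
    "NullSamples",
    "sample_null",
    "p_values",
    "fdr_correct",
]


@dataclass(frozen=True)
class LeverageSpec:
    """Degrees of freedom kappa, data points nu, and leverage h = kappa/nu."""

    kappa: int
    nu: int

    def __post_init__(self):
        if not 0 < self.kappa < self.nu:
            raise ValueError(
                f"leverage requires 0 < kappa < nu, got kappa={self.kappa}, nu={self.nu}"
            )

    @property
    def h(self) -> float:
        return self.kappa / self.nu


def leverage_factor(k: int, lmax: int, dirs_per_shell: int) -> LeverageSpec:
    """Leverage of the voxel-wise rank-1 fit.

    kappa = sum over even l <= lmax of [k + (2l+1) - 1]; nu = k * dirs_per_shell.
    For the 6-shell, 70-direction, lmax=8 protocol: kappa=70, nu=420, h=1/6.
    """
    if k < 1:
        raise ValueError(f"need at least one shell, got k={k}")
    kappa = int(sum(k + (2 * int(l) + 1) - 1 for l in even_orders(lmax)))
    nu = int(k * dirs_per_shell)
    return LeverageSpec(kappa=kappa, nu=nu)


def leverage_scale(h: float, mode: str = "sqrt") -> float:
    """Residual inflation factor: 1/sqrt(1-h) (variance-restoring, default)
    or 1/(1-h)."""
    if not 0 < h < 1:
        raise ValueError(f"leverage h must lie in (0, 1), got {h}")
    if mode == "sqrt":
        return 1.0 / np.sqrt(1.0 - h)
    if mode == "linear":
        return 1.0 / (1.0 - h)
    raise ValueError(f"leverage_mode must be 'sqrt' or 'linear', got {mode!r}")


@dataclass(frozen=True)
class NullSamples:
    """Bootstrap null samples of the pooled effect sizes.

    ``sigmas`` has shape (N, n_components): one row of sigma'_i per
    bootstrap instance (component 1 included for completeness; the test
    concerns i > 1).
    """

    sigmas: np.ndarray
    seed: int
    leverage_mode: str
    replace: bool

    @property
    def n(self) -> int:
        return self.sigmas.shape[0]


def sample_null(
    fit: Rank1Fit,
    fitter: SHFitter,
    spec: LeverageSpec,
    n_perm: int,
    seed,
    leverage_mode: str = "sqrt",
    replace: bool = False,
) -> NullSamples:
    """Sample N bootstrap instances of the rank-1 null for one voxel.

    Each instance permutes the nu residuals (without replacement by
    default; ``replace=True`` resamples i.i.d.), scales them for
    leverage, adds them to the rank-1 representation yhat, refits the SH
    coefficients per shell, and stores the pooled singular values.

    Deterministic for a fixed seed; pass a ``numpy.random.SeedSequence``
    or int.
    """
    if n_perm < 1:
        raise ValueError(f"need at least one bootstrap instance, got {n_perm}")
    rng = np.random.default_rng(seed)
    e = np.asarray(fit.residuals, dtype=float)
    nu = e.shape[-1]
    if nu != spec.nu:
        raise ValueError(
            f"fit has {nu} residual entries but the leverage spec expects {spec.nu}"
        )
    scale = leverage_scale(spec.h, leverage_mode)
    if replace:
        eperm = e[rng.integers(0, nu, size=(n_perm, nu))]
    else:
        eperm = rng.permuted(np.broadcast_to(e, (n_perm, nu)), axis=1, out=None)
    yprime = fit.yhat + scale * eperm
    coeffs = fitter.fit_dw(yprime)
    sig = pooled_sigmas(coeffs, fitter.scheme.k, fitter.lmax)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else -1
    return NullSamples(
        sigmas=sig, seed=int(seed_repr), leverage_mode=leverage_mode, replace=replace
    )


def p_values(data_sigmas: np.ndarray, null: NullSamples) -> np.ndarray:
    """One-sided bootstrap p-values P_i = 1 - (N_i+ + 1)/(N + 1) per component.

    N_i+ counts instances where the measured sigma_i strictly exceeds the
    bootstrap sigma'_i; ties count as not exceeded.  Returns an array
    aligned with ``data_sigmas`` (entry 0, the leading component, is not a
    meaningful test and is returned for index alignment only).
    """
    data_sigmas = np.asarray(data_sigmas, dtype=float)
    n = null.n
    n_plus = np.sum(data_sigmas[None, :] > null.sigmas, axis=0)
    return 1.0 - (n_plus + 1.0) / (n + 1.0)


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over a flat array of p-values.

    Returns the boolean discovery mask at FDR level q.  An empty input
    yields an empty mask.
    """
    pvals = np.asarray(pvals, dtype=float).ravel()
    if pvals.size == 0:
        import warnings

        warnings.warn("empty p-value set: no voxels to correct", stacklevel=2)
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject
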