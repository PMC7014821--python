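"""Model/Results interface for the voxel-wise rank-1 convolution test.

``ShardModel`` wraps one or many voxel signals measured under a
multi-shell gradient scheme.  ``fit()`` performs the per-shell spherical
harmonic fit, assembles the per-order matrices, computes their SVDs and
the rank-1 reconstruction, and returns a ``ShardResults`` carrying the
pooled effect sizes, the explained-power ratio R, residual diagnostics,
and a ``rank_test`` method running the residual-permutation significance
test with Benjamini-Hochberg FDR correction across voxels.

Example
-------
>>> from shardtest import simulate, ShardModel
>>> scheme = simulate.make_scheme()
>>> y = simulate.simulate_voxels(100, simulate.crossing_config("f", 0.4),
...                              scheme, simulate.NoiseSpec("gaussian", 80),
...                              seed=1)
>>> res = ShardModel(y, scheme, lmax=8).fit()
>>> test = res.rank_test(n_perm=999, seed=2)
>>> print(res.summary())          # doctest: +SKIP
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import __about__
from .decomposition import Rank1Fit, build_matrices, decompose, rank1_reconstruct
from .permtest import (
    LeverageSpec,
    fdr_correct,
    leverage_factor,
    p_values,
    sample_null,
)
from .scheme import GradientScheme
from .sh import SHFitter

__all__ = ["ShardModel", "ShardResults", "RankTestResult", "voxel_seed_sequence"]


def voxel_seed_sequence(seed, voxel_index: int) -> np.random.SeedSequence:
    """Seed stream for one voxel, independent of traversal order.

    Mixes the voxel index into the spawn key so whole-image runs are
    reproducible and parallelizable.
    """
    if isinstance(seed, np.random.SeedSequence):
        entropy = seed.entropy
    else:
        entropy = seed
    return np.random.SeedSequence(entropy=entropy, spawn_key=(int(voxel_index),))


class ShardModel:
    """Voxel-wise rank-1 spherical-convolution model.

    Parameters
    ----------
    endog : array, shape (n_measurements,) or (n_voxels, n_measurements)
        Measured signals ordered as the scheme.
    scheme : GradientScheme
    lmax : even int, default 8
        Order of the spherical harmonic fit.
    normalize_b0 : bool, default False
        Divide each voxel by its mean b=0 signal before fitting (only
        available when the scheme contains b=0 measurements).
    """

    def __init__(
        self,
        endog,
        scheme: GradientScheme,
        lmax: int = 8,
        normalize_b0: bool = False,
    ):
        endog = np.asarray(endog, dtype=float)
        self._single = endog.ndim == 1
        endog = np.atleast_2d(endog)
        if endog.shape[1] != scheme.n_measurements:
            raise ValueError(
                f"endog has {endog.shape[1]} measurements per voxel; the scheme "
                f"defines {scheme.n_measurements}"
            )
        if normalize_b0:
            if len(scheme.b0_indices) == 0:
                raise ValueError("normalize_b0 requires b=0 measurements in the scheme")
            b0 = endog[:, scheme.b0_indices].mean(axis=1, keepdims=True)
            if np.any(b0 <= 0):
                raise ValueError("cannot normalize: non-positive mean b=0 signal")
            endog = endog / b0
        self.endog = endog
        self.scheme = scheme
        self.lmax = lmax
        self.normalize_b0 = normalize_b0
        self.fitter = SHFitter(scheme, lmax)
        sizes = {len(s) for s in scheme.shells}
        # kappa depends only on k and lmax; nu is the actual DW count
        self.leverage = LeverageSpec(
            kappa=leverage_factor(scheme.k, lmax, max(sizes)).kappa,
            nu=scheme.n_dw,
        )

    @classmethod
    def from_dataframe(cls, df, scheme: GradientScheme, **kwargs) -> "ShardModel":
        """Build from a DataFrame with one measurement per column, one
        voxel per row (column order must match the scheme)."""
        return cls(np.asarray(df, dtype=float), scheme, **kwargs)

    @property
    def n_voxels(self) -> int:
        return self.endog.shape[0]

    def fit(self, progress: bool = False) -> "ShardResults":
        """Decompose every voxel; returns a :class:`ShardResults`."""
        it = range(self.n_voxels)
        if progress:
            from tqdm import tqdm

            it = tqdm(it, desc="decompose")
        decs, fits = [], []
        for v in it:
            coeffs = self.fitter.fit(self.endog[v])
            dec = decompose(build_matrices(coeffs, self.lmax))
            decs.append(dec)
            fits.append(rank1_reconstruct(dec, self.fitter, self.endog[v]))
        return ShardResults(self, decs, fits)


@dataclass(frozen=True)
class RankTestResult:
    """Permutation-test output over voxels.

    Attributes
    ----------
    components : tuple of tested component indices (1-based; >= 2).
    pvals : (n_voxels, n_components_total) array
        P_i per voxel; column i-1 is component i.  Columns of untested
        components hold NaN.
    fdr_masks : dict {component: boolean (n_voxels,) discovery mask}.
    alpha, fdr_q : significance and FDR levels used.
    n_perm, seed, leverage_mode : test configuration.
    """

    components: tuple
    pvals: np.ndarray
    fdr_masks: dict
    alpha: float
    fdr_q: float
    n_perm: int
    seed: int
    leverage_mode: str

    def significant(self, component: int = 2) -> np.ndarray:
        return self.fdr_masks[component]


class ShardResults:
    """Fitted voxel-wise decompositions and derived statistics."""

    def __init__(self, model: ShardModel, decompositions, rank1_fits):
        self.model = model
        self.decompositions = list(decompositions)
        self.rank1_fits: list[Rank1Fit] = list(rank1_fits)
        self.sigmas = np.stack([d.sigmas for d in self.decompositions])
        self.R = np.array([d.R for d in self.decompositions])
        self.degenerate = np.array([d.degenerate for d in self.decompositions])

    @property
    def n_voxels(self) -> int:
        return len(self.decompositions)

    @property
    def leverage(self) -> LeverageSpec:
        return self.model.leverage

    @property
    def sigma1(self) -> np.ndarray:
        """RMS signal power of the leading component per voxel."""
        return self.sigmas[:, 0]

    @property
    def rms_beyond_leading(self) -> np.ndarray:
        """sqrt(sum_{i>1} sigma_i^2) per voxel."""
        return np.sqrt(np.sum(self.sigmas[:, 1:] ** 2, axis=1))

    @property
    def residuals(self) -> np.ndarray:
        return np.stack([f.residuals for f in self.rank1_fits])

    def rank_test(
        self,
        n_perm: int = 10_000,
        seed=0,
        components=(2,),
        alpha: float = 0.05,
        fdr_q: float = 0.05,
        leverage_mode: str = "sqrt",
        replace: bool = False,
        progress: bool = False,
    ) -> RankTestResult:
        """Residual-permutation test of components beyond the first.

        Per voxel, samples `n_perm` bootstrap instances of the rank-1
        null and converts exceedance counts to p-values; then applies
        Benjamini-Hochberg FDR at level `fdr_q` across voxels, per
        component.
        """
        if n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {n_perm}")
        if n_perm < 99:
            import warnings

            warnings.warn(
                f"n_perm={n_perm} gives a minimum attainable p-value of "
                f"{n_perm / (n_perm + 1):.3f} resolution; consider >= 99",
                stacklevel=2,
            )
        components = tuple(int(c) for c in components)
        n_comp_total = self.sigmas.shape[1]
        if any(c < 2 or c > n_comp_total for c in components):
            raise ValueError(
                f"testable components are 2..{n_comp_total}, got {components}"
            )
        pvals = np.full((self.n_voxels, n_comp_total), np.nan)
        it = range(self.n_voxels)
        if progress:
            from tqdm import tqdm

            it = tqdm(it, desc="permutation test")
        for v in it:
            null = sample_null(
                self.rank1_fits[v],
                self.model.fitter,
                self.leverage,
                n_perm,
                voxel_seed_sequence(seed, v),
                leverage_mode=leverage_mode,
                replace=replace,
            )
            p = p_values(self.sigmas[v], null)
            for c in components:
                pvals[v, c - 1] = p[c - 1]
        masks = {c: fdr_correct(pvals[:, c - 1], q=fdr_q) for c in components}
        seed_repr = seed if isinstance(seed, (int, np.integer)) else -1
        return RankTestResult(
            components=components,
            pvals=pvals,
            fdr_masks=masks,
            alpha=alpha,
            fdr_q=fdr_q,
            n_perm=n_perm,
            seed=int(seed_repr),
            leverage_mode=leverage_mode,
        )

    def summary(self, test: RankTestResult | None = None) -> str:
        """Plain-text summary of the fit (and optionally of a rank test)."""
        m = self.model
        lines = [
            "Voxel-wise SHARD rank-1 decomposition",
            "=" * 54,
            f"voxels:            {self.n_voxels}",
            f"shells (k):        {m.scheme.k}  "
            f"(b = {', '.join(f'{b:.0f}' for b in m.scheme.shell_bvals)} s/mm^2)",
            f"lmax:              {m.lmax}",
            f"leverage:          kappa={self.leverage.kappa}, nu={self.leverage.nu}, "
            f"h={self.leverage.h:.4f}",
            "-" * 54,
            f"sigma_1 (RMS):     median {np.median(self.sigma1):.4g}",
            f"sigma_{{i>1}} (RMS): median {np.median(self.rms_beyond_leading):.4g}",
            f"R (% explained):   median {np.median(self.R):.3f}, "
            f"min {self.R.min():.3f}, max {self.R.max():.3f}",
        ]
        if test is not None:
            lines.append("-" * 54)
            lines.append(
                f"permutation test:  n_perm={test.n_perm}, "
                f"leverage_mode={test.leverage_mode}, alpha={test.alpha}, "
                f"FDR q={test.fdr_q}"
            )
            for c in test.components:
                p = test.pvals[:, c - 1]
                frac = float(np.mean(p < test.alpha))
                ndisc = int(test.fdr_masks[c].sum())
                lines.append(
                    f"component {c}:       median P={np.median(p):.3f}, "
                    f"P<alpha in {frac * 100:.1f}% of voxels, "
                    f"{ndisc} FDR discoveries"
                )
        lines.append("=" * 54)
        lines.append(f"shardtest {__about__.__version__}")
        return "\n".join(lines)
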