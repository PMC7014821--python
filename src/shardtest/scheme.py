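"""Gradient scheme container and shell grouping.

A multi-shell diffusion MRI acquisition is described by one b-value
(s/mm^2) and one unit gradient direction per measurement.  Measurements
sharing a b-value (within a grouping tolerance) form a *shell*; b-values
below ``b0_threshold`` are treated as non-diffusion-weighted (b=0).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientScheme", "group_shells"]

DEFAULT_SHELL_TOLERANCE = 50.0  # s/mm^2
DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2


@dataclass(frozen=True)
class GradientScheme:
    """Sampling scheme of a multi-shell acquisition.

    Parameters
    ----------
    bvals : (n,) array
        b-value of every measurement, in s/mm^2.
    bvecs : (n, 3) array
        Unit direction of every measurement.  Directions of b=0
        measurements are arbitrary.
    shell_bvals : (k,) array
        Representative (mean) b-value of each diffusion-weighted shell,
        in ascending order.
    shells : tuple of (m_i,) index arrays
        Measurement indices belonging to each shell, same order as
        ``shell_bvals``.
    b0_indices : (n0,) index array
        Measurement indices with b below the b=0 threshold.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_bvals: np.ndarray
    shells: tuple
    b0_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) "
                "describe different numbers of measurements"
            )
        sb = np.asarray(self.shell_bvals, dtype=float)
        if sb.size and (np.any(sb <= 0) or np.any(np.diff(sb) <= 0)):
            raise ValueError("shell b-values must be positive, distinct and ascending")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_bvals", sb)
        object.__setattr__(self, "shells", tuple(np.asarray(s, dtype=int) for s in self.shells))
        object.__setattr__(self, "b0_indices", np.asarray(self.b0_indices, dtype=int))

    @property
    def n_measurements(self) -> int:
        return self.bvals.shape[0]

    @property
    def k(self) -> int:
        """Number of diffusion-weighted shells."""
        return len(self.shells)

    @property
    def n_dw(self) -> int:
        """Number of diffusion-weighted measurements (nu in the rank test)."""
        return int(sum(len(s) for s in self.shells))

    @property
    def dw_indices(self) -> np.ndarray:
        """All diffusion-weighted indices, shell by shell."""
        if not self.shells:
            return np.empty(0, dtype=int)
        return np.concatenate(self.shells)

    def shell_directions(self, i: int) -> np.ndarray:
        return self.bvecs[self.shells[i]]

    def min_angle_deg(self, i: int) -> float:
        """Minimum pairwise angular separation (antipodally symmetric) in shell i."""
        d = self.shell_directions(i)
        c = np.abs(d @ d.T)
        np.fill_diagonal(c, 0.0)
        return float(np.degrees(np.arccos(np.clip(c.max(initial=0.0), 0, 1))))

    def __repr__(self) -> str:
        sizes = ", ".join(
            f"b={b:.0f}({len(s)})" for b, s in zip(self.shell_bvals, self.shells)
        )
        return (
            f"GradientScheme({self.n_measurements} measurements: {sizes}, "
            f"{len(self.b0_indices)} b=0)"
        )


def group_shells(
    bvals: np.ndarray,
    bvecs: np.ndarray,
    tol: float = DEFAULT_SHELL_TOLERANCE,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> GradientScheme:
    """Group measurements into shells by single-linkage clustering of b-values.

    b-values whose gaps are within `tol` are merged into one shell whose
    representative b-value is the member mean.  Directions at b > b0_threshold
    are normalized to unit length; a zero vector there is an error.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.array(bvecs, dtype=float)
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
    if bvals.size != bvecs.shape[0]:
        raise ValueError(
            f"bvals has {bvals.size} entries but bvecs has {bvecs.shape[0]} rows"
        )

    b0_mask = bvals <= b0_threshold
    dw = np.flatnonzero(~b0_mask)
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms == 0):
        bad = dw[norms == 0][0]
        raise ValueError(
            f"measurement {bad} has b={bvals[bad]:.0f} s/mm^2 but a zero "
            "direction vector; cannot normalize"
        )
    bvecs[dw] /= norms[:, None]

    shells: list[np.ndarray] = []
    shell_b: list[float] = []
    if dw.size:
        order = dw[np.argsort(bvals[dw], kind="stable")]
        sorted_b = bvals[order]
        breaks = np.flatnonzero(np.diff(sorted_b) > tol) + 1
        for grp in np.split(order, breaks):
            shells.append(np.sort(grp))
            shell_b.append(float(bvals[grp].mean()))

    return GradientScheme(
        bvals=bvals,
        bvecs=bvecs,
        shell_bvals=np.asarray(shell_b),
        shells=tuple(shells),
        b0_indices=np.flatnonzero(b0_mask),
    )
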