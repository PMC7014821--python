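"""Gradient table file I/O: FSL bvals/bvecs pairs and 4-column tables."""
from __future__ import annotations

import numpy as np

from .scheme import (
    DEFAULT_B0_THRESHOLD,
    DEFAULT_SHELL_TOLERANCE,
    GradientScheme,
    group_shells,
)

__all__ = ["read_gradients", "write_gradients"]


def _load_bvecs(path) -> np.ndarray:
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[0] == 3 and arr.shape[1] != 3:
        arr = arr.T  # FSL convention: 3 rows x N columns
    elif arr.shape[1] != 3:
        if arr.shape[0] == 3:  # 3x3: FSL row layout assumed
            arr = arr.T
        else:
            raise ValueError(
                f"bvecs file {path} has shape {arr.shape}; expected 3xN or Nx3"
            )
    return arr


def read_gradients(
    bvals_path,
    bvecs_path=None,
    tol: float = DEFAULT_SHELL_TOLERANCE,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> GradientScheme:
    """Read a gradient table and group it into shells.

    Either an FSL ``bvals``/``bvecs`` pair (bvecs as 3xN or Nx3, detected
    automatically) or, with ``bvecs_path=None``, a single whitespace- or
    comma-separated 4-column table with rows ``x y z b``.
    """
    if bvecs_path is None:
        try:
            table = np.loadtxt(bvals_path, ndmin=2)
        except ValueError:
            table = np.loadtxt(bvals_path, ndmin=2, delimiter=",")
        if table.shape[1] != 4:
            raise ValueError(
                f"gradient table {bvals_path} has {table.shape[1]} columns; "
                "expected 4 (x y z b)"
            )
        bvecs, bvals = table[:, :3], table[:, 3]
    else:
        bvals = np.loadtxt(bvals_path).ravel()
        bvecs = _load_bvecs(bvecs_path)
        if bvals.size != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.size} entries) and bvecs ({bvecs.shape[0]} "
                "directions) do not match"
            )
    return group_shells(bvals, bvecs, tol=tol, b0_threshold=b0_threshold)


def write_gradients(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    """Write a scheme as an FSL bvals/bvecs pair (bvecs as 3 rows)."""
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.10f")
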