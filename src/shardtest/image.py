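"""Whole-image orchestration: NIfTI input/output, voxel loops, map sets.

Runs the voxel-wise decomposition and permutation test over a masked 4-D
volume and writes float32 NIfTI maps (sigma_1, residual RMS, R, P_i,
FDR masks) plus a JSON provenance sidecar sufficient to re-run the
command.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .__about__ import __version__
from .model import ShardModel, voxel_seed_sequence
from .permtest import fdr_correct, sample_null, p_values
from .scheme import GradientScheme

__all__ = ["MapSet", "load_volume", "run_decompose", "run_test", "write_simulated_dataset"]


@dataclass
class MapSet:
    """3-D result maps sharing the input grid and affine.

    ``maps`` holds float arrays keyed by name (e.g. "sigma1", "rms_rest",
    "R", "P2", "fdr2"); ``params`` is the provenance dictionary written
    to the JSON sidecar.
    """

    maps: dict
    affine: np.ndarray
    params: dict = field(default_factory=dict)

    def save(self, outdir, prefix: str = "shard") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.maps.items():
            dtype = np.uint8 if arr.dtype == bool else np.float32
            img = nib.Nifti1Image(arr.astype(dtype), self.affine)
            img.header["descrip"] = f"shardtest {__version__} {name}".encode()[:80]
            nib.save(img, outdir / f"{prefix}_{name}.nii.gz")
        sidecar = dict(self.params)
        sidecar["software"] = {"name": "shardtest", "version": __version__}
        (outdir / f"{prefix}_params.json").write_text(json.dumps(sidecar, indent=2))


def load_volume(image_path, mask_path=None):
    """Load a 4-D NIfTI volume and an optional 3-D mask.

    Returns ``(data, affine, mask)`` with mask boolean over the grid
    (all-True when no mask is given).
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path} is {data.ndim}-D; expected a 4-D volume")
    if mask_path is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    else:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask grid {mask.shape} does not match image grid {data.shape[:3]}"
            )
    return data, img.affine, mask


def _check_scheme(data, scheme: GradientScheme) -> None:
    if data.shape[3] != scheme.n_measurements:
        raise ValueError(
            f"image has {data.shape[3]} volumes but the gradient scheme has "
            f"{scheme.n_measurements} entries"
        )


def run_decompose(
    data: np.ndarray,
    affine: np.ndarray,
    mask: np.ndarray,
    scheme: GradientScheme,
    lmax: int = 8,
    normalize_b0: bool = False,
    fill_value: float = 0.0,
    progress: bool = False,
) -> MapSet:
    """Voxel-wise decomposition maps: sigma_1, RMS beyond-leading power, R.

    Out-of-mask voxels are written as `fill_value` (0 or NaN).
    """
    _check_scheme(data, scheme)
    idx = np.flatnonzero(mask.ravel())
    signals = data.reshape(-1, data.shape[3])[idx]
    res = ShardModel(signals, scheme, lmax=lmax, normalize_b0=normalize_b0).fit(
        progress=progress
    )
    shape3 = data.shape[:3]

    def to_map(values):
        flat = np.full(np.prod(shape3), fill_value, dtype=float)
        flat[idx] = values
        return flat.reshape(shape3)

    params = {
        "operation": "decompose",
        "lmax": lmax,
        "normalize_b0": normalize_b0,
        "shell_bvals": scheme.shell_bvals.tolist(),
        "n_voxels": int(idx.size),
    }
    return MapSet(
        maps={
            "sigma1": to_map(res.sigma1),
            "rms_rest": to_map(res.rms_beyond_leading),
            "R": to_map(res.R),
        },
        affine=affine,
        params=params,
    ), res


def run_test(
    data: np.ndarray,
    affine: np.ndarray,
    mask: np.ndarray,
    scheme: GradientScheme,
    lmax: int = 8,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    components=(2,),
    leverage_mode: str = "sqrt",
    normalize_b0: bool = False,
    fill_value: float = 0.0,
    progress: bool = False,
) -> MapSet:
    """Per-voxel permutation test over a masked image, with BH FDR.

    Voxel seeds are derived from the voxel's position in the flattened
    grid, so results do not depend on traversal order and identical
    seeds give identical maps.
    """
    _check_scheme(data, scheme)
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if n_perm < 99:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} limits p-value resolution; consider >= 99",
            stacklevel=2,
        )
    idx = np.flatnonzero(mask.ravel())
    signals = data.reshape(-1, data.shape[3])[idx]
    model = ShardModel(signals, scheme, lmax=lmax, normalize_b0=normalize_b0)
    res = model.fit(progress=progress)
    components = tuple(int(c) for c in components)
    pvals = {c: np.empty(idx.size) for c in components}
    it = enumerate(idx)
    if progress:
        from tqdm import tqdm

        it = tqdm(list(it), desc="permutation test")
    for row, flat_index in it:
        null = sample_null(
            res.rank1_fits[row],
            model.fitter,
            model.leverage,
            n_perm,
            voxel_seed_sequence(seed, int(flat_index)),
            leverage_mode=leverage_mode,
        )
        p = p_values(res.sigmas[row], null)
        for c in components:
            pvals[c][row] = p[c - 1]
    shape3 = data.shape[:3]

    def to_map(values, fill):
        flat = np.full(np.prod(shape3), fill, dtype=float)
        flat[idx] = values
        return flat.reshape(shape3)

    maps = {}
    for c in components:
        maps[f"P{c}"] = to_map(pvals[c], fill_value if not np.isnan(fill_value) else np.nan)
        rej = fdr_correct(pvals[c], q=fdr_q)
        maps[f"fdr{c}"] = to_map(rej.astype(float), 0.0).astype(bool)
    params = {
        "operation": "test",
        "lmax": lmax,
        "n_perm": n_perm,
        "seed": int(seed),
        "alpha": alpha,
        "fdr_q": fdr_q,
        "components": list(components),
        "leverage_mode": leverage_mode,
        "normalize_b0": normalize_b0,
        "shell_bvals": scheme.shell_bvals.tolist(),
        "kappa": model.leverage.kappa,
        "nu": model.leverage.nu,
        "n_voxels": int(idx.size),
    }
    return MapSet(maps=maps, affine=affine, params=params), res


def write_simulated_dataset(
    signals: np.ndarray,
    scheme: GradientScheme,
    outdir,
    shape3=None,
    prefix: str = "sim",
    voxel_size: float = 2.5,
) -> dict:
    """Write simulated voxel signals as a 4-D NIfTI plus FSL bvals/bvecs
    and a brain mask, so the file-based pipeline can be exercised
    end-to-end.  Returns the paths written.
    """
    from .gradients import write_gradients

    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_vox = signals.shape[0]
    if shape3 is None:
        nx = int(np.ceil(np.cbrt(n_vox)))
        ny = int(np.ceil(np.sqrt(n_vox / nx)))
        nz = int(np.ceil(n_vox / (nx * ny)))
        shape3 = (nx, ny, nz)
    if np.prod(shape3) < n_vox:
        raise ValueError(f"grid {shape3} too small for {n_vox} voxels")
    vol = np.zeros((int(np.prod(shape3)), signals.shape[1]), dtype=np.float32)
    vol[:n_vox] = signals
    mask = np.zeros(int(np.prod(shape3)), dtype=np.uint8)
    mask[:n_vox] = 1
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{prefix}_dwi.nii.gz",
        "mask": outdir / f"{prefix}_mask.nii.gz",
        "bvals": outdir / f"{prefix}.bval",
        "bvecs": outdir / f"{prefix}.bvec",
    }
    nib.save(nib.Nifti1Image(vol.reshape(*shape3, -1), affine), paths["image"])
    nib.save(nib.Nifti1Image(mask.reshape(shape3), affine), paths["mask"])
    write_gradients(scheme, paths["bvals"], paths["bvecs"])
    return paths
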