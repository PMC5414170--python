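"""Reading and writing the standard on-disk formats.

Scalar fields (densities, running maxima) are 3-D NIfTI float32; masks are
3-D NIfTI uint8.  Tensor fields are 4-D NIfTI with six components per
voxel in FSL-style lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
Grid spacing is carried in the NIfTI header pixdims.  Radii series are CSV
with header ``time_days,r_t1_mm,r_t2_mm``; parameters and run provenance
are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fields import GrowthParams, SimulationState, TensorField, VoxelGrid
from .parameters import EstimatedParams, RadiiSeries

__all__ = [
    "save_scalar",
    "load_scalar",
    "save_mask",
    "load_grid",
    "save_tensor",
    "load_tensor",
    "save_radii_csv",
    "load_radii_csv",
    "save_params_json",
    "load_params_json",
    "save_snapshots",
]

#: lower-triangular component order of the 4th NIfTI axis for tensors
LOWER_TRI = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_scalar(path, values: np.ndarray, spacing) -> None:
    """Write a 3-D scalar field as float32 NIfTI."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def load_scalar(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D scalar NIfTI; returns (values, spacing from pixdims)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), spacing


def save_mask(path, mask: np.ndarray, spacing) -> None:
    """Write a boolean mask as uint8 NIfTI."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def load_grid(mask_path) -> VoxelGrid:
    """Build a VoxelGrid from a mask NIfTI (spacing from the header)."""
    values, spacing = load_scalar(mask_path)
    return VoxelGrid(shape=values.shape, spacing=spacing, mask=values > 0)


def save_tensor(path, field: TensorField) -> None:
    """Write a tensor field as 4-D NIfTI, lower-triangular component order.

    The 4th axis holds (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), the common
    FSL-style convention.
    """
    comps = np.stack(
        [field.tensors[..., i, j] for i, j in LOWER_TRI], axis=-1
    ).astype(np.float32)
    img = nib.Nifti1Image(comps, _affine(field.grid.spacing))
    img.header.set_zooms(tuple(field.grid.spacing) + (1.0,))
    nib.save(img, str(path))


def load_tensor(path, grid: VoxelGrid, kind: str = "cell") -> TensorField:
    """Read a 4-D tensor NIfTI in lower-triangular component order.

    Validates that the file carries exactly six components per voxel
    (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) on the supplied grid.
    """
    img = nib.load(str(path))
    data = np.asarray(np.asanyarray(img.dataobj), dtype=float)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(
            f"{path}: expected a 4-D volume with 6 tensor components "
            f"(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), got shape {data.shape}"
        )
    if data.shape[:3] != grid.shape:
        raise ValueError(
            f"{path}: tensor volume shape {data.shape[:3]} does not match "
            f"grid {grid.shape}"
        )
    tensors = np.zeros(grid.shape + (3, 3))
    for comp, (i, j) in enumerate(LOWER_TRI):
        tensors[..., i, j] = data[..., comp]
        tensors[..., j, i] = data[..., comp]
    return TensorField(grid=grid, tensors=tensors, kind=kind)


def save_radii_csv(path, radii: RadiiSeries) -> None:
    pd.DataFrame(
        {"time_days": radii.times, "r_t1_mm": radii.r_t1, "r_t2_mm": radii.r_t2}
    ).to_csv(path, index=False)


def load_radii_csv(path) -> RadiiSeries:
    df = pd.read_csv(path)
    required = {"time_days", "r_t1_mm", "r_t2_mm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: radii CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return RadiiSeries(
        times=tuple(df["time_days"]),
        r_t1=tuple(df["r_t1_mm"]),
        r_t2=tuple(df["r_t2_mm"]),
    )


def save_params_json(path, params: EstimatedParams) -> None:
    Path(path).write_text(json.dumps(asdict(params), indent=2) + "\n")


def load_params_json(path) -> EstimatedParams:
    return EstimatedParams(**json.loads(Path(path).read_text()))


def save_snapshots(
    out_dir,
    snapshots: list[SimulationState],
    params: GrowthParams,
    extra: dict | None = None,
) -> Path:
    """Write a snapshot series as NIfTI files plus a JSON provenance sidecar.

    Each snapshot produces ``density_t<...>.nii.gz``; the sidecar records
    the snapshot times, model parameters, and any extra run settings so the
    run can be re-executed bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = snapshots[0].grid.spacing
    files = []
    for snap in snapshots:
        name = f"density_t{snap.t:07.2f}.nii.gz"
        save_scalar(out / name, snap.c.values, spacing)
        files.append(name)
    final = snapshots[-1]
    save_mask(out / "necrotic_final.nii.gz", final.necrotic, spacing)
    save_scalar(out / "max_history_final.nii.gz", final.m, spacing)
    sidecar = {
        "times_days": [s.t for s in snapshots],
        "files": files,
        "params": asdict(params),
        **(extra or {}),
    }
    (out / "provenance.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return out
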