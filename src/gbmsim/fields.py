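"""Core geometric and field types shared across the simulator.

The spatial domain is a regular voxel grid with per-axis physical spacing
(mm) and a boolean brain mask.  Tumor cell density ``c(x, t)`` lives on this
grid in cells/mm^3, diffusion is governed by a per-voxel symmetric
positive-semidefinite 3x3 tensor field ``D(x)`` (mm^2/day for cell tensors),
and the simulation state additionally tracks the running historical maximum
``m(x) = max over elapsed time of c(x, .)`` which drives the irreversible
necrosis switch: a voxel is necrotic iff ``m >= tau * c_m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "VoxelGrid",
    "TensorField",
    "DensityField",
    "GrowthParams",
    "SimulationState",
    "make_state",
]

#: default tolerance for symmetry / positive-semidefiniteness checks
PSD_TOL = 1e-10

GrowthLaw = Literal["logistic", "exponential", "gompertz"]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel grid with physical spacing and a brain mask.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(nx, ny, nz)``.  A 2-D domain is a
        shape with one singleton axis.
    spacing
        Physical voxel size per axis in mm; all components must be > 0.
    mask
        Boolean inside-brain indicator of shape ``shape``; at least one
        voxel must be inside.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be three positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid shape {shape}"
            )
        if not mask.any():
            raise ValueError("mask is empty: at least one voxel must be inside")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "mask", mask)

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_inside(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    def contains_index(self, index) -> bool:
        """True if ``index`` is a valid in-grid, in-mask voxel index."""
        idx = tuple(int(i) for i in index)
        if len(idx) != 3:
            return False
        if any(i < 0 or i >= n for i, n in zip(idx, self.shape)):
            return False
        return bool(self.mask[idx])


@dataclass(frozen=True)
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensor field.

    ``kind`` distinguishes the water ("spin") diffusion tensor measured by
    DTI from the modeled tumor-cell diffusion tensor ("cell", mm^2/day)
    derived from it.  All in-mask tensors must be symmetric and positive
    semidefinite (smallest eigenvalue >= -tol).
    """

    grid: VoxelGrid
    tensors: np.ndarray = field(repr=False)  # (*grid.shape, 3, 3)
    kind: Literal["spin", "cell"] = "cell"

    def __post_init__(self):
        tensors = np.asarray(self.tensors, dtype=float)
        expected = self.grid.shape + (3, 3)
        if tensors.shape != expected:
            raise ValueError(
                f"tensor array shape {tensors.shape} does not match {expected}"
            )
        if self.kind not in ("spin", "cell"):
            raise ValueError(f"kind must be 'spin' or 'cell', got {self.kind!r}")
        object.__setattr__(self, "tensors", tensors)
        self.validate()

    def validate(self, tol: float = PSD_TOL) -> None:
        """Check symmetry and positive semidefiniteness inside the mask."""
        inside = self.tensors[self.grid.mask]
        asym = np.abs(inside - np.swapaxes(inside, -1, -2)).max(initial=0.0)
        scale = max(np.abs(inside).max(initial=0.0), 1.0)
        if asym > tol * scale:
            raise ValueError(f"tensor field is not symmetric (max asymmetry {asym:g})")
        if inside.size:
            eigmin = np.linalg.eigvalsh(inside)[..., 0].min()
            if eigmin < -tol * scale:
                bad = np.argwhere(self.grid.mask)[
                    int(np.argmin(np.linalg.eigvalsh(inside)[..., 0]))
                ]
                raise ValueError(
                    "tensor field is not positive semidefinite: smallest "
                    f"eigenvalue {eigmin:g} at voxel {tuple(bad)}"
                )

    @classmethod
    def isotropic(cls, grid: VoxelGrid, diffusivity: float,
                  kind: Literal["spin", "cell"] = "cell") -> "TensorField":
        """Uniform isotropic field ``diffusivity * I`` on in-mask voxels."""
        if diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        tensors = np.zeros(grid.shape + (3, 3))
        tensors[grid.mask] = diffusivity * np.eye(3)
        return cls(grid=grid, tensors=tensors, kind=kind)

    def mean_diffusivity(self) -> np.ndarray:
        """Per-voxel mean diffusivity trace(D)/3."""
        return np.trace(self.tensors, axis1=-2, axis2=-1) / 3.0

    def fractional_anisotropy(self) -> np.ndarray:
        """Per-voxel fractional anisotropy in [0, 1]; 0 where the tensor is 0."""
        w = np.linalg.eigvalsh(self.tensors)
        md = w.mean(axis=-1, keepdims=True)
        num = np.sqrt(((w - md) ** 2).sum(axis=-1))
        den = np.sqrt((w ** 2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return fa


@dataclass(frozen=True)
class DensityField:
    """Tumor cell density c(x) in cells/mm^3 on a voxel grid.

    Values are finite, lie in ``[0, c_m]`` (a clipping contract enforced by
    the solver after each step), and are zero outside the brain mask.
    """

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid {self.grid.shape}"
            )
        if not np.isfinite(values).all():
            raise ValueError("density values must be finite")
        if (values < 0).any():
            raise ValueError("density values must be >= 0")
        if values[~self.grid.mask].any():
            raise ValueError("density must be zero outside the mask")
        object.__setattr__(self, "values", values)

    def total_cells(self) -> float:
        """Total cell count: sum of c times voxel volume."""
        return float(self.values.sum() * self.grid.voxel_volume)


@dataclass(frozen=True)
class GrowthParams:
    """Scalar parameters of the proliferation-necrosis model.

    Attributes
    ----------
    rho
        Proliferation rate, /day.
    c_m
        Carrying capacity (maximum cell concentration), cells/mm^3.
    tau
        Necrosis threshold as a fraction of ``c_m`` in (0, 1]; a voxel
        whose historical maximum density reaches ``tau * c_m`` permanently
        switches to necrotic decay.
    eta
        Per-day survival fraction of necrotic tissue in (0, 1); over one
        day a necrotic voxel retains ``eta`` of its density (exponential
        decay; smaller eta means faster necrosis).
    dt
        Reporting time step, days.
    growth_law
        Proliferation law: logistic (default), exponential, or gompertz.
    """

    rho: float
    c_m: float = 1e5
    tau: float = 0.85
    eta: float = 0.9
    dt: float = 1.0
    growth_law: GrowthLaw = "logistic"

    def __post_init__(self):
        # rho = 0 (no proliferation) is allowed for pure-diffusion runs
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.c_m <= 0:
            raise ValueError(f"c_m must be > 0, got {self.c_m}")
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if not 0 < self.eta < 1:
            raise ValueError(f"eta must be in (0, 1), got {self.eta}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.growth_law not in ("logistic", "exponential", "gompertz"):
            raise ValueError(f"unknown growth law {self.growth_law!r}")

    @property
    def necrosis_threshold(self) -> float:
        """Absolute necrosis threshold tau * c_m, cells/mm^3."""
        return self.tau * self.c_m


@dataclass(frozen=True)
class SimulationState:
    """Snapshot of the simulation at time ``t`` (days).

    Invariants: ``m >= c`` pointwise, ``m`` is non-decreasing in time, and
    the necrotic set ``{x : m(x) >= tau * c_m}`` never shrinks.
    """

    t: float
    c: DensityField
    m: np.ndarray = field(repr=False)
    necrotic: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        necrotic = np.asarray(self.necrotic, dtype=bool)
        if m.shape != self.c.grid.shape or necrotic.shape != self.c.grid.shape:
            raise ValueError("m and necrotic must have the grid shape")
        if (m < self.c.values - 1e-12 * max(m.max(initial=0.0), 1.0)).any():
            raise ValueError("running maximum m must dominate c pointwise")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "necrotic", necrotic)

    @property
    def grid(self) -> VoxelGrid:
        return self.c.grid

    def replace(self, **kw) -> "SimulationState":
        return replace(self, **kw)


def make_state(
    grid: VoxelGrid,
    seed_index,
    c0: float,
    params: GrowthParams,
) -> SimulationState:
    """Seed tumor cells in a single voxel and build the initial state.

    Parameters
    ----------
    grid
        Spatial domain.
    seed_index
        Voxel index (i, j, k) of the initial tumor cell deposit; must lie
        inside the brain mask.
    c0
        Seeded cell density in (0, c_m], cells/mm^3.
    params
        Model parameters (used for the tau * c_m necrosis rule).
    """
    idx = tuple(int(i) for i in seed_index)
    if len(idx) != 3:
        raise ValueError(f"seed_index must have three components, got {seed_index}")
    if any(i < 0 or i >= n for i, n in zip(idx, grid.shape)):
        raise ValueError(f"seed voxel {idx} lies outside the grid {grid.shape}")
    if not grid.mask[idx]:
        raise ValueError(f"seed voxel {idx} lies outside the brain mask")
    if not 0 < c0 <= params.c_m:
        raise ValueError(f"c0 must be in (0, c_m], got {c0}")
    values = np.zeros(grid.shape)
    values[idx] = c0
    c = DensityField(grid=grid, values=values)
    m = values.copy()
    necrotic = m >= params.necrosis_threshold
    return SimulationState(t=0.0, c=c, m=m, necrotic=necrotic)
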