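"""Synthetic tensor fields, brain masks, and pseudo-images.

Real diffusion-tensor acquisitions are not required anywhere in the
package: these phantoms emulate the two media that matter for glioma
migration modeling — isotropic tissue and a coherent white-matter fiber
bundle with controllable fractional anisotropy — plus a cartoon
post-contrast T1 renderer sufficient for mutual-information experiments.

Axially symmetric fiber tensors are parameterized exactly by mean
diffusivity MD and fractional anisotropy FA:

    lambda_perp = MD * (1 - a),   lambda_par = MD * (1 + 2a),
    a = FA / sqrt(3 - 2 FA^2),

which inverts the FA definition for an axially symmetric tensor and keeps
lambda_perp >= 0 for any FA in [0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .fields import SimulationState, TensorField, VoxelGrid
from .metrics import T1_FRACTION

__all__ = [
    "PhantomSpec",
    "make_isotropic_phantom",
    "make_fiber_phantom",
    "axially_symmetric_eigenvalues",
    "pseudo_t1",
    "anatomy_texture",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Description of a synthetic medium.

    ``mean_diffusivity`` is in mm^2/day when the phantom stands in for the
    cell tensor directly (``kind="cell"``).  ``fa_target`` and
    ``fiber_axis`` only apply to the fiber-bundle medium; the bundle is a
    straight cylinder of radius ``fiber_radius_mm`` through the grid
    center.  ``seed`` controls any randomized texture.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    medium: str = "isotropic"
    mean_diffusivity: float = 0.0825
    fa_target: float = 0.0
    fiber_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    fiber_radius_mm: float = 8.0
    kind: str = "cell"
    seed: int = 0

    def __post_init__(self):
        if self.medium not in ("isotropic", "fiber_bundle"):
            raise ValueError(f"unknown medium {self.medium!r}")
        if self.mean_diffusivity <= 0:
            raise ValueError("mean_diffusivity must be > 0")
        if not 0 <= self.fa_target < 1:
            raise ValueError(f"fa_target must be in [0, 1), got {self.fa_target}")


def _ellipsoid_mask(shape, spacing) -> np.ndarray:
    """Ellipsoidal brain mask inscribed in the grid with a 1-voxel margin."""
    axes = [np.arange(n) * h for n, h in zip(shape, spacing)]
    center = [(n - 1) * h / 2.0 for n, h in zip(shape, spacing)]
    semi = [max(n * h / 2.0 - h, h / 2.0) for n, h in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip((xx, yy, zz), center, semi))
    return r2 <= 1.0


def make_isotropic_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, TensorField]:
    """Ellipsoidal brain mask filled with ``mean_diffusivity * I`` tensors."""
    if spec.medium != "isotropic":
        raise ValueError("spec.medium must be 'isotropic'")
    mask = _ellipsoid_mask(spec.shape, spec.spacing)
    grid = VoxelGrid(shape=spec.shape, spacing=spec.spacing, mask=mask)
    tensor = TensorField.isotropic(grid, spec.mean_diffusivity, kind=spec.kind)
    return grid, tensor


def axially_symmetric_eigenvalues(md: float, fa: float) -> tuple[float, float]:
    """(lambda_par, lambda_perp) of an axially symmetric tensor from (MD, FA)."""
    if not 0 <= fa < 1:
        raise ValueError(f"FA must be in [0, 1), got {fa}")
    a = fa / math.sqrt(3.0 - 2.0 * fa * fa)
    return md * (1.0 + 2.0 * a), md * (1.0 - a)


def make_fiber_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, TensorField]:
    """Cylindrical coherent fiber bundle in an otherwise isotropic brain.

    Inside the bundle the tensors are axially symmetric with principal
    eigenvector along ``fiber_axis`` and FA equal to ``fa_target``;
    elsewhere they are isotropic.  Mean diffusivity equals
    ``mean_diffusivity`` everywhere in the mask.
    """
    if spec.medium != "fiber_bundle":
        raise ValueError("spec.medium must be 'fiber_bundle'")
    mask = _ellipsoid_mask(spec.shape, spec.spacing)
    grid = VoxelGrid(shape=spec.shape, spacing=spec.spacing, mask=mask)

    n = np.asarray(spec.fiber_axis, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("fiber_axis must be a nonzero vector")
    n = n / norm

    axes = [np.arange(m) * h for m, h in zip(spec.shape, spec.spacing)]
    center = np.array([(m - 1) * h / 2.0 for m, h in zip(spec.shape, spec.spacing)])
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    rel = np.stack([xx - center[0], yy - center[1], zz - center[2]], axis=-1)
    along = rel @ n
    perp2 = (rel ** 2).sum(axis=-1) - along ** 2
    in_bundle = (perp2 <= spec.fiber_radius_mm ** 2) & mask

    lam_par, lam_perp = axially_symmetric_eigenvalues(
        spec.mean_diffusivity, spec.fa_target
    )
    fiber_tensor = lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(n, n)

    tensors = np.zeros(spec.shape + (3, 3))
    tensors[mask] = spec.mean_diffusivity * np.eye(3)
    tensors[in_bundle] = fiber_tensor
    return grid, TensorField(grid=grid, tensors=tensors, kind=spec.kind)


def anatomy_texture(
    grid: VoxelGrid,
    seed: int = 0,
    smoothness_mm: float = 2.0,
    low: float = 0.1,
    high: float = 1.1,
) -> np.ndarray:
    """Deterministic smooth random field emulating anatomical T1 contrast.

    Gaussian-filtered white noise, histogram-equalized to a uniform
    intensity distribution over ``[low, high]`` inside the mask (real
    brain images have broad intensity histograms; equalization keeps any
    particular intensity from being an artificially rare event in
    histogram-based comparisons), zero outside.  Used as the shared
    background when rendering pseudo-images of two tumor fields that live
    in "the same brain".
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    sigma = [smoothness_mm / h for h in grid.spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma)
    inside = smooth[grid.mask]
    tex = np.zeros(grid.shape)
    if inside.size > 1 and inside.max() > inside.min():
        ranks = stats.rankdata(inside, method="average")
        tex[grid.mask] = low + (high - low) * (ranks - 0.5) / inside.size
    else:
        tex[grid.mask] = 0.5 * (low + high)
    return tex


def pseudo_t1(
    state: SimulationState,
    c_m: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    detection_fraction: float = T1_FRACTION,
    background: np.ndarray | float = 0.5,
    rim_level: float = 1.0,
    core_level: float = 0.05,
) -> np.ndarray:
    """Cartoon post-contrast T1 rendering of a simulation state.

    The enhancing rim (density >= ``detection_fraction * c_m`` and not
    necrotic) is painted bright, the necrotic core dark, and everything
    else keeps the background intensity — either a constant or a supplied
    per-voxel texture (e.g. :func:`anatomy_texture`).  Additive Gaussian
    noise with standard deviation ``noise_sd`` is applied inside the mask;
    the result is deterministic given ``seed``.  No MR physics is
    simulated: this is an intensity cartoon sufficient for
    mutual-information experiments.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = state.grid
    if np.isscalar(background):
        img = np.where(grid.mask, float(background), 0.0)
    else:
        img = np.asarray(background, dtype=float).copy()
        if img.shape != grid.shape:
            raise ValueError("background texture shape does not match the grid")
    enhancing = (state.c.values >= detection_fraction * c_m) & grid.mask \
        & ~state.necrotic
    necrotic = state.necrotic & grid.mask
    img[enhancing] = rim_level
    img[necrotic] = core_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + np.where(grid.mask, rng.normal(0.0, noise_sd, grid.shape), 0.0)
    return img
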