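"""Quantitative comparison and morphometry of simulated tumor fields.

Mutual information (in bits, from a joint histogram with equal-width
bins), imaging-threshold detection masks (the T2 margin at 0.16*c_m and
the contrast-enhancing T1 margin at 0.80*c_m), volume-equivalent radii,
enhancing-rim width, and traveling-front speed estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import SimulationState

__all__ = [
    "JointHistogram",
    "joint_histogram",
    "mutual_information",
    "detection_mask",
    "equivalent_radius",
    "rim_width",
    "rim_width_ray",
    "front_speed",
]

T2_FRACTION = 0.16  #: cell-density fraction imaged as the T2 margin
T1_FRACTION = 0.80  #: cell-density fraction imaged as enhancement on T1


@dataclass(frozen=True)
class JointHistogram:
    """Joint histogram of two fields over a common support."""

    counts: np.ndarray = field(repr=False)  # (bins_c, bins_s) non-negative ints
    edges_c: np.ndarray = field(repr=False)
    edges_s: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        """Number of voxels compared."""
        return int(self.counts.sum())

    def marginal_c(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def marginal_s(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def mutual_information(self) -> float:
        """MI in bits; zero-count joint bins contribute 0 (x log x -> 0)."""
        n = self.n
        if n == 0:
            return 0.0
        p = self.counts / n
        pc = p.sum(axis=1, keepdims=True)
        ps = p.sum(axis=0, keepdims=True)
        nz = p > 0
        ratio = p[nz] / (pc @ ps)[nz]
        return float(np.sum(p[nz] * np.log2(ratio)))


def joint_histogram(
    c: np.ndarray,
    s: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 64,
    ranges=None,
) -> JointHistogram:
    """Equal-width joint histogram of two fields over the mask support.

    By default each axis spans its field's own in-mask range; ``ranges``
    (as in :func:`numpy.histogram2d`) pins both axes to fixed intervals,
    which keeps bin widths comparable when several fields are scored
    against a common reference.
    """
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    if c.shape != s.shape:
        raise ValueError(f"field shapes differ: {c.shape} vs {s.shape}")
    if mask is None:
        cv, sv = c.ravel(), s.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != c.shape:
            raise ValueError(f"mask shape {mask.shape} does not match {c.shape}")
        cv, sv = c[mask], s[mask]
    counts, ec, es = np.histogram2d(cv, sv, bins=bins, range=ranges)
    return JointHistogram(counts=counts.astype(np.int64), edges_c=ec, edges_s=es)


def mutual_information(
    c: np.ndarray,
    s: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 64,
    ranges=None,
) -> float:
    """Mutual information between two fields in bits.

    MI = sum_{C,S} p(C,S) log2[p(C,S) / (p(C) p(S))] over the occupied
    bins of an equal-width joint histogram spanning each field's in-mask
    range (or fixed ``ranges``).  By convention MI = 0 when either field
    takes fewer than two distinct values within the mask.
    """
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    if c.shape != s.shape:
        raise ValueError(f"field shapes differ: {c.shape} vs {s.shape}")
    if mask is not None:
        cv, sv = c[np.asarray(mask, bool)], s[np.asarray(mask, bool)]
    else:
        cv, sv = c.ravel(), s.ravel()
    if cv.size == 0 or cv.min() == cv.max() or sv.min() == sv.max():
        return 0.0
    return joint_histogram(c, s, mask, bins, ranges).mutual_information()


def detection_mask(
    state: SimulationState,
    fraction: float,
    c_m: float,
    variant: str = "total",
) -> np.ndarray:
    """Imaging-threshold mask: voxels with density >= fraction * c_m.

    ``variant`` selects what a given MR channel shows:

    - "total": every voxel at or above the threshold (the T2-style margin
      when fraction = 0.16);
    - "enhancing": above threshold and not necrotic (the viable rim that
      enhances on post-contrast T1);
    - "necrotic": the necrotic set itself, regardless of current density.
    """
    if variant == "necrotic":
        return state.necrotic & state.grid.mask
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    above = (state.c.values >= fraction * c_m) & state.grid.mask
    if variant == "total":
        return above
    if variant == "enhancing":
        return above & ~state.necrotic
    raise ValueError(f"unknown detection variant {variant!r}")


def equivalent_radius(mask: np.ndarray, spacing) -> float:
    """Radius (mm) of the sphere with the mask's volume.

    ``(3V / 4 pi)^(1/3)`` with V = voxel count * voxel volume.  For grids
    with a singleton axis the disc-equivalent radius ``sqrt(A / pi)`` is
    used instead, with A the in-plane area.  Empty mask -> 0.
    """
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count == 0:
        return 0.0
    spacing = tuple(float(s) for s in spacing)
    planar = [n == 1 for n in mask.shape]
    if any(planar):
        area = count * float(np.prod([s for s, p in zip(spacing, planar) if not p]))
        return float(np.sqrt(area / np.pi))
    volume = count * float(np.prod(spacing))
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def rim_width(
    state: SimulationState,
    c_m: float,
    detection_fraction: float = T1_FRACTION,
) -> float:
    """Width (mm) of the enhancing rim around the hypointense necrotic core.

    Computed as the difference of volume-equivalent radii,
    ``r(enhancing U core) - r(core)``.  Enhancement is a density property
    of the tissue: every voxel at or above ``detection_fraction * c_m``
    enhances, including voxels already flagged necrotic whose density has
    not yet decayed below the detection level.  The visible core is the
    necrotic tissue that *has* decayed below detection.  With no core this
    reduces to the outer enhancing radius.
    """
    above = detection_mask(state, detection_fraction, c_m, "total")
    core = state.necrotic & state.grid.mask & ~above
    spacing = state.grid.spacing
    outer = equivalent_radius(above | core, spacing)
    inner = equivalent_radius(core, spacing)
    return outer - inner


def _ray_band_width(profile: np.ndarray, h: float, threshold: float) -> float | None:
    """Width of the outermost contiguous above-threshold band on a ray.

    Band edges are located by linear interpolation of the profile through
    the threshold, resolving sub-voxel widths.  Returns None when the ray
    never reaches the threshold.
    """
    above = profile >= threshold
    if not above.any():
        return None
    o = int(np.max(np.nonzero(above)))
    if o + 1 < len(profile) and profile[o] > profile[o + 1]:
        r_out = (o + (profile[o] - threshold) / (profile[o] - profile[o + 1])) * h
    else:
        r_out = o * h
    j = o
    while j > 0 and above[j - 1]:
        j -= 1
    if j == 0:
        r_in = 0.0
    elif profile[j] > profile[j - 1]:
        r_in = (j - 1 + (threshold - profile[j - 1])
                / (profile[j] - profile[j - 1])) * h
    else:
        r_in = j * h
    return r_out - r_in


def rim_width_ray(
    state: SimulationState,
    c_m: float,
    axis: int | None = None,
    center=None,
    detection_fraction: float = T1_FRACTION,
) -> float:
    """Enhancing-band width (mm) read along rays through the tumor center.

    Mimics a caliper measurement on the image: along each cardinal ray
    from ``center`` (default: the voxel of peak historical density, i.e.
    the tumor origin), the width of the outermost contiguous band with
    density >= ``detection_fraction * c_m`` is measured with sub-voxel
    interpolation, and the ray widths are averaged.  Restricting to a single
    ``axis`` (e.g. the fiber axis) measures the rim in that direction.
    Unlike :func:`rim_width` this resolves rims thinner than one voxel and
    is monotone in the necrotic survival fraction eta.
    """
    grid = state.grid
    vals = state.c.values
    if center is None:
        center = np.unravel_index(int(np.argmax(state.m)), grid.shape)
    center = tuple(int(i) for i in center)
    axes = [axis] if axis is not None else [a for a in range(3) if grid.shape[a] > 1]
    threshold = detection_fraction * c_m
    widths = []
    for a in axes:
        for sign in (+1, -1):
            sl = [slice(c, c + 1) for c in center]
            sl[a] = slice(center[a], None) if sign > 0 else slice(center[a], None, -1)
            profile = vals[tuple(sl)].ravel()
            w = _ray_band_width(profile, grid.spacing[a], threshold)
            if w is not None:
                widths.append(w)
    return float(np.mean(widths)) if widths else 0.0


def front_speed(
    snapshots,
    fraction: float,
    c_m: float,
    spacing=None,
) -> float:
    """Asymptotic radial front speed (mm/day) from a snapshot sequence.

    Fits a least-squares line to the volume-equivalent radius of the
    detection mask versus time over the last half of the snapshots,
    discarding the pre-asymptotic transient.  For a Fisher-type traveling
    wave this converges to v = 2 sqrt(rho D) on sufficiently fine grids.
    """
    snapshots = list(snapshots)
    if len(snapshots) < 3:
        raise ValueError("front_speed requires at least 3 snapshots")
    if spacing is None:
        spacing = snapshots[0].grid.spacing
    times = np.array([s.t for s in snapshots])
    radii = np.array([
        equivalent_radius(detection_mask(s, fraction, c_m, "total"), spacing)
        for s in snapshots
    ])
    half = len(snapshots) // 2
    t, r = times[half:], radii[half:]
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("degenerate fit: need >= 2 distinct times in the last half")
    slope = np.polyfit(t, r, 1)[0]
    return float(slope)
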