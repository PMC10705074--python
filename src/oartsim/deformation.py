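"""Time-scaled surface-correspondence displacement fields.

The intrafraction motion model: a displacement vector field (DVF) is built
between the anatomy at the start of the adaptive session (t1 = 0 min) and at
the verification scan (t2 = adaptation time), and the *same* field, scaled by
a time-dependent factor K, yields the anatomy at any intermediate time t_i.

K follows from assuming the bladder volume grows linearly in time and the
wall moves radially with the cube root of volume:

    V(t_i) = V1 + (t_i - t1) * (V2 - V1) / (t2 - t1)
    K(t_i) = [ (V(t_i)/V1)^(1/3) - 1 ] / [ (V2/V1)^(1/3) - 1 ]

so K(t1) = 0, K(t2) = 1, and K is concave in t_i when the bladder fills
(cube-root growth front-loads the wall displacement).

The DVF itself replaces a commercial contour-steered deformable registration
with an analytic star-shaped ray correspondence: each surface point of the
reference structure is matched to the target surface along the ray from the
structure centroid, which is exact for the phantom's ellipsoidal anatomy and
oracle-checkable on digitized spheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import GridGeometry, StructureMask, expand, surface_voxels

__all__ = [
    "DisplacementField",
    "TimeScaling",
    "time_scale_factor",
    "SurfaceCorrespondence",
    "surface_dvf",
    "scale_field",
    "compose_fields",
    "propagate",
]

#: width (mm) of the band outside the steering structures over which the
#: field decays smoothly to zero
DECAY_BAND_MM = 10.0


@dataclass(frozen=True)
class TimeScaling:
    """Times (min) and bladder volumes (mL) anchoring the K factor."""

    t1: float
    t2: float
    V1: float
    V2: float

    def __post_init__(self):
        if not self.t2 > self.t1:
            raise ValueError(f"t2 must exceed t1 (got t1={self.t1}, t2={self.t2})")
        if self.V1 <= 0 or self.V2 <= 0:
            raise ValueError("bladder volumes must be positive")


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on the reference grid.

    ``vectors`` has shape (3, nx, ny, nz); component order matches the grid
    axes.  ``support`` marks where the field may be non-zero (structures plus
    the decay band).
    """

    geometry: GridGeometry
    vectors: np.ndarray
    support: StructureMask

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        expected = (3,) + tuple(self.geometry.shape)
        if self.vectors.shape != expected:
            raise ValueError(f"vectors shape {self.vectors.shape} != {expected}")
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement field contains non-finite values")

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.vectors.astype(np.float64) ** 2).sum(axis=0))

    def sample_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear sample of the field at arbitrary mm points (n, 3)."""
        idx = self.geometry.mm_to_indices(points_mm).T
        out = np.empty((3, idx.shape[1]), dtype=np.float64)
        for c in range(3):
            out[c] = ndimage.map_coordinates(
                self.vectors[c], idx, order=1, mode="constant", cval=0.0
            )
        return out.T


def time_scale_factor(ts: TimeScaling, t_i: float, eps: float = 1e-6) -> float:
    """Relative deformation-vector length at time ``t_i`` vs. time ``t2``.

    Falls back to the linear time ratio (t_i-t1)/(t2-t1) with a warning when
    the two volumes are indistinguishable (no net filling to interpolate).
    Times beyond t2 are allowed and give K > 1 (model-time extrapolation).
    """
    if t_i < ts.t1:
        raise ValueError(f"t_i={t_i} precedes t1={ts.t1}")
    if abs(ts.V2 - ts.V1) / ts.V1 <= eps:
        warnings.warn(
            "V2 ~ V1: time scale factor degenerates to the linear time ratio",
            stacklevel=2,
        )
        return (t_i - ts.t1) / (ts.t2 - ts.t1)
    v_i = ts.V1 + (t_i - ts.t1) * (ts.V2 - ts.V1) / (ts.t2 - ts.t1)
    num = (v_i / ts.V1) ** (1.0 / 3.0) - 1.0
    den = (ts.V2 / ts.V1) ** (1.0 / 3.0) - 1.0
    return float(num / den)


def scale_field(dvf: DisplacementField, k: float) -> DisplacementField:
    """Multiply every displacement vector by ``k`` (support unchanged)."""
    if k < 0:
        raise ValueError(f"scale factor must be >= 0, got {k}")
    return DisplacementField(dvf.geometry, dvf.vectors * np.float32(k), dvf.support)


# ---------------------------------------------------------------------------
# star-shaped ray correspondence


def _surface_points_mm(mask: StructureMask) -> np.ndarray:
    return mask.geometry.indices_to_mm(np.argwhere(surface_voxels(mask)))


class _RadiusLookup:
    """Boundary radius as a function of direction, from surface voxels.

    Directions are keyed by a KD-tree over the unit vectors of the surface
    voxels seen from the centroid; the radius at a query direction is the
    inverse-distance-weighted mean over the nearest few surface directions.
    """

    def __init__(self, points_mm: np.ndarray, centroid: np.ndarray, k: int = 3):
        rel = points_mm - centroid
        radii = np.maximum(np.linalg.norm(rel, axis=1), 1e-9)
        self.radii = radii
        self.dirs = rel / radii[:, None]
        self.tree = cKDTree(self.dirs)
        self.k = min(k, len(radii))

    def __call__(self, units: np.ndarray) -> np.ndarray:
        dist, idx = self.tree.query(units, k=self.k)
        if self.k == 1:
            return self.radii[idx]
        w = 1.0 / np.maximum(dist, 1e-6)
        return (self.radii[idx] * w).sum(axis=1) / w.sum(axis=1)


def _is_star_shaped(mask: StructureMask, centroid: np.ndarray, tol_frac: float = 0.02) -> bool:
    """Check that rays from the centroid to surface voxels stay inside."""
    pts = _surface_points_mm(mask)
    n_steps = 8
    fracs = np.linspace(0.15, 0.85, n_steps)
    samples = centroid[None, None, :] + fracs[None, :, None] * (pts - centroid)[:, None, :]
    idx = mask.geometry.mm_to_indices(samples.reshape(-1, 3)).T
    inside = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), idx, order=0, mode="constant", cval=0
    ).reshape(len(pts), n_steps)
    broken = (~inside.all(axis=1)).mean()
    return broken <= tol_frac


class _PairCorrespondence:
    """Ray correspondence for one (reference, target) structure pair.

    Maps x -> c_to + (rho / r_from(u)) * r_to(u) * u with u = (x - c_from)/rho:
    centroid maps to centroid, the reference surface onto the target surface,
    interior points interpolate radially, exterior points keep the surface
    displacement.  When either structure is not star-shaped about its
    centroid, the target radius function is instead derived from
    nearest-surface-point matches after centroid alignment.
    """

    def __init__(self, from_struct: StructureMask, to_struct: StructureMask):
        self.c_from = from_struct.centroid_mm()
        self.c_to = to_struct.centroid_mm()
        from_pts = _surface_points_mm(from_struct)
        to_pts = _surface_points_mm(to_struct)

        self.star = _is_star_shaped(from_struct, self.c_from) and _is_star_shaped(
            to_struct, self.c_to
        )
        self.r_from = _RadiusLookup(from_pts, self.c_from)
        if self.star:
            self.r_to = _RadiusLookup(to_pts, self.c_to)
        else:
            warnings.warn(
                f"{from_struct.label!r}/{to_struct.label!r} not star-shaped about "
                "its centroid; using nearest-surface-point correspondence",
                stacklevel=4,
            )
            tree = cKDTree(to_pts)
            _, nearest = tree.query(from_pts + (self.c_to - self.c_from))
            matched = to_pts[nearest]
            # key the matched target radii by the *reference* directions so
            # the lookup stays single-valued in u
            r_to = _RadiusLookup(from_pts, self.c_from)
            r_to.radii = np.maximum(np.linalg.norm(matched - self.c_to, axis=1), 1e-9)
            self.r_to = r_to

    def displacement_at(self, points_mm: np.ndarray):
        """Displacement (n, 3) plus signed radial excess rho - r_from (n,)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        rel = pts - self.c_from
        rho = np.linalg.norm(rel, axis=1)
        rho_safe = np.maximum(rho, 1e-9)
        units = rel / rho_safe[:, None]
        r_from = self.r_from(units)
        r_to = self.r_to(units)
        inside = rho <= r_from
        radial_target = np.where(
            inside, rho / np.maximum(r_from, 1e-9) * r_to, rho + (r_to - r_from)
        )
        disp = (self.c_to - self.c_from) + (radial_target / rho_safe - 1.0)[:, None] * rel
        disp[rho < 1e-8] = self.c_to - self.c_from
        return disp, rho - r_from


class SurfaceCorrespondence:
    """Blended multi-pair surface correspondence, evaluable at any points.

    Per-pair fields are blended with inverse-square weights in the radial
    excess distance to each pair's reference structure (each structure
    dominates its own neighbourhood), and the blend decays linearly to zero
    over ``DECAY_BAND_MM`` outside the union of the reference structures.
    This point-wise evaluator is what the pipeline uses; :func:`surface_dvf`
    wraps it into a dense grid field.
    """

    def __init__(
        self,
        from_struct: StructureMask,
        to_struct: StructureMask,
        steering: Sequence[Tuple[StructureMask, StructureMask]] = (),
    ):
        pairs = [(from_struct, to_struct)] + list(steering)
        geom = from_struct.geometry
        for f, t in pairs:
            if f.is_empty() or t.is_empty():
                raise ValueError("steering structures must be non-empty")
            if f.geometry != geom or t.geometry != geom:
                raise ValueError("all structures must share one grid geometry")
        self.geometry = geom
        self.pairs = pairs
        self.correspondences = [_PairCorrespondence(f, t) for f, t in pairs]

    def displacement_at(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        disp_acc = np.zeros_like(pts)
        w_acc = np.zeros(len(pts))
        min_excess = None
        for corr in self.correspondences:
            disp, excess = corr.displacement_at(pts)
            excess_out = np.maximum(excess, 0.0)
            w = 1.0 / (1.0 + excess_out) ** 2
            disp_acc += disp * w[:, None]
            w_acc += w
            min_excess = (
                excess_out if min_excess is None else np.minimum(min_excess, excess_out)
            )
        blended = disp_acc / w_acc[:, None]
        decay = np.clip(1.0 - min_excess / DECAY_BAND_MM, 0.0, 1.0)
        return blended * decay[:, None]


def surface_dvf(
    from_struct: StructureMask,
    to_struct: StructureMask,
    steering: Sequence[Tuple[StructureMask, StructureMask]] = (),
) -> DisplacementField:
    """Analytic contour-correspondence DVF mapping ``from_struct`` to ``to_struct``.

    ``steering`` supplies additional (reference, target) structure pairs
    (e.g. the CTV when the bladder is the primary pair).  The dense field is
    the :class:`SurfaceCorrespondence` evaluated at every voxel of the
    support region (structures plus the decay band); it is zero elsewhere.
    """
    corr = SurfaceCorrespondence(from_struct, to_struct, steering)
    geom = from_struct.geometry

    union = np.zeros(geom.shape, dtype=bool)
    for f, t in corr.pairs:
        union |= f.voxels | t.voxels
    support = expand(StructureMask(geom, union, "dvf-union"), DECAY_BAND_MM, subvoxel=False)
    support.label = "dvf-support"

    # evaluate within the support bounding box only
    nz = np.argwhere(support.voxels)
    lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = geom.coordinate_axes()
    coords = np.meshgrid(*(ax[s] for ax, s in zip(axes, box)), indexing="ij")
    box_shape = coords[0].shape
    pts = np.stack([c.ravel() for c in coords], axis=1)
    disp = corr.displacement_at(pts).T.reshape((3,) + box_shape)

    vectors = np.zeros((3,) + tuple(geom.shape), dtype=np.float32)
    vectors[(slice(None),) + box] = disp.astype(np.float32)
    vectors[:, ~support.voxels] = 0.0
    return DisplacementField(geom, vectors, support)


def compose_fields(
    first: DisplacementField, second: DisplacementField
) -> DisplacementField:
    """Compose two displacement fields: x -> x + first(x) + second(x + first(x)).

    Used to chain the interfraction (reference -> session-start) field with a
    time-scaled intrafraction field when accumulating doses on a common
    reference anatomy.  The composed field lives on ``first``'s support.
    """
    if first.geometry != second.geometry:
        raise ValueError("fields must share one grid geometry")
    geom = first.geometry
    axes = geom.coordinate_axes()
    grids = np.meshgrid(*axes, indexing="ij")
    mid = np.stack(
        [g + first.vectors[c] for c, g in enumerate(grids)], axis=-1
    ).reshape(-1, 3)
    second_at_mid = second.sample_mm(mid).T.reshape((3,) + tuple(geom.shape))
    return DisplacementField(
        geom, first.vectors + second_at_mid.astype(np.float32), first.support
    )


# ---------------------------------------------------------------------------
# contour propagation


def propagate(mask: StructureMask, dvf: DisplacementField) -> StructureMask:
    """Forward-map a mask through a displacement field.

    Foreground voxel centres are displaced by the field value at their own
    voxel, resampled to the nearest grid voxel, and one-voxel gaps left by
    expansive fields are closed morphologically (closing + hole fill).
    Displacements landing outside the grid are clipped with a warning.
    """
    if mask.geometry != dvf.geometry:
        raise ValueError("mask and field must share one grid geometry")
    if mask.is_empty():
        return mask.copy()
    geom = mask.geometry
    idx = np.argwhere(mask.voxels)
    disp_vox = np.stack(
        [dvf.vectors[c][tuple(idx.T)] / geom.spacing[c] for c in range(3)], axis=1
    )
    target = np.rint(idx + disp_vox).astype(np.int64)
    upper = np.asarray(geom.shape) - 1
    clipped = (target < 0) | (target > upper)
    if clipped.any():
        warnings.warn(
            f"propagate: {int(clipped.any(axis=1).sum())} displaced voxels "
            "fell outside the grid and were clipped",
            stacklevel=2,
        )
        target = np.clip(target, 0, upper)
    out = np.zeros(geom.shape, dtype=bool)
    out[tuple(target.T)] = True
    out = ndimage.binary_closing(out, structure=np.ones((3, 3, 3), dtype=bool))
    out = ndimage.binary_fill_holes(out)
    return StructureMask(geom, out, mask.label)
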