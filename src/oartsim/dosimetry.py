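"""Dose grids, gEUD/nEUD dosimetry and deformable dose accumulation.

The figure of merit throughout is the generalized equivalent uniform dose,
the power mean of order ``a`` of the voxel doses inside a structure:

    gEUD = ( (1/N) * sum_i d_i^a )^(1/a)

with ``a = -20`` for the target, which weights cold spots heavily (the
limit a -> -inf is the minimum dose).  nEUD is gEUD divided by the
prescribed dose; an nEUD of 1.0 means the structure effectively receives
the full prescription.

gEUD is evaluated in log space (log-sum-exp): at a = -20 a direct power
sum over doses spanning two orders of magnitude would overflow float64.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .deformation import DisplacementField
from .geometry import GridGeometry, StructureMask

__all__ = [
    "DoseGrid",
    "EUDParams",
    "synth_adapted_dose",
    "geud",
    "neud",
    "dvh",
    "dose_at_volume",
    "warp_dose",
    "accumulate",
]


@dataclass
class DoseGrid:
    """Scalar 3D dose (Gy) sharing a grid geometry with the structure masks."""

    geometry: GridGeometry
    values: np.ndarray
    prescribed_dose: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"dose shape {self.values.shape} does not match grid {self.geometry.shape}"
            )
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("dose values must be finite and non-negative")
        if self.prescribed_dose <= 0:
            raise ValueError("prescribed dose must be positive")


@dataclass(frozen=True)
class EUDParams:
    """Power-law exponent of the gEUD; a = -20 emphasises target cold spots."""

    a: float = -20.0

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("gEUD exponent a must be non-zero")


def synth_adapted_dose(
    ptv: StructureMask, prescribed: float, penumbra_sigma: float
) -> DoseGrid:
    """Conformal dose: full prescription inside the PTV, Gaussian falloff outside.

    Outside the PTV the dose is prescribed * exp(-d^2 / (2 sigma^2)) with d
    the Euclidean distance (mm) to the PTV surface — a stand-in for an
    adapted plan optimized to the PTV of the day, monotone non-increasing
    with distance from the target.
    """
    if ptv.is_empty():
        raise ValueError("PTV must be non-empty")
    if penumbra_sigma <= 0:
        raise ValueError("penumbra sigma must be positive")
    d = ndimage.distance_transform_edt(~ptv.voxels, sampling=ptv.geometry.spacing)
    values = prescribed * np.exp(-(d**2) / (2.0 * penumbra_sigma**2))
    return DoseGrid(ptv.geometry, values, prescribed)


def geud(dose: DoseGrid, roi: StructureMask, params: EUDParams = EUDParams()) -> float:
    """Generalized equivalent uniform dose (Gy) over a structure.

    For a < 0 any zero-dose voxel drives the power mean to its limit value of
    0 Gy; that limit is returned with a warning instead of raising.
    """
    if roi.is_empty():
        raise ValueError("gEUD of an empty structure is undefined")
    if dose.geometry != roi.geometry:
        raise ValueError("dose and structure must share one grid geometry")
    d = dose.values[roi.voxels]
    a = params.a
    if a < 0 and (d <= 0).any():
        warnings.warn(
            "zero-dose voxel inside structure with a < 0: gEUD limit is 0 Gy",
            stacklevel=2,
        )
        return 0.0
    if (d == 0).all():
        return 0.0
    logd = np.log(d[d > 0]) if a > 0 else np.log(d)
    n_all = d.size
    # for a > 0, zero-dose voxels contribute 0 to the power sum but count in N
    log_mean = logsumexp(a * logd) - np.log(n_all)
    return float(np.exp(log_mean / a))


def neud(
    dose: DoseGrid,
    roi: StructureMask,
    params: EUDParams = EUDParams(),
    total_prescribed: float | None = None,
) -> float:
    """gEUD normalized to the prescription (per fraction or accumulated).

    Per-fraction calls normalize by the fraction prescription; accumulated
    calls must pass ``n_fractions * fraction prescription``.
    """
    if total_prescribed is None:
        total_prescribed = dose.prescribed_dose
    if total_prescribed <= 0:
        raise ValueError("total prescribed dose must be positive")
    return geud(dose, roi, params) / total_prescribed


def dvh(
    dose: DoseGrid, roi: StructureMask, bin_width: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram over a structure.

    Returns ``(dose_edges, volume_fraction)`` where ``volume_fraction[i]`` is
    the fraction of the structure receiving at least ``dose_edges[i]``; the
    curve starts at 1 at 0 Gy and reaches 0 above the maximum dose.
    """
    if roi.is_empty():
        raise ValueError("DVH of an empty structure is undefined")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    d = dose.values[roi.voxels]
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    return edges, frac


def dose_at_volume(dose: DoseGrid, roi: StructureMask, volume_fraction: float) -> float:
    """D_v: minimum dose received by the hottest ``volume_fraction`` of the roi."""
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume fraction must be in (0, 1]")
    d = np.sort(dose.values[roi.voxels])[::-1]
    k = int(np.ceil(volume_fraction * d.size)) - 1
    return float(d[k])


def warp_dose(dose: DoseGrid, dvf_ref_to_fraction: DisplacementField) -> DoseGrid:
    """Pull a fraction dose back onto the reference grid.

    The output voxel at reference position x takes the trilinearly
    interpolated dose at x + dvf(x).  Samples falling outside the grid take
    0 Gy; their count is recorded in ``meta['outside_samples']``.
    """
    if dose.geometry != dvf_ref_to_fraction.geometry:
        raise ValueError("dose and field must share one grid geometry")
    geom = dose.geometry
    idx = np.indices(geom.shape, dtype=np.float64)
    coords = [
        idx[c] + dvf_ref_to_fraction.vectors[c] / geom.spacing[c] for c in range(3)
    ]
    outside = np.zeros(geom.shape, dtype=bool)
    for c in range(3):
        outside |= (coords[c] < 0) | (coords[c] > geom.shape[c] - 1)
    values = ndimage.map_coordinates(
        dose.values, coords, order=1, mode="constant", cval=0.0
    )
    out = DoseGrid(geom, np.maximum(values, 0.0), dose.prescribed_dose)
    n_out = int(outside.sum())
    out.meta["outside_samples"] = n_out
    if n_out and n_out > 0.25 * np.prod(geom.shape):
        warnings.warn(
            f"warp_dose: {n_out} samples fell outside the grid", stacklevel=2
        )
    return out


def accumulate(
    doses: Sequence[DoseGrid], dvfs: Sequence[DisplacementField]
) -> DoseGrid:
    """Deformable dose accumulation: sum of fraction doses warped to reference.

    All fractions must share the grid geometry and the per-fraction
    prescription; the accumulated grid carries ``n * prescription`` so that
    accumulated nEUD is directly comparable to per-fraction nEUD.
    """
    if len(doses) != len(dvfs) or not doses:
        raise ValueError("need equally many (non-zero) doses and fields")
    rx = doses[0].prescribed_dose
    geom = doses[0].geometry
    for d in doses:
        if d.geometry != geom:
            raise ValueError("mixed grid geometries in accumulation")
        if not np.isclose(d.prescribed_dose, rx):
            raise ValueError("mixed per-fraction prescriptions in accumulation")
    total = np.zeros(geom.shape, dtype=np.float64)
    outside = 0
    for d, f in zip(doses, dvfs):
        w = warp_dose(d, f)
        total += w.values
        outside += w.meta.get("outside_samples", 0)
    out = DoseGrid(geom, total, rx * len(doses))
    out.meta["outside_samples"] = outside
    return out
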