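"""Digital bladder/CTV phantom: multi-series synthetic treatment cohorts.

Real adaptive-session imaging of this kind is not publicly available, so the
package carries a parametric phantom whose anatomy and motion are known in
closed form.  Each treatment *series* (one patient's course) consists of
fractions; each fraction has

* an anatomy at session start t1 = 0 min (bladder, focal CTV on the bladder
  wall, PTV = CTV + clinical margin), perturbed from the series baseline by
  interfraction set-up jitter,
* a continuous intrafraction motion model — the bladder fills linearly at a
  per-fraction rate and its wall expands radially with the cube root of
  volume, while the whole anatomy drifts posteriorly at a constant rate —
  evaluated at the sampled adaptation time t2 to give the anatomy of the
  verification scan,
* the exact ground-truth displacement field t1 -> t2 implied by that model,
* a conformal adapted dose fixed in room coordinates, optimized to the PTV
  of the day.

Calibration of the defaults follows the clinical summary statistics the
analysis is meant to emulate: bladder volumes with median ~250 mL (range
~113-382 mL), linear filling of 4.29 +/- 0.89 mL/min, adaptation times with
median 18.8 min (range 8.6-33.3 min), and a cohort split into five
time-sensitive series (smaller bladders, median ~110 mL, stronger dorsal
drift) and four time-insensitive series (median ~255 mL).

The bladder is an ellipsoid; real bladders are irregular, but a parametric
solid gives closed-form volumes and displacement fields, hence exact test
oracles.  Interfraction variation perturbs the session-start anatomy (the
set-up of the day); intrafraction motion is the continuous model between t1
and t2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .deformation import DisplacementField
from .dosimetry import DoseGrid, synth_adapted_dose
from .geometry import (
    POSTERIOR_AXIS,
    GridGeometry,
    StructureMask,
    contract,
    expand,
    volume_of,
)

__all__ = [
    "PhantomConfig",
    "AdaptationTimeDist",
    "SeriesSpec",
    "AnatomyInstance",
    "FractionRecord",
    "make_bladder",
    "make_ctv",
    "sample_series",
    "draw_adaptation_times",
    "anatomy_at_time",
    "default_cohort",
    "cohort_geometry",
]

#: posterior unit vector in grid coordinates
POSTERIOR = np.array([0.0, 1.0, 0.0])

#: decay band (mm) of the ground-truth field outside the moving structures
GT_DECAY_BAND_MM = 10.0

#: relative SD of the per-fraction bladder start volume around the series value
VOLUME_JITTER_FRAC = 0.08

#: default intrafraction horizon (min) for model-time evaluation
TIME_HORIZON_MIN = 45.0


class SizingError(ValueError):
    """A requested structure does not fit inside the grid."""


@dataclass(frozen=True)
class PhantomConfig:
    """Per-series anatomy and motion parameters.

    filling_rate / filling_rate_sd parameterize the truncated-normal
    per-fraction bladder filling (mL/min); dorsal_bias is the posterior drift
    rate (mm/min); interfraction jitter (mm) perturbs the session-start
    bladder position and shape from fraction to fraction.
    """

    bladder_volume_start: float = 250.0  # mL
    filling_rate: float = 4.29  # mL/min, population mean
    filling_rate_sd: float = 0.89  # mL/min
    filling_rate_floor: float = 0.5  # mL/min truncation
    ctv_patch_fraction: float = 0.10  # fraction of wall area covered
    wall_thickness: float = 5.0  # mm
    dorsal_bias: float = 0.0  # mm/min posterior drift
    clinical_margin: float = 5.0  # mm CTV -> PTV
    prescribed_dose: float = 2.75  # Gy per fraction
    penumbra_sigma: float = 4.0  # mm dose falloff
    axis_ratios: Tuple[float, float, float] = (1.0, 1.1, 0.95)
    seed: int = 0

    def __post_init__(self):
        if not 50.0 <= self.bladder_volume_start <= 600.0:
            raise ValueError(
                f"bladder_volume_start must be in [50, 600] mL, got {self.bladder_volume_start}"
            )
        if self.filling_rate < 0:
            raise ValueError("filling_rate must be >= 0")
        if not 0.0 < self.ctv_patch_fraction <= 0.5:
            raise ValueError("ctv_patch_fraction must be in (0, 0.5]")
        if self.clinical_margin < 0:
            raise ValueError("clinical_margin must be >= 0")


@dataclass(frozen=True)
class AdaptationTimeDist:
    """Log-normal adaptation-time model, clipped to the observed range.

    The distribution family is a modelling choice; the defaults reproduce
    the clinical summary (median 18.8 min, range 8.6-33.3 min).
    """

    median: float = 18.8
    sigma: float = 0.27  # log-scale SD
    lo: float = 8.6
    hi: float = 33.3

    def __post_init__(self):
        if not (5.0 <= self.lo < self.hi <= 45.0):
            raise ValueError("adaptation-time bounds must lie within [5, 45] min")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        t = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)
        return np.clip(t, self.lo, self.hi)


@dataclass(frozen=True)
class SeriesSpec:
    n_fractions: int = 15
    adaptation_time_dist: AdaptationTimeDist = field(default_factory=AdaptationTimeDist)
    sensitivity_class: str = "time_sensitive"
    interfraction_jitter: float = 2.5  # mm

    def __post_init__(self):
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.sensitivity_class not in ("time_sensitive", "time_insensitive"):
            raise ValueError(f"unknown sensitivity class {self.sensitivity_class!r}")


@dataclass
class AnatomyInstance:
    bladder: StructureMask
    ctv: StructureMask
    ptv: StructureMask
    time: float  # min since session start
    bladder_volume: float  # mL, voxel-counted


@dataclass(frozen=True)
class FractionMotion:
    """Closed-form intrafraction motion of one fraction.

    The bladder at time t is the baseline ellipsoid scaled about its centre
    by s(t) = (V(t)/V1)^(1/3) with V(t) = V1 + rate*t, translated posteriorly
    by dorsal_bias*t.  CTV and bladder move with the same affine map.
    """

    center0: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    V1: float  # mL, analytic
    filling_rate: float  # mL/min
    dorsal_bias: float  # mm/min

    def scale(self, t: float) -> float:
        return ((self.V1 + self.filling_rate * t) / self.V1) ** (1.0 / 3.0)

    def center(self, t: float) -> np.ndarray:
        return np.asarray(self.center0) + self.dorsal_bias * t * POSTERIOR

    def displacement(self, points_mm: np.ndarray, t: float) -> np.ndarray:
        """Exact displacement (n, 3) of material points from t=0 to t."""
        c0 = np.asarray(self.center0)
        s = self.scale(t)
        return (self.center(t) - c0) + (s - 1.0) * (np.atleast_2d(points_mm) - c0)


@dataclass
class FractionRecord:
    series_id: str
    fraction_id: int
    anatomy_t1: AnatomyInstance
    anatomy_t2: AnatomyInstance
    adaptation_time: float  # min
    dose: DoseGrid  # adapted plan, fixed in room coordinates
    filling_rate: float  # mL/min
    sensitivity_class: str
    motion: FractionMotion
    _gt_dvf: Optional[DisplacementField] = None

    @property
    def ground_truth_dvf(self) -> DisplacementField:
        """Exact t1 -> t2 displacement field of the generator's motion model.

        Built lazily: the analysis pipeline never reads it (it consumes only
        what a clinic observes); the test suite uses it as the oracle.
        """
        if self._gt_dvf is None:
            self._gt_dvf = _ground_truth_dvf(
                self.anatomy_t1.bladder.geometry,
                self.motion,
                self.anatomy_t1,
                self.adaptation_time,
            )
        return self._gt_dvf


# ---------------------------------------------------------------------------
# structure construction


def _ellipsoid_mask(
    geometry: GridGeometry,
    center: Sequence[float],
    semi_axes: Sequence[float],
    label: str,
) -> StructureMask:
    axes = geometry.coordinate_axes()
    terms = [((ax - c) / a) ** 2 for ax, c, a in zip(axes, center, semi_axes)]
    inside = (
        terms[0][:, None, None] + terms[1][None, :, None] + terms[2][None, None, :]
    ) <= 1.0
    return StructureMask(geometry, inside, label)


def _semi_axes_for_volume(volume_ml: float, axis_ratios: Sequence[float]) -> np.ndarray:
    ratios = np.asarray(axis_ratios, dtype=float)
    r0 = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    return r0 * ratios


def make_bladder(
    geometry: GridGeometry,
    center: Sequence[float],
    volume_target: float,
    axis_ratios: Sequence[float] = (1.0, 1.0, 1.0),
    label: str = "bladder",
    clearance_mm: float = 10.0,
) -> StructureMask:
    """Solid ellipsoidal bladder of a given volume (mL).

    Voxel-counted volume agrees with ``volume_target`` to within the
    digitization error of the grid (< 2% at the spacings used here).  Raises
    :class:`SizingError` naming the limiting axis if the ellipsoid does not
    leave ``clearance_mm`` to every grid boundary.
    """
    semi = _semi_axes_for_volume(volume_target, axis_ratios)
    lo = np.asarray(geometry.origin)
    hi = lo + (np.asarray(geometry.shape) - 1) * np.asarray(geometry.spacing)
    c = np.asarray(center, dtype=float)
    for ax in range(3):
        if c[ax] - semi[ax] < lo[ax] + clearance_mm or c[ax] + semi[ax] > hi[ax] - clearance_mm:
            raise SizingError(
                f"bladder of {volume_target:.1f} mL does not fit on axis {ax} "
                f"(semi-axis {semi[ax]:.1f} mm, grid extent "
                f"[{lo[ax]:.1f}, {hi[ax]:.1f}] mm, clearance {clearance_mm} mm)"
            )
    return _ellipsoid_mask(geometry, c, semi, label)


def make_ctv(
    bladder: StructureMask,
    patch_fraction: float,
    wall_thickness: float,
    direction: Sequence[float],
) -> StructureMask:
    """Focal tumour patch on the bladder wall.

    The CTV occupies the wall shell — the outer ``wall_thickness`` of the
    bladder plus an equal outward extension — restricted to the spherical cap
    of directions around ``direction`` covering ``patch_fraction`` of the
    wall area (cap area fraction (1 - cos theta)/2).  Deterministic given its
    inputs.
    """
    if bladder.is_empty():
        raise ValueError("bladder mask is empty")
    if not 0.0 < patch_fraction <= 0.5:
        raise ValueError(f"patch_fraction must be in (0, 0.5], got {patch_fraction}")
    u = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    u = u / norm

    shell = (
        expand(bladder, wall_thickness, subvoxel=False).voxels
        & ~contract(bladder, wall_thickness, subvoxel=False).voxels
    )
    c = bladder.centroid_mm()
    axes = bladder.geometry.coordinate_axes()
    rel = [ax - cc for ax, cc in zip(axes, c)]
    dot = (
        rel[0][:, None, None] * u[0]
        + rel[1][None, :, None] * u[1]
        + rel[2][None, None, :] * u[2]
    )
    rho = np.sqrt(
        rel[0][:, None, None] ** 2 + rel[1][None, :, None] ** 2 + rel[2][None, None, :] ** 2
    )
    cos_theta = 1.0 - 2.0 * patch_fraction
    cap = dot >= cos_theta * np.maximum(rho, 1e-9)
    vox = shell & cap
    # keep the principal connected component (cap geometry is contiguous,
    # but digitization can shed isolated voxels at the rim)
    labels, n = ndimage.label(vox)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        vox = labels == (1 + int(np.argmax(sizes)))
    return StructureMask(bladder.geometry, vox, "ctv")


# ---------------------------------------------------------------------------
# continuous motion model


def _bladder_at(
    geometry: GridGeometry, motion: FractionMotion, t: float
) -> StructureMask:
    s = motion.scale(t)
    semi = np.asarray(motion.semi_axes) * s
    return _ellipsoid_mask(geometry, motion.center(t), semi, "bladder")


def _warp_mask_affine(
    mask: StructureMask, motion: FractionMotion, t: float
) -> StructureMask:
    """Evaluate the affine image of a t=0 mask at time t (pull-back resample)."""
    if t == 0.0:
        return mask.copy()
    geom = mask.geometry
    s = motion.scale(t)
    c0 = np.asarray(motion.center0)
    ct = motion.center(t)
    axes = geom.coordinate_axes()
    # inverse map: y = c0 + (x - c(t)) / s
    inv_axes = [
        (c0[i] + (ax - ct[i]) / s - geom.origin[i]) / geom.spacing[i]
        for i, ax in enumerate(axes)
    ]
    coords = np.meshgrid(*inv_axes, indexing="ij")
    vals = ndimage.map_coordinates(
        mask.voxels.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    return StructureMask(geom, vals >= 0.5, mask.label)


def _anatomy_from_motion(
    geometry: GridGeometry,
    motion: FractionMotion,
    ctv_t0: StructureMask,
    clinical_margin: float,
    t: float,
) -> AnatomyInstance:
    bladder = _bladder_at(geometry, motion, t)
    ctv = _warp_mask_affine(ctv_t0, motion, t)
    ptv = expand(ctv, clinical_margin)
    ptv.label = "ptv"
    return AnatomyInstance(bladder, ctv, ptv, t, volume_of(bladder))


def anatomy_at_time(fraction: FractionRecord, t: float) -> AnatomyInstance:
    """Ground-truth anatomy of a fraction at an arbitrary session time (min).

    This is the generator's own continuous model — the oracle that the
    K-scaled deformation model is validated against.  t = 0 reproduces the
    session-start anatomy voxel for voxel; t = adaptation_time reproduces the
    verification anatomy.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if t > TIME_HORIZON_MIN:
        raise ValueError(f"time {t} min exceeds the {TIME_HORIZON_MIN} min horizon")
    geom = fraction.anatomy_t1.bladder.geometry
    margin = fraction.anatomy_t1.ptv.meta.get("clinical_margin", 5.0)
    return _anatomy_from_motion(
        geom, fraction.motion, fraction.anatomy_t1.ctv, margin, t
    )


def _ground_truth_dvf(
    geometry: GridGeometry,
    motion: FractionMotion,
    anatomy_t1: AnatomyInstance,
    t2: float,
) -> DisplacementField:
    core = anatomy_t1.bladder.voxels | anatomy_t1.ctv.voxels
    support = expand(StructureMask(geometry, core, "core"), GT_DECAY_BAND_MM, subvoxel=False)
    support.label = "gt-dvf-support"

    axes = geometry.coordinate_axes()
    c0 = np.asarray(motion.center0)
    s = motion.scale(t2)
    shift = motion.center(t2) - c0

    dist_out = ndimage.distance_transform_edt(~core, sampling=geometry.spacing)
    decay = np.clip(1.0 - dist_out / GT_DECAY_BAND_MM, 0.0, 1.0).astype(np.float32)

    vectors = np.zeros((3,) + tuple(geometry.shape), dtype=np.float32)
    for i in range(3):
        rel = (axes[i] - c0[i]).astype(np.float32)
        comp = np.float32(shift[i]) + np.float32(s - 1.0) * rel
        bcast = [1, 1, 1]
        bcast[i] = -1
        vectors[i] = comp.reshape(bcast) * decay
    vectors[:, ~support.voxels] = 0.0
    return DisplacementField(geometry, vectors, support)


# ---------------------------------------------------------------------------
# series sampling


def sample_series(
    spec: SeriesSpec,
    config: PhantomConfig,
    rng_seed: int,
    geometry: Optional[GridGeometry] = None,
    series_id: str = "S1",
) -> List[FractionRecord]:
    """Generate one treatment series of fractions.

    Per fraction: the adaptation time is drawn from the series' clipped
    log-normal; the session-start anatomy is the series baseline perturbed by
    interfraction jitter (bladder centre, axis ratios and start volume); the
    verification anatomy and the exact ground-truth t1->t2 displacement field
    follow from the closed-form motion model; the adapted dose is a conformal
    distribution around the PTV of the day.  Bit-identical on repeated calls
    with the same seed.
    """
    rng = np.random.default_rng(rng_seed)
    if geometry is None:
        geometry = cohort_geometry([config], [spec])
    center_base = geometry.center_mm

    # adaptation times are drawn first so that draw_adaptation_times() can
    # reproduce them without building any anatomy
    times = spec.adaptation_time_dist.sample(rng, spec.n_fractions)

    # fixed tumour-patch direction for the series: posterior with a random tilt
    tilt = rng.normal(0.0, 0.3, size=3)
    ctv_dir = POSTERIOR + tilt
    ctv_dir = ctv_dir / np.linalg.norm(ctv_dir)

    records: List[FractionRecord] = []
    for k in range(spec.n_fractions):
        t2 = float(times[k])
        if config.filling_rate_sd > 0:
            rate = float(
                np.clip(
                    rng.normal(config.filling_rate, config.filling_rate_sd),
                    config.filling_rate_floor,
                    None,
                )
            )
        else:
            rate = config.filling_rate
        v1 = float(
            np.clip(
                config.bladder_volume_start
                * np.exp(rng.normal(0.0, VOLUME_JITTER_FRAC)),
                50.0,
                600.0,
            )
        )
        center = center_base + rng.normal(0.0, spec.interfraction_jitter, size=3)
        ratios = np.asarray(config.axis_ratios) * np.exp(rng.normal(0.0, 0.04, size=3))
        semi = _semi_axes_for_volume(v1, ratios)

        motion = FractionMotion(
            center0=tuple(center),
            semi_axes=tuple(semi),
            V1=v1,
            filling_rate=rate,
            dorsal_bias=config.dorsal_bias,
        )
        bladder_t1 = _ellipsoid_mask(geometry, center, semi, "bladder")
        ctv_t1 = make_ctv(
            bladder_t1, config.ctv_patch_fraction, config.wall_thickness, ctv_dir
        )
        ptv_t1 = expand(ctv_t1, config.clinical_margin)
        ptv_t1.label = "ptv"
        ptv_t1.meta["clinical_margin"] = config.clinical_margin
        anatomy_t1 = AnatomyInstance(
            bladder_t1, ctv_t1, ptv_t1, 0.0, volume_of(bladder_t1)
        )
        anatomy_t2 = _anatomy_from_motion(
            geometry, motion, ctv_t1, config.clinical_margin, t2
        )
        anatomy_t2.ptv.meta["clinical_margin"] = config.clinical_margin

        dose = synth_adapted_dose(
            ptv_t1, config.prescribed_dose, config.penumbra_sigma
        )

        records.append(
            FractionRecord(
                series_id=series_id,
                fraction_id=k + 1,
                anatomy_t1=anatomy_t1,
                anatomy_t2=anatomy_t2,
                adaptation_time=t2,
                dose=dose,
                filling_rate=rate,
                sensitivity_class=spec.sensitivity_class,
                motion=motion,
            )
        )
    return records


def draw_adaptation_times(spec: SeriesSpec, rng_seed: int) -> np.ndarray:
    """The adaptation times (min) that sample_series(spec, ..., rng_seed) draws.

    Reproduces exactly the per-fraction times of a series without building
    anatomy, so cohort-wide tercile times can be computed before the heavy
    generation pass.
    """
    rng = np.random.default_rng(rng_seed)
    return spec.adaptation_time_dist.sample(rng, spec.n_fractions)


# ---------------------------------------------------------------------------
# default cohort (study conditions)

#: per-series baseline bladder start volumes (mL): five time-sensitive
#: (median 110, matching the clinical ~109.8) and four time-insensitive
#: (median 255, matching ~254.8)
SENSITIVE_VOLUMES = (90.0, 100.0, 110.0, 120.0, 140.0)
INSENSITIVE_VOLUMES = (200.0, 240.0, 270.0, 310.0)

#: dorsal drift rates (mm/min): time-sensitive series deform markedly more
SENSITIVE_DORSAL_BIAS = 0.45
INSENSITIVE_DORSAL_BIAS = 0.08

#: per-class adaptation-time medians (min): the time-sensitive series were
#: the faster (IMRT-like) sessions, the insensitive ones the slower (VMAT-like)
SENSITIVE_TIME_MEDIAN = 18.1
INSENSITIVE_TIME_MEDIAN = 25.7


def default_cohort(
    n_fractions: int = 15, seed: int = 0
) -> List[Tuple[str, SeriesSpec, PhantomConfig]]:
    """The nine-series study cohort: 5 time-sensitive + 4 time-insensitive."""
    cohort = []
    i = 0
    for v in SENSITIVE_VOLUMES:
        i += 1
        spec = SeriesSpec(
            n_fractions=n_fractions,
            adaptation_time_dist=AdaptationTimeDist(median=SENSITIVE_TIME_MEDIAN),
            sensitivity_class="time_sensitive",
            interfraction_jitter=3.0,
        )
        cfg = PhantomConfig(
            bladder_volume_start=v,
            dorsal_bias=SENSITIVE_DORSAL_BIAS,
            seed=seed,
        )
        cohort.append((f"S{i}", spec, cfg))
    for v in INSENSITIVE_VOLUMES:
        i += 1
        spec = SeriesSpec(
            n_fractions=n_fractions,
            adaptation_time_dist=AdaptationTimeDist(median=INSENSITIVE_TIME_MEDIAN),
            sensitivity_class="time_insensitive",
            interfraction_jitter=2.0,
        )
        cfg = PhantomConfig(
            bladder_volume_start=v,
            dorsal_bias=INSENSITIVE_DORSAL_BIAS,
            seed=seed,
        )
        cohort.append((f"S{i}", spec, cfg))
    return cohort


def cohort_geometry(
    configs: Sequence[PhantomConfig],
    specs: Sequence[SeriesSpec],
    spacing: float = 1.0,
) -> GridGeometry:
    """Shared grid large enough for every series at its fullest and most drifted.

    Sizes the grid from the largest end-of-horizon bladder plus wall, margin,
    jitter, drift, the field decay band and boundary clearance.
    """
    max_needed = 0.0
    for cfg, spec in zip(configs, specs):
        t_max = spec.adaptation_time_dist.hi
        v_max = (
            cfg.bladder_volume_start * np.exp(2.5 * VOLUME_JITTER_FRAC)
            + (cfg.filling_rate + 2.5 * cfg.filling_rate_sd) * t_max
        )
        ratios = np.asarray(cfg.axis_ratios) * np.exp(0.12)
        r_max = _semi_axes_for_volume(v_max, ratios).max()
        needed = (
            r_max
            + cfg.wall_thickness
            + cfg.clinical_margin
            + 3.0 * spec.interfraction_jitter
            + cfg.dorsal_bias * t_max
            + GT_DECAY_BAND_MM
            + 12.0  # boundary clearance
        )
        max_needed = max(max_needed, needed)
    n = int(np.ceil(2.0 * max_needed / spacing))
    n = max(n, 8)
    return GridGeometry(
        shape=(n, n, n), spacing=(spacing,) * 3, origin=(0.0, 0.0, 0.0)
    )
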