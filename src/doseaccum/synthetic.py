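"""Synthetic head-and-neck radiotherapy course with known ground truth.

Stands in for a clinical cohort: an ellipsoidal head phantom (soft tissue,
fat shell, cranial bone shell, spine, airway, nasopharyngeal target, two
parotid glands) imaged on a 3 mm-slice planning-CT grid, plus weekly
cone-beam CTs on a 2.5 mm-slice grid.  Each week's anatomy is produced by a
*known* smooth displacement field — parotid shrinkage as a radial
contraction about each gland's (drifting) center, medial gland drift, a
lateral neck-thinning compression — composed with a random rigid setup
error, and the CBCT appearance is corrupted by a multiplicative
low-frequency bias field, additive Gaussian noise and a global HU
miscalibration.  The generating fields and the deformed masks are stored so
registration accuracy can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import GridGeometry, ImageVolume, Modality, StructureMask
from .registration import DisplacementField, RigidTransform, warp


class ConfigError(ValueError):
    """Phantom or course parameters are inconsistent."""


DEFAULT_HU = {
    "air": -1000.0,
    "fat": -100.0,
    "soft": 40.0,
    "parotid": 30.0,
    "bone": 700.0,
}

#: planning-CT grid: 2.5 mm in-plane, 3 mm slices, centered on the head
DEFAULT_CT_GEOMETRY = GridGeometry.centered((96, 96, 64), (2.5, 2.5, 3.0))
#: CBCT grid: 2.5 mm slices (shorter axial coverage than the planning CT)
DEFAULT_CBCT_GEOMETRY = GridGeometry.centered((96, 96, 64), (2.5, 2.5, 2.5))


@dataclass
class PhantomParams:
    """Geometry (mm) and HU assignments of the head phantom."""

    head_semiaxes: tuple[float, float, float] = (80.0, 95.0, 110.0)
    fat_shell_start: float = 0.90          # fraction of head radius
    skull_inner: float = 0.70              # cranial shell, fraction of head radius
    skull_outer: float = 0.82
    skull_z_min: float = 5.0               # shell only above this z (mm)
    spine_center_y: float = -55.0
    spine_radius: float = 10.0
    spine_z_max: float = 15.0
    airway_center: tuple[float, float, float] = (0.0, 30.0, -25.0)
    airway_semiaxes: tuple[float, float, float] = (10.0, 14.0, 28.0)
    target_center: tuple[float, float, float] = (0.0, 8.0, -10.0)
    target_semiaxes: tuple[float, float, float] = (22.0, 18.0, 22.0)
    parotid_lateral_offset: float = 52.0   # |x| of gland centers
    parotid_center_yz: tuple[float, float] = (-8.0, -25.0)
    parotid_semiaxes: tuple[float, float, float] = (15.0, 12.0, 18.0)
    hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    geometry: GridGeometry = field(default_factory=lambda: DEFAULT_CT_GEOMETRY)
    jitter: float = 0.08                   # relative anatomical variability


@dataclass
class CourseParams:
    """Treatment-course schedule and anatomical-change magnitudes."""

    n_weeks: int = 7
    fractions_per_week: int = 5
    fraction_dose_gy: float = 2.0
    total_dose_gy: float = 70.0
    parotid_volume_reduction: float = 0.135  # fractional loss over the course
    medial_drift_mm: float = 4.0             # gland COM shift toward midline
    neck_thinning_mm: float = 3.0            # lateral surface regression
    setup_sigma_mm: float = 2.0              # weekly rigid setup error (SD)
    setup_sigma_deg: float = 1.0
    seed: int = 0
    cbct_geometry: GridGeometry = field(default_factory=lambda: DEFAULT_CBCT_GEOMETRY)

    def __post_init__(self) -> None:
        planned = self.n_weeks * self.fractions_per_week * self.fraction_dose_gy
        if abs(planned - self.total_dose_gy) > self.fraction_dose_gy + 1e-9:
            raise ConfigError(
                f"schedule delivers {planned} Gy but total_dose is "
                f"{self.total_dose_gy} Gy (off by more than one fraction)"
            )
        if self.parotid_volume_reduction >= 0.60:
            raise ConfigError(
                "parotid volume reduction >= 60% would fold the contraction field"
            )
        if self.parotid_volume_reduction < 0:
            raise ConfigError("volume reduction must be non-negative")

    @property
    def n_fractions_total(self) -> int:
        return int(round(self.total_dose_gy / self.fraction_dose_gy))


@dataclass
class DegradationParams:
    """CBCT intensity-corruption model.

    ``bias_sigma_mm`` is the Gaussian correlation length of the
    multiplicative bias (scatter is low-frequency, so it must be much
    larger than the voxel spacing); ``bias_amplitude`` its RMS as a
    fraction of the HU dynamic range; the scale/offset pair models a
    global HU miscalibration.
    """

    bias_amplitude: float = 0.05
    bias_sigma_mm: float = 50.0
    noise_sd_hu: float = 20.0
    hu_scale: float = 0.95
    hu_offset: float = -15.0
    seed: int = 0

    @classmethod
    def none(cls) -> "DegradationParams":
        return cls(bias_amplitude=0.0, noise_sd_hu=0.0, hu_scale=1.0, hu_offset=0.0)


@dataclass
class WeeklyStudy:
    """One week of the course with its generating ground truth."""

    week: int
    cbct: ImageVolume
    fractions: int
    gt_field: DisplacementField          # pull-back, CBCT frame -> pCT frame
    gt_masks: dict[str, StructureMask]   # true structures on the CBCT grid
    setup: RigidTransform


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _ellipsoid_rho(pts: np.ndarray, center, semiaxes) -> np.ndarray:
    rel = (pts - np.asarray(center)) / np.asarray(semiaxes)
    return np.sqrt(np.sum(rel * rel, axis=-1))


def _ellipsoid_indicator(
    geom: GridGeometry, center, semiaxes, ramp_mm: float | None = None
) -> np.ndarray:
    """Anti-aliased ellipsoid indicator: linear ramp in signed distance.

    ``0.5 - d / ramp`` clipped to [0, 1], where ``d ~ (rho - 1)/|grad rho|``
    approximates the signed distance to the surface.  Because the indicator
    is linear in position across a ramp wider than the voxel spacing,
    trilinear interpolation leaves the 0.5 level set in place, so
    warp-then-threshold reproduces the deformed surface without the
    systematic erosion/dilation that binary voxelisation suffers.
    """
    if ramp_mm is None:
        ramp_mm = 2.0 * float(max(geom.spacing))
    pts = geom.world_points(dtype=np.float64)
    semi = np.asarray(semiaxes, dtype=float)
    rel = (pts - np.asarray(center)) / semi
    rho = np.sqrt(np.sum(rel * rel, axis=-1))
    grad_mag = np.sqrt(np.sum((rel / semi) ** 2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(rho > 1e-9, (rho - 1.0) * rho / grad_mag, -semi.min())
    return np.clip(0.5 - d / ramp_mm, 0.0, 1.0).astype(np.float32)


def build_phantom(
    params: PhantomParams | None = None, seed: int = 0
) -> tuple[ImageVolume, dict[str, StructureMask]]:
    """Deterministically build a planning CT and its structure set.

    ``seed`` drives per-patient anatomical jitter (head size, gland size
    and position), giving a cohort a realistic spread of parotid volumes;
    seed 0 with ``jitter=0`` reproduces the nominal phantom exactly.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    j = params.jitter

    def jit(scale: float = 1.0) -> float:
        return float(1.0 + j * scale * rng.uniform(-1, 1))

    head = np.asarray(params.head_semiaxes) * [jit(0.5), jit(0.5), jit(0.5)]
    pg_semi_l = np.asarray(params.parotid_semiaxes) * [jit(), jit(), jit()]
    pg_semi_r = np.asarray(params.parotid_semiaxes) * [jit(), jit(), jit()]
    off = params.parotid_lateral_offset
    cy, cz = params.parotid_center_yz
    pg_center_l = np.array([+off * jit(0.4), cy + 3 * rng.uniform(-1, 1), cz + 3 * rng.uniform(-1, 1)])
    pg_center_r = np.array([-off * jit(0.4), cy + 3 * rng.uniform(-1, 1), cz + 3 * rng.uniform(-1, 1)])

    geom = params.geometry
    pts = geom.world_points()
    hu = params.hu

    rho_head = _ellipsoid_rho(pts, (0, 0, 0), head)
    body = rho_head <= 1.0
    values = np.full(geom.shape, hu["air"], dtype=np.float32)
    values[body] = hu["soft"]
    values[body & (rho_head >= params.fat_shell_start)] = hu["fat"]

    skull = (
        (rho_head >= params.skull_inner)
        & (rho_head <= params.skull_outer)
        & (pts[..., 2] >= params.skull_z_min)
    )
    values[skull & body] = hu["bone"]
    spine = (
        (np.hypot(pts[..., 0], pts[..., 1] - params.spine_center_y) <= params.spine_radius)
        & (pts[..., 2] <= params.spine_z_max)
        & body
    )
    values[spine] = hu["bone"]

    airway = _ellipsoid_rho(pts, params.airway_center, params.airway_semiaxes) <= 1.0
    values[airway & body] = hu["air"]

    ptv = _ellipsoid_rho(pts, params.target_center, params.target_semiaxes) <= 1.0
    pg_l = _ellipsoid_rho(pts, pg_center_l, pg_semi_l) <= 1.0
    pg_r = _ellipsoid_rho(pts, pg_center_r, pg_semi_r) <= 1.0
    if np.any(ptv & (pg_l | pg_r)):
        raise ConfigError("parotid gland overlaps the target volume")
    values[pg_l | pg_r] = hu["parotid"]

    ct = ImageVolume(geom, values, modality=Modality.CT)
    ind = {
        "BODY": _ellipsoid_indicator(geom, (0, 0, 0), head),
        "PTV": _ellipsoid_indicator(geom, params.target_center, params.target_semiaxes),
        "PG_L": _ellipsoid_indicator(geom, pg_center_l, pg_semi_l),
        "PG_R": _ellipsoid_indicator(geom, pg_center_r, pg_semi_r),
    }
    masks = {
        nm: StructureMask(geom, ind[nm] >= 0.5, name=nm, indicator=ind[nm])
        for nm in ("BODY", "PTV", "PG_L", "PG_R")
    }
    for nm in ("PTV", "PG_L", "PG_R"):
        if masks[nm].voxel_count == 0:
            raise ConfigError(f"structure {nm} is empty on the CT grid")
    return ct, masks


# ---------------------------------------------------------------------------
# ground-truth deformation
# ---------------------------------------------------------------------------


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _mask_ellipsoid(mask: StructureMask) -> tuple[np.ndarray, np.ndarray]:
    """Center and effective semi-axes of a mask, treated as a solid ellipsoid."""
    idx = np.argwhere(mask.values)
    w = idx * mask.geometry.spacing_arr + mask.geometry.origin_arr
    center = w.mean(axis=0)
    # for a solid ellipsoid the per-axis SD is a / sqrt(5)
    semi = np.sqrt(5.0) * w.std(axis=0)
    return center, semi


def anatomy_field(
    pts: np.ndarray,
    glands: list[tuple[np.ndarray, np.ndarray]],
    body_semiaxes: np.ndarray,
    *,
    volume_reduction: float,
    medial_drift_mm: float,
    neck_thinning_mm: float,
    support: float = 2.2,
) -> np.ndarray:
    """Pull-back displacement (mm) realising shrinkage + drift + thinning.

    For each gland the field contracts space radially about the *drifted*
    gland center by the linear scale ``s = (1 - reduction)^(1/3)`` (exact
    inside the gland, blended smoothly to zero at ``support`` times the
    gland semi-axes) and translates it medially.  The neck-thinning term
    compresses the body laterally below the skull.
    """
    v = np.zeros_like(pts)
    s = (1.0 - volume_reduction) ** (1.0 / 3.0)
    gland_wgt = np.zeros(pts.shape[:-1])
    for center, semi in glands:
        drift = np.array([-np.sign(center[0]) * medial_drift_mm, 0.0, 0.0])
        new_center = center + drift
        rho = _ellipsoid_rho(pts, new_center, semi)
        wgt = 1.0 - _smoothstep((rho - 1.0) / (support - 1.0))
        gland_wgt = np.maximum(gland_wgt, wgt)
        v += wgt[..., None] * ((pts - new_center) * (1.0 / s - 1.0) - drift)
    if neck_thinning_mm != 0.0:
        rho_head = _ellipsoid_rho(pts, (0, 0, 0), body_semiaxes)
        radial = _smoothstep((rho_head - 0.3) / 0.6)
        zprof = 1.0 - _smoothstep((pts[..., 2] - (-110.0)) / 130.0)
        # glands deform through their own shrinkage term only; shield them
        # from the thinning compression so the requested volume change holds
        amp = neck_thinning_mm * radial * zprof * (1.0 - gland_wgt)
        v[..., 0] += amp * pts[..., 0] / body_semiaxes[0]
        v[..., 1] += 0.5 * amp * pts[..., 1] / body_semiaxes[1]
    return v


def degrade_to_cbct(
    volume: ImageVolume, degrade: DegradationParams
) -> ImageVolume:
    """Apply CBCT-like corruption: ``v*(1+bias)*scale + offset + noise``."""
    rng = np.random.default_rng(degrade.seed)
    geom = volume.geometry
    out = volume.values.astype(np.float64)
    if degrade.bias_amplitude > 0:
        white = rng.standard_normal(geom.shape)
        sigma_vox = degrade.bias_sigma_mm / geom.spacing_arr
        # periodic smoothing keeps the bias spectrum exactly band-limited
        bias = ndimage.gaussian_filter(white, sigma_vox, mode="wrap")
        sd = bias.std()
        if sd > 0:
            bias *= degrade.bias_amplitude / sd
            out = out * (1.0 + bias)
    out = out * degrade.hu_scale + degrade.hu_offset
    if degrade.noise_sd_hu > 0:
        out = out + rng.normal(0.0, degrade.noise_sd_hu, geom.shape)
    return ImageVolume(geom, out, modality=Modality.CBCT)


def simulate_course(
    pct: ImageVolume,
    masks: dict[str, StructureMask],
    course: CourseParams,
    degrade: DegradationParams | None = None,
) -> list[WeeklyStudy]:
    """Generate the weekly CBCT series with ground-truth fields and masks.

    Anatomical change progresses linearly in the week index: week ``w`` of
    ``n`` carries the fraction ``w/n`` of the course-total shrinkage, drift
    and thinning, composed with that week's random rigid setup error.  The
    stored pull-back field maps CBCT-grid points to planning-CT points, so
    warping the planning CT through it reproduces the week's anatomy.
    """
    degrade = degrade or DegradationParams()
    for nm in ("PG_L", "PG_R", "BODY"):
        if nm not in masks:
            raise ConfigError(f"missing required mask {nm}")
        if not masks[nm].geometry.approx_equal(pct.geometry):
            raise ConfigError(f"mask {nm} is not on the planning-CT grid")
    rng = np.random.default_rng(course.seed)
    glands = [_mask_ellipsoid(masks["PG_L"]), _mask_ellipsoid(masks["PG_R"])]
    _, body_semi = _mask_ellipsoid(masks["BODY"])

    cb_geom = course.cbct_geometry
    pts = cb_geom.world_points()
    center = tuple(cb_geom.center)

    fractions = _fraction_schedule(course)
    studies: list[WeeklyStudy] = []
    for week in range(1, course.n_weeks + 1):
        prog = week / course.n_weeks
        v_def = anatomy_field(
            pts,
            glands,
            body_semi,
            volume_reduction=prog * course.parotid_volume_reduction,
            medial_drift_mm=prog * course.medial_drift_mm,
            neck_thinning_mm=prog * course.neck_thinning_mm,
        )
        setup = RigidTransform(
            tuple(rng.normal(0.0, course.setup_sigma_mm, 3)),
            tuple(np.radians(rng.normal(0.0, course.setup_sigma_deg, 3))),
            center,
        )
        mapped = setup.apply(pts + v_def)
        gt_field = DisplacementField(cb_geom, mapped - pts)
        week_ct = warp(pct, gt_field, mode="linear")
        cbct = degrade_to_cbct(
            week_ct, replace(degrade, seed=degrade.seed + 1000 * week)
        )
        gt_masks = {
            nm: warp(m, gt_field, mode="linear") for nm, m in masks.items()
        }
        studies.append(
            WeeklyStudy(
                week=week,
                cbct=cbct,
                fractions=fractions[week - 1],
                gt_field=gt_field,
                gt_masks=gt_masks,
                setup=setup,
            )
        )
    return studies


def _fraction_schedule(course: CourseParams) -> list[int]:
    """Fractions delivered each week; any shortfall lands in the final week."""
    base = [course.fractions_per_week] * course.n_weeks
    deficit = course.n_fractions_total - sum(base)
    base[-1] += deficit
    if base[-1] <= 0:
        raise ConfigError("fraction schedule leaves the final week empty")
    return base
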