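"""Rigid and gradient-based deformable registration.

The deformable stage (GFFD) compares the *normalised 3D gradient vector
fields* of the fixed and moving images rather than their intensities, which
makes it robust to the smooth, low-frequency intensity corruption typical of
cone-beam CT (scatter bias, global HU miscalibration): a constant offset
leaves gradients exactly unchanged, and normalisation makes weak soft-tissue
edges count as much as skin or bone edges.

Displacement fields use the pull-back convention on the fixed grid:
``warped_moving(x) = moving(x + v(x))`` with ``v`` in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import (
    GridGeometry,
    GridObject,
    ImageVolume,
    StructureMask,
    UsageError,
    _rewrap,
    sample_at_points,
)


class RegistrationError(RuntimeError):
    """Registration could not be performed on the given inputs."""


class InvertibilityError(RuntimeError):
    """Displacement field is not invertible (non-positive Jacobian)."""


class ConvergenceError(RuntimeError):
    """Iterative scheme failed to reach its tolerance."""


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (Euler xyz, radians) about ``center`` followed by translation.

    Maps a fixed-frame point to the corresponding moving-frame point:
    ``T(x) = R (x - c) + c + t``.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        R = self.matrix()
        return (points - c) @ R.T + c + t

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            max(abs(v) for v in self.translation) < tol
            and max(abs(v) for v in self.rotation) < tol
        )


@dataclass
class DisplacementField:
    """Dense per-voxel displacement (mm) on a fixed grid, pull-back convention."""

    geometry: GridGeometry
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != self.geometry.shape + (3,):
            raise UsageError(
                f"field shape {self.vectors.shape} does not match grid "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, geometry: GridGeometry) -> "DisplacementField":
        return cls(geometry, np.zeros(geometry.shape + (3,)))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Interpolate the field at world points (...,3); zero outside extent."""
        idx = self.geometry.world_to_index(points)
        coords = np.moveaxis(idx, -1, 0)
        out = np.empty(points.shape, dtype=np.float64)
        for a in range(3):
            out[..., a] = ndimage.map_coordinates(
                self.vectors[..., a], coords, order=1, mode="nearest"
            )
        return out

    def jacobian_determinant(self) -> np.ndarray:
        """Determinant of the Jacobian of the mapping x + v(x), per voxel."""
        sp = self.geometry.spacing
        J = np.empty(self.geometry.shape + (3, 3))
        for comp in range(3):
            grads = np.gradient(self.vectors[..., comp], *sp)
            for axis in range(3):
                J[..., comp, axis] = grads[axis]
            J[..., comp, comp] += 1.0
        return np.linalg.det(J)


def compose_rigid_into_field(
    field: DisplacementField, rigid: RigidTransform
) -> DisplacementField:
    """Total pull-back field for rigid-after-deformable warping.

    Returns ``u`` with ``x + u(x) = T(x + v(x))``: warping the moving image
    by ``u`` equals first displacing by ``v`` and then applying the rigid
    transform, so a rigid pre-alignment and a deformable refinement can be
    expressed as one field.
    """
    pts = field.geometry.world_points()
    mapped = rigid.apply(pts + field.vectors)
    return DisplacementField(field.geometry, mapped - pts)


def compose_fields(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Field of the composition: ``x + u(x) = phi_outer(phi_inner(x))``."""
    pts = inner.geometry.world_points()
    mid = pts + inner.vectors
    mapped = mid + outer.sample(mid)
    return DisplacementField(inner.geometry, mapped - pts)


def warp(
    source: GridObject, field: DisplacementField, mode: str = "linear"
) -> GridObject:
    """Pull ``source`` back through ``field``: ``out(x) = source(x + v(x))``.

    Masks are warped by linear interpolation of the {0,1} indicator followed
    by a 0.5 threshold when ``mode='linear'`` (smoother boundaries than
    nearest-neighbour), or by nearest-neighbour when requested.
    """
    pts = field.geometry.world_points(dtype=np.float64) + field.vectors
    vals = sample_at_points(source, pts, mode=mode)
    return _rewrap(source, field.geometry, vals)


def resample_through_rigid(
    source: ImageVolume, target: GridGeometry, rigid: RigidTransform
) -> ImageVolume:
    """Sample ``source`` at ``T(x)`` for every target voxel center ``x``."""
    pts = rigid.apply(target.world_points())
    vals = sample_at_points(source, pts, mode="linear")
    return ImageVolume(target, vals, modality=source.modality)


# ---------------------------------------------------------------------------
# gradient-field similarity machinery
# ---------------------------------------------------------------------------


def _smoothed(values: np.ndarray, geometry: GridGeometry, sigma_mm) -> np.ndarray:
    sigma_vox = np.asarray(sigma_mm, dtype=float) / geometry.spacing_arr
    return ndimage.gaussian_filter(values.astype(np.float32), sigma_vox)


def normalized_gradient_field(
    values: np.ndarray,
    geometry: GridGeometry,
    sigma_mm,
    eps_rel: float = 0.01,
) -> np.ndarray:
    """Unit-ish gradient vector field of a smoothed image.

    The image is Gaussian-smoothed with a per-axis physical scale
    ``sigma_mm`` (anisotropy-consistent gradient estimation), then each
    voxel's gradient is divided by ``|g| + eps`` with ``eps`` a fixed
    fraction of the 95th-percentile gradient magnitude, which makes the
    descriptor contrast-invariant while suppressing pure-noise gradients.
    """
    sm = _smoothed(values, geometry, sigma_mm)
    g = np.stack(np.gradient(sm, *geometry.spacing), axis=-1)
    mag = np.linalg.norm(g, axis=-1)
    eps = eps_rel * np.percentile(mag, 95)
    if eps <= 0:
        eps = 1e-6
    return g / (mag + eps)[..., None]


def gradient_similarity(ngf_a: np.ndarray, ngf_b: np.ndarray) -> float:
    """Mean squared difference between two normalised gradient fields."""
    d = ngf_a - ngf_b
    return float(np.mean(np.sum(d * d, axis=-1)))


def edge_overlap(a: ImageVolume, b: ImageVolume, sigma_mm: float = 2.0) -> float:
    """Pearson correlation of smoothed gradient magnitudes; 1 = identical edges."""
    ga = np.linalg.norm(
        np.stack(np.gradient(_smoothed(a.values, a.geometry, sigma_mm), *a.geometry.spacing), -1),
        axis=-1,
    ).ravel()
    gb = np.linalg.norm(
        np.stack(np.gradient(_smoothed(b.values, b.geometry, sigma_mm), *b.geometry.spacing), -1),
        axis=-1,
    ).ravel()
    return float(np.corrcoef(ga, gb)[0, 1])


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def _shrink(img: ImageVolume, factor: int) -> ImageVolume:
    if factor == 1:
        return img
    g = img.geometry
    sm = ndimage.gaussian_filter(img.values.astype(np.float32), 0.5 * factor)
    vals = sm[::factor, ::factor, ::factor]
    geom = GridGeometry(
        vals.shape,
        tuple(s * factor for s in g.spacing),
        g.origin,
    )
    return ImageVolume(geom, vals, modality=img.modality)


def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    *,
    sigma_mm: float = 3.0,
    shrink: int = 2,
    max_translation_mm: float = 15.0,
    max_rotation_deg: float = 10.0,
) -> RigidTransform:
    """Recover the rigid setup transform aligning ``moving`` to ``fixed``.

    Maximises gradient-magnitude correlation between the fixed image and the
    rigidly resampled moving image over 3 translations + 3 rotations, by a
    deterministic multi-start Powell search at a coarsened resolution
    followed by a full-resolution refinement.  Rotations are taken about the
    fixed image's physical center.
    """
    if float(np.ptp(fixed.values)) == 0 or float(np.ptp(moving.values)) == 0:
        raise RegistrationError("cannot register a constant image")
    center = tuple(fixed.geometry.center)

    def gradient_magnitude(img: ImageVolume) -> np.ndarray:
        return np.linalg.norm(
            np.stack(
                np.gradient(
                    _smoothed(img.values, img.geometry, [sigma_mm] * 3),
                    *img.geometry.spacing,
                ),
                -1,
            ),
            axis=-1,
        )

    def make_objective(fx: ImageVolume, mv: ImageVolume):
        gfix = gradient_magnitude(fx)
        gfix = gfix - gfix.mean()
        gnorm = np.sqrt(np.sum(gfix * gfix))
        # |grad(I o T)| = |grad I| o T for rigid T, so the moving image's
        # gradient-magnitude map is computed once and merely resampled per
        # candidate transform
        gmov_map = ImageVolume(
            mv.geometry, np.maximum(gradient_magnitude(mv), 0.0),
            modality=mv.modality,
        )
        pts = fx.geometry.world_points()

        def objective(p: np.ndarray) -> float:
            t = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
            idx = mv.geometry.world_to_index(t.apply(pts))
            gm = ndimage.map_coordinates(
                gmov_map.values, np.moveaxis(idx, -1, 0), order=1,
                mode="grid-constant", cval=0.0,
            )
            gm = gm - gm.mean()
            denom = gnorm * np.sqrt(np.sum(gm * gm))
            if denom == 0:
                return 0.0
            return -float(np.sum(gfix * gm) / denom)

        return objective

    tmax = max_translation_mm
    rmax = math.radians(max_rotation_deg)
    bounds = [(-tmax, tmax)] * 3 + [(-rmax, rmax)] * 3

    coarse_obj = make_objective(
        _shrink(fixed, 2 * shrink), _shrink(moving, 2 * shrink)
    )
    starts = [np.zeros(6)]
    for axis in range(3):
        for sign in (-1.0, 1.0):
            s = np.zeros(6)
            s[axis] = sign * 5.0
            starts.append(s)
    results = []
    for s in starts:
        res = optimize.minimize(
            coarse_obj, s, method="Powell",
            bounds=bounds,
            options={"xtol": 1e-2, "ftol": 1e-5, "maxiter": 20},
        )
        results.append(res)
    # lowest objective wins; exact ties broken by smallest translation norm
    results.sort(key=lambda r: (r.fun, float(np.linalg.norm(r.x[:3]))))
    best = results[0].x

    mid_obj = make_objective(_shrink(fixed, shrink), _shrink(moving, shrink))
    res = optimize.minimize(
        mid_obj, best, method="Powell",
        bounds=bounds,
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 20},
    )
    # short full-resolution polish: the half-resolution objective cannot
    # resolve rotations that move the periphery by less than a voxel
    fine_obj = make_objective(fixed, moving)
    res = optimize.minimize(
        fine_obj, res.x, method="Powell",
        bounds=bounds,
        options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": 6},
    )
    p = res.x
    rot = tuple(((r + math.pi) % (2 * math.pi)) - math.pi for r in p[3:])
    return RigidTransform(tuple(p[:3]), rot, center)


# ---------------------------------------------------------------------------
# deformable registration (GFFD)
# ---------------------------------------------------------------------------


@dataclass
class GffdParams:
    """Tuning knobs of the deformable stage.

    ``shrink_factors``/``iterations`` define the coarse-to-fine pyramid.
    Per-level sequences (one entry per pyramid level): ``gradient_sigma_mm``
    is the physical scale of gradient estimation; ``eps_kmed`` sets the
    gradient-normalisation floor as a multiple of the median gradient
    magnitude (the image's noise floor), shared between the two images so
    their descriptors stay comparable; ``fluid_sigma_mm`` is the width of
    the edge-weighted normalised-convolution smoothing of each force update
    (wide kernels extrapolate edge forces across textureless tissue).
    ``regularization_sigma_mm`` is the light elastic smoothing of the
    accumulated field.  ``denoise`` runs a non-local-means prefilter on each
    image whose estimated noise exceeds ``denoise_threshold_hu``, which
    recovers low-contrast boundaries drowned by CBCT noise.
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (80, 80, 40)
    gradient_sigma_mm: tuple[float, ...] = (3.0, 2.0, 3.0)
    eps_kmed: tuple[float, ...] = (3.0, 1.0, 8.0)
    eps_floor_rel: float = 0.01
    fluid_sigma_mm: tuple[float, ...] = (16.0, 8.0, 6.0)
    regularization_sigma_mm: float = 1.0  # elastic smoothing of the total field
    initial_step_vox: float = 1.0
    step_up: float = 1.1
    step_down: float = 0.5
    min_step_vox: float = 0.01
    max_step_vox: float = 1.0          # per-voxel cap on one update
    tol: float = 1e-9
    denoise: bool = True
    denoise_threshold_hu: float = 3.0

    def __post_init__(self) -> None:
        n = len(self.shrink_factors)
        for name in ("iterations", "gradient_sigma_mm", "eps_kmed", "fluid_sigma_mm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} needs one entry per pyramid level")
        if self.tol <= 0 or self.regularization_sigma_mm <= 0:
            raise ValueError("tolerance and regularisation must be positive")


def _upsample_field(
    vectors: np.ndarray, src: GridGeometry, dst: GridGeometry
) -> np.ndarray:
    idx = dst.world_points(dtype=np.float64)
    coords = np.moveaxis((idx - src.origin_arr) / src.spacing_arr, -1, 0)
    out = np.empty(dst.shape + (3,))
    for a in range(3):
        out[..., a] = ndimage.map_coordinates(
            vectors[..., a], coords, order=1, mode="nearest"
        )
    return out


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust white-noise estimate from slice-to-slice pseudo-residuals."""
    d = np.diff(values, axis=2)
    return float(1.4826 * np.median(np.abs(d)) / math.sqrt(2.0))


def denoise_image(volume: ImageVolume, threshold_hu: float = 3.0) -> ImageVolume:
    """Non-local-means prefilter for noisy (CBCT-like) images.

    Patch-based averaging pools evidence along coherent surfaces, which
    preserves low-contrast organ boundaries that Gaussian smoothing at the
    same noise-suppression level would wash out.  Images whose estimated
    noise is below ``threshold_hu`` are returned unchanged.
    """
    from skimage.restoration import denoise_nl_means

    vals = volume.values.astype(np.float32)
    sigma = estimate_noise_sd(vals)
    if sigma < threshold_hu:
        return volume
    den = denoise_nl_means(
        vals, patch_size=3, patch_distance=5, h=0.6 * sigma, sigma=sigma,
        fast_mode=True,
    )
    return ImageVolume(volume.geometry, den, modality=volume.modality)


def _adaptive_eps(grad: np.ndarray, kmed: float, floor_rel: float) -> float:
    mag = np.linalg.norm(grad, axis=-1)
    return float(
        max(kmed * np.median(mag), floor_rel * np.percentile(mag, 95), 1e-9)
    )


def register_gffd(
    fixed: ImageVolume,
    moving: ImageVolume,
    params: GffdParams | None = None,
) -> DisplacementField:
    """Dense deformable registration by normalised-gradient-field matching.

    At each pyramid level the loop is: warp the moving image with the
    current field; build both images' gradient vector fields, normalised
    with a shared noise-adaptive floor; score their mean squared
    difference; push the field along a bi-directional demons force (channel
    differences times the average of the fixed and warped-moving channel
    gradients, normalised per voxel so weak genuine edges move as readily
    as high-contrast ones); spread the force with an edge-weighted
    normalised convolution so textureless regions inherit motion from the
    nearest informative edges without disturbing already-matched ones;
    lightly smooth the accumulated field; and accept the iterate only if
    the similarity improved, growing the step after acceptance and
    shrinking it after rejection.  The monotone accept-or-revert rule
    guarantees the returned field scores no worse than the zero field.
    """
    params = params or GffdParams()
    if not np.all(np.isfinite(fixed.values)) or not np.all(np.isfinite(moving.values)):
        raise RegistrationError("non-finite image values")
    if params.denoise:
        fixed = denoise_image(fixed, params.denoise_threshold_hu)
        moving = denoise_image(moving, params.denoise_threshold_hu)

    field_vec: np.ndarray | None = None
    prev_geom: GridGeometry | None = None
    for level in range(len(params.shrink_factors)):
        fx = _shrink(fixed, params.shrink_factors[level])
        mv = _shrink(moving, params.shrink_factors[level])
        geom = fx.geometry
        if field_vec is None:
            field_vec = np.zeros(geom.shape + (3,))
        else:
            field_vec = _upsample_field(field_vec, prev_geom, geom)
        field_vec = _gffd_level(fx, mv, field_vec, params, level)
        prev_geom = geom

    if prev_geom is None:
        raise RegistrationError("empty pyramid")
    if not prev_geom.approx_equal(fixed.geometry):
        field_vec = _upsample_field(field_vec, prev_geom, fixed.geometry)
    return DisplacementField(fixed.geometry, field_vec)


def gffd_similarity(
    fixed: ImageVolume,
    moving: ImageVolume,
    field: DisplacementField,
    params: GffdParams | None = None,
) -> float:
    """Score a field with the finest-level similarity ``register_gffd`` uses.

    Lets callers verify the monotonicity guarantee (the returned field
    scores no worse than the zero field) without re-running registration.
    """
    params = params or GffdParams()
    geom = fixed.geometry
    sp = geom.spacing_arr
    level = len(params.shrink_factors) - 1
    sigma_mm = [params.gradient_sigma_mm[level]] * 3
    pts = geom.world_points(dtype=np.float64)

    def grad_of(values: np.ndarray) -> np.ndarray:
        return np.stack(np.gradient(_smoothed(values, geom, sigma_mm), *sp), -1)

    g_fix = grad_of(fixed.values)
    g_mov = grad_of(sample_at_points(moving, pts, mode="linear"))
    kmed = params.eps_kmed[level]
    eps = max(
        _adaptive_eps(g_fix, kmed, params.eps_floor_rel),
        _adaptive_eps(g_mov, kmed, params.eps_floor_rel),
    )

    def normalize(g: np.ndarray) -> np.ndarray:
        mag = np.linalg.norm(g, axis=-1)
        return g / (mag + eps)[..., None]

    warped = grad_of(sample_at_points(moving, pts + field.vectors, mode="linear"))
    return gradient_similarity(normalize(g_fix), normalize(warped))


def _gffd_level(
    fixed: ImageVolume,
    moving: ImageVolume,
    field_vec: np.ndarray,
    params: GffdParams,
    level: int,
) -> np.ndarray:
    geom = fixed.geometry
    sp = geom.spacing_arr
    sigma_mm = [params.gradient_sigma_mm[level]] * 3
    fluid_sigma_vox = params.fluid_sigma_mm[level] / sp
    # at least half a voxel of elastic smoothing keeps coarse-grid fields
    # well-conditioned for fixed-point inversion
    reg_sigma_vox = np.maximum(params.regularization_sigma_mm / sp, 0.5)
    n_iter = params.iterations[level]
    min_spacing = float(sp.min())
    pts = geom.world_points(dtype=np.float64)

    def grad_of(values: np.ndarray) -> np.ndarray:
        return np.stack(
            np.gradient(_smoothed(values, geom, sigma_mm), *sp), -1
        )

    g_fix = grad_of(fixed.values)
    g_mov0 = grad_of(sample_at_points(moving, pts, mode="linear"))
    # shared floor keeps the two descriptors comparable; taking the max of
    # the per-image estimates lets the noisier image set the suppression
    kmed = params.eps_kmed[level]
    eps = max(
        _adaptive_eps(g_fix, kmed, params.eps_floor_rel),
        _adaptive_eps(g_mov0, kmed, params.eps_floor_rel),
    )

    def normalize(g: np.ndarray) -> np.ndarray:
        mag = np.linalg.norm(g, axis=-1)
        return g / (mag + eps)[..., None]

    ngf_fix = normalize(g_fix)
    grad_fix = [np.stack(np.gradient(ngf_fix[..., c], *sp), -1) for c in range(3)]

    def warped_ngf(vec: np.ndarray) -> np.ndarray:
        return normalize(grad_of(sample_at_points(moving, pts + vec, mode="linear")))

    ngf_mov = warped_ngf(field_vec)
    sim = gradient_similarity(ngf_fix, ngf_mov)
    if not np.isfinite(sim):
        raise RegistrationError("non-finite similarity")
    step = params.initial_step_vox

    k2 = float(np.mean(sp)) ** 2
    for _ in range(n_iter):
        force = np.zeros_like(field_vec)
        weight = np.zeros(geom.shape)
        for c in range(3):
            diff = ngf_fix[..., c] - ngf_mov[..., c]
            grad_mov_c = np.stack(np.gradient(ngf_mov[..., c], *sp), -1)
            # bi-directional: average of fixed-image and moving-image force,
            # with the demons per-voxel normalisation so weak but genuine
            # edges take steps comparable to high-contrast ones
            J = 0.5 * (grad_fix[c] + grad_mov_c)
            jj = np.sum(J * J, axis=-1)
            denom = jj + diff * diff / k2
            scale = np.divide(
                diff, denom, out=np.zeros_like(diff), where=denom > 1e-12
            )
            force += scale[..., None] * J
            weight += jj
        # edge-weighted normalised convolution: flat regions take their
        # update from the nearest informative edges, matched edges stay put
        num = np.stack(
            [
                ndimage.gaussian_filter(force[..., a] * weight, fluid_sigma_vox)
                for a in range(3)
            ],
            -1,
        )
        den = ndimage.gaussian_filter(weight, fluid_sigma_vox) + 0.1 * weight.mean()
        update = num / den[..., None] * step
        cap = params.max_step_vox * min_spacing
        mag = np.linalg.norm(update, axis=-1)
        over = mag > cap
        if np.any(over):
            update[over] *= (cap / mag[over])[..., None]
        candidate = field_vec + update
        # light elastic smoothing of the accumulated field keeps it regular
        # without eroding displacement built up over many iterations
        for a in range(3):
            candidate[..., a] = ndimage.gaussian_filter(
                candidate[..., a], reg_sigma_vox
            )
        ngf_cand = warped_ngf(candidate)
        cand_sim = gradient_similarity(ngf_fix, ngf_cand)
        if cand_sim < sim - params.tol:
            field_vec, ngf_mov, sim = candidate, ngf_cand, cand_sim
            step *= params.step_up
        else:
            step *= params.step_down
            if step < params.min_step_vox:
                break
    return field_vec


# ---------------------------------------------------------------------------
# field inversion
# ---------------------------------------------------------------------------


def invert_field(
    field: DisplacementField,
    tol: float = 0.05,
    max_iter: int = 50,
    target: GridGeometry | None = None,
    check_jacobian: bool = True,
) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Solves ``v_inv(x) = -v(x + v_inv(x))`` so that the composed mapping is
    the identity.  ``tol`` is the maximum residual update in mm.  The
    inverse may be produced on a different ``target`` grid (e.g. the
    planning grid for a field estimated on the weekly grid).
    """
    if check_jacobian:
        det = field.jacobian_determinant()
        if det.min() <= 0:
            raise InvertibilityError(
                f"field folds: min Jacobian determinant {det.min():.4f}"
            )
    geom = target or field.geometry
    pts = geom.world_points(dtype=np.float64)
    inv = np.zeros_like(pts)
    alpha = 1.0
    prev_delta = np.inf
    for _ in range(max_iter):
        proposal = -field.sample(pts + inv)
        delta = np.abs(proposal - inv).max()
        # damp when the update stops contracting (oscillation or a 2-cycle
        # where the field's local Lipschitz constant approaches 1)
        if delta > 0.95 * prev_delta and alpha > 0.2:
            alpha *= 0.5
        inv = inv + alpha * (proposal - inv)
        prev_delta = delta
        if delta * alpha < tol:
            return DisplacementField(geom, inv)
    raise ConvergenceError(
        f"field inversion did not reach tol={tol} mm in {max_iter} iterations"
    )


def composition_residual(
    forward: DisplacementField, inverse: DisplacementField
) -> np.ndarray:
    """Magnitude of ``phi(phi_inv(x)) - x`` per voxel of the inverse's grid."""
    pts = inverse.geometry.world_points(dtype=np.float64)
    mid = pts + inverse.vectors
    back = mid + forward.sample(mid)
    return np.linalg.norm(back - pts, axis=-1)
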