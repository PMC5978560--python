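"""Surrogate photon dose engine.

A deliberately simple stand-in for a clinical treatment planning system,
keeping the properties the accumulation pipeline exercises: density
dependence through radiological depth, geometric sensitivity through
field edges, and linearity in beam weight.  Each beam is a parallel
rectangular field in the axial plane; along every ray the radiological
depth is the line integral of relative electron density, the depth dose
builds up linearly to ``d_max`` and decays exponentially with coefficient
``mu`` beyond it, and the lateral profile is a rectangle convolved with a
Gaussian penumbra (error-function edges).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .core import DoseFrame, DoseGrid, GridGeometry, ImageVolume, Modality, StructureMask, UsageError


class NormalizationError(RuntimeError):
    """Prescription cannot be normalised (zero dose in the target)."""


@dataclass(frozen=True)
class BeamSpec:
    """One parallel beam in the axial plane.

    ``gantry_deg`` = 0 sends the beam along +y; angles increase clockwise
    when viewed from +z.  ``half_width_mm`` are the field half-apertures
    (lateral, longitudinal); depth-dose shape is ``d_max_mm`` build-up then
    exponential attenuation ``mu_per_mm``.
    """

    gantry_deg: float
    isocenter_mm: tuple[float, float, float]
    half_width_mm: tuple[float, float] = (30.0, 30.0)
    weight: float = 1.0
    d_max_mm: float = 15.0
    mu_per_mm: float = 0.005
    penumbra_sigma_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("beam weight must be non-negative")
        if self.mu_per_mm <= 0 or self.d_max_mm <= 0:
            raise ValueError("depth-dose parameters must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """(propagation direction, lateral unit vector) in world coords."""
        th = math.radians(self.gantry_deg)
        d = np.array([math.sin(th), math.cos(th), 0.0])
        u = np.array([math.cos(th), -math.sin(th), 0.0])
        return d, u


@dataclass
class PlanSpec:
    """Beam set plus prescription; normalisation sets PTV mean = prescription."""

    beams: list[BeamSpec]
    prescription_gy: float = 70.0
    n_fractions: int = 35

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("a plan needs at least one beam")
        if self.prescription_gy <= 0 or self.n_fractions <= 0:
            raise ValueError("prescription and fraction count must be positive")

    @property
    def fraction_dose_gy(self) -> float:
        return self.prescription_gy / self.n_fractions

    def to_json(self, path: str | Path) -> None:
        payload = {
            "prescription_gy": self.prescription_gy,
            "n_fractions": self.n_fractions,
            "beams": [
                {
                    "gantry_deg": b.gantry_deg,
                    "isocenter_mm": list(b.isocenter_mm),
                    "half_width_mm": list(b.half_width_mm),
                    "weight": b.weight,
                    "d_max_mm": b.d_max_mm,
                    "mu_per_mm": b.mu_per_mm,
                    "penumbra_sigma_mm": b.penumbra_sigma_mm,
                }
                for b in self.beams
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanSpec":
        payload = json.loads(Path(path).read_text())
        beams = [
            BeamSpec(
                gantry_deg=b["gantry_deg"],
                isocenter_mm=tuple(b["isocenter_mm"]),
                half_width_mm=tuple(b["half_width_mm"]),
                weight=b.get("weight", 1.0),
                d_max_mm=b.get("d_max_mm", 15.0),
                mu_per_mm=b.get("mu_per_mm", 0.005),
                penumbra_sigma_mm=b.get("penumbra_sigma_mm", 3.0),
            )
            for b in payload["beams"]
        ]
        return cls(beams, payload["prescription_gy"], payload["n_fractions"])


def make_axial_plan(
    ptv: StructureMask,
    n_beams: int = 9,
    prescription_gy: float = 70.0,
    n_fractions: int = 35,
    margin_mm: float = 6.0,
    **beam_kwargs,
) -> PlanSpec:
    """Equi-spaced coplanar beams aimed at the PTV center of mass.

    Field half-widths cover the PTV's largest in-plane and longitudinal
    radius plus ``margin_mm``.
    """
    iso = ptv.com()
    idx = np.argwhere(ptv.values)
    w = idx * ptv.geometry.spacing_arr + ptv.geometry.origin_arr
    lateral = float(np.max(np.linalg.norm(w[:, :2] - iso[:2], axis=1))) + margin_mm
    longitudinal = float(np.max(np.abs(w[:, 2] - iso[2]))) + margin_mm
    beams = [
        BeamSpec(
            gantry_deg=i * 360.0 / n_beams,
            isocenter_mm=tuple(iso),
            half_width_mm=(lateral, longitudinal),
            **beam_kwargs,
        )
        for i in range(n_beams)
    ]
    return PlanSpec(beams, prescription_gy, n_fractions)


def _sample_density(density: ImageVolume, pts: np.ndarray) -> np.ndarray:
    idx = density.geometry.world_to_index(pts)
    return ndimage.map_coordinates(
        density.values, np.moveaxis(idx, -1, 0), order=1, mode="grid-constant", cval=0.0
    )


def beam_dose(
    density: ImageVolume, beam: BeamSpec, step_mm: float | None = None
) -> np.ndarray:
    """Unweighted dose of one beam on the density grid (arbitrary units)."""
    if density.modality != Modality.DENSITY:
        raise UsageError("dose engine expects a DENSITY volume")
    geom = density.geometry
    d, u = beam.axes()
    iso = np.asarray(beam.isocenter_mm)
    step = step_mm or float(min(geom.spacing))

    # beam-aligned grid (u: lateral, v: depth, z) covering the volume
    corners = np.array(
        [
            [geom.origin[0] + a * geom.extent[0], geom.origin[1] + b * geom.extent[1]]
            for a in (0, 1)
            for b in (0, 1)
        ]
    )
    rel = corners - iso[:2]
    u_rng = rel @ u[:2]
    v_rng = rel @ d[:2]
    pad = 2 * step
    u_ax = np.arange(u_rng.min() - pad, u_rng.max() + pad, step)
    v_ax = np.arange(v_rng.min() - pad, v_rng.max() + pad, step)
    z_ax = geom.origin[2] + np.arange(geom.shape[2]) * geom.spacing[2]

    pts = (
        iso[None, None, None, :]
        + u_ax[:, None, None, None] * u[None, None, None, :]
        + v_ax[None, :, None, None] * d[None, None, None, :]
    )
    pts = np.broadcast_to(pts, (len(u_ax), len(v_ax), len(z_ax), 3)).copy()
    pts[..., 2] = z_ax[None, None, :]

    rho = _sample_density(density, pts)
    # radiological depth at cell centers along the propagation axis
    d_rad = (np.cumsum(rho, axis=1) - 0.5 * rho) * step

    dd = np.where(
        d_rad < beam.d_max_mm,
        d_rad / beam.d_max_mm,
        np.exp(-beam.mu_per_mm * np.maximum(d_rad - beam.d_max_mm, 0.0)),
    )
    s2 = beam.penumbra_sigma_mm * math.sqrt(2.0)
    hw_u, hw_z = beam.half_width_mm
    prof_u = 0.5 * (erf((hw_u + u_ax) / s2) + erf((hw_u - u_ax) / s2))
    z_rel = z_ax - iso[2]
    prof_z = 0.5 * (erf((hw_z + z_rel) / s2) + erf((hw_z - z_rel) / s2))
    beam_grid = dd * prof_u[:, None, None] * prof_z[None, None, :]

    # pull the beam-grid dose back onto the density grid
    wpts = geom.world_points()
    rel = wpts[..., :2] - iso[:2]
    coords = np.stack(
        [
            (rel @ u[:2] - u_ax[0]) / step,
            (rel @ d[:2] - v_ax[0]) / step,
            (wpts[..., 2] - z_ax[0]) / geom.spacing[2],
        ]
    )
    out = ndimage.map_coordinates(
        beam_grid, coords, order=1, mode="grid-constant", cval=0.0
    )
    return out


def compute_raw_dose(
    density: ImageVolume, plan: PlanSpec, step_mm: float | None = None
) -> DoseGrid:
    """Weight-summed, unnormalised plan dose on the density grid."""
    total = np.zeros(density.geometry.shape)
    for beam in plan.beams:
        if beam.weight == 0.0:
            continue
        total += beam.weight * beam_dose(density, beam, step_mm=step_mm)
    return DoseGrid(density.geometry, total, frame=DoseFrame.PLANNING)


def compute_dose(
    density: ImageVolume,
    plan: PlanSpec,
    ptv: StructureMask | None = None,
    norm_factor: float | None = None,
    frame: DoseFrame = DoseFrame.PLANNING,
    step_mm: float | None = None,
) -> tuple[DoseGrid, float]:
    """Plan dose normalised so that the PTV mean equals the prescription.

    Either ``ptv`` (normalisation computed here, the planning case) or a
    frozen ``norm_factor`` from a previous planning run (the weekly case —
    reapplying the original plan to new anatomy without renormalising, so
    anatomical change shows up in the delivered dose) must be given.
    Returns the dose and the factor actually applied.
    """
    raw = compute_raw_dose(density, plan, step_mm=step_mm)
    if norm_factor is None:
        if ptv is None:
            raise UsageError("need a PTV mask or a frozen normalisation factor")
        if not ptv.geometry.approx_equal(density.geometry):
            raise UsageError("PTV mask is not on the density grid")
        if ptv.voxel_count == 0:
            raise NormalizationError("empty PTV")
        mean = float(raw.values[ptv.values].mean())
        if mean <= 0:
            raise NormalizationError("PTV receives no dose; cannot normalise")
        norm_factor = plan.prescription_gy / mean
    dose = DoseGrid(density.geometry, raw.values * norm_factor, frame=frame)
    return dose, norm_factor
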