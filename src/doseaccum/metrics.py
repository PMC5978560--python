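"""Dose warping, accumulation and dose-volume-histogram endpoints.

Weekly doses computed on the CBCT-day anatomy are carried back to the
planning frame through the inverse registration fields and summed; parotid
sparing is then summarised by the five standard DVH endpoints: V20/V30/V40
(the percentage of the gland receiving at least 20/30/40 Gy), D50 (the dose
received by at least half the gland) and Dmean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DoseFrame, DoseGrid, StructureMask, UsageError
from .registration import DisplacementField, warp


class StructureError(ValueError):
    """Metric requested on an empty structure."""


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving >= each edge dose."""

    edges_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.edges_gy.shape != self.volume_fraction.shape:
            raise ValueError("edges and values must align")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


@dataclass
class DoseMetrics:
    """The five parotid endpoints plus the structure volume."""

    v20_pct: float
    v30_pct: float
    v40_pct: float
    d50_gy: float
    dmean_gy: float
    volume_cc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "V20": self.v20_pct,
            "V30": self.v30_pct,
            "V40": self.v40_pct,
            "D50": self.d50_gy,
            "Dmean": self.dmean_gy,
            "volume_cc": self.volume_cc,
        }


def warp_dose(
    weekly_dose: DoseGrid,
    inverse_field: DisplacementField,
    fractions: int,
    n_fractions_total: int,
) -> DoseGrid:
    """Map a weekly dose into the planning frame and scale to its fractions.

    ``inverse_field`` lives on the planning grid and maps planning-frame
    points to the weekly frame (the inverse of the registration field).
    The weekly dose represents the *whole course* delivered to that week's
    anatomy, so the warped dose is scaled by ``fractions /
    n_fractions_total`` — the share of the course the week actually
    delivered.
    """
    if weekly_dose.frame != DoseFrame.WEEKLY:
        raise UsageError("warp_dose expects a dose in the WEEKLY frame")
    if fractions < 0 or n_fractions_total <= 0 or fractions > n_fractions_total:
        raise UsageError("invalid fraction counts")
    warped = warp(weekly_dose, inverse_field, mode="linear")
    scale = fractions / n_fractions_total
    return DoseGrid(
        warped.geometry, warped.values * scale, frame=DoseFrame.PLANNING
    )


def accumulate(weekly_doses: list[DoseGrid]) -> DoseGrid:
    """Voxel-wise sum of planning-frame weekly doses."""
    if not weekly_doses:
        raise UsageError("nothing to accumulate")
    ref = weekly_doses[0]
    total = np.zeros(ref.geometry.shape)
    for d in weekly_doses:
        if d.frame != DoseFrame.PLANNING:
            raise UsageError("all doses must be in the planning frame")
        if not d.geometry.approx_equal(ref.geometry):
            raise UsageError("doses live on different grids")
        total += d.values
    return DoseGrid(ref.geometry, total, frame=DoseFrame.PLANNING)


def _masked_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if not mask.geometry.approx_equal(dose.geometry):
        raise UsageError("mask is not on the dose grid")
    if mask.voxel_count == 0:
        raise StructureError(f"empty structure {mask.name!r}")
    return dose.values[mask.values]


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.1
) -> DVHCurve:
    """Cumulative DVH with uniform bins from 0 Gy to just past the maximum."""
    if bin_width_gy <= 0:
        raise UsageError("bin width must be positive")
    d = _masked_doses(dose, mask)
    n_bins = int(math.floor(d.max() / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    sorted_d = np.sort(d)
    # fraction receiving >= edge: count of voxels at or above each edge
    below = np.searchsorted(sorted_d, edges, side="left")
    frac = (d.size - below) / d.size
    return DVHCurve(edges, frac)


def d50_from_sorted(sorted_doses: np.ndarray) -> float:
    """Maximal dose received by at least half the voxels (order statistic)."""
    n = sorted_doses.size
    return float(sorted_doses[n - math.ceil(0.5 * n)])


def compute_metrics(dose: DoseGrid, mask: StructureMask) -> DoseMetrics:
    """Voxel-counting DVH endpoints (>= convention, no partial volumes).

    Vx counts voxels receiving at least x Gy; D50 comes from the order
    statistics of the voxel doses (ties resolved toward the higher dose),
    not from an interpolated histogram.
    """
    d = _masked_doses(dose, mask)
    n = d.size
    sorted_d = np.sort(d)

    def vx(threshold: float) -> float:
        return 100.0 * float(np.count_nonzero(d >= threshold)) / n

    return DoseMetrics(
        v20_pct=vx(20.0),
        v30_pct=vx(30.0),
        v40_pct=vx(40.0),
        d50_gy=d50_from_sorted(sorted_d),
        dmean_gy=float(d.mean()),
        volume_cc=mask.volume_cc,
    )
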