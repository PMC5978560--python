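"""Modified-CBCT construction and contour propagation.

The weekly CBCT has the patient's current anatomy but unreliable HU; the
planning CT has trustworthy HU but stale anatomy.  The modified CBCT
(mCBCT) combines the two: the planning CT is pulled through the deformable
registration field onto the CBCT grid, so the result has CBCT-day anatomy
with calibrated planning-CT intensities and can support dose calculation.
"""

from __future__ import annotations

import numpy as np

from .core import (
    DoseFrame,
    GridGeometry,
    ImageVolume,
    Modality,
    StructureMask,
    UsageError,
)
from .registration import DisplacementField, composition_residual, warp


class PropagationError(RuntimeError):
    """Forward/inverse field pair is inconsistent beyond tolerance."""


def build_mcbct(
    pct: ImageVolume, cbct: ImageVolume, field: DisplacementField
) -> ImageVolume:
    """Warp the planning CT through ``field`` onto the CBCT grid.

    ``field`` must be the pull-back field on the CBCT grid (it registers
    the planning CT, as moving image, to the CBCT).  Linear interpolation
    bounds the output by the planning CT's intensity range.
    """
    if not field.geometry.approx_equal(cbct.geometry):
        raise UsageError("field is not defined on the CBCT grid")
    out = warp(pct, field, mode="linear")
    return ImageVolume(out.geometry, out.values, modality=Modality.MCBCT)


def dice_coefficient(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|) of two masks on the same grid."""
    if not a.geometry.approx_equal(b.geometry):
        raise UsageError("masks live on different grids")
    inter = np.logical_and(a.values, b.values).sum()
    total = int(a.values.sum()) + int(b.values.sum())
    if total == 0:
        return 1.0
    return 2.0 * float(inter) / float(total)


def propagate_contours(
    masks_on_pct: dict[str, StructureMask],
    forward_field: DisplacementField,
    inverse_field: DisplacementField | None = None,
    *,
    max_residual_vox: float = 0.5,
) -> dict[str, StructureMask]:
    """Map planning-CT contours onto the CBCT grid through the forward field.

    When the inverse field is supplied the pair's consistency is verified
    first: the mean magnitude of ``phi(phi_inv(x)) - x`` must stay below
    ``max_residual_vox`` voxels, otherwise the propagation is refused.
    Masks are warped by linear interpolation of the indicator with a 0.5
    threshold; structures that come out empty are reported.
    """
    if inverse_field is not None:
        res = composition_residual(forward_field, inverse_field)
        vox = float(np.min(forward_field.geometry.spacing))
        if res.mean() / vox > max_residual_vox:
            raise PropagationError(
                f"forward/inverse composition residual {res.mean():.2f} mm "
                f"exceeds {max_residual_vox} voxels"
            )
    out: dict[str, StructureMask] = {}
    for name, mask in masks_on_pct.items():
        propagated = warp(mask, forward_field, mode="linear")
        out[name] = StructureMask(propagated.geometry, propagated.values, name=name)
    return out


def empty_structures(masks: dict[str, StructureMask]) -> list[str]:
    """Names of masks that lost all support (flagged, not fatal)."""
    return [name for name, m in masks.items() if m.voxel_count == 0]


# HU -> relative electron density calibration knots: air, water, dense bone
_HU_KNOTS = np.array([-1000.0, 0.0, 1000.0])
_RHO_KNOTS = np.array([0.0, 1.0, 1.6])


def hu_to_density(volume: ImageVolume) -> ImageVolume:
    """Piecewise-linear HU to relative-density conversion.

    Calibration points: -1000 HU (air) -> 0.0, 0 HU (water) -> 1.0,
    +1000 HU (dense bone) -> 1.6; linear between knots, constant above the
    last knot, clipped at zero below.
    """
    rho = np.interp(volume.values, _HU_KNOTS, _RHO_KNOTS)
    rho = np.clip(rho, 0.0, None)
    return ImageVolume(volume.geometry, rho, modality=Modality.DENSITY)
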