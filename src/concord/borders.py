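"""Six-direction border extents and discrepancies in patient coordinates.

Each structure gets one scalar extent per directed patient axis (left, right,
anterior, posterior, superior, inferior under LPS), taken at the centers of
its outermost voxels. A discrepancy compares an observer's extents against a
reference consensus with an outward-positive sign convention: a positive
value always means the observer's contour reaches farther out than the
reference in that direction, whether the axis points toward increasing or
decreasing coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks_io import MaskGrid, ObserverSet

__all__ = [
    "DIRECTIONS",
    "BorderExtents",
    "BorderDiscrepancy",
    "EmptyStructureError",
    "directional_extents",
    "border_discrepancies",
    "direction_variation_summary",
]

DIRECTIONS = ("left", "right", "anterior", "posterior", "superior", "inferior")


class EmptyStructureError(ValueError):
    """Extents requested for a mask with no 1-voxels."""


@dataclass(frozen=True)
class BorderExtents:
    """Outermost voxel-center LPS coordinates (mm) along each directed axis.

    Under LPS, left is the maximum x, right the minimum x, posterior the
    maximum y, anterior the minimum y, superior the maximum z and inferior
    the minimum z.
    """

    left_mm: float
    right_mm: float
    anterior_mm: float
    posterior_mm: float
    superior_mm: float
    inferior_mm: float


@dataclass(frozen=True)
class BorderDiscrepancy:
    """Outward-positive signed border differences (mm) vs a reference.

    ``missing`` is set (and the six values are NaN) when the observer's mask
    was empty.
    """

    observer_label: str
    reference_label: str
    left: float
    right: float
    anterior: float
    posterior: float
    superior: float
    inferior: float
    missing: bool = False

    def as_dict(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in DIRECTIONS}


def directional_extents(mask: MaskGrid) -> BorderExtents:
    """Extremes of 1-voxel center coordinates along the six LPS directions."""
    idx = np.nonzero(mask.voxels)
    if idx[0].size == 0:
        raise EmptyStructureError("cannot compute extents of an empty mask")
    lo = [float(mask.origin[k] + idx[k].min() * mask.spacing[k]) for k in range(3)]
    hi = [float(mask.origin[k] + idx[k].max() * mask.spacing[k]) for k in range(3)]
    return BorderExtents(
        left_mm=hi[0],
        right_mm=lo[0],
        posterior_mm=hi[1],
        anterior_mm=lo[1],
        superior_mm=hi[2],
        inferior_mm=lo[2],
    )


def border_discrepancies(
    obs: ObserverSet, reference: MaskGrid, reference_label: str = "consensus"
) -> list[BorderDiscrepancy]:
    """Outward-positive six-direction differences of each observer vs the
    reference.

    left/posterior/superior compare coordinate maxima (observer − reference);
    right/anterior/inferior compare minima with the sign flipped, so that a
    positive number always means the observer extends beyond the reference.
    Empty observer masks are reported as missing, not fatal.
    """
    if not reference.same_grid(obs.grid):
        raise ValueError("reference mask is not on the panel grid")
    ref = directional_extents(reference)
    out: list[BorderDiscrepancy] = []
    for lbl, mask in zip(obs.observer_labels, obs.masks):
        try:
            ext = directional_extents(mask)
        except EmptyStructureError:
            out.append(
                BorderDiscrepancy(
                    lbl, reference_label, *([float("nan")] * 6), missing=True
                )
            )
            continue
        out.append(
            BorderDiscrepancy(
                observer_label=lbl,
                reference_label=reference_label,
                left=ext.left_mm - ref.left_mm,
                right=ref.right_mm - ext.right_mm,
                anterior=ref.anterior_mm - ext.anterior_mm,
                posterior=ext.posterior_mm - ref.posterior_mm,
                superior=ext.superior_mm - ref.superior_mm,
                inferior=ref.inferior_mm - ext.inferior_mm,
            )
        )
    return out


def direction_variation_summary(
    discrepancies: list[BorderDiscrepancy],
) -> pd.DataFrame:
    """Per-direction spread of discrepancies, ranked by SD (descending).

    Returns a DataFrame indexed by direction with columns ``range_mm``,
    ``sd_mm`` (sample SD), ``mean_abs_mm`` and ``rank`` (1 = most variable).
    Missing observers are excluded; at least two valid observers required.
    """
    valid = [d for d in discrepancies if not d.missing]
    if len(valid) < 2:
        raise ValueError("need at least 2 observers with valid discrepancies")
    table = pd.DataFrame([d.as_dict() for d in valid])
    out = pd.DataFrame(
        {
            "range_mm": table.max() - table.min(),
            "sd_mm": table.std(ddof=1),
            "mean_abs_mm": table.abs().mean(),
        }
    )
    out["rank"] = out["sd_mm"].rank(ascending=False, method="min").astype(int)
    out.index.name = "direction"
    return out
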