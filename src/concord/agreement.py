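"""Panel agreement statistics: volumes, apparent agreement, generalized
(Fleiss) kappa with significance, and the generalized conformity index.

All statistics are voxel-aligned: every observer rates every voxel of a
declared analysis region as in/out of the structure, and agreement is
computed over those binary ratings. The choice of region matters — adding
background voxels where everyone agrees "out" inflates apparent agreement
and shifts kappa through the marginals — so the region is an explicit input
and is carried in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import stats

from .masks_io import MaskGrid, ObserverSet

__all__ = [
    "VolumeStats",
    "KappaResult",
    "ConformityResult",
    "DegenerateAgreementError",
    "EmptyRegionError",
    "volume_stats",
    "analysis_region",
    "apparent_agreement_map",
    "agreed_volume_at_cl",
    "fleiss_kappa",
    "classify_kappa",
    "classify_conformity",
    "generalized_ci",
]

KAPPA_SCALE = (
    (0.0, "no"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (float("inf"), "excellent"),
)


class DegenerateAgreementError(ValueError):
    """All ratings fall in one category; chance agreement is 1 and kappa undefined."""


class EmptyRegionError(ValueError):
    """The requested analysis region contains no voxels."""


@dataclass(frozen=True)
class VolumeStats:
    """Per-case volume summary across observers (cm³, sample SD)."""

    per_observer_cm3: tuple[float, ...]
    min_cm3: float
    max_cm3: float
    mean_cm3: float
    sd_cm3: float
    union_cm3: float
    intersection_cm3: float


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected multi-rater agreement over an analysis region.

    kappa = (apparent − chance) / (1 − chance); the z statistic and two-sided
    p-value come from the Fleiss large-sample variance under the null of
    chance-only agreement. ``region_voxels`` records the region size so the
    statistic is reproducible.
    """

    apparent_agreement: float
    chance_agreement: float
    kappa: float
    z_statistic: float
    p_value: float
    region_voxels: int
    label: str


@dataclass(frozen=True)
class ConformityResult:
    """Generalized conformity index: Σ_pairs |Ai∩Aj| / Σ_pairs |Ai∪Aj|."""

    ci_gen: float
    pairwise_intersections_cm3: float
    pairwise_unions_cm3: float
    label: str


def volume_stats(obs: ObserverSet) -> VolumeStats:
    """Min/max/mean/SD of observer volumes plus union and intersection, cm³."""
    vols = np.array([m.volume_cm3 for m in obs.masks])
    counts = obs.rating_counts()
    vv = obs.grid.voxel_volume_mm3 / 1000.0
    return VolumeStats(
        per_observer_cm3=tuple(float(v) for v in vols),
        min_cm3=float(vols.min()),
        max_cm3=float(vols.max()),
        mean_cm3=float(vols.mean()),
        sd_cm3=float(vols.std(ddof=1)),
        union_cm3=float((counts > 0).sum()) * vv,
        intersection_cm3=float((counts == obs.n_observers).sum()) * vv,
    )


def analysis_region(obs: ObserverSet, margin_mm: float = 10.0) -> np.ndarray:
    """Boolean region mask: union bounding box expanded by ``margin_mm``.

    The margin is converted to whole voxels per axis (rounded up) and the
    box is clipped to the lattice. Raises EmptyRegionError when no observer
    marked any voxel.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    union = obs.rating_counts() > 0
    if not union.any():
        raise EmptyRegionError("union of observer masks is empty")
    region = np.zeros(union.shape, dtype=bool)
    idx = np.nonzero(union)
    slices = []
    for k in range(3):
        pad = ceil(margin_mm / obs.grid.spacing[k] - 1e-9) if margin_mm > 0 else 0
        lo = max(int(idx[k].min()) - pad, 0)
        hi = min(int(idx[k].max()) + pad + 1, union.shape[k])
        slices.append(slice(lo, hi))
    region[tuple(slices)] = True
    return region


def apparent_agreement_map(obs: ObserverSet) -> np.ndarray:
    """Per-voxel fraction of observers marking the voxel, in {0, 1/R, ..., 1}."""
    return obs.rating_counts() / float(obs.n_observers)


def agreed_volume_at_cl(obs: ObserverSet, cl: float) -> MaskGrid:
    """Voxels rated in by at least a fraction ``cl`` of observers.

    cl = 0 selects strictly positive fractions so the endpoint identities
    hold exactly: cl = 0 gives the union and cl = 1 the intersection.
    """
    if not 0.0 <= cl <= 1.0:
        raise ValueError(f"cl must lie in [0, 1], got {cl}")
    counts = obs.rating_counts()
    # smallest observer count whose fraction reaches cl; cl = 0 -> count >= 1
    k = max(1, ceil(cl * obs.n_observers - 1e-9))
    return obs.grid.with_voxels((counts >= k).astype(np.uint8))


def fleiss_kappa(obs: ObserverSet, region: np.ndarray) -> KappaResult:
    """Generalized Fleiss kappa over the voxels of ``region`` (two categories).

    Per voxel i with n_i1 of R observers rating "in":
    P_i = [n_i1(n_i1−1) + n_i0(n_i0−1)] / [R(R−1)]; apparent agreement is the
    mean P_i; chance agreement Σ_c p̄_c² uses marginal category proportions
    pooled over raters; kappa = (P̄ − P̄_e)/(1 − P̄_e). Significance is the
    two-sided normal test with the Fleiss large-sample variance.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != obs.grid.shape:
        raise ValueError("region shape does not match the panel grid")
    if not region.any():
        raise EmptyRegionError("analysis region is empty")
    R = obs.n_observers
    n1 = obs.rating_counts()[region].astype(np.float64)
    n0 = R - n1
    N = n1.size

    p_i = (n1 * (n1 - 1.0) + n0 * (n0 - 1.0)) / (R * (R - 1.0))
    p_bar = float(p_i.mean())
    marg1 = float(n1.sum()) / (N * R)
    marg = np.array([1.0 - marg1, marg1])
    p_e = float((marg**2).sum())
    if p_e >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            "all ratings in one category over the region; kappa undefined"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)

    # Fleiss (1971) large-sample variance under the chance-only null
    sum2, sum3 = p_e, float((marg**3).sum())
    var = (2.0 / (N * R * (R - 1.0))) * (
        sum2 - (2.0 * R - 3.0) * sum2**2 + 2.0 * (R - 2.0) * sum3
    ) / (1.0 - sum2) ** 2
    z = kappa / np.sqrt(var) if var > 0 else np.inf * np.sign(kappa)
    p_value = 2.0 * stats.norm.sf(abs(z))
    # report a representable floor instead of exactly 0
    p_value = float(max(p_value, np.finfo(float).tiny))

    return KappaResult(
        apparent_agreement=p_bar,
        chance_agreement=p_e,
        kappa=float(kappa),
        z_statistic=float(z),
        p_value=p_value,
        region_voxels=int(N),
        label=classify_kappa(float(kappa)),
    )


def classify_kappa(kappa: float) -> str:
    """Qualitative agreement label on the conventional multi-rater scale.

    ≤ 0 no agreement, (0, 0.2] slight, (0.2, 0.4] fair, (0.4, 0.6] moderate,
    (0.6, 0.8] substantial, > 0.8 excellent.
    """
    if kappa > 1.0 + 1e-12:
        raise ValueError(f"kappa cannot exceed 1, got {kappa}")
    for upper, label in KAPPA_SCALE:
        if kappa <= upper:
            return label
    return "excellent"


def classify_conformity(ci_gen: float) -> str:
    """weak below 0.5, suitable at 0.7 or above, intermediate between."""
    if ci_gen < 0.5:
        return "weak"
    if ci_gen >= 0.7:
        return "suitable"
    return "intermediate"


def generalized_ci(obs: ObserverSet) -> ConformityResult:
    """Generalized conformity index over all unordered observer pairs.

    Computed from rating counts: a voxel rated in by n of R observers
    contributes C(n,2) to the pairwise-intersection sum, and each pairwise
    union is |Ai| + |Aj| − |Ai∩Aj|. For R = 2 this reduces to the Jaccard
    index. The index is unbiased by the number of observers.
    """
    counts = obs.rating_counts().astype(np.float64)
    if not (counts > 0).any():
        raise ValueError("conformity undefined: all observer masks are empty")
    R = obs.n_observers
    inter_vox = float((counts * (counts - 1.0) / 2.0).sum())
    sizes = np.array([float(m.voxels.sum()) for m in obs.masks])
    union_vox = (R - 1.0) * float(sizes.sum()) - inter_vox
    vv = obs.grid.voxel_volume_mm3 / 1000.0
    ci = inter_vox / union_vox
    return ConformityResult(
        ci_gen=float(ci),
        pairwise_intersections_cm3=inter_vox * vv,
        pairwise_unions_cm3=union_vox * vv,
        label=classify_conformity(float(ci)),
    )
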