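"""Synthetic multi-observer panels with known statistical structure.

Two observer models are provided on top of an analytic ground truth:

* ``iid`` — each rater marks a truth voxel with probability p_j (their
  sensitivity) and a background voxel with probability 1 − q_j (one minus
  their specificity), independently per voxel. This is exactly the STAPLE
  generative model, so parameter recovery is directly testable.
* ``boundary`` — each rater's mask is the truth with its border displaced
  along the local normal by a smooth zero-mean Gaussian random field,
  emulating the spatially coherent way human contours disagree: interior
  voxels far from the border are never contested.

Everything is deterministic under a fixed seed. One master seed is split
into per-observer streams via ``numpy.random.SeedSequence(seed,
spawn_key=(j,))``, so adding an observer never changes earlier observers'
masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import pi
from pathlib import Path

import numpy as np
from scipy import ndimage

from .masks_io import MaskGrid, ObserverSet, assemble_observer_set

__all__ = [
    "SimulationConfig",
    "TruthClippedError",
    "make_ground_truth",
    "simulate_observers_iid",
    "simulate_observers_boundary",
    "make_paper_like_case",
]

DEFAULT_GRID_SHAPE = (128, 128, 64)
DEFAULT_SPACING_MM = (1.5, 1.5, 2.5)

#: truth volumes (cm³) emulating the scale of the three clinical case kinds
CASE_VOLUMES_CM3 = {"distal": 120.62, "proximal": 152.05, "gb": 131.94}

# boundary-noise defaults for the demo cases: a few-mm, smoothly correlated
# border disagreement typical of expert contour panels
CASE_SD_MM = 4.0
CASE_SMOOTH_MM = 20.0

# boundary displacements are truncated at this many SDs so all disagreement
# provably stays within CLIP_SD * sd_mm of the truth border
CLIP_SD = 4.0


class TruthClippedError(ValueError):
    """Ground truth (or a perturbed observer) touches the lattice boundary."""


@dataclass(frozen=True)
class SimulationConfig:
    """Declarative description of one synthetic panel.

    ``truth_spec`` is a list of shape dicts, unioned together:
    ``{"kind": "ellipsoid", "center_mm": [...], "semi_axes_mm": [...]}`` or
    ``{"kind": "box", "center_mm": [...], "size_mm": [...]}``.
    ``noise_model`` is either
    ``{"kind": "iid", "p": [...], "q": [...]}`` or
    ``{"kind": "boundary", "sd_mm": float, "smooth_mm": float}``.
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    truth_spec: tuple = ()
    n_observers: int = 9
    noise_model: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            grid_shape=tuple(raw.get("grid_shape", DEFAULT_GRID_SHAPE)),
            spacing_mm=tuple(raw.get("spacing_mm", DEFAULT_SPACING_MM)),
            truth_spec=tuple(raw["truth_spec"]),
            n_observers=int(raw.get("n_observers", 9)),
            noise_model=dict(raw["noise_model"]),
            seed=int(raw.get("seed", 0)),
        )


def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize_shape(shape_spec: dict, grid_shape, spacing) -> np.ndarray:
    X, Y, Z = _voxel_centers(grid_shape, spacing)
    c = np.asarray(shape_spec["center_mm"], dtype=float)
    kind = shape_spec["kind"]
    if kind == "ellipsoid":
        a = np.asarray(shape_spec["semi_axes_mm"], dtype=float)
        r2 = ((X - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((Z - c[2]) / a[2]) ** 2
        return r2 <= 1.0
    if kind == "box":
        half = np.asarray(shape_spec["size_mm"], dtype=float) / 2.0
        return (
            (np.abs(X - c[0]) <= half[0])
            & (np.abs(Y - c[1]) <= half[1])
            & (np.abs(Z - c[2]) <= half[2])
        )
    raise ValueError(f"unknown truth shape kind {kind!r}")


def _touches_lattice_face(vox: np.ndarray) -> bool:
    return bool(
        vox[0].any() or vox[-1].any()
        or vox[:, 0].any() or vox[:, -1].any()
        or vox[:, :, 0].any() or vox[:, :, -1].any()
    )


def make_ground_truth(cfg: SimulationConfig) -> MaskGrid:
    """Rasterize the analytic truth: voxel center inside any shape → 1.

    Deterministic. Raises TruthClippedError if the structure reaches the
    lattice boundary, since a clipped truth would bias border analyses.
    """
    if not cfg.truth_spec:
        raise ValueError("truth_spec is empty")
    vox = np.zeros(cfg.grid_shape, dtype=bool)
    for spec in cfg.truth_spec:
        vox |= _rasterize_shape(spec, cfg.grid_shape, cfg.spacing_mm)
    if not vox.any():
        raise ValueError("truth rasterized to an empty mask")
    if _touches_lattice_face(vox):
        raise TruthClippedError("ground truth touches the lattice boundary")
    return MaskGrid(vox.astype(np.uint8), cfg.spacing_mm, (0.0, 0.0, 0.0))


def _observer_rng(seed: int, j: int) -> np.random.Generator:
    # fixed spawn rule: observer j draws from an independent child stream
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))


def simulate_observers_iid(
    truth: MaskGrid,
    region: np.ndarray,
    p: "list[float] | np.ndarray",
    q: "list[float] | np.ndarray",
    seed: int,
    case_id: str = "iid-sim",
) -> ObserverSet:
    """Draw raters from the STAPLE generative model with known (p_j, q_j).

    Within ``region``, rater j marks truth voxels with probability p_j and
    background voxels with probability 1 − q_j, independently per voxel;
    everything outside the region is 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1D arrays of equal length")
    if not ((0 < p) & (p < 1)).all() or not ((0 < q) & (q < 1)).all():
        raise ValueError("all probabilities must lie strictly in (0, 1)")
    region = np.asarray(region, dtype=bool)
    t = truth.voxels.astype(bool)
    masks, labels = [], []
    for j in range(p.size):
        rng = _observer_rng(seed, j)
        u = rng.random(truth.shape)
        mark = np.where(t, u < p[j], u < (1.0 - q[j])) & region
        masks.append(truth.with_voxels(mark.astype(np.uint8)))
        labels.append(f"rater{j + 1:02d}")
    return assemble_observer_set(masks, labels, case_id)


def simulate_observers_boundary(
    truth: MaskGrid,
    sd_mm: float,
    smooth_mm: float,
    n: int,
    seed: int,
    case_id: str = "boundary-sim",
) -> ObserverSet:
    """Observers as smooth boundary perturbations of the truth.

    The truth's signed distance d(x) (negative inside, positive outside, mm)
    is compared against a smooth zero-mean Gaussian field f(x) with pointwise
    SD ``sd_mm`` and correlation length ``smooth_mm``: observer voxels are
    {d(x) ≤ f(x)}. Displacements are truncated at ±CLIP_SD·sd_mm, so every
    disagreement voxel lies within that distance of the truth border.
    sd_mm = 0 reproduces the truth exactly for every observer.
    """
    if sd_mm < 0:
        raise ValueError("sd_mm must be >= 0")
    t = truth.voxels.astype(bool)
    spacing = np.asarray(truth.spacing)
    d_in = ndimage.distance_transform_edt(t, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~t, sampling=spacing)
    sdist = d_out - d_in  # mm; negative strictly inside, positive outside

    masks, labels = [], []
    for j in range(n):
        if sd_mm == 0:
            fld = np.zeros(truth.shape)
        else:
            rng = _observer_rng(seed, j)
            fld = rng.standard_normal(truth.shape)
            if smooth_mm > 0:
                fld = ndimage.gaussian_filter(fld, sigma=smooth_mm / spacing)
            # center before scaling: smoothing preserves the white noise's
            # grid mean, which the rescale would otherwise blow up into a
            # large whole-structure offset
            fld -= fld.mean()
            fld *= sd_mm / fld.std()
            np.clip(fld, -CLIP_SD * sd_mm, CLIP_SD * sd_mm, out=fld)
        vox = sdist <= fld
        if _touches_lattice_face(vox):
            raise TruthClippedError(
                f"observer {j + 1}: displaced structure reaches the lattice boundary"
            )
        masks.append(truth.with_voxels(vox.astype(np.uint8)))
        labels.append(f"rater{j + 1:02d}")
    return assemble_observer_set(masks, labels, case_id)


def make_paper_like_case(case_kind: str, seed: int) -> ObserverSet:
    """A 9-observer boundary-model demo panel at a clinical volume scale.

    ``case_kind`` selects the truth volume (distal 120.6 cm³, proximal
    152.0 cm³, gb 131.9 cm³) on the default 128×128×64 grid at
    (1.5, 1.5, 2.5) mm. The panel emulates scale only; it makes no claim of
    reproducing any clinical statistic.
    """
    if case_kind not in CASE_VOLUMES_CM3:
        raise ValueError(
            f"case_kind must be one of {sorted(CASE_VOLUMES_CM3)}, got {case_kind!r}"
        )
    vol_mm3 = CASE_VOLUMES_CM3[case_kind] * 1000.0
    # mildly anisotropic ellipsoid with semi-axes (a, 0.85a, 1.15a)
    a = (vol_mm3 * 3.0 / (4.0 * pi * 0.85 * 1.15)) ** (1.0 / 3.0)
    center = tuple(
        (n - 1) * s / 2.0 for n, s in zip(DEFAULT_GRID_SHAPE, DEFAULT_SPACING_MM)
    )
    cfg = SimulationConfig(
        truth_spec=(
            {
                "kind": "ellipsoid",
                "center_mm": center,
                "semi_axes_mm": (a, 0.85 * a, 1.15 * a),
            },
        ),
        seed=seed,
    )
    truth = make_ground_truth(cfg)
    return simulate_observers_boundary(
        truth,
        sd_mm=CASE_SD_MM,
        smooth_mm=CASE_SMOOTH_MM,
        n=9,
        seed=seed,
        case_id=f"{case_kind}-synthetic-seed{seed}",
    )
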