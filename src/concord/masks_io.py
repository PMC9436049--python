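"""Binary mask I/O with physical-space metadata.

Masks live on a regular 3D lattice with a physical geometry expressed in the
LPS patient convention (coordinates increase toward the patient's Left,
Posterior and Superior). NIfTI stores an RAS+ affine; on read the volume is
reoriented so that lattice axes (0, 1, 2) run along +L, +P, +S with positive
steps, and the first two affine rows are sign-flipped to convert RAS to LPS.

Only axis-aligned (orthogonal, possibly permuted/flipped) affines are
supported: oblique acquisitions would require resampling, which silently
changes every voxel-aligned statistic downstream, so they are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MaskGrid",
    "ObserverSet",
    "FormatError",
    "OrientationError",
    "AlignmentError",
    "read_mask",
    "write_mask",
    "assemble_observer_set",
    "read_manifest",
]

_GEOM_TOL_MM = 1e-3


class FormatError(ValueError):
    """Input file is not a 3D binary-mask volume."""


class OrientationError(ValueError):
    """Affine is oblique (not an axis permutation with flips)."""


class AlignmentError(ValueError):
    """Observer grids do not share shape/spacing/origin."""


@dataclass(frozen=True)
class MaskGrid:
    """One observer's binary segmentation on a physical lattice.

    Attributes
    ----------
    voxels : numpy.ndarray
        3D uint8 array of {0, 1}; axis k increases along patient axis
        ``axes[k]``.
    spacing : tuple of float
        Voxel size per lattice axis, mm (strictly positive).
    origin : tuple of float
        LPS coordinate (mm) of the *center* of voxel (0, 0, 0).
    axes : tuple of str
        Patient axis per lattice axis; always ("L", "P", "S") after read
        normalization.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axes: tuple[str, str, str] = ("L", "P", "S")

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise FormatError(f"mask must be 3D, got {v.ndim}D")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask voxels must be 0 or 1")
        object.__setattr__(self, "voxels", v.astype(np.uint8, copy=False))
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "axes", tuple(self.axes))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_cm3(self) -> float:
        """Structure volume: 1-voxel count × voxel volume, in cm³."""
        return float(self.voxels.sum()) * self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "MaskGrid", tol_mm: float = _GEOM_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
            and self.axes == other.axes
        )

    def with_voxels(self, voxels: np.ndarray) -> "MaskGrid":
        """New mask on this grid with different voxel content."""
        return MaskGrid(voxels, self.spacing, self.origin, self.axes)


@dataclass(frozen=True)
class ObserverSet:
    """Aligned panel of one mask per observer for a single case."""

    case_id: str
    masks: tuple[MaskGrid, ...]
    observer_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "masks", tuple(self.masks))
        object.__setattr__(self, "observer_labels", tuple(self.observer_labels))
        if len(self.masks) < 2:
            raise ValueError("an observer set needs at least 2 observers")
        if len(self.observer_labels) != len(self.masks):
            raise ValueError("one label per mask required")
        ref = self.masks[0]
        for lbl, m in zip(self.observer_labels[1:], self.masks[1:]):
            if m.shape != ref.shape:
                raise AlignmentError(
                    f"observer {lbl!r}: shape {m.shape} != {ref.shape}"
                )
            if not m.same_grid(ref):
                raise AlignmentError(
                    f"observer {lbl!r}: spacing/origin differs from "
                    f"{self.observer_labels[0]!r} beyond {_GEOM_TOL_MM} mm"
                )

    @property
    def n_observers(self) -> int:
        return len(self.masks)

    @property
    def grid(self) -> MaskGrid:
        """Reference mask carrying the shared grid geometry."""
        return self.masks[0]

    def stack(self) -> np.ndarray:
        """(R, nx, ny, nz) uint8 array of all observer masks."""
        return np.stack([m.voxels for m in self.masks])

    def rating_counts(self) -> np.ndarray:
        """Per-voxel count of observers marking the voxel (int array)."""
        return self.stack().sum(axis=0, dtype=np.int64)


def _lps_affine(mask: MaskGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(mask.spacing)
    aff[:3, 3] = mask.origin
    return aff


def read_mask(path: str | Path, fmt: str = "nifti") -> MaskGrid:
    """Read a binary mask from a NIfTI-1 file, normalizing axes to LPS.

    Float volumes are binarized at > 0.5. Raises FormatError for non-3D
    volumes and OrientationError for oblique affines (off-axis affine
    entries above 1e-3 after permutation/sign normalization).
    """
    if fmt != "nifti":
        raise ValueError(f"unsupported format {fmt!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")

    ras = np.asarray(img.affine, dtype=float)
    lps = ras.copy()
    lps[0] *= -1.0  # RAS -> LPS
    lps[1] *= -1.0
    M = lps[:3, :3]

    # each lattice axis must step along exactly one patient axis
    perm = np.argmax(np.abs(M), axis=0)  # patient axis per lattice axis
    if sorted(perm.tolist()) != [0, 1, 2]:
        raise OrientationError(f"{path}: affine is not an axis permutation")
    for j in range(3):
        off = np.delete(np.abs(M[:, j]), perm[j])
        if (off > 1e-3).any():
            raise OrientationError(
                f"{path}: oblique affine (off-axis entries {off})"
            )

    # reorder lattice axes so axis k runs along patient axis k
    order = np.argsort(perm)
    data = np.transpose(data, order)
    M = M[:, order]
    step = np.diag(M).copy()
    origin = lps[:3, 3].copy()
    for k in range(3):
        if step[k] < 0:  # flip so steps are positive
            data = np.flip(data, axis=k)
            origin[k] += step[k] * (data.shape[k] - 1)
            step[k] = -step[k]

    vox = (np.asarray(data, dtype=float) > 0.5).astype(np.uint8)
    return MaskGrid(vox, tuple(step), tuple(origin))


def write_mask(mask: MaskGrid, path: str | Path) -> None:
    """Write a mask as NIfTI-1 (uint8); re-read reproduces it bit-exactly."""
    lps = _lps_affine(mask)
    ras = lps.copy()
    ras[0] *= -1.0
    ras[1] *= -1.0
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), ras)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def assemble_observer_set(
    masks: list[MaskGrid], labels: list[str], case_id: str
) -> ObserverSet:
    """Validate a panel of observer masks into an ObserverSet.

    Grids are compared exactly on shape and within 1e-3 mm on spacing and
    origin; any mismatch raises AlignmentError naming the observer. No
    resampling is ever performed.
    """
    if len(masks) < 2:
        raise ValueError(f"need at least 2 masks, got {len(masks)}")
    return ObserverSet(case_id=case_id, masks=tuple(masks), observer_labels=tuple(labels))


def read_manifest(path: str | Path) -> ObserverSet:
    """Load a case manifest: {"case_id": ..., "observers": [{label, path}]}.

    Relative mask paths are resolved against the manifest's directory.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    masks, labels = [], []
    for obs in spec["observers"]:
        p = Path(obs["path"])
        if not p.is_absolute():
            p = path.parent / p
        masks.append(read_mask(p))
        labels.append(str(obs["label"]))
    return assemble_observer_set(masks, labels, str(spec["case_id"]))
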