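"""Volume and mask I/O plus the coordinate convention used throughout.

All arrays follow a fixed canonical axis order:

* axis 0 = x, left -> right
* axis 1 = y, posterior -> anterior
* axis 2 = z, inferior -> superior

i.e. RAS+ voxel order. NIfTI inputs in any other orientation are permuted /
flipped to this order on load (``nibabel.as_closest_canonical``); no
resampling is ever performed. A coronal slice is a fixed ``y`` index, an
axial layer a fixed ``z`` index. The physical position of a voxel along an
axis is ``index * spacing`` (voxel centers, 0-based, millimetres).

The posterior-commissure (PC) landmark is never inferred from a header — it
is supplied explicitly (function argument, CLI flag, or a JSON sidecar next
to the image containing ``{"pc_index": [x, y, z]}``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

CANONICAL_ORIENTATION = "RAS"

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_result_json",
    "read_result_json",
    "read_ratings_table",
    "write_ratings_table",
    "voxel_volume_mm3",
]


def voxel_volume_mm3(spacing) -> float:
    """Volume of one voxel in mm^3."""
    sx, sy, sz = spacing
    return float(sx) * float(sy) * float(sz)


def _validate_grid(data: np.ndarray, spacing) -> tuple[float, float, float]:
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D payload")
    if data.size == 0:
        raise ValueError("empty volume")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be three positive lengths, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar image (T1 or phantom) on the canonical grid.

    Parameters
    ----------
    data
        3D intensity array, axis order (x, y, z) as documented above.
    spacing
        Per-axis voxel size in mm.
    pc_index
        0-based voxel coordinate (x, y, z) of the posterior commissure, or
        ``None`` if not yet supplied. Operations that need the landmark
        raise when it is missing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    pc_index: tuple[int, int, int] | None = None
    orientation_label: str = CANONICAL_ORIENTATION

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = _validate_grid(self.data, self.spacing)
        if self.pc_index is not None:
            pc = tuple(int(c) for c in self.pc_index)
            if len(pc) != 3 or any(
                not (0 <= c < n) for c, n in zip(pc, self.data.shape)
            ):
                raise ValueError(
                    f"pc_index {pc} outside grid of shape {self.data.shape}"
                )
            self.pc_index = pc

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.spacing)

    def require_pc(self) -> tuple[int, int, int]:
        if self.pc_index is None:
            raise ValueError(
                "posterior-commissure landmark required but not set "
                "(supply pc_index via argument, --pc flag, or JSON sidecar)"
            )
        return self.pc_index

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical voxel-center positions (mm) along one axis."""
        return np.arange(self.data.shape[axis]) * self.spacing[axis]


@dataclass
class BinaryMask:
    """A {0,1} voxel set on the same canonical grid as an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.data)
        self.spacing = _validate_grid(arr, self.spacing)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0 or 1")
            arr = arr.astype(bool)
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        """cm^3 = voxel count x voxel volume (mm^3) / 1000 — exact identity."""
        return self.n_voxels * voxel_volume_mm3(self.spacing) / 1000.0

    def check_compatible(self, other) -> None:
        if self.shape != other.shape or not np.allclose(self.spacing, other.spacing):
            raise ValueError(
                f"grid mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.check_compatible(other)
        return BinaryMask(self.data & other.data, self.spacing)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self.check_compatible(other)
        return BinaryMask(self.data | other.data, self.spacing)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D payload in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path, pc_index=None) -> ImageVolume:
    """Read a NIfTI volume, reoriented to the canonical axis order.

    ``pc_index`` may be given directly; otherwise a JSON sidecar
    (``image.json`` next to ``image.nii.gz``) with a ``pc_index`` entry is
    consulted; if neither exists the landmark is left unset.
    """
    path = Path(path)
    data, spacing = _load_canonical(path)
    if pc_index is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            if "pc_index" in meta:
                pc_index = tuple(int(c) for c in meta["pc_index"])
    return ImageVolume(data.astype(np.float64), spacing, pc_index)


def write_volume(image: ImageVolume, path) -> None:
    """Write an ImageVolume as NIfTI with a diagonal RAS affine."""
    affine = np.diag(list(image.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(image.data, dtype=np.float32), affine),
             str(path))


def read_mask(path) -> BinaryMask:
    data, spacing = _load_canonical(Path(path))
    return BinaryMask(data > 0.5, spacing)


def write_mask(mask: BinaryMask, path) -> None:
    """Masks are stored as unsigned 8-bit NIfTI volumes with values {0,1}."""
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Result / table I/O


def write_result_json(result, path) -> None:
    """Serialize a QDESHResult (or any object with ``to_dict``) to JSON.

    Undefined per-slice ratios are written as JSON ``null``, never 0; the
    decimal-text round trip reproduces every number bit-exactly.
    """
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_result_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_ratings_table(path):
    """Read a rater-score CSV into a RatingsMatrix.

    Layout: header row = rater names, first column = subject id, one row per
    subject, numeric cells, no missing values.
    """
    from .validation_stats import RatingsMatrix

    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 2:
        raise ValueError("ratings table needs at least 2 rater columns")
    if df.shape[0] < 2:
        raise ValueError("ratings table needs at least 2 subjects")
    try:
        values = df.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in ratings table: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError("ratings table contains missing cells")
    return RatingsMatrix(
        values=values,
        subjects=[str(s) for s in df.index],
        raters=[str(c) for c in df.columns],
    )


def write_ratings_table(ratings, path) -> None:
    df = pd.DataFrame(ratings.values, index=ratings.subjects, columns=ratings.raters)
    df.index.name = "subject"
    df.to_csv(path)
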