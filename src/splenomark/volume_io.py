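"""Reading, validation and grid alignment of 3D label volumes and clinical tables.

Lesion and organ masks arrive as NIfTI label volumes on co-registered grids.
Everything downstream works in physical millimeters through the affine, with a
voxel-center convention: the physical position of voxel index (i, j, k) is
``affine @ (i, j, k, 1)``. Grids are never resampled silently — mismatched
grids are a hard error unless :func:`resample_labels_nearest` is invoked
explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabelVolume",
    "PatientRecord",
    "AlignmentVerdict",
    "read_label_volume",
    "write_label_volume",
    "check_grid_alignment",
    "resample_labels_nearest",
    "read_clinical_table",
]

#: required header of the clinical CSV
CLINICAL_COLUMNS = [
    "patient_id",
    "weight_kg",
    "height_cm",
    "ipi",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
]


@dataclass
class LabelVolume:
    """A 3D integer label array with a voxel-index → physical-mm affine.

    Label 0 is background. The same carrier holds lesion volumes (one label
    per lesion, or binary) and organ masks (binary).
    """

    voxels: np.ndarray
    affine: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must hold integer labels")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        """(sx, sy, sz) in mm/voxel, column norms of the linear part."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def indices_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) physical mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def foreground_indices(self) -> np.ndarray:
        return np.argwhere(self.voxels > 0)

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        return LabelVolume(voxels=voxels, affine=self.affine.copy(), frame_id=self.frame_id)


@dataclass
class PatientRecord:
    """Clinical covariates and right-censored endpoints for one patient.

    ``weight_kg``/``height_cm`` may be None; body-surface-area-normalized
    features are then unavailable for that patient and the raw distance is
    used instead.
    """

    patient_id: str
    weight_kg: Optional[float]
    height_cm: Optional[float]
    ipi: int
    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int

    def __post_init__(self) -> None:
        if self.weight_kg is not None and not self.weight_kg > 0:
            raise ValueError(f"{self.patient_id}: weight must be > 0")
        if self.height_cm is not None and not self.height_cm > 0:
            raise ValueError(f"{self.patient_id}: height must be > 0")
        for name in ("pfs_months", "os_months"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.patient_id}: {name} is negative")
        for name in ("pfs_event", "os_event"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{self.patient_id}: {name} must be 0 or 1")
        if self.pfs_months > self.os_months + 1e-9:
            raise ValueError(
                f"{self.patient_id}: pfs_months ({self.pfs_months}) exceeds "
                f"os_months ({self.os_months})"
            )

    @property
    def bsa_available(self) -> bool:
        return self.weight_kg is not None and self.height_cm is not None


@dataclass
class AlignmentVerdict:
    aligned: bool
    shapes_match: bool
    max_affine_deviation_mm: float

    def __bool__(self) -> bool:
        return self.aligned


def read_label_volume(path: str | Path) -> LabelVolume:
    """Load a NIfTI label volume, enforcing integer labels and a 3D grid.

    Voxel values within 1e-6 of an integer are rounded (NIfTI scaling can
    introduce float fuzz); anything further off is rejected as non-label data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    rounded = np.rint(data)
    if np.max(np.abs(data - rounded)) > 1e-6:
        raise ValueError(f"{path}: voxel values are not integer labels")
    return LabelVolume(
        voxels=rounded.astype(np.int32),
        affine=np.asarray(img.affine, dtype=float),
        frame_id=path.name,
    )


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), vol.affine)
    nib.save(img, str(path))
    return path


def check_grid_alignment(a: LabelVolume, b: LabelVolume, tol: float = 1e-3) -> AlignmentVerdict:
    """Verdict on whether two volumes share an acquisition grid.

    ALIGNED means identical shapes and affines agreeing elementwise within
    ``tol`` mm. Returns a verdict rather than raising: callers decide policy.
    """
    shapes_match = a.shape == b.shape
    max_dev = float(np.max(np.abs(a.affine - b.affine)))
    return AlignmentVerdict(
        aligned=shapes_match and max_dev <= tol,
        shapes_match=shapes_match,
        max_affine_deviation_mm=max_dev,
    )


def _physical_corners(vol: LabelVolume) -> np.ndarray:
    n = np.array(vol.shape, dtype=float)
    corners = np.array(
        [[i, j, k] for i in (0.0, n[0] - 1) for j in (0.0, n[1] - 1) for k in (0.0, n[2] - 1)]
    )
    return vol.indices_to_mm(corners)


def resample_labels_nearest(vol: LabelVolume, target: LabelVolume) -> LabelVolume:
    """Resample ``vol`` onto ``target``'s grid by nearest neighbor in physical space.

    Labels are never interpolated; the output label set is a subset of the
    input's. Raises if the two physical extents do not overlap at all.
    """
    if check_grid_alignment(vol, target).aligned:
        return target.with_voxels(vol.voxels.copy())

    lo_a, hi_a = _physical_corners(vol).min(0), _physical_corners(vol).max(0)
    lo_b, hi_b = _physical_corners(target).min(0), _physical_corners(target).max(0)
    if np.any(hi_a < lo_b) or np.any(hi_b < lo_a):
        raise ValueError("physical extents of the two grids do not overlap")

    # voxel-index map: target index -> physical mm -> source index (rounded)
    M = np.linalg.inv(vol.affine) @ target.affine
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in target.shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    src = idx @ M[:3, :3].T + M[:3, 3]
    src = np.rint(src).astype(np.int64)
    inside = np.all((src >= 0) & (src < np.array(vol.shape)), axis=1)
    out = np.zeros(len(idx), dtype=vol.voxels.dtype)
    s = src[inside]
    out[inside] = vol.voxels[s[:, 0], s[:, 1], s[:, 2]]
    return target.with_voxels(out.reshape(target.shape))


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read the clinical CSV into validated :class:`PatientRecord` rows.

    Rows with missing weight or height are kept but flagged through
    ``bsa_available``; downstream feature extraction falls back to the
    unnormalized distance for them.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                weight_kg=_opt_float(row["weight_kg"]),
                height_cm=_opt_float(row["height_cm"]),
                ipi=int(row["ipi"]),
                pfs_months=float(row["pfs_months"]),
                pfs_event=int(row["pfs_event"]),
                os_months=float(row["os_months"]),
                os_event=int(row["os_event"]),
            )
        )
    return records


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabular view of patient records, one row per patient."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "weight_kg": [r.weight_kg for r in records],
            "height_cm": [r.height_cm for r in records],
            "ipi": [r.ipi for r in records],
            "pfs_months": [r.pfs_months for r in records],
            "pfs_event": [r.pfs_event for r in records],
            "os_months": [r.os_months for r in records],
            "os_event": [r.os_event for r in records],
        }
    )
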