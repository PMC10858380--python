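"""Quality control of automatically segmented spleen masks.

A segmented spleen is suspect when it is not a single connected component or
when it falls (partly) outside the whole-body field of view. Multi-component
masks are auto-corrected by keeping the largest component; out-of-FOV and
empty masks are flagged for manual review — no geometric edit can repair
those. The thresholds here are sanity screens, not precise criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from ._units import mm3_to_cm3
from .volume_io import LabelVolume

__all__ = [
    "QCReport",
    "FOVRegion",
    "connected_components",
    "body_fov_mask",
    "qc_spleen",
    "organ_volume",
]

#: warning codes
MULTI_COMPONENT = "MULTI_COMPONENT"
OUT_OF_FOV = "OUT_OF_FOV"
EMPTY = "EMPTY"

#: minimum fraction of spleen voxels that must lie inside the FOV region
DEFAULT_FOV_CONTAINMENT = 0.95

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class QCReport:
    patient_id: str
    n_components: int
    warning: bool
    warning_reasons: list[str]
    auto_corrected: bool
    spleen_volume_cm3: float
    needs_manual_review: bool

    def __post_init__(self) -> None:
        if self.auto_corrected and not self.warning:
            raise ValueError("auto_corrected implies warning")


def connected_components(mask: LabelVolume, connectivity: int = 26) -> list[tuple[np.ndarray, int]]:
    """Connected components of the foreground, largest first.

    Any label > 0 counts as foreground. Returns ``(component_mask, voxel
    count)`` pairs sorted by count descending; an empty mask yields an empty
    list. Counts always sum to the total foreground count.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    fg = mask.voxels > 0
    labeled, n = ndimage.label(fg, structure=_STRUCTS[connectivity])
    if n == 0:
        return []
    counts = np.bincount(labeled.ravel())[1:]  # skip background
    order = np.argsort(-counts, kind="stable")
    return [(labeled == (i + 1), int(counts[i])) for i in order]


@dataclass
class FOVRegion:
    """Region against which organ containment is tested.

    Either an explicit boolean mask on the acquisition grid, or the full grid
    itself (the default when no body mask is available).
    """

    mask: Optional[np.ndarray] = None
    shape: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if not self.mask.any():
                raise ValueError("FOV region is empty")
            self.shape = self.mask.shape
        elif self.shape is None:
            raise ValueError("either a mask or a grid shape is required")

    def containment_fraction(self, vol: LabelVolume) -> float:
        """Fraction of ``vol``'s foreground voxels lying inside the region."""
        fg = vol.voxels > 0
        total = int(fg.sum())
        if total == 0:
            return 1.0
        if self.mask is None:
            return 1.0  # full grid: everything on the grid is inside
        if self.mask.shape != vol.shape:
            raise ValueError("FOV mask and volume are on different grids")
        return float(np.count_nonzero(fg & self.mask)) / total


def body_fov_mask(
    ct_like: Optional[LabelVolume] = None,
    shape: Optional[tuple] = None,
    z_slices: Optional[tuple[int, int]] = None,
) -> FOVRegion:
    """Build the field-of-view region for containment testing.

    ``ct_like`` supplies a body-outline mask; ``z_slices=(lo, hi)`` restricts
    an otherwise full grid to an axial slab (inclusive bounds); with neither,
    the full grid is the FOV.
    """
    if ct_like is not None:
        m = ct_like.voxels > 0
        if z_slices is not None:
            slab = np.zeros_like(m)
            slab[:, :, z_slices[0] : z_slices[1] + 1] = True
            m = m & slab
        if not m.any():
            raise ValueError("FOV region is empty")
        return FOVRegion(mask=m)
    if shape is None:
        raise ValueError("need a body mask or a grid shape")
    if z_slices is not None:
        m = np.zeros(shape, dtype=bool)
        m[:, :, z_slices[0] : z_slices[1] + 1] = True
        return FOVRegion(mask=m)
    return FOVRegion(shape=tuple(shape))


def organ_volume(mask: LabelVolume) -> float:
    """Physical organ volume in cm³: foreground count × voxel volume."""
    return mm3_to_cm3(mask.n_foreground * mask.voxel_volume_mm3)


def qc_spleen(
    mask: LabelVolume,
    fov: Optional[FOVRegion] = None,
    connectivity: int = 26,
    fov_threshold: float = DEFAULT_FOV_CONTAINMENT,
    patient_id: str = "",
) -> tuple[LabelVolume, QCReport]:
    """Screen a spleen mask and auto-correct what can be corrected.

    Multi-component masks keep only the largest component (warning
    MULTI_COMPONENT, auto-corrected). A mask whose containment fraction in
    the FOV falls below ``fov_threshold`` is flagged OUT_OF_FOV and referred
    to manual review without geometric correction. An empty mask is EMPTY and
    likewise referred. The reported spleen volume is that of the corrected
    mask.
    """
    if fov is None:
        fov = FOVRegion(shape=mask.shape)
    reasons: list[str] = []
    needs_review = False
    corrected = mask
    auto_corrected = False

    comps = connected_components(mask, connectivity=connectivity)
    n_components = len(comps)
    if n_components == 0:
        reasons.append(EMPTY)
        needs_review = True
    elif n_components > 1:
        reasons.append(MULTI_COMPONENT)
        largest = comps[0][0]
        corrected = mask.with_voxels(
            np.where(largest, mask.voxels, 0).astype(mask.voxels.dtype)
        )
        auto_corrected = True

    if n_components > 0 and fov.containment_fraction(corrected) < fov_threshold:
        reasons.append(OUT_OF_FOV)
        needs_review = True

    report = QCReport(
        patient_id=patient_id or mask.frame_id,
        n_components=n_components,
        warning=bool(reasons),
        warning_reasons=reasons,
        auto_corrected=auto_corrected,
        spleen_volume_cm3=organ_volume(corrected),
        needs_manual_review=needs_review,
    )
    return corrected, report
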