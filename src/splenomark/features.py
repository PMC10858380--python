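"""Geometric dissemination biomarkers relative to a reference organ.

Per patient, from the co-registered lesion and organ masks:

* **TMTV** — total tumor volume, the sum of lesion volumes (cm³);
* **Dmax** — centroid distance between the two farthest lesions (cm);
* **Dbulk** — largest distance from the biggest lesion's centroid to any
  other lesion centroid (cm);
* **Spread** (SpreadSpleen when the reference is the spleen) — the population
  standard deviation σ of the organ-centroid→lesion-centroid distances (cm);
* **D** (Dspleen) — distance from the organ centroid to the farthest lesion
  centroid (cm);
* **sD** (sDspleen) — D normalized by the Mosteller body surface area
  √(weight·height)/60, in m⁻¹, presented ×100.

All centroids are unweighted means of member-voxel physical coordinates.
Spleen-referenced features are defined for every patient, including those
with a single lesion (Spread = 0 there; Dmax = Dbulk = 0 by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import spleen_qc
from ._units import cm_to_m, mm3_to_cm3, mm_to_cm
from .volume_io import LabelVolume, PatientRecord, check_grid_alignment

__all__ = [
    "Lesion",
    "LesionSet",
    "ReferencePoint",
    "FeatureVector",
    "lesion_centroids",
    "reference_centroid",
    "distances_to_reference",
    "spread",
    "d_reference",
    "body_surface_area",
    "standardized_distance",
    "dmax",
    "dbulk",
    "tmtv",
    "splenic_invasion",
    "perturb_reference",
    "features_from_lesions",
    "extract_features",
]


@dataclass(frozen=True)
class Lesion:
    lesion_id: int
    centroid_mm: tuple[float, float, float]
    volume_cm3: float

    def __post_init__(self) -> None:
        if not self.volume_cm3 > 0:
            raise ValueError(f"lesion {self.lesion_id}: volume must be > 0")


@dataclass
class LesionSet:
    patient_id: str
    lesions: list[Lesion]

    def __post_init__(self) -> None:
        self.lesions = sorted(self.lesions, key=lambda l: l.lesion_id)
        ids = [l.lesion_id for l in self.lesions]
        if len(set(ids)) != len(ids):
            raise ValueError("lesion_ids must be unique")

    def __len__(self) -> int:
        return len(self.lesions)

    @property
    def centroids_mm(self) -> np.ndarray:
        return np.array([l.centroid_mm for l in self.lesions], dtype=float)

    @property
    def volumes_cm3(self) -> np.ndarray:
        return np.array([l.volume_cm3 for l in self.lesions], dtype=float)


@dataclass(frozen=True)
class ReferencePoint:
    organ: str
    centroid_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.centroid_mm):
            raise ValueError("reference centroid must be finite")


@dataclass
class FeatureVector:
    """Per-patient biomarker record. Distances in cm, volumes in cm³,
    standardized distance in m⁻¹ (``sd_x100`` is the presentation form)."""

    patient_id: str
    organ: str
    tmtv_cm3: float
    spread_cm: float
    d_cm: float
    sd_per_m: Optional[float]
    dmax_cm: float
    dbulk_cm: float
    organ_volume_cm3: float
    invasion: Optional[bool]
    bsa_m2: Optional[float]

    @property
    def sd_x100(self) -> Optional[float]:
        return None if self.sd_per_m is None else 100.0 * self.sd_per_m


def lesion_centroids(
    lesion_vol: LabelVolume,
    mode: str = "per_label",
    connectivity: int = 26,
    patient_id: str = "",
) -> LesionSet:
    """Identify lesions in a label volume and compute centroids and volumes.

    ``per_label`` treats each distinct positive label as one lesion (expert
    masks carry lesion labels); ``connected_components`` splits the binary
    foreground by connectivity instead. The centroid is the unweighted mean
    of member-voxel physical coordinates; because the affine is affine, it
    equals the affine image of the mean voxel index.
    """
    if lesion_vol.n_foreground == 0:
        raise ValueError("lesion volume is empty")
    voxvol_cm3 = mm3_to_cm3(lesion_vol.voxel_volume_mm3)
    lesions: list[Lesion] = []
    if mode == "per_label":
        labels = np.unique(lesion_vol.voxels)
        labels = labels[labels > 0]
        for lab in labels:
            idx = np.argwhere(lesion_vol.voxels == lab)
            c = lesion_vol.indices_to_mm(idx.mean(axis=0))[0]
            lesions.append(Lesion(int(lab), tuple(c), len(idx) * voxvol_cm3))
    elif mode == "connected_components":
        comps = spleen_qc.connected_components(lesion_vol, connectivity=connectivity)
        for i, (comp, count) in enumerate(comps, start=1):
            idx = np.argwhere(comp)
            c = lesion_vol.indices_to_mm(idx.mean(axis=0))[0]
            lesions.append(Lesion(i, tuple(c), count * voxvol_cm3))
    else:
        raise ValueError(f"unknown lesion identification mode: {mode!r}")
    return LesionSet(patient_id=patient_id or lesion_vol.frame_id, lesions=lesions)


def reference_centroid(organ_mask: LabelVolume, organ: str = "spleen") -> ReferencePoint:
    """Unweighted centroid of the organ mask's foreground, in mm."""
    idx = organ_mask.foreground_indices()
    if len(idx) == 0:
        raise ValueError("organ mask is empty")
    c = organ_mask.indices_to_mm(idx.mean(axis=0))[0]
    return ReferencePoint(organ=organ, centroid_mm=tuple(c))


def distances_to_reference(ref: ReferencePoint, lesions: LesionSet) -> np.ndarray:
    """Euclidean distance (mm) from the reference centroid to each lesion
    centroid, in lesion order."""
    if len(lesions) == 0:
        raise ValueError("lesion set is empty")
    diff = lesions.centroids_mm - np.asarray(ref.centroid_mm)
    return np.linalg.norm(diff, axis=1)


def spread(distances_mm: Sequence[float]) -> float:
    """Population SD (÷N, not N−1) of the reference distances, in cm.

    σ = √(Σᵢ(dᵢ − μ)²/N). A single lesion gives 0 — the feature is defined
    for every patient.
    """
    d = np.asarray(distances_mm, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    return mm_to_cm(float(np.std(d)))  # numpy std is the population form


def d_reference(distances_mm: Sequence[float]) -> float:
    """Distance to the farthest lesion from the reference organ, in cm."""
    d = np.asarray(distances_mm, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    return mm_to_cm(float(d.max()))


def body_surface_area(weight_kg: float, height_cm: float) -> float:
    """Mosteller body surface area √(weight_kg × height_cm)/60, in m²."""
    if not weight_kg > 0 or not height_cm > 0:
        raise ValueError("weight and height must be positive")
    return math.sqrt(weight_kg * height_cm) / 60.0


def standardized_distance(d_ref_cm: float, bsa_m2: float) -> float:
    """Reference distance (m) divided by body surface area (m²), in m⁻¹.

    Reporting multiplies by 100 (``FeatureVector.sd_x100``)."""
    if not bsa_m2 > 0:
        raise ValueError("body surface area must be positive")
    return cm_to_m(d_ref_cm) / bsa_m2


def dmax(lesions: LesionSet) -> float:
    """Largest pairwise centroid distance, in cm; 0 for a single lesion."""
    if len(lesions) == 0:
        raise ValueError("lesion set is empty")
    if len(lesions) == 1:
        return 0.0
    return mm_to_cm(float(pdist(lesions.centroids_mm).max()))


def dbulk(lesions: LesionSet) -> float:
    """Largest distance from the bulk (highest-volume) lesion's centroid to
    any other lesion centroid, in cm; ties broken by lowest lesion_id;
    0 for a single lesion. Always ≤ Dmax."""
    if len(lesions) == 0:
        raise ValueError("lesion set is empty")
    if len(lesions) == 1:
        return 0.0
    vols = lesions.volumes_cm3
    bulk_idx = int(np.argmax(vols))  # argmax keeps the first max → lowest id (sorted order)
    cents = lesions.centroids_mm
    d = np.linalg.norm(cents - cents[bulk_idx], axis=1)
    return mm_to_cm(float(d.max()))


def tmtv(lesions: LesionSet) -> float:
    """Total tumor volume: sum of lesion volumes, in cm³."""
    if len(lesions) == 0:
        raise ValueError("lesion set is empty")
    return float(lesions.volumes_cm3.sum())


def splenic_invasion(lesion_vol: LabelVolume, spleen_mask: LabelVolume) -> bool:
    """True iff any lesion voxel overlaps a spleen voxel (same grid)."""
    verdict = check_grid_alignment(lesion_vol, spleen_mask)
    if not verdict.aligned:
        raise ValueError(
            "lesion and spleen masks are on different grids "
            f"(max affine deviation {verdict.max_affine_deviation_mm:.3g} mm)"
        )
    return bool(np.any((lesion_vol.voxels > 0) & (spleen_mask.voxels > 0)))


def perturb_reference(
    ref: ReferencePoint, radius_cm: float, rng: np.random.Generator | int
) -> ReferencePoint:
    """Displace the reference centroid by exactly ``radius_cm`` in a uniformly
    random 3D direction (robustness check for imperfect organ delineation)."""
    if radius_cm < 0:
        raise ValueError("radius must be >= 0")
    if radius_cm == 0:
        return ref
    gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    v = gen.normal(size=3)
    while np.linalg.norm(v) < 1e-12:  # pragma: no cover - probability ~0
        v = gen.normal(size=3)
    v = v / np.linalg.norm(v) * radius_cm * 10.0  # cm -> mm
    new = tuple(np.asarray(ref.centroid_mm) + v)
    return ReferencePoint(organ=ref.organ, centroid_mm=new)


def features_from_lesions(
    patient_id: str,
    lesions: LesionSet,
    ref: ReferencePoint,
    organ_volume_cm3: float = float("nan"),
    invasion: Optional[bool] = None,
    weight_kg: Optional[float] = None,
    height_cm: Optional[float] = None,
) -> FeatureVector:
    """Compose the biomarker vector from analytic lesion/reference geometry.

    This is the single code path behind both image-based extraction and the
    synthetic generator's fast path; identical inputs give identical outputs.
    """
    dists = distances_to_reference(ref, lesions)
    d_cm = d_reference(dists)
    bsa = sd = None
    if weight_kg is not None and height_cm is not None:
        bsa = body_surface_area(weight_kg, height_cm)
        sd = standardized_distance(d_cm, bsa)
    return FeatureVector(
        patient_id=patient_id,
        organ=ref.organ,
        tmtv_cm3=tmtv(lesions),
        spread_cm=spread(dists),
        d_cm=d_cm,
        sd_per_m=sd,
        dmax_cm=dmax(lesions),
        dbulk_cm=dbulk(lesions),
        organ_volume_cm3=organ_volume_cm3,
        invasion=invasion,
        bsa_m2=bsa,
    )


def extract_features(
    patient: PatientRecord,
    lesion_vol: LabelVolume,
    organ_mask: LabelVolume,
    organ: str = "spleen",
    mode: str = "per_label",
    connectivity: int = 26,
) -> FeatureVector:
    """Full per-patient feature extraction from co-registered masks."""
    lesions = lesion_centroids(
        lesion_vol, mode=mode, connectivity=connectivity, patient_id=patient.patient_id
    )
    ref = reference_centroid(organ_mask, organ=organ)
    inv = splenic_invasion(lesion_vol, organ_mask) if organ == "spleen" else None
    return features_from_lesions(
        patient_id=patient.patient_id,
        lesions=lesions,
        ref=ref,
        organ_volume_cm3=spleen_qc.organ_volume(organ_mask),
        invasion=inv,
        weight_kg=patient.weight_kg,
        height_cm=patient.height_cm,
    )
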