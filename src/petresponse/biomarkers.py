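"""Imaging biomarkers from a PET volume and a lesion segmentation.

Four per-acquisition biomarkers are computed:

* **SULpeak** — the highest mean SUL inside a 1.2-cm-diameter spherical
  VOI centred on any segmented voxel (the PERCIST activity measure).
  The sphere itself is *not* restricted to the segmentation, so the peak
  is not necessarily centred on the hottest voxel.
* **TLG** — total lesion glycolysis, the sum over connected lesions of
  MTV × SUVmean (SUVbw), combining volume and metabolic activity.
* **PBI / PLI** — PET bone / liver index: segmented lesion volume inside
  the organ as a percentage of total organ volume, a whole-body tumour
  burden measure for the two sites most affected by metastatic breast
  cancer.

Connected components use 26-connectivity by default; labels are ordered
deterministically by each component's first voxel in a lexicographic
(z, y, x) scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask, ImageVolume, ValueKind, logger

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


class Organ(str, Enum):
    BONE = "bone"
    LIVER = "liver"
    OTHER = "other"


@dataclass
class LesionLabelMap:
    """Integer-labelled lesion components (0 = background, 1..K = lesions)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    connectivity: int

    @property
    def n_lesions(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


@dataclass
class LesionStats:
    label: int
    n_voxels: int
    mtv_ml: float
    suv_mean: float
    tlg: float
    organ: Organ = Organ.OTHER


@dataclass
class SulPeakResult:
    value: float
    center: Optional[tuple[int, int, int]]
    defined: bool

    def __float__(self) -> float:
        return self.value


@dataclass
class BiomarkerPanel:
    """SULpeak, MTV, TLG, PBI and PLI for one acquisition."""

    sul_peak: SulPeakResult
    mtv_total_ml: float
    tlg_total: float
    pbi_pct: float
    pli_pct: float
    per_lesion: list[LesionStats] = field(default_factory=list)

    def as_record(self) -> dict:
        return {
            "sul_peak": self.sul_peak.value if self.sul_peak.defined else 0.0,
            "sul_peak_defined": self.sul_peak.defined,
            "mtv_total_ml": self.mtv_total_ml,
            "tlg_total": self.tlg_total,
            "pbi_pct": self.pbi_pct,
            "pli_pct": self.pli_pct,
            "n_lesions": len(self.per_lesion),
        }


def label_lesions(mask: BinaryMask, connectivity: int = 26) -> LesionLabelMap:
    """Connected-component labelling of a lesion mask.

    Labels are renumbered so that lesion 1 is the component whose first
    voxel comes earliest in a lexicographic (z, y, x) scan, making the
    labelling deterministic across library versions.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    raw, n = ndimage.label(mask.values, structure=_STRUCTURES[connectivity])
    if n > 0:
        scan = raw.transpose(2, 1, 0).ravel()
        nz = np.flatnonzero(scan)
        labels_seen, first_idx = np.unique(scan[nz], return_index=True)
        order = labels_seen[np.argsort(first_idx)]
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[order] = np.arange(1, n + 1)
        raw = remap[raw]
    return LesionLabelMap(labels=raw, spacing=mask.spacing, origin=mask.origin, connectivity=connectivity)


def sphere_offsets(spacing: Sequence[float], diameter_mm: float = 12.0) -> np.ndarray:
    """Integer lattice offsets whose voxel centres lie within the sphere.

    Membership uses world-mm distance from the candidate centre with an
    inclusive (≤ radius) comparison; offsets are returned in lexicographic
    order.  On a 2 mm isotropic grid the default 12 mm sphere holds 123
    voxels.
    """
    r = diameter_mm / 2.0
    sx, sy, sz = (float(s) for s in spacing)
    ni, nj, nk = (int(np.floor(r / s)) for s in (sx, sy, sz))
    out = []
    for di in range(-ni, ni + 1):
        for dj in range(-nj, nj + 1):
            for dk in range(-nk, nk + 1):
                if (di * sx) ** 2 + (dj * sy) ** 2 + (dk * sz) ** 2 <= r * r:
                    out.append((di, dj, dk))
    return np.array(out, dtype=np.intp)


def sul_peak(
    sul: ImageVolume,
    mask: BinaryMask,
    sphere_diameter_mm: float = 12.0,
) -> SulPeakResult:
    """Peak spherical-VOI mean SUL over all segmented candidate centres.

    Every voxel of ``mask`` is tried as the centre of a sphere of the
    given diameter; the sphere includes *all* image voxels whose centres
    lie within the radius (not only segmented ones).  Spheres reaching
    beyond the image border are truncated to existing voxels.  Returns
    the maximum sphere mean and one argmax centre (first in scan order on
    ties); an empty mask yields an undefined-flagged result.
    """
    sul.require_same_lattice(mask, "SUL volume vs lesion mask")
    centers = np.argwhere(mask.values)
    if centers.shape[0] == 0:
        return SulPeakResult(value=float("nan"), center=None, defined=False)

    values = np.ascontiguousarray(np.asarray(sul.values, dtype=np.float64))
    offsets = sphere_offsets(sul.spacing, sphere_diameter_mm)
    shape = np.array(values.shape)
    maxoff = np.abs(offsets).max(axis=0)

    means = np.empty(centers.shape[0], dtype=np.float64)
    interior = np.all((centers >= maxoff) & (centers <= shape - 1 - maxoff), axis=1)

    if np.any(interior):
        flat = values.ravel()
        s1, s2 = values.shape[1], values.shape[2]
        flat_centers = centers[interior, 0] * (s1 * s2) + centers[interior, 1] * s2 + centers[interior, 2]
        flat_off = offsets[:, 0] * (s1 * s2) + offsets[:, 1] * s2 + offsets[:, 2]
        gathered = flat[flat_centers[:, None] + flat_off[None, :]]
        means[interior] = gathered.mean(axis=1)

    n_truncated = 0
    for idx in np.nonzero(~interior)[0]:
        pts = centers[idx] + offsets
        valid = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[valid]
        if len(pts) < len(offsets):
            n_truncated += 1
        means[idx] = np.mean(values[pts[:, 0], pts[:, 1], pts[:, 2]])
    if n_truncated:
        logger.debug("sul_peak: %d candidate spheres truncated at the image border", n_truncated)

    best = int(np.argmax(means))
    return SulPeakResult(value=float(means[best]), center=tuple(int(c) for c in centers[best]), defined=True)


def _label_counts(labelmap: LesionLabelMap) -> np.ndarray:
    """Voxel count per label 1..K (single bincount pass)."""
    k = labelmap.n_lesions
    return np.bincount(labelmap.labels.ravel(), minlength=k + 1)[1:]


def lesion_stats(labelmap: LesionLabelMap, suv: ImageVolume) -> list[LesionStats]:
    """Per-lesion MTV (mL), SUVmean and TLG = MTV × SUVmean."""
    suv.require_same_lattice(
        BinaryMask(labelmap.labels != 0, labelmap.spacing, labelmap.origin), "SUV volume vs label map"
    )
    k = labelmap.n_lesions
    if k == 0:
        return []
    counts = _label_counts(labelmap)
    flat_labels = labelmap.labels.ravel()
    sums = np.bincount(flat_labels, weights=np.asarray(suv.values, dtype=np.float64).ravel(), minlength=k + 1)[1:]
    vv = labelmap.voxel_volume_ml
    out = []
    for lab, n, s in zip(range(1, k + 1), counts, sums):
        mtv = float(n) * vv
        mean = float(s) / float(n)
        out.append(LesionStats(label=int(lab), n_voxels=int(n), mtv_ml=mtv, suv_mean=mean, tlg=mtv * mean))
    return out


def assign_organ(
    labelmap: LesionLabelMap,
    bone: BinaryMask | None,
    liver: BinaryMask | None,
    majority: float = 0.5,
) -> list[Organ]:
    """Tag each lesion bone / liver / other by strict-majority voxel fraction.

    A lesion is tagged bone (resp. liver) iff more than ``majority`` of
    its voxels lie inside the organ mask; bone takes precedence when both
    fractions exceed the threshold.
    """
    k = labelmap.n_lesions
    if k == 0:
        return []
    counts = _label_counts(labelmap)

    def frac(mask: BinaryMask | None) -> np.ndarray:
        if mask is None:
            return np.zeros(k)
        inside = np.bincount(labelmap.labels[mask.values], minlength=k + 1)[1:]
        return inside / counts

    if bone is not None and liver is not None and np.any(bone.values & liver.values):
        logger.warning(
            "bone and liver masks overlap on %d voxels; bone takes precedence",
            int(np.count_nonzero(bone.values & liver.values)),
        )
    f_bone, f_liver = frac(bone), frac(liver)
    tags = []
    for fb, fl in zip(f_bone, f_liver):
        if fb > majority:
            tags.append(Organ.BONE)
        elif fl > majority:
            tags.append(Organ.LIVER)
        else:
            tags.append(Organ.OTHER)
    return tags


def _organ_index(labelmap: LesionLabelMap, organ_mask: BinaryMask, tags: Sequence[Organ], organ: Organ) -> float:
    organ_voxels = int(np.count_nonzero(organ_mask.values))
    if organ_voxels == 0:
        raise ValueError(f"empty {organ.value} mask: index undefined")
    k = labelmap.n_lesions
    if k == 0:
        return 0.0
    counts = _label_counts(labelmap)
    lesion_voxels = sum(int(n) for n, t in zip(counts, tags) if t == organ)
    return 100.0 * lesion_voxels / organ_voxels


def pet_bone_index(
    labelmap: LesionLabelMap,
    bone: BinaryMask,
    tags: Sequence[Organ] | None = None,
    majority: float = 0.5,
) -> float:
    """PBI: full volume of bone-tagged lesions over total bone volume, in percent."""
    if tags is None:
        tags = assign_organ(labelmap, bone, None, majority)
    return _organ_index(labelmap, bone, tags, Organ.BONE)


def pet_liver_index(
    labelmap: LesionLabelMap,
    liver: BinaryMask,
    bone: BinaryMask | None = None,
    tags: Sequence[Organ] | None = None,
    majority: float = 0.5,
) -> float:
    """PLI: full volume of liver-tagged lesions over total liver volume, in percent."""
    if tags is None:
        tags = assign_organ(labelmap, bone, liver, majority)
    return _organ_index(labelmap, liver, tags, Organ.LIVER)


def biomarker_panel(
    sul: ImageVolume,
    suv: ImageVolume,
    mask: BinaryMask,
    bone: BinaryMask,
    liver: BinaryMask,
    connectivity: int = 26,
    sphere_diameter_mm: float = 12.0,
    majority: float = 0.5,
) -> BiomarkerPanel:
    """Compute the full four-biomarker panel for one acquisition.

    SULpeak is taken on the SUL volume and TLG on the SUVbw volume, each
    biomarker on the image it is defined on.  An empty segmentation
    yields zero volumes and an undefined-flagged SULpeak.
    """
    if sul.value_kind != ValueKind.SUL:
        raise ValueError(f"SULpeak requires a SUL volume, got {sul.value_kind.value}")
    for vol in (suv, mask, bone, liver):
        sul.require_same_lattice(vol, "panel inputs")
    labelmap = label_lesions(mask, connectivity)
    stats = lesion_stats(labelmap, suv)
    tags = assign_organ(labelmap, bone, liver, majority)
    for s, t in zip(stats, tags):
        s.organ = t
    return BiomarkerPanel(
        sul_peak=sul_peak(sul, mask, sphere_diameter_mm),
        mtv_total_ml=float(sum(s.mtv_ml for s in stats)),
        tlg_total=float(sum(s.tlg for s in stats)),
        pbi_pct=pet_bone_index(labelmap, bone, tags=tags),
        pli_pct=pet_liver_index(labelmap, liver, tags=tags),
        per_lesion=stats,
    )
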