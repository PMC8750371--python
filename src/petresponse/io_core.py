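"""Volume, mask and metadata data model plus NIfTI / tabular I/O.

All geometry is expressed in world millimetres: a voxel at index
``(i, j, k)`` has its centre at ``origin + index * spacing``.  Every
inter-volume operation in this package requires the two lattices (shape,
spacing, origin) to match exactly; spatial registration is upstream of
this pipeline and deliberately out of scope.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger("petresponse")

_LATTICE_ATOL = 1e-4  # mm; NIfTI headers store float32 geometry


class ValueKind(str, Enum):
    """Semantics of the scalar stored in an :class:`ImageVolume`."""

    ACTIVITY = "activity_Bq_per_mL"
    SUV_BW = "suv_bw"
    SUL = "sul"
    HOUNSFIELD = "hounsfield"
    PROBABILITY = "probability"


class Timepoint(str, Enum):
    BL = "BL"
    FU1 = "FU1"
    FU2 = "FU2"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Percist(str, Enum):
    """PET Response Criteria in Solid Tumors categories."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular anisotropic lattice.

    Parameters
    ----------
    values
        3D array, indexed ``[i, j, k]``.
    spacing
        Voxel size in mm along each axis; strictly positive.
    origin
        World-mm coordinate of the centre of voxel ``(0, 0, 0)``.
    value_kind
        Declared semantics of the voxel values.  Never inferred.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_kind: ValueKind = ValueKind.SUV_BW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if min(self.values.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.value_kind = ValueKind(self.value_kind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_lattice(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing, atol=_LATTICE_ATOL)
            and np.allclose(self.origin, other.origin, atol=_LATTICE_ATOL)
        )

    def require_same_lattice(self, other: "ImageVolume | BinaryMask", what: str = "volumes") -> None:
        if not self.same_lattice(other):
            raise ValueError(
                f"lattice mismatch between {what}: "
                f"{self.values.shape}/{self.spacing}/{self.origin} vs "
                f"{other.values.shape}/{other.spacing}/{other.origin}"
            )


@dataclass
class BinaryMask:
    """A boolean mask on the same lattice as a reference :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.values.ndim}D")
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask voxels must be binary, found values {uniq[:10]}")
            self.values = self.values.astype(bool)
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def volume_ml(self) -> float:
        return float(np.count_nonzero(self.values)) * self.voxel_volume_ml

    def same_lattice(self, other: "ImageVolume | BinaryMask") -> bool:
        return ImageVolume.same_lattice(self, other)  # type: ignore[arg-type]

    def require_same_lattice(self, other: "ImageVolume | BinaryMask", what: str = "volumes") -> None:
        ImageVolume.require_same_lattice(self, other, what)  # type: ignore[arg-type]


@dataclass
class AcquisitionMeta:
    """Per-acquisition patient and injection metadata.

    ``injected_activity_bq`` must already be decay-corrected to scan
    start; no decay chain is computed anywhere in this package.
    """

    patient_id: str
    timepoint: Timepoint
    injected_activity_bq: float
    weight_kg: float
    height_m: float
    sex: Sex
    percist: Optional[Percist] = None

    def __post_init__(self) -> None:
        self.timepoint = Timepoint(self.timepoint)
        self.sex = Sex(self.sex)
        if self.percist is not None:
            self.percist = Percist(self.percist)
        if self.injected_activity_bq <= 0:
            raise ValueError("injected activity must be > 0")
        if self.weight_kg <= 0 or self.height_m <= 0:
            raise ValueError("weight and height must be > 0")
        if self.percist is not None and self.timepoint == Timepoint.BL:
            raise ValueError("PERCIST category applies to follow-up acquisitions only")


@dataclass
class Acquisition:
    """One imaging session: PET volume, lesion mask and its metadata."""

    pet: ImageVolume
    mask: BinaryMask
    meta: AcquisitionMeta


@dataclass
class PatientTimeline:
    """Baseline plus one or more follow-up acquisitions, with organ masks.

    All volumes of one patient must share a lattice; the pipeline
    assumes pre-registered input.
    """

    baseline: Acquisition
    followups: list[Acquisition] = field(default_factory=list)
    organ_masks: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.followups) < 1:
            raise ValueError("a patient timeline needs at least one follow-up acquisition")
        ref = self.baseline.pet
        for acq in [self.baseline, *self.followups]:
            ref.require_same_lattice(acq.pet, "timeline volumes")
            ref.require_same_lattice(acq.mask, "timeline masks")
        for name, m in self.organ_masks.items():
            ref.require_same_lattice(m, f"organ mask '{name}'")

    @property
    def patient_id(self) -> str:
        return self.baseline.meta.patient_id


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, value_kind: ValueKind | str) -> ImageVolume:
    """Load a NIfTI-1 file as an :class:`ImageVolume`.

    The caller declares ``value_kind``; units are never guessed from the
    header.  Raises on missing files, non-3D images and non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    bad = np.count_nonzero(~np.isfinite(data))
    if bad:
        raise ValueError(f"{path} contains {bad} non-finite voxels")
    aff = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in aff[:3, 3])
    return ImageVolume(values=data, spacing=spacing, origin=origin, value_kind=ValueKind(value_kind))


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` to NIfTI-1 (float32)."""
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: ImageVolume | None = None) -> BinaryMask:
    """Load a uint8 {0,1} NIfTI mask; optionally check it against a reference lattice."""
    vol = read_volume(path, ValueKind.PROBABILITY)
    mask = BinaryMask(values=vol.values != 0, spacing=vol.spacing, origin=vol.origin)
    if reference is not None:
        reference.require_same_lattice(mask, "mask vs reference")
    return mask


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    # SimpleITK arrays are indexed (k, j, i)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(vol.values, dtype=np.float64).transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def resample_to_grid(
    moving: ImageVolume,
    reference: ImageVolume | BinaryMask,
    fill_value: float | None = None,
) -> ImageVolume:
    """Trilinearly resample ``moving`` onto the lattice of ``reference``.

    Voxels falling outside the moving field of view are filled with
    ``fill_value`` (default: the minimum of the moving volume, a sensible
    background for both CT in HU and PET in SUV).
    """
    if min(reference.values.shape) < 1:
        raise ValueError("degenerate reference lattice")
    if fill_value is None:
        fill_value = float(np.min(moving.values))
    img = _to_sitk(moving)
    out = sitk.Resample(
        img,
        tuple(int(n) for n in reference.values.shape),
        sitk.Transform(),
        sitk.sitkLinear,
        reference.origin,
        reference.spacing,
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        float(fill_value),
        sitk.sitkFloat64,
    )
    values = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    return ImageVolume(
        values=values,
        spacing=reference.spacing,
        origin=reference.origin,
        value_kind=moving.value_kind,
    )


# ---------------------------------------------------------------------------
# Tabular reports and manifests


def write_report(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Write homogeneous records to CSV (header always present, full float precision).

    ``columns`` fixes the header for an empty record list and the column
    order otherwise.
    """
    df = pd.DataFrame(list(rows), columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


MANIFEST_COLUMNS = [
    "patient_id",
    "timepoint",
    "pet_path",
    "mask_path",
    "bone_path",
    "liver_path",
    "value_kind",
    "injected_activity_MBq",
    "weight_kg",
    "height_m",
    "sex",
    "percist",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its schema."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    return df


def meta_from_row(row) -> AcquisitionMeta:
    percist = row.get("percist")
    if percist is not None and (pd.isna(percist) or percist == ""):
        percist = None
    return AcquisitionMeta(
        patient_id=str(row["patient_id"]),
        timepoint=Timepoint(row["timepoint"]),
        injected_activity_bq=float(row["injected_activity_MBq"]) * 1e6,
        weight_kg=float(row["weight_kg"]),
        height_m=float(row["height_m"]),
        sex=Sex(row["sex"]),
        percist=None if percist is None else Percist(percist),
    )


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
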