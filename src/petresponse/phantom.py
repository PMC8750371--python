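"""Synthetic whole-body PET/CT phantom cohorts with exact ground truth.

Each patient is a stylised whole-body volume in SUVbw space: an
elliptic-cylinder body at background SUV 1, an ellipsoidal liver at
SUV 2, a spine-plus-pelvis bone compartment, and non-overlapping
spherical lesions (SUV 3–15, diameter 8–40 mm) some of which are placed
fully inside bone and liver by construction.  A Gaussian point-spread
function and additive Gaussian noise emulate scanner resolution and
statistical noise; the ground-truth lesion masks are the pre-blur
supports, mimicking the fact that experts outline lesions rather than
their PSF tails.

A follow-up acquisition is derived from the baseline by scaling every
lesion's SUV amplitude and volume with per-patient response factors:
responders draw factors below one (complete resolution for a fraction of
them), non-responders draw factors at or above one and may progress by
growth or by a new lesion.  The PERCIST category (CR/PR/SD/PD) is
derived from the planted factors, so the planted responder flag always
matches the binarised category.

Truth biomarkers (MTV, TLG, PBI, PLI) are bookkept analytically from the
pre-noise, pre-PSF piecewise-constant model, so on noiseless, PSF-free
phantoms the measured panel on the ground-truth mask reproduces them to
floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import (
    Acquisition,
    AcquisitionMeta,
    BinaryMask,
    ImageVolume,
    PatientTimeline,
    Percist,
    Sex,
    Timepoint,
    ValueKind,
    write_mask,
    write_volume,
)

_BIOMARKERS = ("sul_peak", "mtv_total_ml", "tlg_total", "pbi_pct", "pli_pct")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort; defaults define the study conditions."""

    shape: tuple[int, int, int] = (96, 96, 192)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_suv: float = 1.0
    liver_suv: float = 2.0
    lesion_count_mean: float = 8.0  # Poisson, min 1
    lesion_diameter_mm: tuple[float, float] = (8.0, 40.0)
    lesion_suv: tuple[float, float] = (3.0, 15.0)
    psf_fwhm_mm: float = 6.0
    noise_sd_suv: float = 0.05
    responder_suv_factor: tuple[float, float] = (0.3, 0.7)
    responder_volume_factor: tuple[float, float] = (0.3, 0.8)
    nonresponder_suv_factor: tuple[float, float] = (0.95, 1.4)
    nonresponder_volume_factor: tuple[float, float] = (1.0, 1.3)
    responder_fraction: float = 0.5
    cr_probability: float = 0.15  # responders resolving completely
    new_lesion_probability: float = 0.3  # PD via a new follow-up lesion
    organ_lesion_order: tuple[str, ...] = ("bone", "liver")
    # stylised geometry, all in mm
    body_semiaxes: tuple[float, float] = (100.0, 70.0)
    liver_center_frac: tuple[float, float, float] = (0.65, 0.48, 0.68)
    liver_semiaxes: tuple[float, float, float] = (50.0, 40.0, 35.0)
    spine_offset_y_mm: float = 40.0
    spine_radius_mm: float = 14.0
    pelvis_z_frac: float = 0.23
    pelvis_radius_mm: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        for rng_field in ("lesion_diameter_mm", "lesion_suv"):
            lo, hi = getattr(self, rng_field)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {rng_field}: ({lo}, {hi})")
        if any(s <= 0 for s in self.spacing) or min(self.shape) < 8:
            raise ValueError("invalid phantom lattice")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class LesionTruth:
    center_idx: tuple[int, int, int]
    radius_mm: float
    suv: float
    n_voxels: int
    organ: str  # bone / liver / other, by the same majority rule as measurement
    new_at_followup: bool = False


@dataclass
class PhantomTruth:
    """Exact per-patient ground truth, recomputable from spec + seed alone."""

    patient_id: str
    responder: bool
    percist: Percist
    suv_factor: float
    volume_factor: float
    lesions: dict[str, list[LesionTruth]] = field(default_factory=dict)
    panels: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry template (cached: identical for every patient of a spec)

_template_cache: dict[tuple, dict] = {}


def _geometry_key(spec: PhantomSpec) -> tuple:
    return (
        spec.shape,
        spec.spacing,
        spec.body_semiaxes,
        spec.liver_center_frac,
        spec.liver_semiaxes,
        spec.spine_offset_y_mm,
        spec.spine_radius_mm,
        spec.pelvis_z_frac,
        spec.pelvis_radius_mm,
    )


def _template(spec: PhantomSpec) -> dict:
    key = _geometry_key(spec)
    if key in _template_cache:
        return _template_cache[key]
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    x = (np.arange(nx) * sx)[:, None, None]
    y = (np.arange(ny) * sy)[None, :, None]
    z = (np.arange(nz) * sz)[None, None, :]
    fov = (nx * sx, ny * sy, nz * sz)
    cx, cy = fov[0] / 2.0, fov[1] / 2.0

    rx, ry = spec.body_semiaxes
    body = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    body = np.broadcast_to(body, spec.shape).copy()

    lcx, lcy, lcz = (f * d for f, d in zip(spec.liver_center_frac, fov))
    la, lb, lc = spec.liver_semiaxes
    liver = (((x - lcx) / la) ** 2 + ((y - lcy) / lb) ** 2 + ((z - lcz) / lc) ** 2 <= 1.0) & body

    spine_y = cy + spec.spine_offset_y_mm
    spine = ((x - cx) ** 2 + (y - spine_y) ** 2 <= spec.spine_radius_mm**2) & (z >= 0.15 * fov[2]) & (
        z <= 0.95 * fov[2]
    )
    pelvis_z = spec.pelvis_z_frac * fov[2]
    pelvis = ((y - spine_y) ** 2 + (z - pelvis_z) ** 2 <= spec.pelvis_radius_mm**2) & (
        np.abs(x - cx) <= 0.6 * rx
    )
    bone = (np.broadcast_to(spine, spec.shape) | np.broadcast_to(pelvis, spec.shape)) & body & ~liver

    sampling = spec.spacing
    tpl = {
        "body": body,
        "liver": liver,
        "bone": bone,
        "edt_body": ndimage.distance_transform_edt(body, sampling=sampling),
        "edt_liver": ndimage.distance_transform_edt(liver, sampling=sampling),
        "edt_bone": ndimage.distance_transform_edt(bone, sampling=sampling),
    }
    _template_cache[key] = tpl
    return tpl


# ---------------------------------------------------------------------------
# Lesion placement and painting


def _place_lesion(
    rng: np.random.Generator,
    spec: PhantomSpec,
    tpl: dict,
    region: str,
    radius_mm: float,
    existing: list[tuple[np.ndarray, float]],
    gap_mm: float,
    max_tries: int = 500,
) -> tuple[int, int, int]:
    """Sample a lesion centre (voxel index) fully inside ``region`` and clear of others."""
    edt = tpl[f"edt_{region}"]
    candidates = np.argwhere(edt >= radius_mm + 0.1)
    if candidates.shape[0] == 0:
        raise RuntimeError(f"no room for a {2 * radius_mm:.0f} mm lesion inside the {region}")
    spacing = np.asarray(spec.spacing)
    for _ in range(max_tries):
        c = candidates[rng.integers(candidates.shape[0])]
        c_mm = c * spacing
        ok = True
        for other_mm, other_r in existing:
            if np.linalg.norm(c_mm - other_mm) <= radius_mm + other_r + gap_mm:
                ok = False
                break
        if ok:
            return tuple(int(v) for v in c)
    raise RuntimeError(f"infeasible lesion placement after {max_tries} retries")


def _paint(
    spec: PhantomSpec,
    tpl: dict,
    lesions: list[dict],
) -> tuple[np.ndarray, np.ndarray, list[LesionTruth]]:
    """Paint the piecewise-constant SUV model; return (suv, gt_mask, truths)."""
    suv = np.zeros(spec.shape, dtype=np.float64)
    suv[tpl["body"]] = spec.background_suv
    suv[tpl["liver"]] = spec.liver_suv
    gt = np.zeros(spec.shape, dtype=bool)
    spacing = np.asarray(spec.spacing)
    truths = []
    for les in lesions:
        c = np.asarray(les["center_idx"])
        r, amp = les["radius_mm"], les["suv"]
        lo = np.maximum(0, np.floor(c - r / spacing).astype(int) - 1)
        hi = np.minimum(np.array(spec.shape) - 1, np.ceil(c + r / spacing).astype(int) + 1)
        sl = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
        grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij")
        d2 = sum(((g - ci) * s) ** 2 for g, ci, s in zip(grids, c, spacing))
        inside = d2 <= r * r
        suv[sl][inside] = amp
        gt[sl][inside] = True
        n = int(np.count_nonzero(inside))
        n_bone = int(np.count_nonzero(inside & tpl["bone"][sl]))
        n_liver = int(np.count_nonzero(inside & tpl["liver"][sl]))
        if n_bone / n > 0.5:
            organ = "bone"
        elif n_liver / n > 0.5:
            organ = "liver"
        else:
            organ = "other"
        truths.append(
            LesionTruth(
                center_idx=tuple(int(v) for v in c),
                radius_mm=float(r),
                suv=float(amp),
                n_voxels=n,
                organ=organ,
                new_at_followup=bool(les.get("new", False)),
            )
        )
    return suv, gt, truths


def _truth_panel(spec: PhantomSpec, tpl: dict, truths: list[LesionTruth]) -> dict[str, float]:
    vv = spec.voxel_volume_ml
    bone_n = int(np.count_nonzero(tpl["bone"]))
    liver_n = int(np.count_nonzero(tpl["liver"]))
    return {
        "mtv_total_ml": sum(t.n_voxels for t in truths) * vv,
        "tlg_total": sum(t.n_voxels * t.suv for t in truths) * vv,
        "pbi_pct": 100.0 * sum(t.n_voxels for t in truths if t.organ == "bone") / bone_n,
        "pli_pct": 100.0 * sum(t.n_voxels for t in truths if t.organ == "liver") / liver_n,
        "n_lesions": float(len(truths)),
    }


def _degrade(spec: PhantomSpec, suv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply the Gaussian PSF and additive noise, clipping at zero."""
    out = suv
    if spec.psf_fwhm_mm > 0:
        sigma = [spec.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s for s in spec.spacing]
        out = ndimage.gaussian_filter(out, sigma=sigma)
    if spec.noise_sd_suv > 0:
        out = out + rng.normal(0.0, spec.noise_sd_suv, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Patient and cohort generation


def _draw_lesions(rng: np.random.Generator, spec: PhantomSpec, tpl: dict) -> list[dict]:
    n = max(1, min(int(rng.poisson(spec.lesion_count_mean)), 15))
    gap = 2.5 * max(spec.spacing)
    d_lo, d_hi = spec.lesion_diameter_mm
    caps = {"bone": spec.spine_radius_mm - 2.0, "liver": min(spec.liver_semiaxes) / 2.0, "body": d_hi / 2.0}
    lesions: list[dict] = []
    placed: list[tuple[np.ndarray, float]] = []
    for i in range(n):
        region = spec.organ_lesion_order[i] if i < len(spec.organ_lesion_order) else "body"
        r = float(np.clip(rng.uniform(d_lo, d_hi) / 2.0, d_lo / 2.0, caps.get(region, d_hi / 2.0)))
        amp = float(rng.uniform(*spec.lesion_suv))
        center = _place_lesion(rng, spec, tpl, region, r, placed, gap)
        lesions.append({"center_idx": center, "radius_mm": r, "suv": amp})
        placed.append((np.asarray(center) * np.asarray(spec.spacing), r))
    return lesions


def _followup_lesions(
    rng: np.random.Generator,
    spec: PhantomSpec,
    tpl: dict,
    baseline: list[dict],
    suv_factor: float,
    volume_factor: float,
    add_new: bool,
) -> list[dict]:
    """Scale baseline lesions by the response factors; drop resolved ones."""
    out = []
    placed = []
    min_r = min(spec.spacing) / 2.0
    for les in baseline:
        amp_fu = les["suv"] * suv_factor
        r_fu = les["radius_mm"] * volume_factor ** (1.0 / 3.0)
        c = les["center_idx"]
        local_bg = spec.liver_suv if tpl["liver"][c] else spec.background_suv
        if amp_fu <= local_bg + 0.3 or r_fu < min_r:
            continue  # lesion resolved below detectable contrast
        out.append({"center_idx": c, "radius_mm": r_fu, "suv": amp_fu})
        placed.append((np.asarray(c) * np.asarray(spec.spacing), r_fu))
    if add_new:
        r = float(rng.uniform(4.0, 12.0))
        amp = float(rng.uniform(3.0, 8.0))
        center = _place_lesion(rng, spec, tpl, "body", r, placed, 2.5 * max(spec.spacing))
        out.append({"center_idx": center, "radius_mm": r, "suv": amp, "new": True})
    return out


def generate_patient(
    spec: PhantomSpec,
    seed: int | np.random.SeedSequence,
    patient_id: str = "P000",
    responder: Optional[bool] = None,
) -> tuple[PatientTimeline, PhantomTruth]:
    """Generate one baseline + follow-up phantom pair with exact ground truth.

    The same seed reproduces the patient bit-for-bit.  ``responder``
    overrides the planted class (drawn from ``responder_fraction`` when
    None), which :func:`generate_cohort` uses to plant exact class counts.
    """
    rng = np.random.default_rng(seed)
    tpl = _template(spec)

    weight = float(np.clip(rng.normal(70.0, 12.0), 45.0, 110.0))
    height = float(np.clip(rng.normal(1.65, 0.07), 1.45, 1.90))
    activity_bq = 4.0e6 * weight  # nominal 4 MBq/kg injection

    if responder is None:
        responder = bool(rng.random() < spec.responder_fraction)

    baseline_lesions = _draw_lesions(rng, spec, tpl)

    add_new = False
    if responder:
        suv_f = float(rng.uniform(*spec.responder_suv_factor))
        vol_f = float(rng.uniform(*spec.responder_volume_factor))
        if rng.random() < spec.cr_probability:
            suv_f, vol_f = 0.0, 0.0  # complete resolution
    else:
        suv_f = float(rng.uniform(*spec.nonresponder_suv_factor))
        vol_f = float(rng.uniform(*spec.nonresponder_volume_factor))
        if suv_f < 1.3 and rng.random() < spec.new_lesion_probability:
            add_new = True
            suv_f = max(suv_f, 1.0)  # progression by new disease never shrinks the rest

    fu_lesions = _followup_lesions(rng, spec, tpl, baseline_lesions, suv_f, vol_f, add_new)

    if responder:
        percist = Percist.CR if not fu_lesions else Percist.PR
    else:
        percist = Percist.PD if (add_new or suv_f >= 1.3) else Percist.SD

    suv_bl, gt_bl, truths_bl = _paint(spec, tpl, baseline_lesions)
    suv_fu, gt_fu, truths_fu = _paint(spec, tpl, fu_lesions)
    suv_bl = _degrade(spec, suv_bl, rng)
    suv_fu = _degrade(spec, suv_fu, rng)

    def acq(values, gt, timepoint, percist_label):
        meta = AcquisitionMeta(
            patient_id=patient_id,
            timepoint=timepoint,
            injected_activity_bq=activity_bq,
            weight_kg=weight,
            height_m=height,
            sex=Sex.FEMALE,
            percist=percist_label,
        )
        vol = ImageVolume(values=values, spacing=spec.spacing, value_kind=ValueKind.SUV_BW)
        mask = BinaryMask(values=gt, spacing=spec.spacing)
        return Acquisition(pet=vol, mask=mask, meta=meta)

    timeline = PatientTimeline(
        baseline=acq(suv_bl, gt_bl, Timepoint.BL, None),
        followups=[acq(suv_fu, gt_fu, Timepoint.FU1, percist)],
        organ_masks={
            "bone": BinaryMask(values=tpl["bone"], spacing=spec.spacing),
            "liver": BinaryMask(values=tpl["liver"], spacing=spec.spacing),
        },
    )
    truth = PhantomTruth(
        patient_id=patient_id,
        responder=responder,
        percist=percist,
        suv_factor=suv_f,
        volume_factor=vol_f,
        lesions={"BL": truths_bl, "FU1": truths_fu},
        panels={
            "BL": _truth_panel(spec, tpl, truths_bl),
            "FU1": _truth_panel(spec, tpl, truths_fu),
        },
    )
    return timeline, truth


def iter_cohort(
    spec: PhantomSpec,
    n_patients: int,
    seed: int,
):
    """Stream a cohort patient by patient, with exact planted class counts.

    ``round(responder_fraction * n_patients)`` patients are planted as
    responders; the assignment order is a seeded permutation and each
    patient is generated from an independently spawned substream, so the
    cohort is reproducible from (spec, n, seed) alone.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients + 1)
    master = np.random.default_rng(children[0])
    n_resp = int(round(spec.responder_fraction * n_patients))
    flags = np.zeros(n_patients, dtype=bool)
    flags[:n_resp] = True
    flags = master.permutation(flags)
    for i in range(n_patients):
        yield generate_patient(spec, children[i + 1], patient_id=f"P{i:03d}", responder=bool(flags[i]))


def generate_cohort(
    spec: PhantomSpec,
    n_patients: int,
    seed: int,
) -> list[tuple[PatientTimeline, PhantomTruth]]:
    """Materialised form of :func:`iter_cohort` (small cohorts only)."""
    return list(iter_cohort(spec, n_patients, seed))


# ---------------------------------------------------------------------------
# On-disk cohort layout


def write_cohort(cohort: list[tuple[PatientTimeline, PhantomTruth]], out_dir: str | Path) -> pd.DataFrame:
    """Write a NIfTI tree plus manifest.csv and truth.csv; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for timeline, truth in cohort:
        pid = timeline.patient_id
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        bone_path = pdir / "bone.nii.gz"
        liver_path = pdir / "liver.nii.gz"
        write_mask(timeline.organ_masks["bone"], bone_path)
        write_mask(timeline.organ_masks["liver"], liver_path)
        for a in [timeline.baseline, *timeline.followups]:
            tp = a.meta.timepoint.value
            pet_path = pdir / f"{tp}_pet.nii.gz"
            mask_path = pdir / f"{tp}_mask.nii.gz"
            write_volume(a.pet, pet_path)
            write_mask(a.mask, mask_path)
            rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "pet_path": str(pet_path),
                    "mask_path": str(mask_path),
                    "bone_path": str(bone_path),
                    "liver_path": str(liver_path),
                    "value_kind": a.pet.value_kind.value,
                    "injected_activity_MBq": a.meta.injected_activity_bq / 1e6,
                    "weight_kg": a.meta.weight_kg,
                    "height_m": a.meta.height_m,
                    "sex": a.meta.sex.value,
                    "percist": "" if a.meta.percist is None else a.meta.percist.value,
                }
            )
        for tp, panel in truth.panels.items():
            truth_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "responder": truth.responder,
                    "percist": truth.percist.value,
                    "suv_factor": truth.suv_factor,
                    "volume_factor": truth.volume_factor,
                    **panel,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return manifest
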