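"""Standardized uptake value normalisations.

Activity concentration images are normalised either by total body weight
(SUVbw) or by Janmahasatian lean body mass (SUL), the quantity used by
PERCIST because it is less biased by adipose tissue than body weight.
Clipping to [0, 5] is provided only to emulate segmentation-network input
preprocessing; biomarkers are always computed on unclipped images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import AcquisitionMeta, ImageVolume, Sex, ValueKind


@dataclass(frozen=True)
class BodyComposition:
    bmi: float  # kg/m^2
    lbm: float  # kg


def lean_body_mass(weight_kg: float, height_m: float, sex: Sex | str) -> float:
    """Janmahasatian lean body mass in kg.

    female: 9270·W / (8780 + 244·BMI)
    male:   9270·W / (6680 + 216·BMI),  BMI = W / H².
    """
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be > 0")
    bmi = weight_kg / height_m**2
    if Sex(sex) == Sex.FEMALE:
        return 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)
    return 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)


def body_composition(meta: AcquisitionMeta) -> BodyComposition:
    return BodyComposition(
        bmi=meta.weight_kg / meta.height_m**2,
        lbm=lean_body_mass(meta.weight_kg, meta.height_m, meta.sex),
    )


def _require_kind(vol: ImageVolume, *kinds: ValueKind) -> None:
    if vol.value_kind not in kinds:
        raise ValueError(f"expected value_kind in {[k.value for k in kinds]}, got {vol.value_kind.value}")


def to_suv_bw(pet: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Convert an activity-concentration image (Bq/mL) to SUVbw.

    SUV = C · weight(g) / injected_activity(Bq); the injected activity is
    assumed decay-corrected to scan start.
    """
    _require_kind(pet, ValueKind.ACTIVITY)
    factor = meta.weight_kg * 1000.0 / meta.injected_activity_bq
    return ImageVolume(
        values=np.asarray(pet.values, dtype=np.float64) * factor,
        spacing=pet.spacing,
        origin=pet.origin,
        value_kind=ValueKind.SUV_BW,
    )


def to_sul(pet: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Convert an activity-concentration image (Bq/mL) to SUL (lean-mass SUV)."""
    _require_kind(pet, ValueKind.ACTIVITY)
    lbm = lean_body_mass(meta.weight_kg, meta.height_m, meta.sex)
    factor = lbm * 1000.0 / meta.injected_activity_bq
    return ImageVolume(
        values=np.asarray(pet.values, dtype=np.float64) * factor,
        spacing=pet.spacing,
        origin=pet.origin,
        value_kind=ValueKind.SUL,
    )


def suv_bw_to_sul(suv: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Rescale an SUVbw image to SUL via the constant ratio lbm/weight."""
    _require_kind(suv, ValueKind.SUV_BW)
    ratio = lean_body_mass(meta.weight_kg, meta.height_m, meta.sex) / meta.weight_kg
    return ImageVolume(
        values=np.asarray(suv.values, dtype=np.float64) * ratio,
        spacing=suv.spacing,
        origin=suv.origin,
        value_kind=ValueKind.SUL,
    )


def suv_bw_to_activity(suv: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Invert :func:`to_suv_bw`: recover activity concentration in Bq/mL."""
    _require_kind(suv, ValueKind.SUV_BW)
    factor = meta.injected_activity_bq / (meta.weight_kg * 1000.0)
    return ImageVolume(
        values=np.asarray(suv.values, dtype=np.float64) * factor,
        spacing=suv.spacing,
        origin=suv.origin,
        value_kind=ValueKind.ACTIVITY,
    )


def clip_suv(vol: ImageVolume, lo: float = 0.0, hi: float = 5.0) -> ImageVolume:
    """Clip an SUV/SUL image to [lo, hi].

    This emulates network input preprocessing only; never apply it before
    biomarker computation (hot lesions routinely exceed SUV 5).
    """
    _require_kind(vol, ValueKind.SUV_BW, ValueKind.SUL)
    if lo >= hi:
        raise ValueError(f"invalid clip range [{lo}, {hi}]")
    return ImageVolume(
        values=np.clip(vol.values, lo, hi),
        spacing=vol.spacing,
        origin=vol.origin,
        value_kind=vol.value_kind,
    )
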