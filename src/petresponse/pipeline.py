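"""End-to-end study replica on a synthetic cohort.

For every patient the pipeline computes the four-biomarker panel on two
segmentation routes: the exact ground-truth lesion masks ("reference",
standing in for expert manual segmentation) and a fixed-threshold
SUV ≥ 2.5 segmentation ("automatic", a classical stand-in for a trained
network).  From the panels it derives percent changes between baseline
and each follow-up, assesses treatment response against the planted
PERCIST categories (ROC, AUC, Youden cutoff, Mann–Whitney, DeLong), and
quantifies agreement between the two routes (Lin's CCC, Spearman,
Wilcoxon).  Segmentation quality of the automatic route is summarised
with mean/global Dice and 50 %-overlap detection counts.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import biomarkers as bm
from . import response_stats as rs
from . import segeval
from .io_core import BinaryMask, ImageVolume, PatientTimeline, ValueKind, logger
from .phantom import PhantomSpec, PhantomTruth, iter_cohort
from .suv import suv_bw_to_sul

BIOMARKER_NAMES = ("sul_peak", "mtv_total_ml", "tlg_total", "pbi_pct", "pli_pct")
DELTA_NAMES = {"sul_peak": "d_sulpeak", "tlg_total": "d_tlg", "pbi_pct": "d_pbi", "pli_pct": "d_pli"}


@dataclass
class PipelineConfig:
    """Study configuration; the defaults reproduce the method's constants
    (1.2 cm SULpeak sphere, 50 % detection overlap, significance 0.001)."""

    out_dir: Optional[str] = None
    n_patients: int = 20
    seed: int = 0
    connectivity: int = 26
    sphere_diameter_mm: float = 12.0
    overlap_threshold: float = 0.5
    organ_majority: float = 0.5
    alpha: float = 0.001
    seg_threshold_suv: float = 2.5
    seg_min_voxels: int = 2
    automatic_route: bool = True  # also segment by threshold and compare against the reference masks
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def to_dict(self) -> dict:
        # out_dir is a deployment detail, not part of the scientific
        # configuration: identical studies written to two directories
        # must produce byte-identical bundles
        d = asdict(self)
        d.pop("out_dir", None)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.pop("phantom", {}).items()})
        return cls(phantom=phantom, **raw)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:12]


def threshold_segmentation(
    suv: ImageVolume,
    threshold: float = 2.5,
    min_voxels: int = 2,
    connectivity: int = 26,
) -> BinaryMask:
    """Classical SUV-threshold lesion segmentation (malignancy threshold 2.5).

    Components smaller than ``min_voxels`` are discarded as noise
    speckle.  Used by the pipeline as the automatic segmentation route.
    """
    mask = np.asarray(suv.values) >= threshold
    if min_voxels > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=bm._STRUCTURES[connectivity])
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= min_voxels
        mask = keep[labels]
    return BinaryMask(values=mask, spacing=suv.spacing, origin=suv.origin)


def panel_value(panel_record: dict, biomarker: str) -> float:
    """Scalar value of a biomarker from a panel record; undefined SULpeak reads 0
    (an empty segmentation means no measurable disease)."""
    if biomarker == "sul_peak" and not panel_record.get("sul_peak_defined", True):
        return 0.0
    return float(panel_record[biomarker])


def iter_phantom_cohort(
    spec: PhantomSpec, n_patients: int, seed: int
) -> Iterator[tuple[PatientTimeline, PhantomTruth]]:
    """Stream a seeded cohort patient by patient (exact planted class counts)."""
    return iter_cohort(spec, n_patients, seed)


@dataclass
class StudyReport:
    config: PipelineConfig
    panels: pd.DataFrame
    deltas: pd.DataFrame
    response: pd.DataFrame
    concordance: pd.DataFrame
    segmentation: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("panels", "deltas", "response", "concordance", "segmentation"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "run.json").write_text(
            json.dumps({"config": self.config.to_dict(), "config_hash": self.config.config_hash()},
                       indent=2, default=str)
        )


def _acquisition_rows(config: PipelineConfig, timeline: PatientTimeline) -> tuple[list[dict], list[dict], list[dict]]:
    """Panels (both routes), per-acquisition Dice/detection, for one patient."""
    panel_rows, seg_rows = [], []
    bone = timeline.organ_masks["bone"]
    liver = timeline.organ_masks["liver"]
    for acq in [timeline.baseline, *timeline.followups]:
        suv = acq.pet
        if suv.value_kind != ValueKind.SUV_BW:
            raise ValueError("pipeline expects phantom volumes in SUVbw space")
        sul = suv_bw_to_sul(suv, acq.meta)
        routes = [("reference", acq.mask)]
        if config.automatic_route:
            pred = threshold_segmentation(suv, config.seg_threshold_suv, config.seg_min_voxels, config.connectivity)
            routes.append(("automatic", pred))
        for source, mask in routes:
            panel = bm.biomarker_panel(
                sul, suv, mask, bone, liver,
                connectivity=config.connectivity,
                sphere_diameter_mm=config.sphere_diameter_mm,
                majority=config.organ_majority,
            )
            panel_rows.append(
                {
                    "patient_id": acq.meta.patient_id,
                    "timepoint": acq.meta.timepoint.value,
                    "source": source,
                    "percist": "" if acq.meta.percist is None else acq.meta.percist.value,
                    **panel.as_record(),
                }
            )
        if config.automatic_route:
            det = segeval.detection_counts(acq.mask, pred, config.overlap_threshold, config.connectivity)
            seg_rows.append(
                {
                    "patient_id": acq.meta.patient_id,
                    "timepoint": acq.meta.timepoint.value,
                    "dice": segeval.dice(acq.mask, pred),
                    "gt_voxels": int(np.count_nonzero(acq.mask.values)),
                    "pred_voxels": int(np.count_nonzero(pred.values)),
                    "inter_voxels": int(np.count_nonzero(acq.mask.values & pred.values)),
                    "tp": det.tp,
                    "fn": det.fn,
                    "fp": det.fp,
                }
            )
    return panel_rows, seg_rows, []


def compute_deltas(panels: pd.DataFrame) -> pd.DataFrame:
    """Percent change of each biomarker between baseline and every follow-up."""
    rows = []
    for (pid, source), grp in panels.groupby(["patient_id", "source"], sort=True):
        bl = grp[grp.timepoint == "BL"]
        if bl.empty:
            raise ValueError(f"patient {pid} has no baseline panel")
        bl = bl.iloc[0]
        for _, fu in grp[grp.timepoint != "BL"].iterrows():
            row = {"patient_id": pid, "timepoint": fu.timepoint, "source": source, "percist": fu.percist}
            for biomarker, dname in DELTA_NAMES.items():
                d = rs.delta(panel_value(bl, biomarker), panel_value(fu, biomarker))
                row[dname] = d.value
                row[f"{dname}_flag"] = d.flag or ""
            rows.append(row)
    return pd.DataFrame(rows)


def assess_response(deltas: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Per-biomarker ROC/AUC, Youden cutoff and group tests, per panel source."""
    if deltas.empty:
        raise ValueError("no follow-up acquisitions: response assessment needs at least one Δ per patient")
    rows = []
    for source, grp in deltas.groupby("source", sort=True):
        labels = grp.percist.astype(str)
        if labels.eq("").any():
            raise ValueError("every follow-up needs a PERCIST category for response assessment")
        responder = np.array([rs.binarize_percist(v) for v in labels])
        if responder.all() or not responder.any():
            raise ValueError("response assessment needs both responders and non-responders in the cohort")
        ref_deltas = grp[DELTA_NAMES["sul_peak"]].to_numpy()
        for biomarker, dname in DELTA_NAMES.items():
            d = grp[dname].to_numpy()
            roc = rs.roc(d, responder)
            cut = rs.youden_cutoff(roc)
            mw_p = rs.mann_whitney(d[responder], d[~responder])
            delong = rs.delong_test(d, ref_deltas, responder)
            rows.append(
                {
                    "source": source,
                    "biomarker": dname,
                    "auc": roc.auc,
                    "cutoff_pct": cut.cutoff,
                    "sensitivity": cut.sensitivity,
                    "specificity": cut.specificity,
                    "youden_j": cut.j,
                    "mann_whitney_p": mw_p,
                    "mann_whitney_significant": mw_p <= alpha,
                    "delong_p_vs_sulpeak": delong.p,
                    "n_responder": int(responder.sum()),
                    "n_nonresponder": int((~responder).sum()),
                }
            )
    return pd.DataFrame(rows)


def compute_concordance(panels: pd.DataFrame) -> pd.DataFrame:
    """Agreement between reference and automatic panels, per biomarker."""
    ref = panels[panels.source == "reference"].set_index(["patient_id", "timepoint"]).sort_index()
    auto = panels[panels.source == "automatic"].set_index(["patient_id", "timepoint"]).sort_index()
    rows = []
    for biomarker in BIOMARKER_NAMES:
        x = np.array([panel_value(r, biomarker) for _, r in ref.iterrows()])
        y = np.array([panel_value(r, biomarker) for _, r in auto.iterrows()])
        res = rs.concordance(x, y)
        rows.append(
            {
                "biomarker": biomarker,
                "lin_ccc": res.ccc,
                "spearman_rho": res.spearman_rho,
                "wilcoxon_p": res.wilcoxon_p,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def summarize_segmentation(seg_rows: pd.DataFrame) -> pd.DataFrame:
    """Per-acquisition rows plus a pooled summary row (Dice and detection)."""
    per = seg_rows.copy()
    dice_scores = per.dice.to_numpy()
    global_dice = (
        1.0
        if (per.gt_voxels.sum() + per.pred_voxels.sum()) == 0
        else 2.0 * per.inter_voxels.sum() / (per.gt_voxels.sum() + per.pred_voxels.sum())
    )
    tp, fn, fp = int(per.tp.sum()), int(per.fn.sum()), int(per.fp.sum())
    summary = {
        "patient_id": "ALL",
        "timepoint": "ALL",
        "dice": float(dice_scores.mean()),
        "dice_sd": float(dice_scores.std(ddof=1)) if len(dice_scores) > 1 else 0.0,
        "global_dice": float(global_dice),
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "recall": tp / (tp + fn) if tp + fn else math.nan,
        "precision": tp / (tp + fp) if tp + fp else math.nan,
    }
    per["dice_sd"] = np.nan
    per["global_dice"] = np.nan
    per["recall"] = np.nan
    per["precision"] = np.nan
    return pd.concat([per, pd.DataFrame([summary])], ignore_index=True)


def run_study(config: PipelineConfig, write: bool | None = None) -> StudyReport:
    """Run the full replica: phantom cohort → panels → Δ → response + agreement.

    Patients are processed one at a time so cohort size is limited by
    time, not memory.  With ``write`` (default: when ``config.out_dir``
    is set) the report bundle is written as CSVs plus a run log.
    """
    t0 = time.time()
    panel_rows: list[dict] = []
    seg_rows: list[dict] = []
    failures: list[str] = []
    for timeline, _truth in iter_phantom_cohort(config.phantom, config.n_patients, config.seed):
        try:
            p_rows, s_rows, _ = _acquisition_rows(config, timeline)
            panel_rows.extend(p_rows)
            seg_rows.extend(s_rows)
        except Exception as exc:  # collect, do not silently drop
            failures.append(f"{timeline.patient_id}: {exc}")
    if failures:
        raise RuntimeError("pipeline failed on patients: " + "; ".join(failures))
    logger.info("panels computed for %d patients in %.1fs", config.n_patients, time.time() - t0)

    panels = pd.DataFrame(panel_rows)
    deltas = compute_deltas(panels)
    response = assess_response(deltas, config.alpha)
    if config.automatic_route:
        concord = compute_concordance(panels)
        seg = summarize_segmentation(pd.DataFrame(seg_rows))
    else:
        concord = pd.DataFrame()
        seg = pd.DataFrame()
    report = StudyReport(
        config=config, panels=panels, deltas=deltas, response=response, concordance=concord, segmentation=seg
    )
    if write is None:
        write = config.out_dir is not None
    if write:
        if config.out_dir is None:
            raise ValueError("write requested but config.out_dir is not set")
        report.write(config.out_dir)
        logger.info("report bundle written to %s (config %s)", config.out_dir, config.config_hash())
    return report
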