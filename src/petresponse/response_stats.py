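"""Longitudinal response assessment and agreement statistics.

The change of a biomarker between baseline and follow-up is expressed as
a percentage, Δ = 100·(FU − BL)/BL.  PERCIST expert categories are
binarised (CR/PR → responder, SD/PD → non-responder) and each observed Δ
is evaluated as a candidate decision threshold: a patient is called a
responder when Δ ≤ threshold, since response manifests as a *decrease*.
The resulting ROC curve, its AUC, the Youden-optimal cutoff and the
DeLong test for paired AUCs quantify each biomarker's discriminative
power; Lin's concordance correlation, Spearman rank correlation and the
usual nonparametric tests quantify agreement between two measurement
routes of the same biomarker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .io_core import Percist, logger


class DeltaValue(NamedTuple):
    """Percent change with a degenerate-baseline flag.

    ``flag`` is ``None`` for the regular case, ``"zero_baseline"`` when
    BL = FU = 0 (Δ defined as 0) and ``"new_disease"`` when BL = 0 but
    FU > 0 (Δ is a +inf sentinel: disease appeared where none was
    measured at baseline).
    """

    value: float
    flag: Optional[str]


def delta(bl: float, fu: float) -> DeltaValue:
    """Percent change 100·(FU − BL)/BL with an explicit zero-baseline policy."""
    if bl < 0 or fu < 0:
        raise ValueError("biomarker values must be non-negative")
    if bl == 0:
        if fu == 0:
            return DeltaValue(0.0, "zero_baseline")
        return DeltaValue(math.inf, "new_disease")
    return DeltaValue(100.0 * (fu - bl) / bl, None)


def binarize_percist(label: Percist | str) -> bool:
    """CR/PR → responder (True); SD/PD → non-responder (False)."""
    label = Percist(label)
    return label in (Percist.CR, Percist.PR)


@dataclass
class ROCResult:
    """ROC over the observed Δ values, responders as the positive class."""

    thresholds: np.ndarray  # ascending; leading -inf sentinel
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc(deltas: Sequence[float], responder: Sequence[bool]) -> ROCResult:
    """ROC curve using every observed Δ as a candidate threshold.

    A subject is called a responder when its Δ is less than or equal to
    the threshold, so the true/false positive rates are the responder and
    non-responder fractions at or below each observed value.  The AUC is
    the trapezoidal area, identical to the Mann–Whitney concordance
    estimate.
    """
    d = np.asarray(deltas, dtype=np.float64)
    y = np.asarray(responder, dtype=bool)
    if d.shape != y.shape:
        raise ValueError("deltas and responder flags must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both responders and non-responders")
    thresholds = np.concatenate([[-np.inf], np.unique(d)])
    tpr = np.array([np.count_nonzero(d[y] <= t) / n_pos for t in thresholds])
    fpr = np.array([np.count_nonzero(d[~y] <= t) / n_neg for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    j: float


def youden_cutoff(roc_result: ROCResult) -> CutoffResult:
    """Operating point maximising Youden's J = sensitivity + specificity − 1.

    Only observed Δ values are candidate cutoffs; ties on J are broken
    toward the most negative Δ, the most conservative responder call.
    """
    sens = roc_result.tpr
    spec = 1.0 - roc_result.fpr
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first maximum = most negative threshold
    cutoff = roc_result.thresholds[best]
    if not np.isfinite(cutoff):  # J maximal only at the sentinel: no discrimination
        best = 1 if len(j) > 1 else 0
        cutoff = roc_result.thresholds[best]
    return CutoffResult(
        cutoff=float(cutoff),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        j=float(j[best]),
    )


def classify_response(delta_pct: float, cutoff: float) -> bool:
    """Responder iff Δ ≤ cutoff (boundary inclusive); +inf (new disease) → non-responder."""
    return bool(delta_pct <= cutoff)


class DelongResult(NamedTuple):
    z: float
    p: float
    auc_a: float
    auc_b: float


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components for one marker (higher score = positive)."""
    pos, neg = scores[y], scores[~y]
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    gt = (pos[:, None] > neg[None, :]).astype(np.float64)
    eq = (pos[:, None] == neg[None, :]).astype(np.float64)
    psi = gt + 0.5 * eq
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_test(
    deltas_a: Sequence[float],
    deltas_b: Sequence[float],
    responder: Sequence[bool],
) -> DelongResult:
    """Paired DeLong test comparing the AUCs of two biomarkers on the same subjects.

    Uses the placement-value (structural component) covariance estimate
    and a two-sided normal approximation.  Comparing a biomarker with
    itself gives z = 0, p = 1.
    """
    da = np.asarray(deltas_a, dtype=np.float64)
    db = np.asarray(deltas_b, dtype=np.float64)
    y = np.asarray(responder, dtype=bool)
    if not (da.shape == db.shape == y.shape):
        raise ValueError("paired design requires equal-length inputs")
    if y.all() or not y.any():
        raise ValueError("DeLong test needs both responders and non-responders")

    # lower Δ indicates response, so score = -Δ orients responders high
    v10a, v01a, auc_a = _placements(-da, y)
    v10b, v01b, auc_b = _placements(-db, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var = float(s[0, 0] + s[1, 1] - 2.0 * s[0, 1])
    diff = auc_a - auc_b
    if var <= 0 or np.isclose(diff, 0.0):
        z = 0.0 if np.isclose(diff, 0.0) else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return DelongResult(z=float(z), p=float(p), auc_a=auc_a, auc_b=auc_b)


@dataclass
class ConcordanceResult:
    ccc: float
    spearman_rho: float
    wilcoxon_p: float
    n: int


def lin_ccc(x: Sequence[float], y: Sequence[float], sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2·cov(x,y) / (var x + var y + (mean x − mean y)²), with
    population (biased) moments as in Lin's original estimator; set
    ``sample_moments`` for the n−1 variant.  Measures agreement with the
    identity line, not just correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("lin_ccc needs two equal-length samples with n >= 2")
    ddof = 1 if sample_moments else 0
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    cov = np.cov(x, y, ddof=ddof)[0, 1]
    mean_gap = (x.mean() - y.mean()) ** 2
    denom = vx + vy + mean_gap
    if denom == 0:  # both constant with equal means: perfect agreement by continuity
        logger.warning("lin_ccc: zero variance in both samples with equal means; returning 1.0")
        return 1.0
    return float(2.0 * cov / denom)


def concordance(x: Sequence[float], y: Sequence[float]) -> ConcordanceResult:
    """Agreement summary between two measurement routes of one biomarker."""
    return ConcordanceResult(
        ccc=lin_ccc(x, y),
        spearman_rho=spearman(x, y),
        wilcoxon_p=wilcoxon_signed_rank(x, y),
        n=len(np.asarray(x)),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks for ties)."""
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value; zero differences dropped.

    All-zero differences are degenerate: returns NaN with a warning.
    """
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    if np.all(d == 0):
        logger.warning("wilcoxon_signed_rank: all differences are zero; p undefined")
        return float("nan")
    return float(stats.wilcoxon(d[d != 0], alternative="two-sided").pvalue)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann–Whitney U p-value between two independent samples."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def ks_normality(x: Sequence[float]) -> float:
    """Kolmogorov–Smirnov p-value against a normal with the sample's moments."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("ks_normality needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)
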