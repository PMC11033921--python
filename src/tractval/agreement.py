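"""Exploratory agreement statistics between tractograms and DES outcomes.

Distances behave like a screening-test score with *small* values indicating a
positive (eloquent) site, so the decision rule throughout is
``distance <= threshold  =>  predicted positive``. Candidate thresholds are
midpoints between consecutive unique distances (plus -inf/+inf sentinels);
on integer distances this yields the half-integer cutoffs (5.5, 12.5, 13.5 mm
and so on) that make the <= vs < choice immaterial.

To remedy the bias toward patients contributing many stimulation sites,
the headline ROC pathway first averages distances per patient per DES
response type (:func:`average_per_patient`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCCurve",
    "ConfusionSummary",
    "DeLongResult",
    "average_per_patient",
    "roc_curve",
    "youden_cutoff",
    "confusion_at_cutoff",
    "delong_test",
]


def _as_binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "USO":
        return lab == "positive"
    return lab.astype(bool)


@dataclass
class ROCCurve:
    """ROC over distance thresholds, positive class = pDES.

    ``sensitivity[t]`` is the fraction of positives with distance <= threshold,
    ``specificity[t]`` the fraction of negatives with distance > threshold.
    AUC is the trapezoidal area over (1 - specificity, sensitivity), which
    equals the tie-corrected Mann-Whitney statistic U/(n_pos * n_neg).
    Per-case data are retained for DeLong comparisons.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    distances: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(t) for t in self.thresholds],
            "sensitivity": [float(s) for s in self.sensitivity],
            "specificity": [float(s) for s in self.specificity],
            "auc": float(self.auc),
            "n_pos": int(self.n_pos),
            "n_neg": int(self.n_neg),
        }


def roc_curve(distances: Sequence[float], labels) -> ROCCurve:
    """ROC curve of distance-to-tractogram as a predictor of DES positivity."""
    d = np.asarray(distances, dtype=float)
    pos = _as_binary_labels(labels)
    if d.shape != pos.shape:
        raise ValueError("distances and labels must align")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve requires both classes present")
    uniq = np.unique(d)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    sens = (d[pos][:, None] <= thresholds[None, :]).mean(axis=0)
    spec = (d[~pos][:, None] > thresholds[None, :]).mean(axis=0)
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return ROCCurve(thresholds, sens, spec, auc, n_pos, n_neg, d, pos)


def youden_cutoff(roc: ROCCurve) -> float:
    """The finite threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smaller cutoff (the more conservative surgical
    margin). On integer distances this returns half-integer cutoffs.
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ValueError("no finite candidate thresholds (all distances equal)")
    j = roc.sensitivity[finite] + roc.specificity[finite] - 1.0
    thr = roc.thresholds[finite]
    # ties (within float noise of the max) break toward the smaller cutoff
    near_max = j >= j.max() - 1e-9
    return float(thr[near_max].min())


@dataclass
class ConfusionSummary:
    """2x2 agreement counts at a distance cutoff plus the five percentage
    summaries. Percentages are kept at full precision; round for display."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.fp + self.tn)

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    def summary_row(self, ndigits: int = 1) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": round(self.accuracy, ndigits),
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "ppv": round(self.ppv, ndigits),
            "npv": round(self.npv, ndigits),
        }


def confusion_at_cutoff(distances: Sequence[float], labels, cutoff_mm: float) -> ConfusionSummary:
    """Binary agreement at a cutoff: pairs with distance <= cutoff are
    predicted positive (true positives for pDES, false positives for nDES);
    pairs exceeding it are predicted negative."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("confusion_at_cutoff requires nonempty input")
    pos = _as_binary_labels(labels)
    pred = d <= cutoff_mm
    return ConfusionSummary(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def average_per_patient(
    records: pd.DataFrame,
    by: Sequence[str] = ("patient_id", "method", "bundle", "response"),
) -> pd.DataFrame:
    """Mean distance within each grouping cell (real-valued, no re-rounding).

    The default grouping keeps methods separate; pass
    ``by=("patient_id", "response")`` to pool methods for the headline
    patient-averaged ROC.
    """
    if len(records) == 0:
        raise ValueError("average_per_patient requires nonempty input")
    out = (
        records.groupby(list(by), as_index=False, observed=True)["distance_mm"]
        .mean()
        .rename(columns={"distance_mm": "distance_mm"})
    )
    return out


# ---------------------------------------------------------------------------
# DeLong AUC comparison
# ---------------------------------------------------------------------------

@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    auc_diff: float
    variance: float
    z: float
    p: float
    paired: bool
    n_dropped: int = 0


def _placements(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """DeLong placement values with mid-rank tie handling."""
    psi = (
        (scores_pos[:, None] > scores_neg[None, :]).astype(float)
        + 0.5 * (scores_pos[:, None] == scores_neg[None, :])
    )
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def _single_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_test(
    distances_a: Sequence[float],
    distances_b: Sequence[float],
    labels,
    labels_b=None,
    *,
    paired: bool = True,
) -> DeLongResult:
    """DeLong comparison of two AUCs for distance-based prediction of pDES.

    In paired mode the two methods must score the *same* cases (equal-length,
    case-aligned arrays); cases missing (NaN) under either method are dropped
    and counted. In unpaired mode the samples are independent and the variance
    of the AUC difference is the sum of the two single-curve DeLong variances.
    """
    da = np.asarray(distances_a, dtype=float)
    db = np.asarray(distances_b, dtype=float)
    la = _as_binary_labels(labels)
    n_dropped = 0
    if paired:
        if labels_b is not None:
            lb = _as_binary_labels(labels_b)
            if len(lb) != len(la) or not np.array_equal(la, lb):
                raise ValueError("paired DeLong requires identical case sets")
        if da.shape != db.shape or da.shape != la.shape:
            raise ValueError("paired DeLong requires case-aligned arrays")
        keep = np.isfinite(da) & np.isfinite(db)
        n_dropped = int((~keep).sum())
        da, db, la = da[keep], db[keep], la[keep]
        lb = la
    else:
        lb = _as_binary_labels(labels_b) if labels_b is not None else la
        keep_a = np.isfinite(da)
        keep_b = np.isfinite(db)
        n_dropped = int((~keep_a).sum() + (~keep_b).sum())
        da, la = da[keep_a], la[keep_a]
        db, lb = db[keep_b], lb[keep_b]
    if la.sum() == 0 or (~la).sum() == 0 or lb.sum() == 0 or (~lb).sum() == 0:
        raise ValueError("delong_test requires both classes present")

    # smaller distance predicts the positive class -> score is -distance
    v10a, v01a, auc_a = _placements(-da[la], -da[~la])
    v10b, v01b, auc_b = _placements(-db[lb], -db[~lb])
    diff = float(auc_a - auc_b)
    if paired:
        m, n = len(v10a), len(v01a)
        s10 = np.var(v10a - v10b, ddof=1) if m > 1 else 0.0
        s01 = np.var(v01a - v01b, ddof=1) if n > 1 else 0.0
        var = s10 / m + s01 / n
    else:
        var = _single_variance(v10a, v01a) + _single_variance(v10b, v01b)
    if var <= 1e-16:
        z = 0.0 if abs(diff) <= 1e-12 else float(np.sign(diff) * np.inf)
    else:
        z = diff / float(np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(float(auc_a), float(auc_b), diff, float(var), float(z), p,
                        paired, n_dropped)
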