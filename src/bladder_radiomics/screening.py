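"""Univariate feature screening on a training cohort.

Each (sequence, feature) pair is compared between muscle-invasive and
non-invasive patients with the Mann-Whitney U-test (asymptotic,
tie-corrected, continuity-corrected — the standard choice at cohort sizes
around 40), followed by empirical ROC analysis and a Youden-index cut-off.
Screening is exploratory: no multiplicity adjustment is applied, the
model-level control being the locked two-feature descriptor evaluated on an
independent cohort.

Orientation is auto-selected per feature so the AUC is always >= 0.5 and is
stored with the result, making downstream cut-offs unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ScreeningError


@dataclass
class RocCurve:
    """Empirical ROC: candidate thresholds with Se/Sp, plus orientation.

    ``orientation`` is ``">"`` (positive if value > c) or ``"<"``.
    Thresholds are the sorted unique observed values; the degenerate
    endpoints (Se, Sp) = (1, 0) and (0, 1) are included.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: str
    degenerate: bool = False


@dataclass
class FeatureScreenResult:
    sequence: str
    feature: str
    n_pos: int
    n_neg: int
    u_statistic: float
    p_value: float
    auc: float
    orientation: str
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    significant: bool

    def to_dict(self) -> dict:
        return asdict(self)


def mann_whitney_u(group_pos, group_neg) -> tuple[float, float]:
    """U statistic (pairs where pos > neg, ties counted 1/2) and two-sided p.

    p-value from the normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(group_pos, dtype=np.float64)
    y = np.asarray(group_neg, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        # all values identical: the tie-corrected variance is 0
        return x.size * y.size / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def empirical_roc(scores_pos, scores_neg) -> RocCurve:
    """Empirical ROC over observed thresholds, oriented so AUC >= 0.5."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    degenerate = np.ptp(np.concatenate([pos, neg])) == 0
    if degenerate:
        warnings.warn("constant scores in both groups: degenerate ROC (AUC = 0.5)")
    u, _ = mann_whitney_u(pos, neg)
    a = u / (pos.size * neg.size)
    orientation = ">" if a >= 0.5 else "<"
    thr = np.unique(np.concatenate([pos, neg]))
    if orientation == ">":
        se = np.array([(pos > c).mean() for c in thr])
        sp = np.array([(neg <= c).mean() for c in thr])
    else:
        se = np.array([(pos < c).mean() for c in thr])
        sp = np.array([(neg >= c).mean() for c in thr])
    # endpoint conventions: everything-positive and everything-negative
    thr = np.concatenate([[-np.inf if orientation == ">" else np.inf], thr])
    se = np.concatenate([[1.0], se])
    sp = np.concatenate([[0.0], sp])
    if not (se[-1] == 0.0 and sp[-1] == 1.0):
        thr = np.concatenate([thr, [np.inf if orientation == ">" else -np.inf]])
        se = np.concatenate([se, [0.0]])
        sp = np.concatenate([sp, [1.0]])
    return RocCurve(thr, se, sp, orientation, degenerate)


def auc(curve_or_pos, scores_neg=None) -> float:
    """AUC via the U identity: A = U / (n_pos * n_neg), oriented >= 0.5.

    Accepts either two score arrays or nothing useful from a curve (the
    curve-based call recomputes from the stored Se/Sp trapezoid, which
    coincides with the U identity for the empirical curve).
    """
    if scores_neg is not None:
        pos = np.asarray(curve_or_pos, dtype=np.float64)
        neg = np.asarray(scores_neg, dtype=np.float64)
        u, _ = mann_whitney_u(pos, neg)
        a = u / (pos.size * neg.size)
        return float(max(a, 1.0 - a))
    curve: RocCurve = curve_or_pos
    fpr = 1.0 - curve.specificity
    order = np.lexsort((curve.sensitivity, fpr))
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float, float]:
    """(cutoff, Se, Sp, J) maximizing J over observed thresholds.

    Ties are broken toward higher specificity, then higher cut-off, so the
    result is deterministic. The infinite endpoint thresholds are excluded
    from the scan.
    """
    finite = np.isfinite(curve.thresholds)
    thr = curve.thresholds[finite]
    se = curve.sensitivity[finite]
    sp = curve.specificity[finite]
    j = se + sp - 1.0
    best = max(range(len(thr)), key=lambda k: (j[k], sp[k], thr[k]))
    return float(thr[best]), float(se[best]), float(sp[best]), float(j[best])


def screen_feature(sequence, feature, values_pos, values_neg, alpha=0.05) -> FeatureScreenResult:
    u, p = mann_whitney_u(values_pos, values_neg)
    curve = empirical_roc(values_pos, values_neg)
    a = u / (len(values_pos) * len(values_neg))
    a = max(a, 1.0 - a)
    c, se, sp, j = youden_cutoff(curve)
    return FeatureScreenResult(
        sequence=sequence,
        feature=feature,
        n_pos=len(values_pos),
        n_neg=len(values_neg),
        u_statistic=u,
        p_value=p,
        auc=a,
        orientation=curve.orientation,
        cutoff=c,
        sensitivity=se,
        specificity=sp,
        youden_j=j,
        significant=bool(p < alpha),
    )


def screen_cohort(feature_table: pd.DataFrame, labels: pd.Series, alpha=0.05) -> pd.DataFrame:
    """Screen every (sequence, feature) column of a tidy feature table.

    ``feature_table`` has one row per patient x sequence with columns
    ``patient_id``, ``sequence`` and one column per feature; ``labels`` maps
    patient_id -> 0/1. Returns one row per (sequence, feature), the
    screening-table analogue, deterministic for fixed input.
    """
    labels = pd.Series(labels)
    if labels.nunique() != 2 or labels.value_counts().min() < 2:
        raise ScreeningError("screening requires >= 2 patients in each class")
    meta_cols = {"patient_id", "sequence", "label"}
    feat_cols = [c for c in feature_table.columns if c not in meta_cols]
    rows = []
    for seq, sub in feature_table.groupby("sequence", sort=True):
        lab = labels.loc[sub["patient_id"]].to_numpy()
        for feat in feat_cols:
            vals = sub[feat].to_numpy(dtype=np.float64)
            res = screen_feature(seq, feat, vals[lab == 1], vals[lab == 0], alpha=alpha)
            rows.append(res.to_dict())
    return pd.DataFrame(rows)
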