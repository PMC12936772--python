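"""ROC evaluation: AUC with DeLong confidence interval, Youden threshold,
and stratified sensitivity/specificity tables.

Orientation is fixed package-wide: higher score means higher cancer
risk, and the positive class is cancer (label 1).  A case is called
positive when its score is >= the threshold.  The AUC is the trapezoidal
area under the empirical ROC, identical to the Mann-Whitney statistic
with ties counted one half; its 95% CI uses the DeLong structural-
components variance with a normal interval truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    auc_se: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    curve: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)


def _check_labels(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.isin(classes, [0, 1]).all() or classes.size != 2:
        raise ValueError("labels must contain both classes 0 and 1")


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance (single-curve case).

    Structural components: V10_i = mean over negatives of the indicator
    (score_pos > score_neg, ties 1/2), V01_j likewise over positives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midranks(np.concatenate([pos, neg]))
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - r_pos) / n          # per-positive components
    v01 = 1.0 - (all_r[m:] - r_neg) / m    # per-negative components
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n if m > 1 and n > 1 else np.nan
    return float(auc), float(var)


def youden_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity - 1.

    Candidate thresholds are midpoints between consecutive distinct
    scores (plus one below the minimum and one above the maximum), so a
    perfectly separating threshold is reported as the midpoint of the
    separating gap.  Ties in J are broken toward the lower threshold
    (higher sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = (-np.inf, np.nan, np.nan, np.nan)
    for t in candidates:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return float(t), sens, spec


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC with AUC, DeLong 95% CI and the Youden operating point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    auc, var = delong_auc_variance(scores, labels)
    se = float(np.sqrt(var)) if np.isfinite(var) else np.nan
    if np.isfinite(se):
        lo = max(0.0, auc - 1.959963984540054 * se)
        hi = min(1.0, auc + 1.959963984540054 * se)
    else:
        lo, hi = 0.0, 1.0
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    t, sens, spec = youden_point(scores, labels)
    return ROCResult(auc=auc, ci95=(lo, hi), auc_se=se, youden_threshold=t,
                     sensitivity=sens, specificity=spec, curve=curve)


def stratified_performance(
    scores, labels, strata, threshold: float, external_cancer: bool = False
) -> pd.DataFrame:
    """Per-stratum detection table at a fixed threshold.

    Cancer strata (label 1, e.g. stages I..IV) report detected/total and
    sensitivity; the non-cancer stratum reports correct/total and
    specificity.  With ``external_cancer`` every case is a cancer and
    only sensitivities are reported (signature applied to a cancers-only
    cohort).  Empty strata appear with n = 0 and a blank value; the
    ``percent`` column is rounded to the nearest integer.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    strata = np.asarray(strata, dtype=object)
    if external_cancer and not (labels == 1).all():
        raise ValueError("external_cancer mode expects all labels = 1")

    rows = []
    for s in pd.unique(strata):
        sel = strata == s
        lab = labels[sel]
        if sel.sum() and (lab == 1).all():
            n = int(sel.sum())
            hit = int(np.sum(scores[sel] >= threshold))
            metric = "sensitivity"
        elif sel.sum() and (lab == 0).all():
            n = int(sel.sum())
            hit = int(np.sum(scores[sel] < threshold))
            metric = "specificity"
        else:
            n, hit, metric = int(sel.sum()), 0, "mixed"
        value = hit / n if n else np.nan
        rows.append(
            {"stratum": s, "metric": metric, "n": n, "count": hit,
             "value": value, "percent": round(100 * value) if n else ""}
        )
    return pd.DataFrame(rows)
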