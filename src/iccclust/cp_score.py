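"""Three-marker clinicopathological (CP) score and cluster-prediction metrics.

The CP score sums three one-point components: S100P IHC positivity, KRT17
IHC positivity, and serum CA19-9 >= 100 U/ml (inclusive cut-off).  Scores
0-1 are "low", 2-3 "high"; any missing marker makes the score missing (no
imputation).  Among mutation-free (Cluster3) tumours the score splits a
"classical-like" (CP high) from a "progenitor-like" (CP low) subgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError

CA199_CUTOFF = 100.0

CLASSICAL_LIKE = "classical-like"
PROGENITOR_LIKE = "progenitor-like"
NOT_APPLICABLE = "n/a"


@dataclass(frozen=True)
class CPResult:
    sample_id: str | None
    s100p_point: int | None
    krt17_point: int | None
    ca199_point: int | None
    cp_score: int | None
    cp_class: str  # "low" | "high" | "missing"


_POSITIVE = {"pos", "positive", "1", "true", "+"}
_NEGATIVE = {"neg", "negative", "0", "false", "-"}


def _marker_point(value) -> int | None:
    """Map an IHC reading to a 0/1 point; None for missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return None
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    s = str(value).strip().lower()
    if s in _POSITIVE:
        return 1
    if s in _NEGATIVE:
        return 0
    raise ValidationError(f"cannot interpret IHC value {value!r}")


def compute_cp(s100p, krt17, ca199, ca199_cutoff: float = CA199_CUTOFF, sample_id: str | None = None) -> CPResult:
    """Compute the CP score for one sample.

    ``ca199`` is the serum level in U/ml (>= cutoff scores a point; negative
    values are rejected).  A missing marker yields a missing score.
    """
    p_s100p = _marker_point(s100p)
    p_krt17 = _marker_point(krt17)
    if ca199 is None or (isinstance(ca199, float) and np.isnan(ca199)) or ca199 is pd.NA:
        p_ca199 = None
    else:
        ca199 = float(ca199)
        if ca199 < 0:
            raise ValidationError("CA19-9 must be non-negative")
        p_ca199 = int(ca199 >= ca199_cutoff)

    if None in (p_s100p, p_krt17, p_ca199):
        return CPResult(sample_id, p_s100p, p_krt17, p_ca199, None, "missing")
    score = p_s100p + p_krt17 + p_ca199
    return CPResult(sample_id, p_s100p, p_krt17, p_ca199, score, "high" if score >= 2 else "low")


def cp_table(
    clinical: pd.DataFrame,
    s100p_col: str = "s100p",
    krt17_col: str = "krt17",
    ca199_col: str = "ca19_9",
    ca199_cutoff: float = CA199_CUTOFF,
) -> pd.DataFrame:
    """CP results for every row of a clinical table, indexed by sample."""
    for col in (s100p_col, krt17_col, ca199_col):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table has no column {col!r}")
    rows = []
    for sample, row in clinical.iterrows():
        r = compute_cp(row[s100p_col], row[krt17_col], row[ca199_col], ca199_cutoff, sample_id=sample)
        rows.append(
            {
                "s100p_point": r.s100p_point,
                "krt17_point": r.krt17_point,
                "ca199_point": r.ca199_point,
                "cp_score": r.cp_score,
                "cp_class": r.cp_class,
            }
        )
    out = pd.DataFrame(rows, index=clinical.index)
    for col in ("s100p_point", "krt17_point", "ca199_point", "cp_score"):
        out[col] = out[col].astype("Int64")
    return out


def modified_clustering(assignments: pd.DataFrame, cp: pd.DataFrame) -> pd.Series:
    """Split Cluster3 samples by CP class: high -> classical-like, low -> progenitor-like.

    Non-Cluster3 samples and Cluster3 samples without a CP score get ``n/a``
    (the latter with a warning).
    """
    common = assignments.index.intersection(cp.index)
    out = pd.Series(NOT_APPLICABLE, index=assignments.index, dtype=object)
    n_missing = 0
    for sample in common:
        if assignments.loc[sample, "cluster"] != "C3":
            continue
        cls = cp.loc[sample, "cp_class"]
        if cls == "high":
            out[sample] = CLASSICAL_LIKE
        elif cls == "low":
            out[sample] = PROGENITOR_LIKE
        else:
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} Cluster3 samples lack a CP score; left n/a")
    return out


# ---------------------------------------------------------------------------
# Cluster-prediction performance
# ---------------------------------------------------------------------------

def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """(sensitivity, specificity) from a confusion table."""
    if tp + fn == 0 or fp + tn == 0:
        raise UndefinedMetricError("both truth classes must be represented")
    return tp / (tp + fn), tn / (fp + tn)


def classifier_metrics(
    score,
    truth,
    positive: str = "C1",
    negative: str = "C2",
    threshold: int = 2,
    max_score: int = 3,
) -> dict:
    """Sensitivity/specificity at an operating threshold plus a threshold-sweep ROC.

    ``score`` is the ordinal CP score (0..max_score); ``truth`` the genomic
    cluster label.  "High" predictions are ``score >= threshold``.  The ROC
    sweeps all integer thresholds and the AUC is the trapezoid over its
    points; a constant score therefore yields AUC 0.5.
    """
    score = pd.Series(np.asarray(score, dtype=float))
    truth = pd.Series(np.asarray(truth, dtype=object))
    if len(score) != len(truth):
        raise ValidationError("score and truth must have equal length")
    keep = score.notna()
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} samples with missing score")
        score, truth = score[keep], truth[keep]
    unknown = ~truth.isin([positive, negative])
    if unknown.any():
        raise ValidationError(f"truth labels must be {positive!r} or {negative!r}")
    is_pos = (truth == positive).to_numpy()
    if is_pos.all() or (~is_pos).all():
        raise UndefinedMetricError("truth contains a single class; metrics undefined")

    s = score.to_numpy()
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())

    def confusion(thr: float) -> tuple[int, int, int, int]:
        pred = s >= thr
        tp = int(np.sum(pred & is_pos))
        fp = int(np.sum(pred & ~is_pos))
        return tp, n_pos - tp, fp, n_neg - fp

    tp, fn, fp, tn = confusion(threshold)
    sensitivity, specificity = metrics_from_confusion(tp, fn, fp, tn)

    points = []
    for thr in range(max_score + 1, -1, -1):
        ctp, _, cfp, _ = confusion(thr)
        points.append((cfp / n_neg, ctp / n_pos))
    points = sorted(set(points))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))

    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        "roc_fpr": fpr,
        "roc_tpr": tpr,
        "auc": auc,
        "threshold": threshold,
    }


def reconstruct_confusion(n_pos: int, n_neg: int, sens_pct: float, spec_pct: float) -> tuple[int, int, int, int]:
    """Integer confusion table (tp, fn, fp, tn) matching printed group sizes and percentages.

    Scans all feasible integer counts and returns the table whose rounded
    sensitivity/specificity best match the printed values -- the inverse
    problem of reporting only percentages for known class sizes.
    """
    tp = min(range(n_pos + 1), key=lambda t: abs(100.0 * t / n_pos - sens_pct))
    tn = min(range(n_neg + 1), key=lambda t: abs(100.0 * t / n_neg - spec_pct))
    return tp, n_pos - tp, n_neg - tn, tn
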