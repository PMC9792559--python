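"""AP logFC as a standalone predictor of antibody quality.

The question: does the alkaline-phosphatase-induced log fold change alone
predict the Good/Bad label produced by the full six-factor score?  The tools:
a ROC curve with the predictor oriented so that *lower* (more negative) logFC
indicates Good, the trapezoid AUC, a Youden-J operating point, the inclusive
``logFC <= cutoff`` selection filter, a 2x2 chi-square association test, and
an AUC sweep over candidate score cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateTableError, UndefinedRocError, ValidationError


@dataclass
class RocResult:
    """ROC of logFC against Good/Bad labels (lower logFC => predicted Good).

    ``thresholds`` are on the logFC scale: at threshold t an antibody is
    called Good when its logFC <= t.  The curve starts at (0, 0)
    (threshold -inf) and ends at (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_cutoff: float
    n_pos: int
    n_neg: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold_logfc": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class ContingencyResult:
    """2x2 association between the logFC filter and the Good/Bad label.

    Rows: logFC <= cutoff / > cutoff; columns: Good / Bad.
    """

    table: np.ndarray
    chi2: float
    p_value: float
    correction: bool
    logfc_cutoff: float


def _as_good_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind == "b":
        return labels
    return labels == "Good"


def roc_auc(logfc, labels) -> RocResult:
    """ROC curve and trapezoid AUC of ap_logfc against Good/Bad labels.

    Sweeps every distinct threshold (no intermediate dropping); the trapezoid
    AUC equals the tie-corrected Mann-Whitney concordance probability.
    Raises :class:`UndefinedRocError` when only one class is present.
    """
    logfc = np.asarray(logfc, dtype=float)
    if not np.all(np.isfinite(logfc)):
        raise ValidationError("predictor contains non-finite values")
    good = _as_good_mask(labels)
    n_pos = int(good.sum())
    n_neg = int(len(good) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRocError("ROC undefined: only one class present in labels")
    # orientation: lower logFC indicates Good, so score on -logfc
    fpr, tpr, thr = _sk_roc_curve(good, -logfc, drop_intermediate=False)
    auc_val = float(_trapezoid_auc(fpr, tpr))
    thresholds = -thr  # back to the logFC scale; first entry is -inf (call nothing Good)
    youden = _youden_from_curve(thresholds, fpr, tpr)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc_val,
        youden_cutoff=youden,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _youden_from_curve(thresholds, fpr, tpr) -> float:
    j = np.asarray(tpr) - np.asarray(fpr)
    finite = np.isfinite(thresholds)
    if not finite.any():
        return float("-inf")
    j_f = j[finite]
    t_f = np.asarray(thresholds)[finite]
    best = np.flatnonzero(j_f == j_f.max())
    # ties -> the most negative threshold (the strictest filter)
    return float(t_f[best].min())


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximizing Youden's J = tpr - fpr (ties: most negative)."""
    return _youden_from_curve(roc.thresholds, roc.fpr, roc.tpr)


def select_antibodies(metrics_frame: pd.DataFrame, logfc_cutoff: float) -> list[str]:
    """Antibody ids with ap_logfc <= cutoff (inclusive), in stable input order."""
    df = metrics_frame
    mask = df["ap_logfc"].to_numpy(float) <= logfc_cutoff
    return df.loc[mask, "antibody_id"].tolist()


def chi_square_association(
    logfc, labels, logfc_cutoff: float, *, correction: bool = False
) -> ContingencyResult:
    """Pearson chi-square on the 2x2 table (logFC <= cutoff) x (Good/Bad).

    Yates continuity correction is off by default (panel sizes here are
    large); enable with ``correction=True``.  A zero margin raises
    :class:`DegenerateTableError`.
    """
    logfc = np.asarray(logfc, dtype=float)
    good = _as_good_mask(labels)
    passed = logfc <= logfc_cutoff
    table = np.array(
        [
            [int(np.sum(passed & good)), int(np.sum(passed & ~good))],
            [int(np.sum(~passed & good)), int(np.sum(~passed & ~good))],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"2x2 table has a zero margin: {table.tolist()}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return ContingencyResult(
        table=table,
        chi2=float(chi2),
        p_value=float(p),
        correction=correction,
        logfc_cutoff=logfc_cutoff,
    )


def auc_sweep(
    logfc, scores, cutoffs=(5, 6, 7, 8)
) -> pd.DataFrame:
    """AUC of logFC at each candidate score cutoff, labels re-derived each time.

    Rows where the cutoff makes the labels single-class carry a NaN marker
    instead of raising.  Duplicate cutoffs are deduplicated (first occurrence
    order kept).
    """
    logfc = np.asarray(logfc, dtype=float)
    scores = np.asarray(scores, dtype=float)
    seen: list[int] = []
    rows = []
    for cutoff in cutoffs:
        if cutoff in seen:
            continue
        seen.append(cutoff)
        labels = np.where(scores >= cutoff, "Good", "Bad")
        try:
            res = roc_auc(logfc, labels)
            rows.append(
                {
                    "score_cutoff": cutoff,
                    "auc": res.auc,
                    "n_good": res.n_pos,
                    "n_bad": res.n_neg,
                    "youden_logfc": res.youden_cutoff,
                }
            )
        except UndefinedRocError:
            n_good = int(np.sum(scores >= cutoff))
            rows.append(
                {
                    "score_cutoff": cutoff,
                    "auc": math.nan,
                    "n_good": n_good,
                    "n_bad": len(scores) - n_good,
                    "youden_logfc": math.nan,
                }
            )
    return pd.DataFrame(rows)
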