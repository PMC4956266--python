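"""Univariate significance testing and ROC analysis.

Welch's unequal-variance two-sample t-test (two-tailed) is the univariate
criterion for per-metabolite group differences; ROC curves are built by a
threshold sweep with half-credit tie handling, so the trapezoidal AUC
equals the Mann–Whitney concordance probability exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .latent import PCAModel
from .tables import MetaboliteTable, SampleMetadata

__all__ = [
    "TTestResult",
    "RocCurve",
    "welch_ttest",
    "roc_auc",
    "pca_score_roc",
    "significance_table",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class RocCurve:
    """A receiver operating characteristic curve with its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "auc": self.auc,
        }


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sample unequal-variance t-test, two-tailed.

    Uses the Welch statistic with Satterthwaite degrees of freedom.  The
    degenerate case of two zero-variance samples with equal means returns
    t = 0, p = 1 (no evidence of difference); zero variance with unequal
    means returns p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(t=sign * float("inf"),
                           df=float(len(a) + len(b) - 2), p=0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    positive_high: bool = True,
) -> RocCurve:
    """ROC curve from a threshold sweep over the unique scores.

    ``labels`` are booleans (True = positive).  Ties receive half credit:
    tied positive and negative scores advance the curve diagonally, making
    the trapezoidal AUC identical to the Mann–Whitney statistic with tie
    correction.  With ``positive_high`` False, low scores indicate the
    positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise StatsError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatsError("both classes must be present")
    s = scores if positive_high else -scores
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    lab_sorted = labels[order]

    thresholds = [np.inf]
    tps, fps = [0], [0]
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tps.append(tps[-1] + int(lab_sorted[i:j].sum()))
        fps.append(fps[-1] + int((~lab_sorted[i:j]).sum()))
        thresholds.append(s_sorted[i])
        i = j
    tpr = np.array(tps, dtype=float) / n_pos
    fpr = np.array(fps, dtype=float) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=np.array(thresholds), fpr=fpr, tpr=tpr, auc=auc
    )


def pca_score_roc(
    model: PCAModel,
    labels: Sequence[bool],
    components: Sequence[int] = (1, 2),
) -> dict[int, dict]:
    """Group discrimination of individual PCA score vectors, as AUC.

    ``components`` are 1-based score-vector numbers.  Each AUC is oriented
    so it is ≥ 0.5 and the chosen sign is reported alongside.
    """
    labels = np.asarray(labels, dtype=bool)
    out: dict[int, dict] = {}
    for comp in components:
        if comp < 1 or comp > model.n_components:
            raise StatsError(
                f"component {comp} outside the model's 1..{model.n_components}"
            )
        t = model.scores[:, comp - 1]
        curve = roc_auc(t, labels)
        sign = 1
        if curve.auc < 0.5:
            curve = roc_auc(-t, labels)
            sign = -1
        out[comp] = {"auc": curve.auc, "sign": sign, "curve": curve}
    return out


def significance_table(
    table: MetaboliteTable,
    metadata: Sequence[SampleMetadata],
    contrast: tuple[str, str],
    alpha: float = 0.05,
    log_transform: bool = True,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-feature Welch tests between two (pooled) groups.

    Direction is the sign of the group-1 minus group-2 mean difference on
    the natural-log scale (multiplicative data model).  No multiple-testing
    adjustment by default (raw p < alpha); Benjamini–Hochberg adjusted
    q-values are added when ``bh_correct`` is set.
    """
    g1, g2 = contrast
    by_id = {m.sample_id: (m.pooled_group or m.group) for m in metadata}
    rows1 = [i for i, s in enumerate(table.sample_ids) if by_id.get(s) == g1]
    rows2 = [i for i, s in enumerate(table.sample_ids) if by_id.get(s) == g2]
    if not rows1 or not rows2:
        raise StatsError(f"contrast groups {contrast} not both present")
    X = table.values
    if log_transform:
        if np.any(X <= 0):
            raise StatsError("log transform requires strictly positive values")
        X = np.log(X)
    records = []
    for j, f in enumerate(table.features):
        res = welch_ttest(X[rows1, j], X[rows2, j])
        diff = float(X[rows1, j].mean() - X[rows2, j].mean())
        records.append(
            {
                "feature": f.name,
                "chem_class": f.chem_class,
                "mean_log_diff": diff,
                "direction": int(np.sign(diff)),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    frame = pd.DataFrame.from_records(records)
    if bh_correct:
        frame["q"] = sps.false_discovery_control(frame["p"], method="bh")
        frame["significant"] = frame["q"] < alpha
    else:
        frame["significant"] = frame["p"] < alpha
    return frame
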