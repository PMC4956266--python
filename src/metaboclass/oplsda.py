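"""Two-class OPLS-DA: fit, prediction, cross-validation and CV-ANOVA.

Orthogonal projections to latent structures discriminant analysis separates
the between-class ("predictive") variation of a data matrix from variation
orthogonal to class membership.  For a single ±1-coded response the model
has one predictive component plus ``A_o`` orthogonal components, extracted
by the single-y algorithm:

1. ``w ∝ X'y`` (unit norm);
2. for each orthogonal component: ``t = Xw``; ``p = X't/t't``;
   ``w_o = p − (w'p)w`` normalized; ``t_o = Xw_o``; ``p_o = X't_o/t_o't_o``;
   deflate ``X ← X − t_o p_o'``;
3. final predictive score ``t = Xw`` with response loading
   ``c = y't/t't``.

Per-feature discriminatory weight is reported as p(corr): the Pearson
correlation between the predictive score vector and the (scaled) data
column, bounded in [−1, 1].

Cross-validation uses deterministic round-robin folds stratified by class
and refits the entire preprocessing inside every fold.  CV-ANOVA compares
the cross-validated prediction error (PRESS) against total response
variance via an F statistic with ``1 + A_o`` model degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .latent import ModelError, ScalingSpec, _apply_scaler, _fit_scaler

__all__ = [
    "OplsModel",
    "CvPrediction",
    "CvAnovaResult",
    "fit_oplsda",
    "predict",
    "cross_validate",
    "cv_anova",
    "confusion_from_cv",
]


@dataclass
class OplsModel:
    """A fitted two-class OPLS-DA model (one predictive component)."""

    positive_class: str
    negative_class: str
    means: np.ndarray
    scale_weights: np.ndarray
    y_mean: float
    w: np.ndarray
    c: float
    t_pred: np.ndarray
    p_pred: np.ndarray
    w_ortho: np.ndarray  # (K, A_o)
    t_ortho: np.ndarray  # (N, A_o)
    p_ortho: np.ndarray  # (K, A_o)
    n_ortho: int
    r2x: float
    r2y: float
    pcorr: np.ndarray
    ss_x_scaled: float
    ss_y: float

    @property
    def y_coding(self) -> dict:
        return {self.positive_class: 1.0, self.negative_class: -1.0}

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "n_ortho": self.n_ortho,
            "r2x": self.r2x,
            "r2y": self.r2y,
            "c": self.c,
            "pcorr": self.pcorr.tolist(),
        }


@dataclass
class CvPrediction:
    """Cross-validated predicted responses, one per sample."""

    y: np.ndarray
    y_hat_cv: np.ndarray
    fold_assignment: np.ndarray
    q2: float
    positive_class: str
    negative_class: str
    n_ortho: int


@dataclass
class CvAnovaResult:
    """F-test of cross-validated prediction error against response variance."""

    ss_total: float
    press: float
    df_model: float
    df_error: float
    F: float
    p: float


@dataclass
class ConfusionSummary:
    """Counts plus the derived sensitivity/specificity fractions."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ModelError("confusion counts must be nonnegative")
        self.sensitivity = (
            self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")
        )
        self.specificity = (
            self.tn / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")
        )


def _encode_labels(
    labels: Sequence[str], positive_class: Optional[str]
) -> tuple[np.ndarray, str, str]:
    labels = list(labels)
    classes = list(dict.fromkeys(labels))  # order of appearance
    if len(classes) != 2:
        raise ModelError(f"exactly two classes required, got {classes}")
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in classes:
        raise ModelError(f"positive class {positive_class!r} not among {classes}")
    negative_class = next(c for c in classes if c != positive_class)
    y = np.array([1.0 if l == positive_class else -1.0 for l in labels])
    for c in classes:
        if labels.count(c) < 3:
            raise ModelError(f"class {c!r} has fewer than 3 samples")
    return y, positive_class, negative_class


def fit_oplsda(
    X: np.ndarray,
    labels: Sequence[str],
    n_ortho: int = 1,
    scaling: ScalingSpec = ScalingSpec(),
    positive_class: Optional[str] = None,
) -> OplsModel:
    """Fit a single-response OPLS-DA model.

    ``positive_class`` (coded +1) defaults to the first label in order of
    appearance; in disease-versus-control contrasts pass the disease so
    that positive p(corr) means higher in disease.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    y, pos, neg = _encode_labels(labels, positive_class)
    if len(y) != n:
        raise ModelError("labels length does not match X rows")
    if n_ortho < 0:
        raise ModelError("n_ortho must be >= 0")
    if n_ortho > min(n, k) - 1:
        raise ModelError(
            f"n_ortho={n_ortho} too large for a {n}×{k} matrix"
        )

    means, weights = _fit_scaler(X, scaling)
    Xs = _apply_scaler(X, means, weights)
    y_mean = float(y.mean()) if scaling.center else 0.0
    yc = y - y_mean

    w = Xs.T @ yc
    norm_w = np.linalg.norm(w)
    if norm_w == 0:
        raise ModelError("X carries no covariance with the class response")
    w = w / norm_w

    Xd = Xs.copy()
    W_o = np.zeros((k, n_ortho))
    T_o = np.zeros((n, n_ortho))
    P_o = np.zeros((k, n_ortho))
    for a in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm_wo = np.linalg.norm(w_o)
        if norm_wo < 1e-12:
            raise ModelError(
                f"no orthogonal variation left for component {a + 1}; "
                f"reduce n_ortho"
            )
        w_o = w_o / norm_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, a], T_o[:, a], P_o[:, a] = w_o, t_o, p_o

    t = Xd @ w
    tt = float(t @ t)
    if tt == 0:
        raise ModelError("degenerate predictive score (zero variance)")
    p = Xd.T @ t / tt
    c = float(yc @ t / tt)

    ss_x = float(np.sum(Xs**2))
    ss_y = float(np.sum(yc**2))
    captured = tt * float(p @ p) + sum(
        float(T_o[:, a] @ T_o[:, a]) * float(P_o[:, a] @ P_o[:, a])
        for a in range(n_ortho)
    )
    r2x = captured / ss_x if ss_x else float("nan")
    r2y = 1.0 - float(np.sum((yc - c * t) ** 2)) / ss_y if ss_y else float("nan")

    # p(corr): correlation of the predictive score with each scaled column
    Xc = Xs - Xs.mean(axis=0)
    tc = t - t.mean()
    denom = np.sqrt(np.sum(Xc**2, axis=0) * float(tc @ tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr = np.where(denom > 0, Xc.T @ tc / denom, 0.0)
    pcorr = np.clip(pcorr, -1.0, 1.0)

    return OplsModel(
        positive_class=pos,
        negative_class=neg,
        means=means,
        scale_weights=weights,
        y_mean=y_mean,
        w=w,
        c=c,
        t_pred=t,
        p_pred=p,
        w_ortho=W_o,
        t_ortho=T_o,
        p_ortho=P_o,
        n_ortho=n_ortho,
        r2x=r2x,
        r2y=r2y,
        pcorr=pcorr,
        ss_x_scaled=ss_x,
        ss_y=ss_y,
    )


def predict(model: OplsModel, X_new: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Predicted responses and class labels for new observations.

    Orthogonal variation is removed from the scaled data by sequential
    projection before applying the predictive weights; the class threshold
    is zero (ŷ of exactly zero is assigned the positive class).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.w):
        raise ModelError(
            f"expected {len(model.w)} columns, got {X_new.shape[1]}"
        )
    Xs = _apply_scaler(X_new, model.means, model.scale_weights)
    for a in range(model.n_ortho):
        t_o = Xs @ model.w_ortho[:, a]
        Xs = Xs - np.outer(t_o, model.p_ortho[:, a])
    y_hat = (Xs @ model.w) * model.c + model.y_mean
    labels = [
        model.positive_class if v >= 0 else model.negative_class for v in y_hat
    ]
    return y_hat, labels


def cross_validate(
    X: np.ndarray,
    labels: Sequence[str],
    n_ortho: int = 1,
    folds: int = 7,
    scaling: ScalingSpec = ScalingSpec(),
    positive_class: Optional[str] = None,
) -> CvPrediction:
    """Round-robin, class-stratified cross-validated predictions.

    Within each class, samples are dealt to folds in row order; each fold's
    model (scaling included) is refit without the held-out rows.  ``q2`` is
    ``1 − PRESS / SS`` on the ±1-coded response.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = X.shape[0]
    if folds < 2:
        raise ModelError("folds must be >= 2")
    folds = min(folds, n)
    y, pos, neg = _encode_labels(labels, positive_class)

    assign = np.empty(n, dtype=int)
    counters: dict[str, int] = {}
    for i, lab in enumerate(labels):
        c = counters.get(lab, 0)
        assign[i] = c % folds
        counters[lab] = c + 1

    y_hat = np.full(n, np.nan)
    for f in np.unique(assign):
        test = assign == f
        train = ~test
        train_labels = [labels[i] for i in np.nonzero(train)[0]]
        if len(set(train_labels)) < 2:
            raise ModelError(f"fold {f} leaves a single-class training set")
        m = fit_oplsda(
            X[train], train_labels, n_ortho, scaling, positive_class=pos
        )
        y_hat[test], _ = predict(m, X[test])

    press = float(np.sum((y - y_hat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss
    return CvPrediction(
        y=y,
        y_hat_cv=y_hat,
        fold_assignment=assign,
        q2=q2,
        positive_class=pos,
        negative_class=neg,
        n_ortho=n_ortho,
    )


def cv_anova(cv: CvPrediction) -> CvAnovaResult:
    """CV-ANOVA significance of an OPLS-DA model.

    ``F = ((SS_total − PRESS)/df_model) / (PRESS/df_error)`` with
    ``df_model = 1 + A_o`` and ``df_error = N − 1 − (1 + A_o)``; when the
    cross-validated error is no better than the mean (PRESS ≥ SS_total) the
    statistic is truncated at zero and p = 1.
    """
    n = len(cv.y)
    df_model = 1.0 + cv.n_ortho
    df_error = n - 1.0 - df_model
    if df_error <= 0:
        raise ModelError(f"df_error = {df_error} <= 0 (too few samples)")
    ss_total = float(np.sum((cv.y - cv.y.mean()) ** 2))
    press = float(np.sum((cv.y - cv.y_hat_cv) ** 2))
    if press >= ss_total or press == 0.0:
        if press == 0.0:
            return CvAnovaResult(ss_total, press, df_model, df_error,
                                 float("inf"), 0.0)
        return CvAnovaResult(ss_total, press, df_model, df_error, 0.0, 1.0)
    F = ((ss_total - press) / df_model) / (press / df_error)
    p = float(stats.f.sf(F, df_model, df_error))
    p = max(p, np.nextafter(0, 1))
    return CvAnovaResult(ss_total, press, df_model, df_error, F, p)


def confusion_from_cv(cv: CvPrediction) -> ConfusionSummary:
    """Sensitivity/specificity of sign-thresholded cross-validated predictions.

    Positive class is the disease; ŷ ≥ 0 predicts positive.
    """
    pred_pos = cv.y_hat_cv >= 0
    actual_pos = cv.y > 0
    tp = int(np.sum(pred_pos & actual_pos))
    fn = int(np.sum(~pred_pos & actual_pos))
    tn = int(np.sum(~pred_pos & ~actual_pos))
    fp = int(np.sum(pred_pos & ~actual_pos))
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)
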