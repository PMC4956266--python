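"""NIPALS principal component analysis with distance-to-model statistics.

This is the latent-variable engine shared by the data-overview PCA, the
internal-standard normalizer (one non-centered component) and the SIMCA
class models.  Components are extracted one at a time by the NIPALS power
iteration with deflation; residual machinery provides the normalized
distance to model (DModX) and its F-distribution critical limit (DCrit)
used for soft class membership.

Degrees-of-freedom conventions
------------------------------
For a centered model with ``N`` training rows, ``K`` variables and ``A``
components, the pooled residual standard deviation uses
``(N - A - 1) * (K - A)`` degrees of freedom (``(N - A) * (K - A)`` when
non-centered), and training-set DModX values carry the leverage correction
``sqrt(N / (N - A - 1))``.  The exact correction used by commercial
chemometrics software is unpublished; the convention here is validated by a
calibration simulation (in-class held-out observations are rejected at the
nominal rate of the F-test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "ScalingSpec",
    "PCAModel",
    "DistanceResult",
    "fit_pca",
    "q2_pca",
    "project",
    "dmodx",
    "dcrit",
]

SCALING_MODES = ("none", "unit_variance", "pareto")


class ModelError(ValueError):
    """Raised for invalid model requests (rank, convergence, dimensions)."""


@dataclass(frozen=True)
class ScalingSpec:
    """Column preprocessing: optional mean-centering plus variance scaling.

    ``unit_variance`` divides each column by its training standard
    deviation, ``pareto`` by the square root of the standard deviation.
    Statistics are always taken from training data only.
    """

    center: bool = True
    mode: str = "unit_variance"

    def __post_init__(self) -> None:
        if self.mode not in SCALING_MODES:
            raise ModelError(f"unknown scaling mode {self.mode!r}")


def _fit_scaler(X: np.ndarray, spec: ScalingSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (means, weights) so that the scaled matrix is (X - means) * weights.

    Zero-variance columns get weight 0 under variance scaling (they carry no
    information after centering and would otherwise divide by zero).
    """
    n, k = X.shape
    means = X.mean(axis=0) if spec.center else np.zeros(k)
    if spec.mode == "none":
        weights = np.ones(k)
    else:
        sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(k)
        with np.errstate(divide="ignore"):
            if spec.mode == "unit_variance":
                weights = np.where(sd > 0, 1.0 / sd, 0.0)
            else:  # pareto
                weights = np.where(sd > 0, 1.0 / np.sqrt(sd), 0.0)
    return means, weights


def _apply_scaler(X: np.ndarray, means: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return (X - means) * weights


@dataclass
class PCAModel:
    """A fitted principal component model.

    Loadings ``P`` (K × A) have orthonormal columns; scores ``T`` (N × A)
    are mutually orthogonal.  ``s0`` is the pooled residual standard
    deviation of the training set, the yardstick for DModX.
    """

    n_train: int
    n_vars: int
    n_components: int
    means: np.ndarray
    scale_weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    r2x_per_component: np.ndarray
    r2x_cum: np.ndarray
    s0: float
    ss_scaled: float
    scaling: ScalingSpec
    q2_cum: Optional[np.ndarray] = None

    @property
    def dof_residual_rows(self) -> int:
        a = self.n_components
        return self.n_train - a - 1 if self.scaling.center else self.n_train - a

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "n_vars": self.n_vars,
            "n_components": self.n_components,
            "means": self.means.tolist(),
            "scale_weights": self.scale_weights.tolist(),
            "loadings": self.loadings.tolist(),
            "scores": self.scores.tolist(),
            "r2x_per_component": self.r2x_per_component.tolist(),
            "r2x_cum": self.r2x_cum.tolist(),
            "q2_cum": None if self.q2_cum is None else self.q2_cum.tolist(),
            "s0": self.s0,
            "scaling": {"center": self.scaling.center, "mode": self.scaling.mode},
        }


@dataclass
class DistanceResult:
    """Normalized distances to a class model with the membership verdict."""

    dmodx_abs: np.ndarray
    dmodx_norm: np.ndarray
    dcrit: float
    inside: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inside is None:
            self.inside = self.dmodx_norm <= self.dcrit


def fit_pca(
    X: np.ndarray,
    n_components: int,
    scaling: ScalingSpec = ScalingSpec(),
    tol: float = 1e-9,
    max_iter: int = 10000,
) -> PCAModel:
    """Fit a PCA model by NIPALS with deflation.

    Each component maximizes the residual variance explained; convergence is
    declared when the relative change of the score vector falls below
    ``tol``.  The sign of each loading vector is fixed so its
    largest-magnitude element is positive, making scores reproducible.
    Requesting more components than the attainable rank raises
    :class:`ModelError` naming the rank.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ModelError("X must be 2-D")
    n, k = X.shape
    max_a = min(n - (1 if scaling.center else 0), k)
    if n_components < 1:
        raise ModelError("n_components must be >= 1")
    if n_components > max_a:
        raise ModelError(
            f"requested {n_components} components but at most {max_a} are "
            f"attainable for a {n}×{k} matrix"
        )
    if np.any(~np.isfinite(X)):
        raise ModelError("X contains non-finite values")

    means, weights = _fit_scaler(X, scaling)
    Xs = _apply_scaler(X, means, weights)
    ss0 = float(np.sum(Xs**2))
    if ss0 == 0.0:
        raise ModelError("scaled data matrix has zero sum of squares (degenerate)")

    resid = Xs.copy()
    P = np.zeros((k, n_components))
    T = np.zeros((n, n_components))
    r2 = np.zeros(n_components)
    for a in range(n_components):
        ss_res = float(np.sum(resid**2))
        if ss_res <= 1e-12 * ss0:
            raise ModelError(
                f"residual exhausted after {a} components; attainable rank is {a}"
            )
        t = resid[:, int(np.argmax(np.sum(resid**2, axis=0)))].copy()
        if np.allclose(t, 0):
            t = resid[:, 0] + 1e-12
        converged = False
        for _ in range(max_iter):
            p = resid.T @ t
            p /= np.linalg.norm(p)
            t_new = resid @ p
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            raise ModelError(
                f"NIPALS failed to converge for component {a + 1} "
                f"within {max_iter} iterations"
            )
        p = resid.T @ t
        p /= np.linalg.norm(p)
        t = resid @ p
        # sign convention: largest-|loading| element positive
        jmax = int(np.argmax(np.abs(p)))
        if p[jmax] < 0:
            p = -p
            t = -t
        resid -= np.outer(t, p)
        P[:, a] = p
        T[:, a] = t
        r2[a] = float(t @ t) / ss0

    a_final = n_components
    dof_rows = n - a_final - 1 if scaling.center else n - a_final
    ss_resid = float(np.sum(resid**2))
    if dof_rows > 0 and k > a_final:
        s0 = float(np.sqrt(ss_resid / (dof_rows * (k - a_final))))
    else:
        s0 = float("nan")

    return PCAModel(
        n_train=n,
        n_vars=k,
        n_components=a_final,
        means=means,
        scale_weights=weights,
        loadings=P,
        scores=T,
        r2x_per_component=r2,
        r2x_cum=np.cumsum(r2),
        s0=s0,
        ss_scaled=ss0,
        scaling=scaling,
    )


def q2_pca(
    X: np.ndarray,
    n_components: int,
    scaling: ScalingSpec = ScalingSpec(),
    folds: int = 7,
    tol: float = 1e-9,
    max_iter: int = 10000,
) -> np.ndarray:
    """Cross-validated Q² per cumulative component count.

    Rows are assigned to folds deterministically round-robin by row order
    (row ``i`` goes to fold ``i mod folds``).  For each fold the model
    (including scaling) is refit on the retained rows and held-out rows are
    predicted against its loadings; ``Q2_cum(a) = 1 - PRESS(a) / SS`` where
    SS is the total sum of squares of the held-out rows under their
    training-fold scaling.

    The predictive residual for variable ``j`` of a held-out row is formed
    with scores estimated from the *other* variables only (least squares
    against the loadings with row ``j`` deleted).  A naive projection that
    uses the full row to estimate its own scores reconstructs roughly an
    ``A/K`` share of even pure noise; excluding the predicted variable
    removes that bias, so uninformative data yield Q² ≤ 0.  With orthonormal
    loadings the per-variable score correction has the closed form
    ``t(-j) = (I + p_j p_j' / (1 - |p_j|²)) (P'x - p_j x_j)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if folds < 2:
        raise ModelError("folds must be >= 2")
    folds = min(folds, n)
    assign = np.arange(n) % folds
    press = np.zeros(n_components)
    ss_total = 0.0
    for f in range(folds):
        test = assign == f
        train = ~test
        if not np.any(train):
            raise ModelError(f"fold {f} would leave no training rows")
        model = fit_pca(X[train], n_components, scaling, tol=tol, max_iter=max_iter)
        Xs_te = _apply_scaler(X[test], model.means, model.scale_weights)
        ss_total += float(np.sum(Xs_te**2))
        for a in range(n_components):
            P = model.loadings[:, : a + 1]          # K × (a+1)
            base = Xs_te @ P                        # scores from full rows
            row_norms = np.sum(P**2, axis=1)        # |p_j|² per variable
            denom = 1.0 - row_norms
            denom = np.where(denom < 1e-12, 1e-12, denom)
            # t(-j) = base - x_j p_j, then Sherman-Morrison inflation
            pred = np.empty_like(Xs_te)
            for j in range(model.n_vars):
                pj = P[j]
                tmj = base - np.outer(Xs_te[:, j], pj)
                tmj = tmj + np.outer(tmj @ pj, pj) / denom[j]
                pred[:, j] = tmj @ pj
            press[a] += float(np.sum((Xs_te - pred) ** 2))
    if ss_total == 0.0:
        raise ModelError("held-out sum of squares is zero (degenerate data)")
    return 1.0 - press / ss_total


def project(model: PCAModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project new observations: returns (scores, residual matrix).

    The stored centering/scaling is applied; scores are least-squares
    projections onto the (orthonormal) loadings and the residual is the
    part of each scaled row outside the model plane.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_vars:
        raise ModelError(
            f"expected {model.n_vars} columns, got {X_new.shape[1]}"
        )
    Xs = _apply_scaler(X_new, model.means, model.scale_weights)
    scores = Xs @ model.loadings
    resid = Xs - scores @ model.loadings.T
    return scores, resid


def dmodx(
    model: PCAModel,
    X_new: np.ndarray,
    is_training: bool = False,
    alpha: float = 0.05,
) -> DistanceResult:
    """Normalized distance to the model for each observation.

    ``dmodx_abs`` is the residual standard deviation of the observation over
    ``K - A`` degrees of freedom; ``dmodx_norm`` divides by the training
    pool ``s0``, with a leverage correction for training rows.  Membership
    compares ``dmodx_norm`` against :func:`dcrit` at ``alpha``.
    """
    if model.dof_residual_rows <= 0:
        raise ModelError(
            "model has too few training rows for residual statistics "
            f"(N={model.n_train}, A={model.n_components})"
        )
    _, resid = project(model, X_new)
    k, a = model.n_vars, model.n_components
    if k <= a:
        raise ModelError("no residual degrees of freedom (K <= A)")
    d_abs = np.sqrt(np.sum(resid**2, axis=1) / (k - a))
    crit = dcrit(model, alpha)
    if model.s0 == 0.0 or not np.isfinite(model.s0):
        # degenerate: the model reproduces training data exactly; any
        # nonzero residual is infinitely far away
        d_norm = np.where(d_abs > 0, np.inf, 0.0)
        return DistanceResult(d_abs, d_norm, crit)
    d_norm = d_abs / model.s0
    if is_training:
        d_norm = d_norm * np.sqrt(model.n_train / model.dof_residual_rows)
    return DistanceResult(d_abs, d_norm, crit)


def dcrit(model: PCAModel, alpha: float = 0.05) -> float:
    """Critical limit for the normalized distance to model.

    ``sqrt`` of the upper ``alpha`` quantile of an F distribution with
    ``K - A`` and ``dof_rows * (K - A)`` degrees of freedom; observations
    with ``dmodx_norm`` above it are rejected from the class at level
    ``alpha``.  Monotone decreasing in ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ModelError("alpha must be in (0, 1)")
    d1 = model.n_vars - model.n_components
    d2 = model.dof_residual_rows * d1
    if d1 <= 0 or d2 <= 0:
        raise ModelError(
            f"nonpositive degrees of freedom (d1={d1}, d2={d2}) for DCrit"
        )
    return float(np.sqrt(stats.f.ppf(1.0 - alpha, d1, d2)))
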