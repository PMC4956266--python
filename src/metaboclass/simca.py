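"""SIMCA soft classification: one PCA model per class, membership by DModX.

Soft Independent Modeling of Class Analogy fits a separate principal
component model to each class's training samples.  A new observation
belongs to a class when its normalized distance to that class model
(DModX) does not exceed the F-test critical distance (DCrit); membership
in zero, one or several classes is possible.  For a two-class problem the
pair of distances forms the Coomans plot coordinates, whose critical-
distance lines partition samples into membership quadrants.

Leave-one-out validation refits the class model without each own-class
sample in turn: sensitivity of a class model is the fraction of held-out
own-class samples still inside it, specificity the fraction of other-class
samples outside the full model (leave-one-out removal is only defined for
own-class members).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .latent import (
    ModelError,
    PCAModel,
    ScalingSpec,
    dcrit,
    dmodx,
    fit_pca,
    q2_pca,
)
from .oplsda import ConfusionSummary
from .tables import MetaboliteTable, SampleMetadata

__all__ = [
    "SimcaModel",
    "CoomansCoordinates",
    "fit_simca",
    "classify",
    "loo_validate",
    "select_components",
]


@dataclass
class SimcaClass:
    label: str
    model: PCAModel
    dcrit: float


@dataclass
class SimcaModel:
    """Per-class PCA models with their critical distances."""

    classes: list  # of SimcaClass
    alpha: float
    feature_names: list

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classes]

    def class_for(self, label: str) -> SimcaClass:
        for c in self.classes:
            if c.label == label:
                return c
        raise ModelError(f"no class model for {label!r}")


@dataclass
class CoomansCoordinates:
    """Distances of each sample to two class models, with critical lines."""

    sample_ids: list
    labels: list
    d1: np.ndarray
    d2: np.ndarray
    dcrit1: float
    dcrit2: float
    class1: str
    class2: str

    def membership(self) -> list[tuple[bool, bool]]:
        return [
            (float(a) <= self.dcrit1, float(b) <= self.dcrit2)
            for a, b in zip(self.d1, self.d2)
        ]


def _class_rows(
    table: MetaboliteTable, metadata: Sequence[SampleMetadata], label: str
) -> np.ndarray:
    by_id = {m.sample_id: (m.pooled_group or m.group) for m in metadata}
    idx = [
        i for i, s in enumerate(table.sample_ids) if by_id.get(s) == label
    ]
    return np.asarray(idx, dtype=int)


def select_components(
    X: np.ndarray,
    scaling: ScalingSpec = ScalingSpec(),
    max_components: int = 5,
) -> int:
    """Pick the component count maximizing leave-one-out Q² (searching 1..5)."""
    n = X.shape[0]
    best_a, best_q2 = 1, -np.inf
    upper = min(max_components, n - (2 if scaling.center else 1), X.shape[1] - 1)
    upper = max(upper, 1)
    for a in range(1, upper + 1):
        try:
            q2 = q2_pca(X, a, scaling, folds=n)[-1]
        except ModelError:
            break
        if q2 > best_q2:
            best_a, best_q2 = a, q2
    return best_a


def fit_simca(
    table: MetaboliteTable,
    metadata: Sequence[SampleMetadata],
    class_labels: Sequence[str],
    components: Optional[dict] = None,
    alpha: float = 0.05,
    scaling: ScalingSpec = ScalingSpec(),
) -> SimcaModel:
    """Fit one PCA class model per requested label.

    ``components`` maps label → component count; labels absent from the map
    get a count chosen by leave-one-out Q² (1..5).  Each class needs at
    least ``components + 2`` samples.
    """
    components = dict(components or {})
    classes = []
    for label in class_labels:
        rows = _class_rows(table, metadata, label)
        if len(rows) == 0:
            raise ModelError(f"class {label!r} has no samples in metadata")
        Xc = table.values[rows]
        a = components.get(label)
        if a is None:
            a = select_components(Xc, scaling)
        if len(rows) < a + 2:
            raise ModelError(
                f"class {label!r} has {len(rows)} samples; needs >= {a + 2} "
                f"for {a} components"
            )
        model = fit_pca(Xc, a, scaling)
        classes.append(SimcaClass(label=label, model=model, dcrit=dcrit(model, alpha)))
    return SimcaModel(classes=classes, alpha=alpha, feature_names=table.feature_names)


def classify(
    simca: SimcaModel,
    table: MetaboliteTable,
    metadata: Optional[Sequence[SampleMetadata]] = None,
) -> tuple[dict, Optional[CoomansCoordinates]]:
    """Soft membership of new samples in every class model.

    Returns ``{label: {"dmodx": array, "inside": array}}`` plus Coomans
    coordinates when the model has exactly two classes.
    """
    if table.feature_names != simca.feature_names:
        raise ModelError("feature columns do not match the fitted SIMCA model")
    dists = {}
    for c in simca.classes:
        res = dmodx(c.model, table.values, is_training=False, alpha=simca.alpha)
        dists[c.label] = {"dmodx": res.dmodx_norm, "inside": res.dmodx_norm <= c.dcrit}
    coomans = None
    if len(simca.classes) == 2:
        c1, c2 = simca.classes
        labels = (
            [(m.pooled_group or m.group) for m in metadata]
            if metadata is not None
            else [""] * table.n_samples
        )
        coomans = CoomansCoordinates(
            sample_ids=list(table.sample_ids),
            labels=labels,
            d1=dists[c1.label]["dmodx"],
            d2=dists[c2.label]["dmodx"],
            dcrit1=c1.dcrit,
            dcrit2=c2.dcrit,
            class1=c1.label,
            class2=c2.label,
        )
    return dists, coomans


def loo_validate(
    table: MetaboliteTable,
    metadata: Sequence[SampleMetadata],
    class_labels: Sequence[str],
    components: Optional[dict] = None,
    alpha: float = 0.05,
    scaling: ScalingSpec = ScalingSpec(),
) -> tuple[dict, Optional[CoomansCoordinates]]:
    """Leave-one-out validation of each class model.

    For every own-class sample the class model is refit without it and the
    held-out sample's membership recorded (→ sensitivity); other-class
    samples are judged against the full model (→ specificity).  Returns
    ``{label: ConfusionSummary}`` plus cross-validated Coomans coordinates
    for two-class problems.
    """
    full = fit_simca(table, metadata, class_labels, components, alpha, scaling)
    components = {
        c.label: c.model.n_components for c in full.classes
    }
    by_id = {m.sample_id: (m.pooled_group or m.group) for m in metadata}
    n = table.n_samples
    # cross-validated distance of every sample to every class model
    cv_dist: dict[str, np.ndarray] = {}
    summaries: dict[str, ConfusionSummary] = {}
    for c in full.classes:
        rows = _class_rows(table, metadata, c.label)
        a = components[c.label]
        d = np.full(n, np.nan)
        # other-class (and unlabeled) samples: full model
        res_full = dmodx(c.model, table.values, is_training=False, alpha=alpha)
        d[:] = res_full.dmodx_norm
        inside_thresh = np.full(n, c.dcrit)
        # own-class samples: refit without each
        for i in rows:
            keep = rows[rows != i]
            if len(keep) < a + 2:
                raise ModelError(
                    f"class {c.label!r} too small for LOO with {a} components"
                )
            m = fit_pca(table.values[keep], a, scaling)
            res = dmodx(m, table.values[i : i + 1], is_training=False, alpha=alpha)
            d[i] = res.dmodx_norm[0]
            inside_thresh[i] = dcrit(m, alpha)
        inside = d <= inside_thresh
        own = np.zeros(n, dtype=bool)
        own[rows] = True
        other = np.array(
            [
                (by_id.get(s) in class_labels) and not own[i]
                for i, s in enumerate(table.sample_ids)
            ]
        )
        tp = int(np.sum(inside & own))
        fn = int(np.sum(~inside & own))
        tn = int(np.sum(~inside & other))
        fp = int(np.sum(inside & other))
        summaries[c.label] = ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)
        cv_dist[c.label] = d

    coomans = None
    if len(full.classes) == 2:
        c1, c2 = full.classes
        coomans = CoomansCoordinates(
            sample_ids=list(table.sample_ids),
            labels=[by_id.get(s, "") for s in table.sample_ids],
            d1=cv_dist[c1.label],
            d2=cv_dist[c2.label],
            dcrit1=c1.dcrit,
            dcrit2=c2.dcrit,
            class1=c1.label,
            class2=c2.label,
        )
    return summaries, coomans
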