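"""Internal-standard normalization of peak-area tables.

Eleven isotope-labeled internal standards are spiked into every sample at
fixed amounts, so their shared intensity variation measures each sample's
injection/ion-suppression efficiency.  A one-component *non-centered*
principal component model is fit on the internal-standard submatrix (each
IS column scaled to unit mean so no high-abundance standard dominates);
the magnitude of each sample's first score is taken as its overall
intensity factor.  Factors are rescaled to median 1 so normalized data stay
on the original intensity scale, and every analyte value is divided by its
sample's factor; the IS columns are dropped from the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .latent import ScalingSpec, fit_pca
from .tables import MetaboliteTable

__all__ = ["NormalizationModel", "fit_is_normalizer", "apply_normalizer"]


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationModel:
    """Per-sample intensity factors estimated from the internal standards."""

    is_names: list
    column_scale: np.ndarray
    sample_ids: list
    factors: np.ndarray
    rescale_constant: float

    def factor_for(self, sample_id: str) -> float:
        try:
            return float(self.factors[self.sample_ids.index(sample_id)])
        except ValueError:
            raise NormalizationError(f"unknown sample id {sample_id!r}") from None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tfactor\n")
            for sid, f in zip(self.sample_ids, self.factors):
                fh.write(f"{sid}\t{f:.12g}\n")


def fit_is_normalizer(table: MetaboliteTable) -> NormalizationModel:
    """Fit the one-component non-centered IS model and extract factors.

    Requires at least two strictly positive internal-standard columns.  The
    rescaled factors have median exactly 1.
    """
    is_idx = [j for j, f in enumerate(table.features) if f.is_internal_standard]
    if len(is_idx) < 2:
        raise NormalizationError(
            f"need >= 2 internal-standard columns, found {len(is_idx)}"
        )
    Z = table.values[:, is_idx]
    if np.any(Z <= 0):
        i, j = np.argwhere(Z <= 0)[0]
        raise NormalizationError(
            f"internal standard {table.features[is_idx[j]].name!r} has a "
            f"nonpositive value in sample {table.sample_ids[i]!r}"
        )
    column_scale = Z.mean(axis=0)
    Zs = Z / column_scale
    model = fit_pca(Zs, 1, ScalingSpec(center=False, mode="none"))
    t1 = np.abs(model.scores[:, 0])
    med = float(np.median(t1))
    if med == 0:
        raise NormalizationError("degenerate internal-standard matrix (zero scores)")
    factors = t1 / med
    return NormalizationModel(
        is_names=[table.features[j].name for j in is_idx],
        column_scale=column_scale,
        sample_ids=list(table.sample_ids),
        factors=factors,
        rescale_constant=med,
    )


def apply_normalizer(
    table: MetaboliteTable, model: NormalizationModel
) -> MetaboliteTable:
    """Divide every analyte value by its sample's factor; drop IS columns."""
    unknown = set(table.sample_ids) - set(model.sample_ids)
    if unknown:
        raise NormalizationError(f"samples not in normalizer: {sorted(unknown)}")
    keep = [j for j, f in enumerate(table.features) if not f.is_internal_standard]
    factors = np.array([model.factor_for(s) for s in table.sample_ids])
    values = table.values[:, keep] / factors[:, None]
    return MetaboliteTable(
        values, table.sample_ids, [table.features[j] for j in keep]
    )
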