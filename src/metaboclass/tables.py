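"""Core data containers and delimited-text I/O for metabolite peak-area tables.

A study is represented by three tab-separated files:

* a values table (samples in rows, features in columns, sample ids in the
  first column),
* a sample-metadata table (``sample_id``, ``group`` and optional ``age``,
  ``sex`` columns), and
* an optional feature-annotation table (``name``, ``identified``,
  ``chem_class``, ``is_internal_standard``, ``retention_index``).

Tab separation is deliberate: metabolite names routinely contain commas
("2,3-dihydroxybutanoic acid"), so TSV round-trips safely where CSV would
not.  Missing values are rejected at load time rather than imputed — the
modeling matrix is required to be complete.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

#: Chemical classes used for feature annotation.
CHEM_CLASSES = ("amino_acid", "organic_acid", "fatty_acid", "purine", "other", "unknown")

#: The seven clinical groups (three SLE severity phenotypes, primary
#: Sjögren's syndrome, limited and diffuse cutaneous systemic sclerosis,
#: and healthy volunteers).
GROUPS = ("SLE_G1", "SLE_G2", "SLE_G3", "pSS", "SSc_lc", "SSc_dc", "HV")

#: Pooling map collapsing clinical subgroups into the four diagnosis-level
#: cohorts used by the classification models.
POOLED_GROUPS = ("SLE", "pSS", "SSc", "HV")
_POOL_MAP = {
    "SLE_G1": "SLE",
    "SLE_G2": "SLE",
    "SLE_G3": "SLE",
    "SSc_lc": "SSc",
    "SSc_dc": "SSc",
    "pSS": "pSS",
    "HV": "HV",
}


class TableError(ValueError):
    """Raised for structurally invalid tables or metadata."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """Per-feature annotation.

    Internal standards are spiked-in labeled compounds used only for
    normalization; they are never simultaneously flagged as identified
    analytes usable in modeling.
    """

    name: str
    identified: bool = False
    chem_class: str = "unknown"
    is_internal_standard: bool = False
    retention_index: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise TableError(
                f"unknown chem_class {self.chem_class!r} for feature {self.name!r}; "
                f"expected one of {CHEM_CLASSES}"
            )
        if self.identified and self.is_internal_standard:
            raise TableError(
                f"feature {self.name!r} cannot be both an identified analyte and "
                "an internal standard"
            )
        if self.retention_index is not None and not np.isfinite(self.retention_index):
            raise TableError(f"non-finite retention index for feature {self.name!r}")


@dataclass
class SampleMetadata:
    """Clinical metadata for one sample."""

    sample_id: str
    group: str
    pooled_group: Optional[str] = None
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TableError(
                f"unknown group label {self.group!r} for sample {self.sample_id!r}; "
                f"expected one of {GROUPS}"
            )
        if self.pooled_group is not None and self.pooled_group not in POOLED_GROUPS:
            raise TableError(
                f"unknown pooled group {self.pooled_group!r} for sample "
                f"{self.sample_id!r}"
            )


class MetaboliteTable:
    """Samples × features matrix of nonnegative relative intensities.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` array of finite, nonnegative peak areas
        (arbitrary units).
    sample_ids
        Unique sample identifiers, one per row.
    features
        One :class:`FeatureAnnotation` per column, with unique names.
    """

    def __init__(
        self,
        values: np.ndarray,
        sample_ids: Sequence[str],
        features: Sequence[FeatureAnnotation],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise TableError("values must be a 2-D matrix")
        if values.shape[0] != len(sample_ids):
            raise TableError(
                f"{values.shape[0]} rows but {len(sample_ids)} sample ids"
            )
        if values.shape[1] != len(features):
            raise TableError(
                f"{values.shape[1]} columns but {len(features)} feature annotations"
            )
        dup = _duplicates(sample_ids)
        if dup:
            raise TableError(f"duplicate sample ids: {dup}")
        dup = _duplicates([f.name for f in features])
        if dup:
            raise TableError(f"duplicate feature names: {dup}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise TableError(
                f"non-finite value at sample {sample_ids[bad[0]]!r}, "
                f"feature {features[bad[1]].name!r}"
            )
        if np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative value at sample {sample_ids[bad[0]]!r}, "
                f"feature {features[bad[1]].name!r}"
            )
        self.values = values
        self.sample_ids = list(sample_ids)
        self.features = list(features)

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_names,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MetaboliteTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MetaboliteTable(self.values[idx], list(sample_ids), self.features)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MetaboliteTable({self.n_samples} samples × {self.n_features} features)"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetaboliteTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.features == other.features
            and np.array_equal(self.values, other.values)
        )


@dataclass
class AnalysisConfig:
    """Tunable parameters for the end-to-end analysis.

    Defaults follow the study design: 5% significance for critical
    distances and univariate tests, 7-fold cross-validation, one orthogonal
    OPLS component per two-class contrast, and a ±10 retention-index
    acceptance window for identification.
    """

    scaling_center: bool = True
    scaling_mode: str = "unit_variance"
    n_components_overview: int = 4
    simca_components_per_class: dict = field(default_factory=dict)
    alpha: float = 0.05
    cv_folds: int = 7
    opls_orthogonal_components: int = 1
    seed: int = 0
    ri_window: float = 10.0
    min_match_value: float = 700.0
    drop_internal_standards: bool = True
    drop_unidentified: bool = True
    contrasts: list = field(
        default_factory=lambda: [
            ("SLE", "HV"),
            ("SSc", "HV"),
            ("pSS", "HV"),
            ("SLE", "pSS"),
            ("SLE", "SSc"),
        ]
    )
    skip_steps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise TableError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("n_components_overview", "cv_folds"):
            if getattr(self, name) < 1:
                raise TableError(f"{name} must be >= 1")
        if self.opls_orthogonal_components < 0:
            raise TableError("opls_orthogonal_components must be >= 0")
        self.contrasts = [tuple(c) for c in self.contrasts]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for it in items:
        if it in seen and it not in dup:
            dup.append(it)
        seen.add(it)
    return dup


def read_table(
    path: str | Path,
    metadata_path: str | Path,
    features_path: str | Path | None = None,
) -> tuple[MetaboliteTable, list[SampleMetadata]]:
    """Read a values TSV plus sample metadata (and optional annotations).

    The values file has one header row naming features and sample ids in the
    first column.  Non-numeric or missing cells are rejected with the
    offending position named.  Every sample must have exactly one metadata
    record and vice versa.  When ``features_path`` is omitted, all features
    default to unidentified / unknown class / not internal standard.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    sample_ids = list(raw.index)
    feature_names = list(raw.columns.astype(str))

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            cell = raw.loc[bad[0], col]
            raise TableError(
                f"non-numeric value {cell!r} at sample {bad[0]!r}, feature {col!r}"
            )
        values[:, j] = parsed.to_numpy()

    if features_path is not None:
        features = read_feature_annotations(features_path)
        ann_names = [f.name for f in features]
        if ann_names != feature_names:
            missing = sorted(set(feature_names) - set(ann_names))
            extra = sorted(set(ann_names) - set(feature_names))
            raise TableError(
                "feature annotations do not match table columns"
                + (f"; unannotated: {missing}" if missing else "")
                + (f"; extraneous: {extra}" if extra else "")
            )
    else:
        features = [FeatureAnnotation(name=n) for n in feature_names]

    metadata = read_sample_metadata(metadata_path)
    meta_ids = [m.sample_id for m in metadata]
    orphans_t = sorted(set(sample_ids) - set(meta_ids))
    orphans_m = sorted(set(meta_ids) - set(sample_ids))
    if orphans_t or orphans_m:
        raise TableError(
            "table/metadata mismatch"
            + (f"; samples without metadata: {orphans_t}" if orphans_t else "")
            + (f"; metadata without samples: {orphans_m}" if orphans_m else "")
        )
    order = {s: i for i, s in enumerate(sample_ids)}
    metadata = sorted(metadata, key=lambda m: order[m.sample_id])

    return MetaboliteTable(values, sample_ids, features), metadata


def write_table(
    table: MetaboliteTable,
    path: str | Path,
    metadata: Sequence[SampleMetadata] | None = None,
    metadata_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> None:
    """Write the values (and optionally metadata/annotations) as TSV."""
    frame = table.to_frame()
    frame.to_csv(path, sep="\t", float_format="%.12g")
    if metadata is not None and metadata_path is not None:
        write_sample_metadata(metadata, metadata_path)
    if features_path is not None:
        write_feature_annotations(table.features, features_path)


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in frame.columns or "group" not in frame.columns:
        raise TableError("metadata must have 'sample_id' and 'group' columns")
    dup = _duplicates(frame["sample_id"])
    if dup:
        raise TableError(f"duplicate sample ids in metadata: {dup}")
    records = []
    for _, row in frame.iterrows():
        age = _opt_str(row.get("age"))
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                pooled_group=_opt_str(row.get("pooled_group")),
                age=float(age) if age is not None else None,
                sex=_opt_str(row.get("sex")),
            )
        )
    return records


def write_sample_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "group": [m.group for m in metadata],
            "pooled_group": [m.pooled_group or "" for m in metadata],
            "age": [m.age if m.age is not None else "" for m in metadata],
            "sex": [m.sex or "" for m in metadata],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_feature_annotations(path: str | Path) -> list[FeatureAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "identified", "chem_class", "is_internal_standard"}
    missing = required - set(frame.columns)
    if missing:
        raise TableError(f"feature annotation file missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        ri = row.get("retention_index")
        out.append(
            FeatureAnnotation(
                name=str(row["name"]),
                identified=_parse_bool(row["identified"]),
                chem_class=str(row["chem_class"]),
                is_internal_standard=_parse_bool(row["is_internal_standard"]),
                retention_index=(
                    float(ri) if _opt_str(ri) is not None else None
                ),
            )
        )
    return out


def write_feature_annotations(
    features: Sequence[FeatureAnnotation], path: str | Path
) -> None:
    frame = pd.DataFrame(
        {
            "name": [f.name for f in features],
            "identified": [str(f.identified) for f in features],
            "chem_class": [f.chem_class for f in features],
            "is_internal_standard": [str(f.is_internal_standard) for f in features],
            "retention_index": [
                "" if f.retention_index is None else f"{f.retention_index:.12g}"
                for f in features
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def _opt_str(x) -> Optional[str]:
    if x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x) or x == "":
        return None
    return str(x)


def _parse_bool(x) -> bool:
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise TableError(f"cannot parse boolean value {x!r}")


# ---------------------------------------------------------------------------
# Cohort bookkeeping
# ---------------------------------------------------------------------------

def pool_sle_subgroups(metadata: Sequence[SampleMetadata]) -> list[SampleMetadata]:
    """Collapse clinical subgroups to diagnosis level.

    The three SLE severity phenotypes pool to ``SLE`` and the two cutaneous
    SSc subsets to ``SSc``; pSS and HV map to themselves.  The original
    subgroup label is preserved.  Idempotent and order-preserving.
    """
    out = []
    for m in metadata:
        out.append(dataclasses.replace(m, pooled_group=_POOL_MAP[m.group]))
    return out


def filter_features(
    table: MetaboliteTable,
    drop_internal_standards: bool = True,
    drop_unidentified: bool = True,
) -> MetaboliteTable:
    """Restrict the table to features passing the annotation predicate.

    The study-faithful modeling set drops both internal standards and
    unidentified putative features, leaving only uniquely identified
    analytes.  Sample rows are unchanged; column order is preserved.
    """
    keep = []
    for j, f in enumerate(table.features):
        if drop_internal_standards and f.is_internal_standard:
            continue
        if drop_unidentified and not f.identified and not f.is_internal_standard:
            continue
        keep.append(j)
    if not keep:
        raise TableError("feature filter removed every feature")
    return MetaboliteTable(
        table.values[:, keep], table.sample_ids, [table.features[j] for j in keep]
    )


def groups_of(metadata: Sequence[SampleMetadata]) -> dict[str, list[str]]:
    """Map pooled group (falling back to raw group) to its sample ids."""
    out: dict[str, list[str]] = {}
    for m in metadata:
        out.setdefault(m.pooled_group or m.group, []).append(m.sample_id)
    return out
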