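"""End-to-end orchestration of the serum-metabolomics classification analysis.

The pipeline reproduces the study workflow on a real or synthetic cohort
table:

1. internal-standard normalization (fits the one-component IS model, scales
   every sample, drops IS columns);
2. feature filtering to the identified-analyte modeling set;
3. pooling of clinical subgroups into diagnosis-level cohorts;
4. PCA overview of the three SLE severity phenotypes;
5. four-group PCA with per-score ROC panel for the pairwise group contrasts;
6. SIMCA class models for SLE and HV with leave-one-out validation and soft
   prediction of the pSS and SSc groups (Coomans coordinates);
7. OPLS-DA contrasts (disease vs HV and between-disease pairs) with
   p(corr) profiles, CV-ANOVA, cross-validated ROC and confusion summaries;
8. Welch significance tables per contrast; and
9. a joint cross-contrast p(corr) comparison table.

Every step is a pure function of (table, metadata, config); steps whose
required groups are absent are skipped with a logged notice.  Artifacts are
written as TSV/JSON into a run directory with a manifest recording config,
seed and versions, and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .latent import ModelError, ScalingSpec, fit_pca, q2_pca
from .normalization import apply_normalizer, fit_is_normalizer
from .oplsda import (
    OplsModel,
    confusion_from_cv,
    cross_validate,
    cv_anova,
    fit_oplsda,
)
from .simca import classify, fit_simca, loo_validate
from .stats import pca_score_roc, roc_auc, significance_table
from .tables import (
    AnalysisConfig,
    MetaboliteTable,
    SampleMetadata,
    filter_features,
    groups_of,
    pool_sle_subgroups,
)

__all__ = ["PipelineResult", "run_pipeline", "compare_profiles"]

log = logging.getLogger("metaboclass")

SLE_SUBGROUPS = ("SLE_G1", "SLE_G2", "SLE_G3")
PCA_ROC_PAIRS = (("SLE", "HV"), ("HV", "SSc"), ("SSc", "pSS"),
                 ("SLE", "SSc"), ("SLE", "pSS"))


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run, keyed by step."""

    provenance: dict
    artifacts: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def __getitem__(self, key: str):
        return self.artifacts[key]

    def __contains__(self, key: str) -> bool:
        return key in self.artifacts


def run_pipeline(
    table: MetaboliteTable,
    metadata: Sequence[SampleMetadata],
    config: Optional[AnalysisConfig] = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis sequence; see the module docstring."""
    config = config or AnalysisConfig()
    scaling = ScalingSpec(center=config.scaling_center, mode=config.scaling_mode)
    skip = set(config.skip_steps)
    result = PipelineResult(
        provenance={
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_samples": table.n_samples,
            "n_features_input": table.n_features,
            "scaling": {"center": scaling.center, "mode": scaling.mode},
        }
    )

    # 1. normalization (needs IS columns, hence runs before the feature filter)
    has_is = any(f.is_internal_standard for f in table.features)
    if "normalize" not in skip and has_is:
        norm = fit_is_normalizer(table)
        table = apply_normalizer(table, norm)
        result.artifacts["normalization"] = norm
        log.info("normalized %d samples using %d internal standards",
                 table.n_samples, len(norm.is_names))
    elif not has_is:
        result.skipped.append(("normalize", "no internal-standard columns"))
        log.info("normalization skipped: no internal-standard columns")

    # 2. feature filter
    if "filter" not in skip:
        before = table.n_features
        table = filter_features(
            table,
            drop_internal_standards=config.drop_internal_standards,
            drop_unidentified=config.drop_unidentified,
        )
        log.info("feature filter: %d -> %d features", before, table.n_features)
    result.provenance["n_features_model"] = table.n_features
    result.provenance["feature_set"] = table.feature_names

    # 3. pool clinical subgroups
    metadata = pool_sle_subgroups(metadata)
    groups = groups_of(metadata)
    for g, ids in groups.items():
        if len(ids) < 10:
            log.warning("group %s has only %d samples", g, len(ids))

    by_id = {m.sample_id: m for m in metadata}
    pooled = np.array([by_id[s].pooled_group for s in table.sample_ids])
    raw_group = np.array([by_id[s].group for s in table.sample_ids])

    # 4. SLE phenotype overview PCA
    if "phenotype_pca" not in skip:
        sle_rows = np.isin(raw_group, SLE_SUBGROUPS)
        if sle_rows.sum() >= config.n_components_overview + 2:
            Xs = table.values[sle_rows]
            a = min(config.n_components_overview,
                    int(sle_rows.sum()) - 1, table.n_features)
            model = fit_pca(Xs, a, scaling)
            model.q2_cum = q2_pca(Xs, a, scaling, folds=config.cv_folds)
            result.artifacts["phenotype_pca"] = {
                "model": model,
                "sample_ids": [s for s, keep in zip(table.sample_ids, sle_rows) if keep],
                "groups": list(raw_group[sle_rows]),
            }
        else:
            result.skipped.append(("phenotype_pca", "missing SLE subgroups"))
            log.info("phenotype PCA skipped: SLE subgroups absent")

    # 5. four-group PCA + per-score ROC
    if "overview_pca" not in skip:
        a = min(config.n_components_overview, table.n_samples - 1, table.n_features)
        model = fit_pca(table.values, a, scaling)
        model.q2_cum = q2_pca(table.values, a, scaling, folds=config.cv_folds)
        rocs = {}
        for g1, g2 in PCA_ROC_PAIRS:
            if g1 not in groups or g2 not in groups:
                result.skipped.append((f"pca_roc_{g1}_vs_{g2}", "group absent"))
                continue
            mask = np.isin(pooled, (g1, g2))
            sub = fit_pca(table.values[mask], min(2, a), scaling)
            labels = pooled[mask] == g1
            rocs[(g1, g2)] = {
                comp: {"auc": r["auc"], "sign": r["sign"]}
                for comp, r in pca_score_roc(sub, labels, (1, 2)).items()
            }
        result.artifacts["overview_pca"] = {
            "model": model,
            "groups": list(pooled),
            "score_roc": rocs,
        }

    # 6. SIMCA: SLE and HV class models, predict pSS/SSc
    if "simca" not in skip:
        if "SLE" in groups and "HV" in groups:
            comp = dict(config.simca_components_per_class)
            summaries, coomans_cv = loo_validate(
                table, metadata, ["SLE", "HV"],
                components=comp or None, alpha=config.alpha, scaling=scaling,
            )
            simca_model = fit_simca(
                table, metadata, ["SLE", "HV"],
                components=comp or None, alpha=config.alpha, scaling=scaling,
            )
            external = {}
            ext_ids = [s for s in table.sample_ids
                       if by_id[s].pooled_group in ("pSS", "SSc")]
            if ext_ids:
                sub = table.subset_samples(ext_ids)
                dists, coomans_ext = classify(
                    simca_model, sub, [by_id[s] for s in ext_ids]
                )
                # specificity of each class model against the other diseases
                spec = {
                    lab: float(np.mean(~d["inside"])) for lab, d in dists.items()
                }
                external = {
                    "distances": dists,
                    "coomans": coomans_ext,
                    "specificity": spec,
                    "specificity_mean": float(np.mean(list(spec.values()))),
                }
            result.artifacts["simca"] = {
                "model": simca_model,
                "loo_confusion": summaries,
                "coomans_cv": coomans_cv,
                "external": external,
            }
        else:
            result.skipped.append(("simca", "SLE or HV group absent"))
            log.info("SIMCA skipped: SLE or HV group absent")

    # 7. OPLS-DA contrasts
    opls_models: dict[tuple, OplsModel] = {}
    if "oplsda" not in skip:
        contrasts = {}
        for g1, g2 in config.contrasts:
            if g1 not in groups or g2 not in groups:
                result.skipped.append((f"oplsda_{g1}_vs_{g2}", "group absent"))
                log.info("OPLS-DA %s vs %s skipped: group absent", g1, g2)
                continue
            mask = np.isin(pooled, (g1, g2))
            X = table.values[mask]
            labels = list(pooled[mask])
            model = fit_oplsda(
                X, labels, config.opls_orthogonal_components, scaling,
                positive_class=g1,
            )
            cv = cross_validate(
                X, labels, config.opls_orthogonal_components,
                config.cv_folds, scaling, positive_class=g1,
            )
            contrasts[(g1, g2)] = {
                "model": model,
                "cv": cv,
                "cv_anova": cv_anova(cv),
                "confusion": confusion_from_cv(cv),
                "roc": roc_auc(cv.y_hat_cv, cv.y > 0),
            }
            opls_models[(g1, g2)] = model
        result.artifacts["oplsda"] = contrasts

    # 8. Welch significance tables
    if "significance" not in skip:
        tables = {}
        for g1, g2 in config.contrasts:
            if g1 not in groups or g2 not in groups:
                continue
            tables[(g1, g2)] = significance_table(
                table, metadata, (g1, g2), alpha=config.alpha
            )
        result.artifacts["significance"] = tables

    # 9. joint p(corr) comparison across the disease-vs-HV contrasts
    if "compare_profiles" not in skip and opls_models:
        vs_hv = {c: m for c, m in opls_models.items() if c[1] == "HV"}
        if vs_hv:
            result.artifacts["pcorr_comparison"] = compare_profiles(
                vs_hv, table.feature_names
            )

    if out_dir is not None:
        _write_artifacts(result, table, Path(out_dir))
    return result


def compare_profiles(
    models: dict, feature_names: Sequence[str]
) -> pd.DataFrame:
    """Joint p(corr) table: one row per feature, one column per contrast.

    All models must share the feature set, and each must have been fit with
    the disease as positive class so positive p(corr) means higher in
    disease.
    """
    if not models:
        raise ModelError("no models to compare")
    frame = pd.DataFrame(index=pd.Index(feature_names, name="feature"))
    for contrast, model in models.items():
        if len(model.pcorr) != len(feature_names):
            raise ModelError(
                f"model for {contrast} has {len(model.pcorr)} features, "
                f"expected {len(feature_names)}"
            )
        name = (
            "_vs_".join(contrast) if isinstance(contrast, tuple) else str(contrast)
        )
        frame[f"pcorr_{name}"] = model.pcorr
    return frame


# ---------------------------------------------------------------------------
# Artifact serialization
# ---------------------------------------------------------------------------

def _contrast_name(contrast: tuple) -> str:
    return "_vs_".join(contrast)


def _write_artifacts(
    result: PipelineResult, table: MetaboliteTable, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "provenance": {
            k: v for k, v in result.provenance.items() if k != "feature_set"
        },
        "skipped": [list(s) for s in result.skipped],
        "files": [],
    }

    def record(name: str) -> Path:
        manifest["files"].append(name)
        return out_dir / name

    if "normalization" in result:
        result["normalization"].write_tsv(record("normalization_factors.tsv"))

    for key in ("phenotype_pca", "overview_pca"):
        if key in result:
            art = result[key]
            model = art["model"]
            with open(record(f"{key}.json"), "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "r2x_cum": model.r2x_cum.tolist(),
                        "q2_cum": None
                        if model.q2_cum is None
                        else model.q2_cum.tolist(),
                        "n_components": model.n_components,
                        "score_roc": {
                            _contrast_name(c): {
                                str(comp): v for comp, v in d.items()
                            }
                            for c, d in art.get("score_roc", {}).items()
                        },
                    },
                    fh,
                    indent=1,
                )
            scores = pd.DataFrame(
                model.scores,
                columns=[f"t{a + 1}" for a in range(model.n_components)],
            )
            scores.insert(0, "group", art.get("groups", art.get("sample_ids")))
            scores.to_csv(record(f"{key}_scores.tsv"), sep="\t", index=False)

    if "simca" in result:
        art = result["simca"]
        conf = {
            lab: {
                "tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp,
                "sensitivity": c.sensitivity, "specificity": c.specificity,
            }
            for lab, c in art["loo_confusion"].items()
        }
        if art["external"]:
            conf["external_specificity"] = art["external"]["specificity"]
            conf["external_specificity_mean"] = art["external"]["specificity_mean"]
        with open(record("simca_confusion.json"), "w", encoding="utf-8") as fh:
            json.dump(conf, fh, indent=1)
        co = art["coomans_cv"]
        if co is not None:
            frame = pd.DataFrame(
                {
                    "sample_id": co.sample_ids,
                    "group": co.labels,
                    f"dmodx_{co.class1}": co.d1,
                    f"dmodx_{co.class2}": co.d2,
                }
            )
            frame[f"dcrit_{co.class1}"] = co.dcrit1
            frame[f"dcrit_{co.class2}"] = co.dcrit2
            frame.to_csv(record("coomans.tsv"), sep="\t", index=False)

    if "oplsda" in result:
        for contrast, art in result["oplsda"].items():
            name = _contrast_name(contrast)
            model, cv, anova = art["model"], art["cv"], art["cv_anova"]
            with open(record(f"oplsda_{name}.json"), "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        **model.to_dict(),
                        "q2": cv.q2,
                        "cv_anova": {
                            "F": anova.F, "p": anova.p,
                            "press": anova.press, "ss_total": anova.ss_total,
                        },
                        "confusion": {
                            "tp": art["confusion"].tp,
                            "fn": art["confusion"].fn,
                            "tn": art["confusion"].tn,
                            "fp": art["confusion"].fp,
                            "sensitivity": art["confusion"].sensitivity,
                            "specificity": art["confusion"].specificity,
                        },
                        "cv_roc_auc": art["roc"].auc,
                    },
                    fh,
                    indent=1,
                )
            pd.DataFrame(
                {"feature": table.feature_names, "pcorr": model.pcorr}
            ).to_csv(record(f"pcorr_{name}.tsv"), sep="\t", index=False)

    if "significance" in result:
        for contrast, frame in result["significance"].items():
            frame.to_csv(
                record(f"significance_{_contrast_name(contrast)}.tsv"),
                sep="\t", index=False,
            )

    if "pcorr_comparison" in result:
        result["pcorr_comparison"].to_csv(
            record("pcorr_comparison.tsv"), sep="\t"
        )

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
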