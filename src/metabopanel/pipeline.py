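"""End-to-end discovery -> validation workflow orchestration.

``run_pipeline`` chains the stages a biomarker study runs after peak
extraction: preprocessing, PCA overview, OPLS-DA with permutation validation
per comparison, differential-metabolite selection, optional precursor-mass
annotation, SVM panel search with the discovery-frozen cutoff, and validation
(plus optional early-stage subset) evaluation.  Every stage writes plain-text
outputs under the run directory, and a JSON manifest records stages, seeds,
parameters and output checksums so a run is fully reproducible from its
manifest.

A comparison whose permutation test flags overfitting (pQ2 >= 0.05) stops
before panel search unless ``force`` is set — a null model has no business
nominating biomarkers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from .classify import (
    assemble_matrix,
    clinical_marker_roc,
    evaluate,
    exhaustive_panel_search,
    hybrid_model,
    train_svm,
)
from .data import FeatureTable, SampleMetadata, read_feature_table, read_metadata
from .multivariate import fit_oplsda, fit_pca, permutation_test
from .preprocess import PreprocessConfig, preprocess_pipeline
from .univariate import ComparisonSpec, differential_analysis, write_differential_table

STAGES = (
    "preprocess", "pca", "multivariate", "differential",
    "annotate", "panel", "evaluate",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class ComparisonConfig:
    """One contrast plus its model hyperparameters.

    Defaults per contrast follow the emulated study: gamma 0.1 everywhere,
    cost 100 / seed 1000 for the normal-vs-tumour model, cost 10 / seed 520
    for the tumour-subtype models.
    """

    spec: ComparisonSpec
    n_orthogonal: int = 1
    folds: int = 7
    n_permutations: int = 1000
    gamma: float = 0.1
    cost: float = 100.0
    seed: int = 1000
    max_panel_size: int = 10
    # pipeline-level default keeps full enumeration for small candidate sets
    # and switches to greedy forward selection beyond ~2000 subsets
    budget: int = 2000
    clinical_marker: str | None = None
    fixed_marker_cutoff: float | None = None
    early_stage: bool = False            # add a FIGO I-II subset evaluation


def default_comparisons(clinical_marker: str | None = "ca125") -> list[ComparisonConfig]:
    """The three contrasts of the emulated study design."""
    return [
        ComparisonConfig(
            spec=ComparisonSpec(
                "normal", "benign+borderline+malignant",
                mode="fdr_rule", name="normal_vs_tumor",
            ),
            gamma=0.1, cost=100.0, seed=1000,
            clinical_marker=clinical_marker, fixed_marker_cutoff=35.0,
        ),
        ComparisonConfig(
            spec=ComparisonSpec(
                "benign", "malignant", mode="p_rule",
                merge_borderline_into_malignant=True,
                name="benign_vs_malignant",
            ),
            gamma=0.1, cost=10.0, seed=520,
            clinical_marker=clinical_marker, fixed_marker_cutoff=35.0,
            early_stage=True,
        ),
        ComparisonConfig(
            spec=ComparisonSpec(
                "borderline", "malignant", mode="p_rule",
                name="borderline_vs_malignant",
            ),
            gamma=0.1, cost=10.0, seed=520,
            clinical_marker=clinical_marker,
        ),
    ]


@dataclass
class RunConfig:
    feature_table_path: str | Path | None = None
    metadata_path: str | Path | None = None
    reference_list_path: str | Path | None = None
    out_dir: str | Path = "run"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    comparisons: list[ComparisonConfig] = field(default_factory=default_comparisons)
    seed: int = 0
    force: bool = False
    skip_qc_filter: bool = False
    max_candidates: int = 60             # cap panel-search candidates by VIP


# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _comparison_matrices(processed: FeatureTable, meta, comp: ComparisonSpec, cohort):
    """(X, y, sample ids) for one comparison/cohort from a processed table.

    Features constant across the selected samples are dropped (scaling would
    be undefined); returns their positions too so VIPs can be re-expanded.
    """
    ids_a, ids_b = comp.sample_ids(meta, cohort=cohort)
    ids = ids_a.append(ids_b)
    X = processed.intensities[ids].T.to_numpy()
    y = np.concatenate([np.zeros(len(ids_a), dtype=int), np.ones(len(ids_b), dtype=int)])
    keep = X.std(axis=0, ddof=1) > 0
    return X[:, keep], y, ids, keep


def run_pipeline(
    config: RunConfig,
    table: FeatureTable | None = None,
    meta: SampleMetadata | None = None,
) -> dict:
    """Execute the full workflow; returns the manifest (also written to
    ``out_dir/manifest.json``).  ``table``/``meta`` may be passed in memory,
    otherwise they are read from the configured paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if table is None:
        if config.feature_table_path is None:
            raise PipelineError("no feature table given (path or in-memory)")
        table = read_feature_table(config.feature_table_path)
    if meta is None:
        if config.metadata_path is None:
            raise PipelineError("no metadata given (path or in-memory)")
        meta = read_metadata(config.metadata_path)

    manifest: dict = {
        "stages": [],
        "seed": config.seed,
        "outputs": {},
        "comparisons": {},
    }

    def _record(stage: str, **info) -> None:
        manifest["stages"].append(stage)
        if info:
            manifest.setdefault("stage_info", {})[stage] = info

    def _write_text(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        manifest["outputs"][name] = _sha256(p)

    # 1. preprocess ---------------------------------------------------------
    try:
        processed, report = preprocess_pipeline(
            table, meta, config.preprocess, skip_qc_filter=config.skip_qc_filter
        )
    except Exception as exc:
        raise PipelineError(f"stage preprocess failed: {exc}") from exc
    p = out / "processed_table.csv"
    processed.intensities.to_csv(p, index_label="feature")
    manifest["outputs"]["processed_table.csv"] = _sha256(p)
    _write_text("preprocess_report.txt", report.to_text())
    _record(
        "preprocess",
        features_in=report.n_features_in,
        features_out=report.n_features_out,
        removed_missingness=report.removed_missingness,
        removed_qc_cv=report.removed_qc_cv,
    )

    # 2. PCA overview (all samples incl. QC) -------------------------------
    try:
        n_comp = min(5, processed.n_samples - 1, processed.n_features)
        pca = fit_pca(processed.values.T, n_components=n_comp)
        _write_text(
            "pca.json",
            json.dumps(
                {
                    "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
                    "sample_ids": list(processed.sample_ids),
                    "scores": pca.scores.tolist(),
                }
            ),
        )
    except Exception as exc:
        raise PipelineError(f"stage pca failed: {exc}") from exc
    _record("pca", explained=pca.explained_variance_ratio[:2].sum())

    references = (
        annotate_mod.read_reference_list(config.reference_list_path)
        if config.reference_list_path
        else None
    )

    # 3-7. per-comparison ---------------------------------------------------
    any_multivariate = any_diff = any_annot = any_panel = any_eval = False
    for cc in config.comparisons:
        name = cc.spec.name
        cm: dict = {"mode": cc.spec.mode}
        manifest["comparisons"][name] = cm
        try:
            X, y, ids, keep = _comparison_matrices(
                processed, meta, cc.spec, "discovery"
            )
            model = fit_oplsda(
                X, y, n_orthogonal=cc.n_orthogonal, kind="pareto",
                cv_folds=cc.folds, seed=cc.seed,
            )
            perm = permutation_test(
                X, y, n_orthogonal=cc.n_orthogonal, kind="pareto",
                folds=cc.folds, n_permutations=cc.n_permutations, seed=cc.seed,
            )
        except Exception as exc:
            raise PipelineError(f"stage multivariate ({name}) failed: {exc}") from exc
        any_multivariate = True
        _write_text(f"{name}_opls.json", json.dumps(model.to_dict()))
        _write_text(
            f"{name}_permutation.json",
            json.dumps(
                {
                    "n_permutations": perm.n_permutations,
                    "observed_r2y": perm.observed_r2y,
                    "observed_q2": perm.observed_q2,
                    "p_r2y": perm.p_r2y,
                    "p_q2": perm.p_q2,
                    "overfit": perm.overfit,
                    "seed": perm.seed,
                }
            ),
        )
        cm.update(r2y=model.r2y, q2=model.q2, p_q2=perm.p_q2, overfit=perm.overfit)

        # VIPs re-expanded over all features (dropped-constant ones get 0)
        vip_full = np.zeros(processed.n_features)
        vip_full[np.where(keep)[0]] = model.vip
        try:
            diff = differential_analysis(
                processed, meta, cc.spec, vip_full, cohort="discovery"
            )
        except Exception as exc:
            raise PipelineError(f"stage differential ({name}) failed: {exc}") from exc
        any_diff = True
        if references is not None:
            diff = annotate_mod.annotate_table(diff, references)
            any_annot = True
        dp = out / f"{name}_differential.csv"
        write_differential_table(diff, dp)
        manifest["outputs"][dp.name] = _sha256(dp)
        cm["n_selected"] = int(diff["selected"].sum())

        if perm.overfit and not config.force:
            cm["panel_search"] = "declined: permutation test flags overfitting"
            continue
        candidates = (
            diff[diff["selected"]]
            .sort_values("vip", ascending=False)["label"]
            .head(config.max_candidates)
            .tolist()
        )
        if not candidates:
            cm["panel_search"] = "declined: no differential features selected"
            continue

        try:
            Xdf = processed.intensities.loc[:, ids].T[  # samples x candidates
                candidates
            ]
            search = exhaustive_panel_search(
                candidates, Xdf, y, max_panel_size=cc.max_panel_size,
                folds=cc.folds, gamma=cc.gamma, cost=cc.cost,
                seed=cc.seed, budget=cc.budget, keep_scores=False,
            )
            panel_model = train_svm(
                Xdf[search.panel], y, panel=search.panel,
                gamma=cc.gamma, cost=cc.cost, seed=cc.seed,
            )
            cutoff = panel_model.set_cutoff_from(Xdf[search.panel].to_numpy(), y)
        except Exception as exc:
            raise PipelineError(f"stage panel ({name}) failed: {exc}") from exc
        any_panel = True
        _write_text(
            f"{name}_panel.json",
            json.dumps(
                {
                    "panel": search.panel,
                    "cv_auc": search.cv_auc,
                    "method": search.method,
                    "n_evaluated": search.n_evaluated,
                    "gamma": cc.gamma,
                    "cost": cc.cost,
                    "seed": cc.seed,
                    "cutoff": cutoff,
                    "scaling_means": panel_model.scaler.means_.tolist(),
                    "scaling_divisors": panel_model.scaler.divisors_.tolist(),
                    "training_samples_sha256": hashlib.sha256(
                        ",".join(ids).encode()
                    ).hexdigest(),
                }
            ),
        )
        cm.update(panel=search.panel, cv_auc=search.cv_auc, cutoff=cutoff,
                  search_method=search.method)

        # evaluation: discovery self-consistency + frozen-cutoff validation
        try:
            rows = []
            disc_eval = evaluate(
                panel_model, Xdf[search.panel].to_numpy(), y, cohort="discovery"
            )
            rows.append({"model": "panel", **disc_eval.to_row()})
            Xv, yv, ids_v, _ = None, None, None, None
            try:
                ids_a_v, ids_b_v = cc.spec.sample_ids(meta, cohort="validation")
            except Exception:
                ids_a_v = ids_b_v = None     # no validation cohort present
            if ids_a_v is not None:
                ids_v = ids_a_v.append(ids_b_v)
                Xv = processed.intensities.loc[search.panel, ids_v].T.to_numpy()
                yv = np.concatenate(
                    [np.zeros(len(ids_a_v), dtype=int), np.ones(len(ids_b_v), dtype=int)]
                )
                val_eval = evaluate(panel_model, Xv, yv, cohort="validation")
                rows.append({"model": "panel", **val_eval.to_row()})
                cm.update(
                    discovery_auc=disc_eval.auc, validation_auc=val_eval.auc,
                    validation_sensitivity=val_eval.sensitivity,
                    validation_specificity=val_eval.specificity,
                )
            marker = cc.clinical_marker
            if marker and marker in meta.table.columns and meta.marker(marker).notna().any():
                mk = clinical_marker_roc(
                    meta, y, marker, ids,
                    fixed_cutoff=cc.fixed_marker_cutoff, cohort="discovery",
                )
                rows.append({"model": marker, **mk.at_youden.to_row()})
                if mk.at_fixed is not None:
                    rows.append({"model": f"{marker}_fixed", **mk.at_fixed.to_row()})
                hyb, kept, _ = hybrid_model(
                    processed, meta, search.panel, marker, ids,
                    pd.Series(y, index=ids), gamma=cc.gamma, cost=cc.cost,
                    seed=cc.seed,
                )
                yk = pd.Series(y, index=ids).loc[kept].to_numpy()
                Xh_full, _, _ = assemble_matrix(
                    processed, meta, search.panel, kept, marker=marker
                )
                hyb.set_cutoff_from(Xh_full.to_numpy(), yk)
                hyb_eval = evaluate(hyb, Xh_full.to_numpy(), yk, cohort="discovery")
                rows.append({"model": f"panel+{marker}", **hyb_eval.to_row()})
            if cc.early_stage and ids_v is not None:
                stages_ok = meta.table.loc[ids_v, "stage"].isin(["I", "II"])
                benign_side = meta.table.loc[ids_v, "group"].isin(cc.spec.groups_a())
                keep_es = (stages_ok | benign_side).to_numpy()
                if keep_es.any() and len(np.unique(yv[keep_es])) == 2:
                    es_eval = evaluate(
                        panel_model, Xv[keep_es], yv[keep_es],
                        cohort="validation",
                    )
                    es_eval.subset = "early_stage"
                    rows.append({"model": "panel", **es_eval.to_row()})
        except Exception as exc:
            raise PipelineError(f"stage evaluate ({name}) failed: {exc}") from exc
        any_eval = True
        ep = out / f"{name}_evaluation.csv"
        pd.DataFrame(rows).to_csv(ep, index=False)
        manifest["outputs"][ep.name] = _sha256(ep)

    if any_multivariate:
        _record("multivariate")
    if any_diff:
        _record("differential")
    _record("annotate", enabled=bool(references))
    if any_panel:
        _record("panel")
    if any_eval:
        _record("evaluate")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
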