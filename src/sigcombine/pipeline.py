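"""End-to-end orchestration: map, impute, standardize, fit, predict, combine.

``run_stages`` executes the whole analysis on in-memory objects;
``run_pipeline`` is its file-based wrapper reading/writing the external
formats and emitting a deterministic manifest of stage outputs (path,
sha256, problem sizes) together with the configuration snapshot and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    RunConfig,
    SurvivalData,
    align_samples,
)
from .coxridge import CoxRidgeModel, CVProfile, fit_gene_set
from .evaluation import univariate_cox
from .integration import ClusterResult, CombinedPI, cluster_patients, combine_pca, export_heatmap_data
from .mapping import MappingResult, PlatformAnnotation, collapse_probes, map_gene_set
from .preprocess import knn_impute, standardize
from .signature import PIMatrix, SignatureReport, build_pi_matrix, summarize_signatures

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    mappings: dict[str, MappingResult]
    models: dict[str, CoxRidgeModel]
    profiles: dict[str, CVProfile]
    pi_matrix: PIMatrix
    signature_report: SignatureReport
    clusters: ClusterResult
    combined: CombinedPI
    evaluation: pd.DataFrame


def _map_and_collapse(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    annotation: PlatformAnnotation | None,
) -> tuple[dict[str, MappingResult], dict[str, ExpressionMatrix]]:
    """Per-set mapping and probe collapsing against one cohort's matrix.

    Without an annotation the platform is assumed native: identifiers are
    taken as probe ids directly (the synthetic generator's convention).
    """
    if annotation is None:
        frame = pd.DataFrame(
            {
                "probe_id": expr.gene_ids,
                "unigene": [""] * expr.n_genes,
                "symbol": [""] * expr.n_genes,
                "aliases": [""] * expr.n_genes,
            }
        )
        annotation = PlatformAnnotation(frame)
    mappings = {}
    collapsed = {}
    for gene_set in sets:
        mapping = map_gene_set(gene_set, annotation)
        mappings[gene_set.name] = mapping
        collapsed[gene_set.name] = collapse_probes(expr, mapping)
    return mappings, collapsed


def run_stages(
    expr_train: ExpressionMatrix,
    surv_train: SurvivalData,
    expr_test: ExpressionMatrix,
    surv_test: SurvivalData,
    sets: GeneSetCollection,
    config: RunConfig,
    annotation: PlatformAnnotation | None = None,
) -> PipelineResult:
    """Mapping -> collapse -> impute -> per-cohort standardize -> per-set
    penalty selection and fit -> test-cohort PI -> clustering + PCA
    combination -> median cut -> evaluation table."""
    try:
        mappings, collapsed_train = _map_and_collapse(expr_train, sets, annotation)
        _, collapsed_test = _map_and_collapse(expr_test, sets, annotation)
    except Exception as exc:  # noqa: BLE001
        raise StageError("map", exc) from exc

    models: dict[str, CoxRidgeModel] = {}
    profiles: dict[str, CVProfile] = {}
    std_test: dict[str, ExpressionMatrix] = {}
    grid = config.lambda_grid
    for name in sets.names:
        try:
            tr = knn_impute(collapsed_train[name], k=min(config.knn_k,
                            collapsed_train[name].n_genes - 1))
            te = knn_impute(collapsed_test[name], k=min(config.knn_k,
                            collapsed_test[name].n_genes - 1))
        except Exception as exc:  # noqa: BLE001
            raise StageError("impute", exc) from exc
        try:
            tr_std, _ = standardize(tr, source_cohort="train")
            te_std, _ = standardize(te, source_cohort="test")
            std_test[name] = te_std
        except Exception as exc:  # noqa: BLE001
            raise StageError("standardize", exc) from exc
        try:
            expr_aligned, surv_aligned = align_samples(tr_std, surv_train)
            model, profile = fit_gene_set(
                expr_aligned.values.T,
                surv_aligned,
                gene_ids=expr_aligned.gene_ids,
                grid=grid,
                scheme=config.cv_scheme,
                k=config.cv_k,
                seed=config.seed,
            )
            models[name] = model
            profiles[name] = profile
        except Exception as exc:  # noqa: BLE001
            raise StageError("fit", exc) from exc

    try:
        # per-set standardized test matrices are stacked gene-wise; gene ids
        # are unique within each model so prediction subsets per set
        pi_rows = []
        status = []
        for name in sets.names:
            from .signature import predict_pi

            pi_rows.append(predict_pi(models[name], std_test[name]))
            status.append(models[name].status)
        pim = PIMatrix(
            set_names=list(sets.names),
            sample_ids=list(expr_test.sample_ids),
            pi=np.vstack(pi_rows),
            status=status,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("predict", exc) from exc

    try:
        sig_report = _signature_report(models, pim, std_test, surv_test)
    except Exception as exc:  # noqa: BLE001
        raise StageError("signature-report", exc) from exc

    try:
        clusters = cluster_patients(pim, surv=surv_test)
        combined = combine_pca(pim, basis=config.pca_basis)
    except Exception as exc:  # noqa: BLE001
        raise StageError("combine", exc) from exc

    try:
        surv_eval = surv_test.subset(combined.sample_ids)
        rows = [
            univariate_cox(surv_eval, combined.risk_labels,
                           name="combined_pi").to_frame(),
            univariate_cox(surv_eval, clusters.risk_labels,
                           name="pi_clusters").to_frame(),
        ]
        from .signature import dichotomize_pi

        for name, row, st in zip(pim.set_names, pim.pi, pim.status):
            if st == "null_model":
                continue
            labels = dichotomize_pi(row)
            if len(np.unique(labels)) < 2:
                continue
            rows.append(univariate_cox(surv_eval, labels, name=name).to_frame())
        evaluation = pd.concat(rows, ignore_index=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", exc) from exc

    return PipelineResult(
        mappings=mappings,
        models=models,
        profiles=profiles,
        pi_matrix=pim,
        signature_report=sig_report,
        clusters=clusters,
        combined=combined,
        evaluation=evaluation,
    )


def _signature_report(models, pim, std_test, surv_test) -> SignatureReport:
    from .evaluation import logrank_test
    from .signature import delta_deviance, dichotomize_pi

    dd, lrp = [], []
    surv = surv_test.subset(pim.sample_ids)
    for name, row, st in zip(pim.set_names, pim.pi, pim.status):
        dd.append(delta_deviance(models[name], std_test[name], surv_test))
        labels = dichotomize_pi(row)
        if st == "null_model" or len(np.unique(labels)) < 2:
            lrp.append(np.nan)
        else:
            _, _, p = logrank_test(surv, labels)
            lrp.append(p)
    return SignatureReport(
        set_names=list(pim.set_names),
        delta_deviance=np.asarray(dd),
        pi_sd=pim.sd,
        logrank_p=np.asarray(lrp),
    )


# ---------------------------------------------------------------------------
# file-based wrapper with manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineManifest:
    seed: int
    config: dict
    outputs: dict[str, dict] = field(default_factory=dict)
    timestamps: dict[str, float] | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "outputs": self.outputs,
        }
        if self.timestamps is not None:
            payload["timestamps"] = self.timestamps
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(
    config: RunConfig,
    train_expression: str,
    train_clinical: str,
    test_expression: str,
    test_clinical: str,
    gene_sets: str,
    out_dir: str,
    annotation: str | None = None,
    time_column: str = "time",
    event_column: str | None = None,
    swap_cohorts: bool = False,
) -> PipelineManifest:
    """Read inputs, run every stage, write stage TSVs and the manifest.

    ``swap_cohorts`` exchanges training and test roles (the robustness
    variant, typically combined with k-fold CV in the config).  The
    manifest is deterministic given the seed; wall-clock timestamps are
    recorded only when ``config.record_timestamps`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    event_column = event_column or config.endpoint

    expr_train = sio.read_expression(train_expression)
    surv_train = sio.read_clinical(train_clinical, time_column=time_column,
                                   event_column=event_column)
    expr_test = sio.read_expression(test_expression)
    surv_test = sio.read_clinical(test_clinical, time_column=time_column,
                                  event_column=event_column)
    sets = sio.read_gmt(gene_sets, namespace="clone_id" if annotation is None
                        else "symbol")
    annot = PlatformAnnotation(sio.read_annotation(annotation)) if annotation else None

    if swap_cohorts:
        expr_train, expr_test = expr_test, expr_train
        surv_train, surv_test = surv_test, surv_train

    t0 = _time.time()
    result = run_stages(expr_train, surv_train, expr_test, surv_test, sets,
                        config, annotation=annot)

    written: dict[str, Path] = {}

    mapping_frame = pd.concat(
        [m.to_frame().assign(set=name) for name, m in result.mappings.items()],
        ignore_index=True,
    )
    written["mapping"] = out / "mapping.tsv"
    mapping_frame.to_csv(written["mapping"], sep="\t", index=False)

    profile_frame = pd.concat(
        [p.to_frame().assign(set=name) for name, p in result.profiles.items()],
        ignore_index=True,
    )
    written["cv_profiles"] = out / "cv_profiles.tsv"
    profile_frame.to_csv(written["cv_profiles"], sep="\t", index=False)

    written["pi_matrix"] = out / "pi_matrix.tsv"
    result.pi_matrix.to_frame().to_csv(written["pi_matrix"], sep="\t")

    written["signature_report"] = out / "signature_report.tsv"
    result.signature_report.to_frame().to_csv(written["signature_report"], sep="\t")

    written["heatmap"] = out / "pi_heatmap.tsv"
    export_heatmap_data(result.pi_matrix, config.trim_quantile).to_csv(
        written["heatmap"], sep="\t")

    written["combined"] = out / "combined_pi.tsv"
    result.combined.to_frame().to_csv(written["combined"], sep="\t")

    written["evaluation"] = out / "evaluation.tsv"
    result.evaluation.to_csv(written["evaluation"], sep="\t", index=False)

    manifest = PipelineManifest(
        seed=config.seed,
        config={k: (v if not isinstance(v, np.ndarray) else v.tolist())
                for k, v in dataclasses.asdict(config).items()},
        outputs={
            name: {
                "path": str(path.name),
                "sha256": _sha256(path),
                "bytes": path.stat().st_size,
            }
            for name, path in written.items()
        },
        timestamps={"elapsed_s": _time.time() - t0}
        if config.record_timestamps else None,
    )
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    logger.info("run_pipeline: %d outputs under %s", len(written), out)
    return manifest
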