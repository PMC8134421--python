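"""End-to-end orchestration on synthetic cohorts.

Runs the stages in dependency order — simulate a cohort, call ASE,
build the planted-signal feature matrix, train the boosted ensemble,
evaluate on the holdout, run the gene-function bias diagnostic and apply
the model to the full variant table — writing each stage's outputs plus
a manifest (inputs, seeds, row counts, SHA-256 checksums) so any stage
can be re-run and verified in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from .ase import AseCohortModel
from .classifier import AsePredictor, TrainConfig, TrainedEnsemble, split_holdout
from .evaluation import evaluate_ensemble
from .features import impute_and_encode
from .simulate import (CohortSimConfig, FeatureSimConfig, simulate_cohort,
                       simulate_feature_matrix, simulate_gene_annotation)

logger = logging.getLogger(__name__)


def _default_feature_config() -> FeatureSimConfig:
    effects = [1.5, 1.0, 0.8] + [0.0] * 7 + [0.8, 0.0]
    return FeatureSimConfig(n_features_numeric=10, n_features_categorical=2,
                            effect_vector=tuple(effects), missing_rate=0.05)


@dataclass
class PipelineConfig:
    """All stage settings plus the global seed and decision threshold."""

    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    features: FeatureSimConfig = field(default_factory=_default_feature_config)
    train: TrainConfig = field(default_factory=TrainConfig)
    min_individuals: int = 5
    fdr_threshold: float = 0.05
    threshold: float = 0.5
    bias_resamples: int = 10
    bias_top_k: int = 10
    loci_per_gene: int = 5
    seed: int = 0

    def __post_init__(self):
        # the global seed fans out to every stage deterministically
        self.cohort.seed = self.seed
        self.features.seed = self.seed + 1
        self.train.seed = self.seed + 2


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def apply_to_variants(ensemble: TrainedEnsemble, matrix, threshold: float = 0.5,
                      passthrough: pd.DataFrame | None = None) -> pd.DataFrame:
    """Probability and thresholded ASE flag for every variant row.

    ``passthrough`` columns (e.g. gene, MAF, consequence) are joined onto
    the output by row id; a per-gene ``k out of N`` summary is logged
    when a ``gene`` column is available.
    """
    probs = ensemble.predict_proba(matrix)
    frame = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame) else matrix
    out = pd.DataFrame({"locus_id": list(frame.index), "p_ase": probs,
                        "predicted_ase": probs >= threshold})
    if passthrough is not None:
        out = out.merge(passthrough.reset_index(), on="locus_id", how="left")
    if "gene" in out.columns:
        for gene, grp in out.groupby("gene"):
            logger.info("%s: %d out of %d variants predicted ASE",
                        gene, int(grp["predicted_ase"].sum()), len(grp))
    return out


def run_end_to_end(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, **info):
        entry = dict(info)
        entry["outputs"] = {}
        for p in info.get("paths", []):
            entry["outputs"][Path(p).name] = _sha256(Path(p))
        entry.pop("paths", None)
        manifest["stages"][stage] = entry
        logger.info("stage %s done: %s", stage, {k: v for k, v in info.items() if k != "paths"})

    try:
        # 1. simulate cohort
        cohort = simulate_cohort(config.cohort)
        counts_path, truth_path = out / "counts.tsv", out / "truth.tsv"
        cohort.write(counts_path, truth_path)
        record("simulate", paths=[counts_path, truth_path],
               n_loci=int(cohort.truth.shape[0]), n_records=int(cohort.counts.shape[0]))

        # 2. call ASE
        calls = AseCohortModel(cohort.counts).fit(config.min_individuals,
                                                  config.fdr_threshold)
        calls_path = out / "ase_calls.tsv"
        calls.to_tsv(calls_path)
        call_table = calls.table.set_index("locus_id")
        record("call_ase", paths=[calls_path], n_tested=len(calls),
               n_ase=int(call_table["is_ase"].sum()))

        # 3. features for the tested loci, planted on the simulation truth
        truth = cohort.truth.set_index("locus_id")["is_ase"]
        tested = call_table.index
        matrix = simulate_feature_matrix(truth.loc[tested], config.features)
        encoded = impute_and_encode(matrix)
        feat_path, sidecar = out / "features.tsv", out / "features.json"
        encoded.to_tsv(feat_path, sidecar)
        record("build_features", paths=[feat_path, sidecar],
               n_rows=encoded.shape[0], n_features=encoded.shape[1])

        # 4. train on the ASE calls
        labels = call_table.loc[tested, "is_ase"].astype(int)
        (X_tr, y_tr), (X_te, y_te) = split_holdout(
            encoded, labels, config.train.holdout_fraction, config.train.seed)
        ensemble = AsePredictor(X_tr, y_tr, config.train).fit()
        model_path = out / "model.joblib"
        ensemble.save(model_path)
        imp_path = out / "importance.tsv"
        ensemble.feature_importance().to_csv(imp_path, sep="\t", index=False)
        record("train", paths=[imp_path], n_train=len(X_tr),
               outer_auroc_mean=float(np.mean(ensemble.outer_aurocs)))

        # 5. holdout evaluation
        report = evaluate_ensemble(ensemble, X_te, y_te, config.threshold)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=1))
        record("evaluate", paths=[report_path], n_test=len(X_te),
               auroc_mean=report.auroc_mean)

        # 6. bias diagnostic on correctly predicted ASE-SNVs
        full_ase = call_table.index[call_table["is_ase"]].tolist()
        bias_path = out / "bias_report.tsv"
        if len(full_ase) >= 2:
            probs = ensemble.predict_proba(encoded)
            prob_map = dict(zip(encoded.row_ids, probs))
            predicted = [s for s in full_ase if prob_map[s] >= config.threshold]
            if predicted:
                gene_ids = {s: f"GENE{i // config.loci_per_gene:05d}"
                            for i, s in enumerate(sorted(tested))}
                n_genes = max(50, len(tested) // config.loci_per_gene + 1)
                anno = simulate_gene_annotation(n_genes=n_genes, n_terms=30,
                                                genes_per_term=(5, 15),
                                                seed=config.seed + 3)
                background = sorted(set(gene_ids.values()))
                bias = bias_mod.rank_resampling_test(
                    predicted, full_ase, gene_ids, anno.gene_sets, background,
                    n_resamples=config.bias_resamples, top_k=config.bias_top_k,
                    seed=config.seed + 4)
                bias.to_frame().to_csv(bias_path, sep="\t", index=False)
                record("bias_test", paths=[bias_path], subset_size=bias.subset_size,
                       n_resamples=bias.n_resamples)
            else:
                record("bias_test", skipped="no correctly predicted ASE-SNVs")
        else:
            record("bias_test", skipped="fewer than 2 ASE-SNVs called")

        # 7. apply to the full variant table
        applied = apply_to_variants(ensemble, encoded, config.threshold)
        apply_path = out / "applications.tsv"
        applied.to_csv(apply_path, sep="\t", index=False)
        record("apply", paths=[apply_path], n_variants=len(applied),
               n_predicted_ase=int(applied["predicted_ase"].sum()))
    except Exception:
        logger.exception("pipeline halted; partial outputs retained in %s", out)
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
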