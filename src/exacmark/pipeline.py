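"""End-to-end discovery and replication runs with artifact writing.

Discovery (run on the discovery cohort): preprocess -> paired moderated
differential expression -> candidate selection -> elastic-net panel fit ->
leave-pair-out CV-AUC -> constrained Youden thresholds.  Replication (run
on an independent cohort): preprocess -> score with the fixed panel ->
Mann-Whitney AUC -> apply thresholds -> rank-sum comparison; the panel is
never refitted.

Artifacts (exclusion report CSV, differential-expression table CSV, panel
JSON, evaluation report JSON and a log) are written under the configured
output directory; reports are byte-stable for a fixed config and seed
(timestamps live only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .classifier import FitConfig, PanelLogit, PanelModel
from .diffexp import PairedDifferentialExpression
from .evaluate import (
    EvalReport,
    PairScheme,
    ThresholdResult,
    auc_fixed,
    compare_states,
    evaluate_scores,
    lpocv_auc,
    select_thresholds,
    _positive_mask,
)
from .preprocess import QCThresholds, preprocess_pipeline

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage parameters of a pipeline run."""

    peptide_csv: str | None = None
    samples_csv: str | None = None
    protein_csv: str | None = None  # enter the pipeline at the protein stage
    outdir: str = "exacmark_out"
    qc: QCThresholds = field(default_factory=QCThresholds)
    fit: FitConfig = field(default_factory=FitConfig)
    scheme: PairScheme = field(default_factory=PairScheme)
    fdr_max: float = 0.01
    fc_min: float = 1.2
    dialect: dict | None = None


@dataclass
class DiscoveryResult:
    matrix: "eio.ProteinMatrix"
    exclusions: pd.DataFrame
    diffexp: pd.DataFrame
    candidates: list[str]
    panel: PanelModel
    report: EvalReport
    thresholds: ThresholdResult


def _load_matrix(cfg: RunConfig):
    """Read input at whichever stage it is provided, preprocessing if needed."""
    if cfg.protein_csv is not None:
        matrix = eio.read_protein_matrix(cfg.protein_csv, cfg.samples_csv)
        return matrix, pd.DataFrame(
            columns=["peptide_id", "protein_id", "rule", "all_failed_rules"]
        )
    if cfg.peptide_csv is None:
        raise eio.ValidationError("no input table configured")
    table = eio.read_peptide_table(cfg.peptide_csv, cfg.samples_csv, cfg.dialect)
    return preprocess_pipeline(table, cfg.qc)


def run_discovery(cfg: RunConfig, matrix=None, exclusions=None) -> DiscoveryResult:
    """Full discovery pipeline; ``matrix`` may be passed in-memory."""
    outdir = Path(cfg.outdir)
    if matrix is None:
        matrix, exclusions = _load_matrix(cfg)
    if exclusions is None:
        exclusions = pd.DataFrame(
            columns=["peptide_id", "protein_id", "rule", "all_failed_rules"]
        )
    de = PairedDifferentialExpression(matrix).fit()
    candidates = de.candidates(cfg.fdr_max, cfg.fc_min)
    if not candidates:
        raise eio.ValidationError("no candidate proteins passed the FDR/FC gate")
    logger.info("candidates (%d): %s", len(candidates), candidates)

    X = matrix.values.loc[candidates].T
    y = matrix.states()
    panel = PanelLogit(X, y, cfg.fit).fit().model
    logger.info(
        "panel: intercept %.3f, %d protein(s) %s",
        panel.intercept,
        len(panel.weights),
        sorted(panel.weights),
    )

    lp = lpocv_auc(matrix, candidates, cfg.fit, cfg.scheme, refit=True)
    labels = matrix.samples.loc[lp.heldout_scores.index, "state"]
    report = evaluate_scores(
        lp.heldout_scores,
        labels,
        cv_auc=lp.cv_auc,
        n_pairs=lp.n_pairs,
        n_failed=lp.n_failed,
    )
    thr = ThresholdResult(
        threshold_exac=report.threshold_exac,
        threshold_conv=report.threshold_conv,
        sens_at_exac=report.sens_at_exac,
        spec_at_exac=report.spec_at_exac,
        sens_at_conv=report.sens_at_conv,
        spec_at_conv=report.spec_at_conv,
    )

    outdir.mkdir(parents=True, exist_ok=True)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    de.to_table().to_csv(outdir / "diffexp_table.csv", index=False)
    panel.to_json(outdir / "panel.json")
    with open(outdir / "eval_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("discovery CV-AUC %.3f over %d pairs", report.cv_auc, lp.n_pairs)
    return DiscoveryResult(
        matrix=matrix,
        exclusions=exclusions,
        diffexp=de.frame,
        candidates=candidates,
        panel=panel,
        report=report,
        thresholds=thr,
    )


def run_replication(
    cfg: RunConfig,
    model: PanelModel,
    thresholds: ThresholdResult | None = None,
    matrix=None,
) -> EvalReport:
    """Score an independent cohort with a fixed panel (no refitting)."""
    outdir = Path(cfg.outdir)
    if matrix is None:
        matrix, _ = _load_matrix(cfg)
    missing = sorted(set(model.weights) - set(matrix.values.index))
    if missing:
        raise eio.ValidationError(f"panel protein(s) absent from cohort: {missing}")
    scores = model.score_frame(matrix.values)
    labels = matrix.samples.loc[scores.index, "state"]
    pos = _positive_mask(labels)
    auc = auc_fixed(scores[pos], scores[~pos])
    report = evaluate_scores(scores, labels, cv_auc=auc, thresholds=thresholds)
    outdir.mkdir(parents=True, exist_ok=True)
    scores.rename_axis("sample_id").to_csv(outdir / "replication_scores.csv")
    with open(outdir / "replication_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("replication AUC %.3f", report.cv_auc)
    return report
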