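"""Peptide QC filtering, LOD imputation, log2 transform and protein rollup.

The quantification unit is the per-sample ratio of endogenous peptide signal
to the spiked stable-isotope-labelled standard.  Quality control removes
peptides that quantify poorly before any statistics are computed:

* median ratio across samples below ``min_median_ratio`` (default 0.005),
* median instrument response below ``min_median_response`` (default 100),
* more than ``max_standards_out`` (default 2) heavy-standard recoveries
  outside the inclusive ``[recovery_low, recovery_high]`` window
  (default 80-120 percent),
* more than ``max_missing_fraction`` (default 25 percent) of samples
  missing, signalling that the peptide sits below the limit of detection.

All four exclusions are strict inequalities; a peptide exactly at a
threshold is retained.  Remaining missing values are imputed at half the
peptide's own minimum observed ratio (a standard below-LOD convention),
values are log2 transformed, and each protein is represented by the peptide
that attains the per-sample maximum in the largest number of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PeptideTable, ProteinMatrix, ValidationError

logger = logging.getLogger(__name__)

# attribution order for the exclusion report (first failed rule is reported)
RULE_ORDER = ("low_median_ratio", "low_median_response", "standards_out", "high_missing")


@dataclass
class QCThresholds:
    """Peptide-level QC exclusion thresholds (see module docstring)."""

    min_median_ratio: float = 0.005
    min_median_response: float = 100.0
    recovery_low: float = 80.0
    recovery_high: float = 120.0
    max_standards_out: int = 2
    max_missing_fraction: float = 0.25

    def __post_init__(self) -> None:
        vals = [
            self.min_median_ratio,
            self.min_median_response,
            self.recovery_low,
            self.recovery_high,
            self.max_missing_fraction,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError("QC thresholds must be finite")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


def _failed_rules(table: PeptideTable, q: QCThresholds) -> pd.DataFrame:
    """Boolean peptide x rule frame; medians use non-missing values only."""
    ratios = table.ratios
    med_ratio = ratios.median(axis=1, skipna=True)
    missing_frac = ratios.isna().mean(axis=1)
    n_out = pd.Series(
        [
            int(sum(1 for r in recs if not (q.recovery_low <= r <= q.recovery_high)))
            for recs in table.peptide_meta["standard_recoveries"]
        ],
        index=ratios.index,
    )
    return pd.DataFrame(
        {
            "low_median_ratio": med_ratio < q.min_median_ratio,
            "low_median_response": table.peptide_meta["median_response"]
            < q.min_median_response,
            "standards_out": n_out > q.max_standards_out,
            "high_missing": missing_frac > q.max_missing_fraction,
        }
    )


def filter_peptides(
    table: PeptideTable, q: QCThresholds | None = None
) -> tuple[PeptideTable, pd.DataFrame]:
    """Apply the four QC exclusion rules (pure conjunction of retention).

    Returns the retained table and an exclusion report with one row per
    excluded peptide, attributing the first failed rule in the fixed order
    ratio, response, standards, missingness (all failed rules are also
    listed).
    """
    q = q or QCThresholds()
    failed = _failed_rules(table, q)
    excluded = failed.any(axis=1)
    rows = []
    for pid in failed.index[excluded]:
        hits = [r for r in RULE_ORDER if failed.loc[pid, r]]
        rows.append(
            {
                "peptide_id": pid,
                "protein_id": table.peptide_meta.loc[pid, "protein_id"],
                "rule": hits[0],
                "all_failed_rules": ";".join(hits),
            }
        )
    report = pd.DataFrame(rows, columns=["peptide_id", "protein_id", "rule", "all_failed_rules"])
    kept = list(failed.index[~excluded])
    if not kept:
        err = ValidationError("all peptides excluded by QC filtering")
        err.report = report
        raise err
    logger.info(
        "QC filtering retained %d/%d peptides (%d excluded)",
        len(kept),
        table.n_peptides,
        int(excluded.sum()),
    )
    return table.subset_peptides(kept), report


def impute_missing(table: PeptideTable) -> PeptideTable:
    """Replace missing ratios by half the peptide's own minimum observed ratio."""
    out = table.copy()
    all_missing = out.ratios.isna().all(axis=1)
    if all_missing.any():
        raise ValidationError(
            f"all-missing peptide(s): {sorted(out.ratios.index[all_missing])}"
        )
    half_min = out.ratios.min(axis=1, skipna=True) * 0.5
    out.ratios = out.ratios.apply(lambda row: row.fillna(half_min[row.name]), axis=1)
    return out


def log2_transform(table: PeptideTable) -> PeptideTable:
    """Elementwise log2; raises naming the peptide and sample on nonpositive values."""
    out = table.copy()
    bad = out.ratios <= 0
    if bad.any().any():
        pid = bad.any(axis=1).idxmax()
        sid = bad.loc[pid].idxmax()
        raise ValidationError(
            f"nonpositive value at peptide {pid!r}, sample {sid!r}; "
            "impute before transforming"
        )
    out.ratios = np.log2(out.ratios)
    return out


def rollup_to_proteins(table: PeptideTable) -> ProteinMatrix:
    """Pick one representative peptide per protein and build the protein matrix.

    The representative is the peptide attaining the per-sample maximum among
    the protein's peptides in the largest number of samples; ties go to the
    peptide with the higher overall median, then to the lexicographically
    smaller peptide_id.  Provenance records the choice and the win counts.
    """
    ratios = table.ratios
    prov_rows = []
    values = []
    proteins = table.peptide_meta["protein_id"]
    for protein, meta in table.peptide_meta.groupby("protein_id", sort=True):
        peps = list(meta.index)
        block = ratios.loc[peps]
        if len(peps) == 1:
            best = peps[0]
            wins = block.shape[1]
        else:
            # a peptide "wins" a sample when it attains the per-sample max
            # (shared maxima count for every peptide attaining them)
            counts = block.eq(block.max(axis=0), axis=1).sum(axis=1)
            medians = block.median(axis=1)
            best = min(peps, key=lambda p: (-counts[p], -medians[p], p))
            wins = int(counts[best])
        prov_rows.append(
            {
                "protein_id": protein,
                "peptide_id": best,
                "wins": int(wins),
                "n_samples": block.shape[1],
                "n_peptides": len(peps),
            }
        )
        values.append(ratios.loc[best].rename(protein))
    prov = pd.DataFrame(prov_rows).set_index("protein_id")
    matrix = pd.DataFrame(values)
    matrix.index.name = "protein_id"
    return ProteinMatrix(values=matrix, samples=table.samples.copy(), provenance=prov)


def preprocess_pipeline(
    table: PeptideTable, q: QCThresholds | None = None
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """filter -> impute -> log2 -> rollup, returning matrix and exclusion report."""
    kept, report = filter_peptides(table, q)
    kept = impute_missing(kept)
    kept = log2_transform(kept)
    matrix = rollup_to_proteins(kept)
    logger.info(
        "preprocessing produced %d proteins x %d samples",
        matrix.values.shape[0],
        matrix.values.shape[1],
    )
    return matrix, report
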