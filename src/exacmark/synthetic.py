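"""Synthetic paired MRM-MS cohort generator with known ground truth.

Emulates the statistical structure the pipeline assumes: each patient
contributes a paired exacerbation/convalescent plasma sample; protein log2
abundances have a patient baseline (between-patient variation) plus
within-patient noise; a subset of proteins shifts between states by fold
changes drawn from the 1.2-1.64 range; peptide ratios are log-normal around
the protein level with a fixed per-peptide offset (so the rollup's
"highest level" choice is meaningful); low values are masked as missing
below a per-peptide limit-of-detection quantile; and a configurable number
of peptides is injected to fail each of the four QC rules.

The default differential proteins carry the gene symbols and directions of
the published 7-protein candidate list (APOA4, C9, FN1, APOC2, CRP, TTR,
LBP) so the fixed 5-protein panel can be applied to generated cohorts.

All randomness flows from a single seed through independent
``numpy.random.SeedSequence`` child streams per generation stage, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONVALESCENT, EXACERBATION, PeptideTable, ProteinMatrix

logger = logging.getLogger(__name__)

# gene symbols and state directions (+1 = up in exacerbation) of the
# default differential proteins
TABLE_PROTEINS = {
    "APOA4": -1,
    "C9": +1,
    "FN1": -1,
    "APOC2": -1,
    "CRP": +1,
    "TTR": -1,
    "LBP": +1,
}

QC_RULES = ("low_median_ratio", "low_median_response", "standards_out", "high_missing")


@dataclass
class SimConfig:
    """Generation parameters; defaults mirror the discovery-cohort scale."""

    n_patients: int = 72
    n_proteins: int = 129
    n_peptides_total: int = 230
    n_differential: int = 7
    effect_low: float = float(np.log2(1.2))
    effect_high: float = float(np.log2(1.64))
    within_patient_sd: float = 0.3
    between_patient_sd: float = 0.7
    peptide_offset_sd: float = 0.5
    baseline_mean: float = -1.5  # log2 ratio scale
    baseline_sd: float = 1.5
    lod_quantile: float = 0.05
    qc_fail_spec: dict = field(
        default_factory=lambda: {r: 3 for r in QC_RULES}
    )
    cohort: str = "synthetic"
    convalescent_day: int = 14

    def __post_init__(self) -> None:
        if self.n_differential > self.n_proteins:
            raise ValueError("n_differential exceeds n_proteins")
        if not (self.within_patient_sd > 0 and self.between_patient_sd > 0):
            raise ValueError("variance components must be positive")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must lie in [0, 1)")
        if self.n_peptides_total < self.n_proteins:
            raise ValueError("need at least one peptide per protein")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort."""

    effects: dict[str, float]  # protein -> signed log2 effect (exac - conv)
    qc_fail: dict[str, list[str]]  # rule -> peptide ids injected to fail it
    masked: list[tuple[str, str]]  # (peptide, sample) positions masked as missing
    protein_of_peptide: dict[str, str]

    def analytic_auc(self, cfg: SimConfig) -> float:
        """AUC of the true linear score sum_g effect_g * x_g over cross pairs.

        The score difference between an exacerbation and an independent
        convalescent sample is Normal(sum e^2, 2(b^2+w^2) sum e^2), giving
        AUC = Phi(sqrt(sum e^2) / sqrt(2(b^2+w^2))).
        """
        from scipy.stats import norm

        e2 = sum(v**2 for v in self.effects.values())
        sig2 = 2.0 * (cfg.between_patient_sd**2 + cfg.within_patient_sd**2)
        return float(norm.cdf(np.sqrt(e2) / np.sqrt(sig2)))


def _streams(seed: int) -> list[np.random.Generator]:
    """Independent child streams (design, effects, biology, peptide offsets,
    peptide metadata/noise, QC injection, LOD masking) from one seed."""
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    return [np.random.default_rng(s) for s in ss.spawn(7)]


def _peptide_offsets(cfg: SimConfig, counts, rng) -> list[np.ndarray]:
    """Fixed per-peptide log2 offsets (systematic response differences)."""
    return [rng.normal(0.0, cfg.peptide_offset_sd, int(k)) for k in counts]


def _protein_names(cfg: SimConfig) -> list[str]:
    named = list(TABLE_PROTEINS)
    generic = [f"PROT{i:03d}" for i in range(1, cfg.n_proteins - len(named) + 1)]
    return (named + generic)[: cfg.n_proteins]


def _peptide_counts(cfg: SimConfig, rng) -> np.ndarray:
    counts = np.ones(cfg.n_proteins, dtype=int)
    extra = cfg.n_peptides_total - cfg.n_proteins
    # distribute extra peptides (at most 2 extra per protein -> 1-3 peptides)
    order = rng.permutation(cfg.n_proteins)
    i = 0
    while extra > 0:
        p = order[i % cfg.n_proteins]
        if counts[p] < 3:
            counts[p] += 1
            extra -= 1
        i += 1
    return counts


def generate_cohort(cfg: SimConfig | None = None, seed: int = 0):
    """Generate a paired cohort; returns (PeptideTable, SimTruth)."""
    cfg = cfg or SimConfig()
    rng_design, rng_effect, rng_bio, rng_off, rng_pep, rng_qc, rng_mask = _streams(seed)

    proteins = _protein_names(cfg)
    counts = _peptide_counts(cfg, rng_design)
    offsets_by_protein = _peptide_offsets(cfg, counts, rng_off)

    # signed effects: named proteins keep their published directions
    if cfg.n_differential <= len(TABLE_PROTEINS):
        diff_proteins = list(TABLE_PROTEINS)[: cfg.n_differential]
        signs = {p: TABLE_PROTEINS[p] for p in diff_proteins}
    else:
        extra = [p for p in proteins if p not in TABLE_PROTEINS]
        diff_proteins = list(TABLE_PROTEINS) + extra[
            : cfg.n_differential - len(TABLE_PROTEINS)
        ]
        signs = {p: TABLE_PROTEINS.get(p, rng_effect.choice([-1, 1])) for p in diff_proteins}
    magnitudes = rng_effect.uniform(cfg.effect_low, cfg.effect_high, len(diff_proteins))
    effects = {p: float(signs[p] * m) for p, m in zip(diff_proteins, magnitudes)}

    mu = rng_design.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_proteins)

    n = cfg.n_patients
    baseline = mu[:, None] + rng_bio.normal(
        0.0, cfg.between_patient_sd, (cfg.n_proteins, n)
    )
    conv = baseline + rng_bio.normal(0.0, cfg.within_patient_sd, (cfg.n_proteins, n))
    exac = baseline + rng_bio.normal(0.0, cfg.within_patient_sd, (cfg.n_proteins, n))
    effect_vec = np.array([effects.get(p, 0.0) for p in proteins])
    exac = exac + effect_vec[:, None]

    patients = [f"P{i + 1:03d}" for i in range(n)]
    sample_ids = [f"{p}_E" for p in patients] + [f"{p}_C" for p in patients]
    samples = pd.DataFrame(
        {
            "patient_id": patients * 2,
            "state": [EXACERBATION] * n + [CONVALESCENT] * n,
            "cohort": cfg.cohort,
            "timepoint_days": [0] * n + [cfg.convalescent_day] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    protein_log2 = np.hstack([exac, conv])  # proteins x samples

    # peptide layer
    pep_rows, meta_rows, protein_of_peptide = [], [], {}
    for gi, (protein, k) in enumerate(zip(proteins, counts)):
        offsets = offsets_by_protein[gi]
        for pi in range(k):
            pid = f"{protein}_pep{pi + 1}"
            protein_of_peptide[pid] = protein
            noise = rng_pep.normal(0.0, 0.05, protein_log2.shape[1])
            pep_rows.append(2.0 ** (protein_log2[gi] + offsets[pi] + noise))
            meta_rows.append(
                {
                    "peptide_id": pid,
                    "protein_id": protein,
                    "uniprot_id": f"UP{gi:05d}",
                    "gene_symbol": protein,
                    "median_response": float(rng_pep.lognormal(np.log(5000.0), 0.5)),
                    "standard_recoveries": list(
                        np.round(rng_pep.normal(100.0, 5.0, 4), 1)
                    ),
                }
            )
    ratios = pd.DataFrame(
        pep_rows,
        index=pd.Index([m["peptide_id"] for m in meta_rows], name="peptide_id"),
        columns=sample_ids,
    )
    meta = pd.DataFrame(meta_rows).set_index("peptide_id")

    # QC-failure injection, targeting peptides of non-differential proteins
    eligible = [
        p
        for p in ratios.index
        if protein_of_peptide[p] not in effects
    ]
    need = sum(cfg.qc_fail_spec.get(r, 0) for r in QC_RULES)
    if need > len(eligible):
        raise ValueError("qc_fail_spec asks for more failing peptides than available")
    chosen = list(rng_qc.choice(eligible, size=need, replace=False))
    qc_fail: dict[str, list[str]] = {}
    pos = 0
    for rule in QC_RULES:
        k = cfg.qc_fail_spec.get(rule, 0)
        qc_fail[rule] = chosen[pos : pos + k]
        pos += k
    for pid in qc_fail["low_median_ratio"]:
        med = ratios.loc[pid].median()
        ratios.loc[pid] *= 0.002 / med
    for pid in qc_fail["low_median_response"]:
        meta.at[pid, "median_response"] = float(rng_qc.uniform(10.0, 90.0))
    for pid in qc_fail["standards_out"]:
        meta.at[pid, "standard_recoveries"] = [70.0, 131.5, 74.2, 100.0]

    # below-LOD masking: lowest lod_quantile of each peptide's values
    masked: list[tuple[str, str]] = []
    if cfg.lod_quantile > 0:
        for pid in ratios.index:
            row = ratios.loc[pid]
            cutoff = row.quantile(cfg.lod_quantile)
            low = row.index[row < cutoff]
            ratios.loc[pid, low] = np.nan
            masked.extend((pid, s) for s in low)
    for pid in qc_fail["high_missing"]:
        row = ratios.loc[pid]
        present = [s for s in row.index if not np.isnan(row[s])]
        k = int(np.ceil(0.30 * len(row.index))) - int(row.isna().sum())
        drop = rng_mask.choice(present, size=max(k, 0), replace=False)
        ratios.loc[pid, drop] = np.nan
        masked.extend((pid, s) for s in drop)

    table = PeptideTable(ratios=ratios, peptide_meta=meta, samples=samples)
    truth = SimTruth(
        effects=effects,
        qc_fail=qc_fail,
        masked=masked,
        protein_of_peptide=protein_of_peptide,
    )
    logger.info(
        "generated cohort: %d patients, %d proteins, %d peptides (seed %d)",
        n,
        cfg.n_proteins,
        table.n_peptides,
        seed,
    )
    return table, truth


def generate_external_group(
    cfg: SimConfig | None = None,
    shift: float = 0.0,
    n_samples: int = 20,
    seed: int = 0,
    cohort: str = "external",
) -> ProteinMatrix:
    """Unpaired samples from the convalescent distribution plus a mean shift.

    ``shift`` may be a scalar (applied to all proteins) or a mapping
    protein -> shift.  Returns a log2 ProteinMatrix directly on the scale
    the preprocessing pipeline would produce for a cohort with the same
    seed (each protein carries its representative-peptide offset, the
    maximum of that protein's fixed offsets); ``n_samples = 0`` yields an
    empty matrix.
    """
    cfg = cfg or SimConfig()
    rng_design, _, _, rng_off, _, _, _ = _streams(seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE87E47A1]))
    proteins = _protein_names(cfg)
    counts = _peptide_counts(cfg, rng_design)
    offsets = _peptide_offsets(cfg, counts, rng_off)
    mu = rng_design.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_proteins)
    rep_offset = np.array([o.max() for o in offsets])
    total_sd = np.sqrt(cfg.between_patient_sd**2 + cfg.within_patient_sd**2)
    values = (
        mu[:, None]
        + rep_offset[:, None]
        + rng.normal(0.0, total_sd, (cfg.n_proteins, n_samples))
    )
    if np.isscalar(shift):
        values = values + float(shift)
    else:
        values = values + np.array([shift.get(p, 0.0) for p in proteins])[:, None]
    ids = [f"X{i + 1:03d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "patient_id": ids,
            "state": CONVALESCENT,
            "cohort": cohort,
            "timepoint_days": 0,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return ProteinMatrix(
        values=pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"), columns=ids),
        samples=samples,
        provenance=None,
    )
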