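"""Paired differential expression with empirical-Bayes variance moderation.

For each protein g the paired log2 difference (exacerbation minus
convalescence) is computed per patient.  Per-protein variances are shrunk
toward a prior scaled inverse-chi-square distribution with hyperparameters
(d0, s0^2) estimated across proteins by the method of moments on the log
variances (Smyth's moderated t).  With n patients and d = n - 1 residual
degrees of freedom,

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_tilde_g   = mean_g / (s_tilde_g / sqrt(n))

and two-sided p-values come from a t distribution with d0 + d degrees of
freedom (standard normal when d0 is infinite).  Benjamini-Hochberg adjusted
p-values control the FDR, and candidate proteins are those with FDR < 0.01
and fold change > 1.2 (both strict, evaluated on unrounded values).

The model object follows the usual fit/results split:

>>> results = PairedDifferentialExpression(matrix).fit()
>>> results.frame          # per-protein statistics
>>> results.candidates()   # FDR/fold-change gated protein list
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CONVALESCENT, EXACERBATION, ProteinMatrix, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# paired differences


def paired_differences(matrix: ProteinMatrix, convalescent_pick: str = "earliest"):
    """Per-protein, per-patient paired log2 differences (exac - conv).

    Each patient must contribute exactly one exacerbation sample; patients
    with several convalescent timepoints contribute the earliest (or
    ``latest``) one, and the choice is logged.  Patients missing either
    state raise a ``ValidationError`` listing them.
    """
    if convalescent_pick not in ("earliest", "latest"):
        raise ValueError("convalescent_pick must be 'earliest' or 'latest'")
    samples = matrix.samples.loc[matrix.values.columns]
    exac, conv, patients = [], [], []
    unpaired = []
    for patient, grp in samples.groupby("patient_id", sort=True):
        e = grp[grp["state"] == EXACERBATION]
        c = grp[grp["state"] == CONVALESCENT]
        if len(e) != 1 or len(c) == 0:
            unpaired.append(patient)
            continue
        if len(c) > 1:
            c = c.sort_values("timepoint_days")
            chosen = c.index[0] if convalescent_pick == "earliest" else c.index[-1]
            logger.info(
                "patient %s has %d convalescent samples; using %s (%s)",
                patient,
                len(c),
                chosen,
                convalescent_pick,
            )
        else:
            chosen = c.index[0]
        exac.append(e.index[0])
        conv.append(chosen)
        patients.append(patient)
    if unpaired:
        raise ValidationError(f"unpaired patient(s): {unpaired}")
    diffs = (
        matrix.values[exac].to_numpy() - matrix.values[conv].to_numpy()
    )
    return pd.DataFrame(diffs, index=matrix.values.index, columns=patients)


# ---------------------------------------------------------------------------
# empirical-Bayes hyperparameters


@dataclass
class ModerationHyperparams:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float  # may be math.inf
    s0_sq: float


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (monotone decreasing, so unique).

    Newton iteration on the reciprocal scale, as is standard for this
    function; for extreme y the asymptotic limits 1/y (y -> 0) and
    1/sqrt(y) (y -> inf) seed the search.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(variances, df: int) -> ModerationHyperparams:
    """Method-of-moments fit of (d0, s0^2) from per-protein sample variances.

    Works on z_g = log s_g^2, whose mean and spread under the scaled
    inverse-chi-square model identify the hyperparameters through digamma /
    trigamma moments.  When the observed spread does not exceed what df
    degrees of freedom already imply, d0 is infinite and s0^2 is the
    common-variance (geometric-mean based) limit.
    """
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size < 2:
        raise ValidationError("need at least 2 finite variances")
    if df < 1:
        raise ValidationError("df must be >= 1")
    # guard exact zeros (constant differences) — tiny positive floor
    floor = np.finfo(float).tiny
    z = np.log(np.maximum(s2, floor))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return ModerationHyperparams(d0=np.inf, s0_sq=float(np.exp(e.mean())))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationHyperparams(d0=float(d0), s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated test and multiplicity


def moderated_paired_test(
    diffs: pd.DataFrame, hyper: ModerationHyperparams | None = None
) -> pd.DataFrame:
    """Moderated one-sample t-test on each row of a difference matrix.

    ``hyper`` defaults to hyperparameters estimated from the data; passing
    d0 = 0 recovers the ordinary paired t-test, d0 = inf the fully
    shrunken (normal-reference) statistic.
    """
    n = diffs.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 patients")
    d = n - 1
    x = diffs.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    if hyper is None:
        hyper = estimate_moderation(s2, d)
    if np.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0_sq)
        df_total = np.inf
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + d * s2) / (hyper.d0 + d)
        df_total = hyper.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    t = np.where(mean == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    frame = pd.DataFrame(
        {
            "mean_log2_diff": mean,
            "moderated_t": t,
            "df_total": df_total,
            "p_value": p,
            "fdr": bh_fdr(p),
            "fold_change": 2.0 ** np.abs(mean),
            "direction": np.where(mean > 0, "Up", "Down"),
        },
        index=diffs.index,
    )
    frame.attrs["d0"] = hyper.d0
    frame.attrs["s0_sq"] = hyper.s0_sq
    frame.attrs["n_patients"] = n
    return frame


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_candidates(
    results: pd.DataFrame, fdr_max: float = 0.01, fc_min: float = 1.2
) -> list[str]:
    """Proteins with fdr < fdr_max and fold_change > fc_min (strict), by p ascending."""
    hits = results[(results["fdr"] < fdr_max) & (results["fold_change"] > fc_min)]
    return list(hits.sort_values("p_value").index)


# ---------------------------------------------------------------------------
# model / results objects


class PairedDifferentialExpression:
    """Moderated paired t-test model over a :class:`ProteinMatrix`.

    Parameters
    ----------
    matrix : ProteinMatrix
        Log2 protein levels with paired exacerbation/convalescent samples.
    convalescent_pick : str
        Which convalescent timepoint represents patients with several
        ("earliest" or "latest").
    """

    def __init__(self, matrix: ProteinMatrix, convalescent_pick: str = "earliest"):
        self.matrix = matrix
        self.diffs = paired_differences(matrix, convalescent_pick)

    def fit(self, hyper: ModerationHyperparams | None = None) -> "DiffExpResults":
        frame = moderated_paired_test(self.diffs, hyper)
        return DiffExpResults(frame, self)


class DiffExpResults:
    """Per-protein moderated statistics with multiplicity adjustment."""

    def __init__(self, frame: pd.DataFrame, model: PairedDifferentialExpression):
        self.frame = frame
        self.model = model
        self.d0 = frame.attrs["d0"]
        self.s0_sq = frame.attrs["s0_sq"]
        self.n_patients = frame.attrs["n_patients"]

    def candidates(self, fdr_max: float = 0.01, fc_min: float = 1.2) -> list[str]:
        return select_candidates(self.frame, fdr_max, fc_min)

    def to_table(self, peptide_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        """Publication-shaped table (peptide/protein annotations + statistics)."""
        out = self.frame.sort_values("p_value").copy()
        out = out[["p_value", "fdr", "fold_change", "direction"]]
        out.insert(0, "protein_id", out.index)
        if peptide_meta is not None:
            ann = peptide_meta.drop_duplicates("protein_id").set_index("protein_id")
            out.insert(0, "gene_symbol", ann["gene_symbol"].reindex(out.index).values)
            out.insert(0, "uniprot_id", ann["uniprot_id"].reindex(out.index).values)
        return out.reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Paired differential expression (moderated t)",
            f"  proteins: {len(self.frame)}   patients: {self.n_patients}",
            f"  prior df d0: {self.d0:.4g}   prior variance s0^2: {self.s0_sq:.4g}",
            f"  candidates (FDR<0.01, FC>1.2): {len(self.candidates())}",
            "",
            self.frame.sort_values("p_value")
            .head(10)
            .to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
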