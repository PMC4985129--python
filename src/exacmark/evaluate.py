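"""Leave-pair-out cross-validated AUC, thresholds, predictive values.

Plain resubstitution AUCs overfit badly at the sample sizes typical of
paired exacerbation cohorts, so out-of-sample performance is estimated by
leave-pair-out cross-validation (LPOCV): for every (positive, negative)
sample pair the panel is refitted with the pair held out (and, by default,
every sample of the two patients involved, so a held-out sample's partner
never leaks into training) and the pair contributes 1, 0.5 or 0 according
to whether the held-out positive outscores the negative.  The mean over
pairs is the CV-AUC — with refitting disabled it reduces exactly to the
Mann-Whitney AUC of the fixed score.

Decision thresholds on the biomarker score are selected from held-out
scores: one cutoff guarantees sensitivity >= 0.90 for detecting
exacerbation, another specificity >= 0.90 for detecting convalescence, and
each maximizes Youden's J = sens + spec - 1 subject to its constraint.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import FitConfig, PanelLogit, PanelModel
from .io import CONVALESCENT, EXACERBATION, ProteinMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PairScheme:
    """Which (positive, negative) pairs to hold out, and how."""

    mode: str = "all_cross_pairs"  # or "within_patient_pairs"
    patient_aware_removal: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("all_cross_pairs", "within_patient_pairs"):
            raise ValueError(f"unknown pair scheme mode {self.mode!r}")


@dataclass
class ThresholdResult:
    threshold_exac: float
    threshold_conv: float
    sens_at_exac: float
    spec_at_exac: float
    sens_at_conv: float
    spec_at_conv: float


@dataclass
class LpocvResult:
    cv_auc: float
    heldout_scores: pd.Series  # mean held-out score per sample
    n_pairs: int
    n_failed: int  # pairs excluded because the inner fit failed


@dataclass
class EvalReport:
    """Bundle of the evaluation outputs, serializable to JSON."""

    cv_auc: float
    roc_points: list  # (1 - specificity, sensitivity) pairs
    threshold_exac: float
    threshold_conv: float
    sens_at_exac: float
    spec_at_exac: float
    sens_at_conv: float
    spec_at_conv: float
    wilcoxon_p: float
    ppv_npv_table: list
    n_pairs: int = 0
    n_failed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# fixed-score AUC


def auc_fixed(scores_pos, scores_neg) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 * P(pos = neg)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be nonempty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """(1 - specificity, sensitivity) swept over all score cutoffs."""
    scores = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(pos[order])
    fp = np.cumsum(~pos[order])
    sens = tp / max(pos.sum(), 1)
    fpr = fp / max((~pos).sum(), 1)
    pts = [(0.0, 0.0)] + list(zip(fpr.tolist(), sens.tolist()))
    return pts


def _positive_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    return np.asarray(
        [v in (1, True, EXACERBATION) for v in labels], dtype=bool
    )


# ---------------------------------------------------------------------------
# leave-pair-out cross-validation


def _pair_seed(global_seed: int, removed_patients) -> int:
    tag = "|".join(sorted(map(str, removed_patients)))
    return (int(global_seed) ^ zlib.crc32(tag.encode())) % (2**31 - 1)


def lpocv_auc(
    matrix: ProteinMatrix,
    candidates,
    fit_cfg: FitConfig | None = None,
    scheme: PairScheme | None = None,
    refit: bool = True,
    model: PanelModel | None = None,
) -> LpocvResult:
    """Leave-pair-out cross-validated AUC over a candidate-protein matrix.

    With ``refit=True`` the elastic net is refitted for every held-out
    training set (training sets are cached by the removed patient set, and
    each fold's inner CV gets a deterministic seed derived from the global
    seed and the removed patients).  With ``refit=False`` a fixed ``model``
    scores everything once — the estimator then equals the Mann-Whitney
    AUC of that score.
    """
    fit_cfg = fit_cfg or FitConfig()
    scheme = scheme or PairScheme()
    candidates = list(candidates)
    X = matrix.values.loc[candidates].T  # samples x proteins
    states = matrix.states()
    patients = matrix.samples.loc[X.index, "patient_id"]
    pos_ids = list(X.index[states == EXACERBATION])
    neg_ids = list(X.index[states == CONVALESCENT])
    if len(pos_ids) < 2 or len(neg_ids) < 2:
        raise ValidationError("need at least 2 samples per class")

    if scheme.mode == "within_patient_pairs":
        by_patient = {patients[s]: s for s in pos_ids}
        pairs = [
            (by_patient[patients[j]], j)
            for j in neg_ids
            if patients[j] in by_patient
        ]
    else:
        pairs = [(i, j) for i in pos_ids for j in neg_ids]

    if not refit:
        if model is None:
            raise ValidationError("refit=False requires a fixed model")
        s = model.score_frame(X.T)
        wins = [_h(s[i] - s[j]) for i, j in pairs]
        return LpocvResult(
            cv_auc=float(np.mean(wins)),
            heldout_scores=s,
            n_pairs=len(pairs),
            n_failed=0,
        )

    y = (states == EXACERBATION).astype(int)
    cache: dict[frozenset, PanelModel | None] = {}
    sums = pd.Series(0.0, index=X.index)
    counts = pd.Series(0, index=X.index)
    wins, n_failed = [], 0
    for i, j in pairs:
        removed_patients = frozenset({patients[i], patients[j]})
        if scheme.patient_aware_removal:
            held = set(X.index[patients.isin(removed_patients).to_numpy()])
        else:
            held = {i, j}
        key = frozenset(held)
        if key not in cache:
            train = [s for s in X.index if s not in held]
            cfg = FitConfig(
                alpha=fit_cfg.alpha,
                lambda_grid=fit_cfg.lambda_grid,
                n_lambda=fit_cfg.n_lambda,
                lambda_min_ratio=fit_cfg.lambda_min_ratio,
                inner_cv_folds=fit_cfg.inner_cv_folds,
                seed=_pair_seed(fit_cfg.seed, removed_patients),
                selection_rule=fit_cfg.selection_rule,
            )
            try:
                cache[key] = PanelLogit(X.loc[train], y.loc[train], cfg).fit().model
            except Exception as exc:  # fold fit failed: pair will be excluded
                logger.warning("LPOCV fold fit failed (%s): %s", sorted(held), exc)
                cache[key] = None
        fold_model = cache[key]
        if fold_model is None:
            n_failed += 1
            continue
        si = fold_model.score(X.loc[i])
        sj = fold_model.score(X.loc[j])
        wins.append(_h(si - sj))
        sums[i] += si
        counts[i] += 1
        sums[j] += sj
        counts[j] += 1
    if not wins:
        raise ValidationError("every LPOCV pair failed to fit")
    heldout = sums[counts > 0] / counts[counts > 0]
    return LpocvResult(
        cv_auc=float(np.mean(wins)),
        heldout_scores=heldout.rename("biomarker_score"),
        n_pairs=len(pairs),
        n_failed=n_failed,
    )


def _h(delta: float) -> float:
    return 1.0 if delta > 0 else (0.5 if delta == 0 else 0.0)


# ---------------------------------------------------------------------------
# thresholds and predictive values


def _sens_spec(scores, pos, threshold) -> tuple[float, float]:
    pred_pos = scores >= threshold
    sens = float(np.mean(pred_pos[pos])) if pos.any() else np.nan
    spec = float(np.mean(~pred_pos[~pos])) if (~pos).any() else np.nan
    return sens, spec


def select_thresholds(scores, labels) -> ThresholdResult:
    """Constrained Youden threshold selection on held-out scores.

    Candidate cutoffs are the midpoints between adjacent distinct scores;
    a sample is called an exacerbation when score >= threshold.
    ``threshold_exac`` maximizes J among cutoffs with sensitivity >= 0.90,
    ``threshold_conv`` among cutoffs with specificity >= 0.90.  Raises when
    a constraint cannot be met (e.g. all scores identical).
    """
    scores = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels)
    if not pos.any() or pos.all():
        raise ValidationError("both classes must be present")
    uniq = np.unique(scores)
    cutoffs = (uniq[:-1] + uniq[1:]) / 2.0
    best = {"exac": None, "conv": None}
    for c in cutoffs:
        sens, spec = _sens_spec(scores, pos, c)
        j = sens + spec - 1.0
        if sens >= 0.90:
            cur = best["exac"]
            if cur is None or (j, spec, c) > (cur[1], cur[2], cur[0]):
                best["exac"] = (c, j, spec, sens)
        if spec >= 0.90:
            cur = best["conv"]
            if cur is None or (j, sens, -c) > (cur[1], cur[3], -cur[0]):
                best["conv"] = (c, j, spec, sens)
    if best["exac"] is None:
        raise ValidationError("no cutoff achieves sensitivity >= 0.90")
    if best["conv"] is None:
        raise ValidationError("no cutoff achieves specificity >= 0.90")
    te, _, spec_e, sens_e = best["exac"]
    tc, _, spec_c, sens_c = best["conv"]
    return ThresholdResult(
        threshold_exac=float(te),
        threshold_conv=float(tc),
        sens_at_exac=sens_e,
        spec_at_exac=spec_e,
        sens_at_conv=sens_c,
        spec_at_conv=spec_c,
    )


def ppv_npv(sens: float, spec: float, prevalence_grid) -> pd.DataFrame:
    """Positive/negative predictive values over a prevalence grid.

    PPV = sens*pi / (sens*pi + (1-spec)(1-pi)); NPV = spec(1-pi) /
    ((1-sens)pi + spec(1-pi)); 0/0 is reported as NaN (undefined), not 0.
    """
    pi = np.asarray(prevalence_grid, dtype=float)
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("prevalences must lie in [0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv_num = sens * pi
        ppv_den = sens * pi + (1.0 - spec) * (1.0 - pi)
        npv_num = spec * (1.0 - pi)
        npv_den = (1.0 - sens) * pi + spec * (1.0 - pi)
        ppv = np.where(ppv_den > 0, ppv_num / np.where(ppv_den > 0, ppv_den, 1), np.nan)
        npv = np.where(npv_den > 0, npv_num / np.where(npv_den > 0, npv_den, 1), np.nan)
    return pd.DataFrame({"prevalence": pi, "ppv": ppv, "npv": npv})


# ---------------------------------------------------------------------------
# score-distribution comparison


def compare_states(scores, labels) -> float:
    """Two-sided Wilcoxon rank-sum p-value between the two score groups.

    Uses exact enumeration when both groups have <= 10 tie-free
    observations, otherwise the tie-corrected normal approximation.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels)
    x, ycomp = scores[pos], scores[~pos]
    if x.size == 0 or ycomp.size == 0:
        raise ValidationError("both classes must be nonempty")
    ties = np.unique(scores).size < scores.size
    method = "exact" if (x.size <= 10 and ycomp.size <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, ycomp, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def evaluate_scores(
    scores: pd.Series,
    labels,
    prevalence_grid=(0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
    cv_auc: float | None = None,
    n_pairs: int = 0,
    n_failed: int = 0,
    thresholds: ThresholdResult | None = None,
) -> EvalReport:
    """Assemble an :class:`EvalReport` from per-sample scores and labels.

    Thresholds are selected from the scores unless fixed ``thresholds``
    (e.g. carried over from a discovery run) are supplied, in which case
    the reported sensitivities/specificities are those of the fixed
    cutoffs on these scores.
    """
    scores = pd.Series(scores)
    pos = _positive_mask(labels)
    auc = auc_fixed(scores[pos], scores[~pos]) if cv_auc is None else cv_auc
    if thresholds is None:
        thr = select_thresholds(scores.to_numpy(), labels)
    else:
        s = scores.to_numpy()
        se, sp_e = _sens_spec(s, pos, thresholds.threshold_exac)
        sc, sp_c = _sens_spec(s, pos, thresholds.threshold_conv)
        thr = ThresholdResult(
            threshold_exac=thresholds.threshold_exac,
            threshold_conv=thresholds.threshold_conv,
            sens_at_exac=se,
            spec_at_exac=sp_e,
            sens_at_conv=sc,
            spec_at_conv=sp_c,
        )
    table = ppv_npv(thr.sens_at_exac, thr.spec_at_exac, prevalence_grid)
    return EvalReport(
        cv_auc=float(auc),
        roc_points=roc_points(scores.to_numpy(), labels),
        threshold_exac=thr.threshold_exac,
        threshold_conv=thr.threshold_conv,
        sens_at_exac=thr.sens_at_exac,
        spec_at_exac=thr.spec_at_exac,
        sens_at_conv=thr.sens_at_conv,
        spec_at_conv=thr.spec_at_conv,
        wilcoxon_p=compare_states(scores.to_numpy(), labels),
        ppv_npv_table=table.to_numpy().tolist(),
        n_pairs=n_pairs,
        n_failed=n_failed,
    )
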