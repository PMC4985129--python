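"""Elastic-net logistic biomarker panels and the fixed 5-protein score.

The biomarker score is the linear predictor of a penalized logistic
regression of disease state (exacerbation = 1) on log2 protein levels,

    score = w0 + w1 * protein1 + ... + wN * proteinN,

with the glmnet-style penalty lambda * [alpha * ||w||_1 +
(1 - alpha)/2 * ||w||_2^2].  Features are standardized internally before
penalization and the coefficients are reported back on the input (log2)
scale.  lambda is chosen on a log-spaced grid by inner stratified k-fold
cross-validated deviance, with either the deviance-minimizing value or the
parsimonious one-standard-error value (the default, which favours
stringent feature selection).

The published 5-protein panel (apolipoprotein A-IV, complement C9,
fibronectin, apolipoprotein C-II and LBP, keyed by gene symbol) ships as a
fixed :class:`PanelModel` via :func:`published_panel`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import EXACERBATION, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Hyperparameters of the elastic-net fit.

    alpha is the L1 mixing weight in (0, 1]; lambda_grid (descending) is
    built from the data when omitted, spanning lambda_max down to
    lambda_max * lambda_min_ratio over n_lambda log-spaced values.
    """

    alpha: float = 0.9
    lambda_grid: list[float] | None = None
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    inner_cv_folds: int = 5
    seed: int = 20160815
    selection_rule: str = "one_se"  # or "min_deviance"
    tol: float = 1e-5  # saga convergence tolerance

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.selection_rule not in ("one_se", "min_deviance"):
            raise ValueError("selection_rule must be 'one_se' or 'min_deviance'")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if self.lambda_grid is not None:
            grid = sorted(float(l) for l in self.lambda_grid)
            if not grid or grid[0] <= 0:
                raise ValueError("lambda_grid must be nonempty and positive")
            self.lambda_grid = grid[::-1]


@dataclass
class PanelModel:
    """A fitted (or fixed) biomarker panel: intercept + sparse weights."""

    intercept: float
    weights: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def score(self, values) -> float | pd.Series:
        """Linear predictor w0 + sum_i w_i * value_i (no logistic transform).

        ``values`` is a mapping/Series (one sample, returns a float) or a
        DataFrame with proteins as columns or rows (returns a Series per
        sample).  Every panel protein must be present.
        """
        if isinstance(values, pd.DataFrame):
            frame = values
            if not set(self.weights) <= set(frame.columns) and set(
                self.weights
            ) <= set(frame.index):
                frame = frame.T
            missing = sorted(set(self.weights) - set(frame.columns))
            if missing:
                raise ValidationError(f"missing panel protein(s): {missing}")
            w = pd.Series(self.weights)
            return frame[list(w.index)].to_numpy() @ w.to_numpy() + self.intercept
        values = dict(values) if not isinstance(values, pd.Series) else values
        missing = sorted(set(self.weights) - set(values.keys() if isinstance(values, dict) else values.index))
        if missing:
            raise ValidationError(f"missing panel protein(s): {missing}")
        total = self.intercept
        for pid, w in self.weights.items():
            total += w * float(values[pid])
        return float(total)

    def score_frame(self, frame: pd.DataFrame) -> pd.Series:
        """Per-sample scores for a proteins-by-samples (or transposed) frame."""
        cols = frame.columns if set(self.weights) <= set(frame.index) else frame.index
        vals = self.score(frame)
        return pd.Series(np.asarray(vals), index=cols, name="biomarker_score")

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "intercept": self.intercept,
                "weights": self.weights,
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "PanelModel":
        if hasattr(source, "read"):
            data = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(
            intercept=float(data["intercept"]),
            weights={k: float(v) for k, v in data["weights"].items()},
            metadata=data.get("metadata", {}),
        )


# fixed, published panel weights on the log2 protein scale (gene symbols)
_PUBLISHED_INTERCEPT = -0.272
_PUBLISHED_WEIGHTS = {
    "APOA4": -1.016,  # apolipoprotein A-IV
    "C9": 0.643,  # complement component C9
    "FN1": -0.321,  # fibronectin
    "APOC2": -0.225,  # apolipoprotein C-II
    "LBP": 0.289,  # lipopolysaccharide-binding protein
}


def published_panel() -> PanelModel:
    """The fixed 5-protein AECOPD panel (intercept -0.272)."""
    return PanelModel(
        intercept=_PUBLISHED_INTERCEPT,
        weights=dict(_PUBLISHED_WEIGHTS),
        metadata={"source": "published 5-protein panel"},
    )


# ---------------------------------------------------------------------------
# elastic-net fitting


def _lambda_max(Xs: np.ndarray, y: np.ndarray, alpha: float) -> float:
    n = len(y)
    resid = y - y.mean()
    return float(np.max(np.abs(Xs.T @ resid)) / (n * max(alpha, 1e-3)))


def _path_fit(Xs, y, lambdas, alpha, tol=1e-5, random_state=0):
    """Warm-started coefficient path over a descending lambda grid."""
    n = len(y)
    est = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        max_iter=20000,
        tol=tol,
        warm_start=True,
        random_state=random_state,
    )
    coefs, intercepts = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            est.C = 1.0 / (n * lam)
            est.fit(Xs, y)
            coefs.append(est.coef_[0].copy())
            intercepts.append(float(est.intercept_[0]))
    return np.array(coefs), np.array(intercepts)


def _deviance(Xs, y, coef, intercept) -> float:
    """Mean binomial deviance (2 * mean negative log-likelihood)."""
    eta = Xs @ coef + intercept
    # log(1 + exp(-y*eta)) with y in {-1, +1}, computed stably
    yy = 2.0 * y - 1.0
    return float(2.0 * np.mean(np.logaddexp(0.0, -yy * eta)))


class PanelLogit:
    """Elastic-net logistic panel model (fit on candidate proteins).

    Parameters
    ----------
    X : DataFrame, samples x proteins
        Log2 protein levels for the candidate proteins.
    y : array-like
        Binary state labels (1/"exacerbation" = positive class).
    config : FitConfig
    """

    def __init__(self, X: pd.DataFrame, y, config: FitConfig | None = None):
        self.config = config or FitConfig()
        self.X = X
        self.feature_names = list(X.columns)
        if not self.feature_names:
            raise ValidationError("empty candidate set")
        y = np.asarray(
            [1 if v in (1, True, EXACERBATION) else 0 for v in np.asarray(y)]
        )
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValidationError("labels contain a single class")
        if min(np.sum(y == 0), np.sum(y == 1)) < 2:
            raise ValidationError("need at least 2 samples per class")
        self.y = y

    def fit(self) -> "PanelFit":
        cfg = self.config
        X = self.X.to_numpy(dtype=float)
        y = self.y
        n = len(y)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd_safe

        if cfg.lambda_grid is not None:
            lambdas = np.asarray(cfg.lambda_grid, dtype=float)
        else:
            lmax = max(_lambda_max(Xs, y, cfg.alpha), 1e-6)
            lambdas = np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.n_lambda)

        # inner CV deviance per lambda
        folds = min(cfg.inner_cv_folds, int(np.min(np.bincount(y))))
        cv_dev = None
        if len(lambdas) > 1:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
            dev = np.empty((folds, len(lambdas)))
            for k, (tr, va) in enumerate(skf.split(Xs, y)):
                if len(np.unique(y[tr])) < 2:
                    dev[k] = np.nan
                    continue
                coefs, intercepts = _path_fit(
                    Xs[tr], y[tr], lambdas, cfg.alpha, cfg.tol,
                    random_state=(cfg.seed + k) % (2**31 - 1),
                )
                dev[k] = [
                    _deviance(Xs[va], y[va], c, b)
                    for c, b in zip(coefs, intercepts)
                ]
            cv_mean = np.nanmean(dev, axis=0)
            cv_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(folds)
            best = int(np.nanargmin(cv_mean))
            if cfg.selection_rule == "one_se":
                ok = np.where(cv_mean <= cv_mean[best] + cv_se[best])[0]
                chosen = int(ok[0])  # grid is descending: first = most penalized
            else:
                chosen = best
            cv_dev = pd.DataFrame(
                {"lambda": lambdas, "cv_deviance": cv_mean, "cv_se": cv_se}
            )
        else:
            chosen = 0

        coefs, intercepts = _path_fit(
            Xs, y, lambdas, cfg.alpha, cfg.tol,
            random_state=cfg.seed % (2**31 - 1),
        )
        w_std = coefs[chosen]
        b_std = intercepts[chosen]
        w = w_std / sd_safe
        b = b_std - float(np.sum(w * mu))
        weights = {
            name: float(wj)
            for name, wj in zip(self.feature_names, w)
            if wj != 0.0
        }
        model = PanelModel(
            intercept=float(b),
            weights=weights,
            metadata={
                "alpha": cfg.alpha,
                "lambda": float(lambdas[chosen]),
                "selection_rule": cfg.selection_rule,
                "seed": cfg.seed,
                "candidates": self.feature_names,
                "n_samples": n,
            },
        )
        nnz_path = (coefs != 0.0).sum(axis=1)
        return PanelFit(model, self, lambdas, nnz_path, cv_dev)


class PanelFit:
    """Results of a :class:`PanelLogit` fit: model, path and CV diagnostics."""

    def __init__(self, model, parent, lambdas, nnz_path, cv_deviance):
        self.model = model
        self.parent = parent
        self.lambdas = np.asarray(lambdas)
        self.nnz_path = np.asarray(nnz_path)
        self.cv_deviance = cv_deviance

    @property
    def intercept(self) -> float:
        return self.model.intercept

    @property
    def weights(self) -> dict[str, float]:
        return self.model.weights

    def summary(self) -> str:
        lines = [
            "Elastic-net logistic panel",
            f"  alpha: {self.model.metadata['alpha']}   "
            f"lambda: {self.model.metadata['lambda']:.4g} "
            f"({self.model.metadata['selection_rule']})",
            f"  candidates: {len(self.parent.feature_names)}   "
            f"selected: {len(self.model.weights)}",
            f"  intercept (w0): {self.model.intercept:+.3f}",
        ]
        for name, w in sorted(self.model.weights.items()):
            lines.append(f"    {name:>12s}  {w:+.3f}")
        return "\n".join(lines)


def fit_elastic_net(X: pd.DataFrame, y, config: FitConfig | None = None) -> PanelModel:
    """Functional wrapper: fit a panel and return its :class:`PanelModel`."""
    return PanelLogit(X, y, config).fit().model


def score(model: PanelModel, protein_values) -> float | pd.Series:
    """Biomarker score of one sample (mapping) or many (DataFrame)."""
    return model.score(protein_values)
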