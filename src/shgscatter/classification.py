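"""Multi-metric tissue classification by canonical discriminant analysis.

The SHG emission directionality, relative conversion efficiency, and
reduced-scattering metrics (with their wavelength dependence) each probe a
different facet of extracellular-matrix organization; combined in a
canonical linear discriminant they separate tissue types far better than
any single metric.  This module fits the canonical axes (a generalized
eigenproblem on the between- and within-class scatter matrices, with
shrinkage regularization for the few-samples-per-class regime), scores
pairwise tissue classification under cross-validation, derives ROC curves
from a logistic model, and runs ANOVA / Fisher-LSD group comparisons.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "DiscriminantModel",
    "PairwiseAccuracyMatrix",
    "ROCResult",
    "fit_canonical_discriminant",
    "pairwise_classify",
    "roc_from_logistic",
    "group_comparison",
]

TISSUE_LABELS = ("normal", "benign", "LGS", "endometrioid", "HGS")

#: Shrinkage of the within-class scatter toward its diagonal.
DEFAULT_SHRINKAGE = 1e-3

MAX_CANONICAL_VARIABLES = 3


@dataclass
class FeatureTable:
    """Labeled per-sample metric vectors.

    Wraps a DataFrame with a ``sample_id`` column, a ``tissue_label``
    column, and one column per named feature (e.g. ``fb_988``,
    ``fb_slope``, ``eff_988``, ``mus_prime_390``, ``m_shape``).
    """

    frame: pd.DataFrame
    label_column: str = "tissue_label"
    id_column: str = "sample_id"

    def __post_init__(self) -> None:
        for col in (self.label_column, self.id_column):
            if col not in self.frame.columns:
                raise ValueError(f"feature table missing column {col!r}")
        if self.frame[self.label_column].isna().any():
            raise ValueError("every row must carry a tissue label")

    @property
    def feature_names(self) -> list[str]:
        return [
            c for c in self.frame.columns if c not in (self.label_column, self.id_column)
        ]

    @property
    def labels(self) -> np.ndarray:
        return self.frame[self.label_column].to_numpy()

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    def subset(self, labels: Sequence[str]) -> "FeatureTable":
        mask = self.frame[self.label_column].isin(labels)
        return FeatureTable(
            self.frame[mask].reset_index(drop=True), self.label_column, self.id_column
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FeatureTable":
        return cls(pd.read_csv(path), **kwargs)


@dataclass
class DiscriminantModel:
    """Fitted canonical discriminant: projection + class centroids."""

    weights: np.ndarray  # (features, canonical variables)
    centroids: dict[str, np.ndarray]
    feature_names: list[str]
    feature_means: np.ndarray
    feature_stds: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_canonical(self) -> int:
        return self.weights.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.feature_means) / self.feature_stds
        return Xs @ self.weights

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Nearest class centroid in canonical space, equal priors."""
        scores = self.project(X)
        labels = list(self.centroids)
        cents = np.stack([self.centroids[l] for l in labels])
        d2 = ((scores[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(labels, dtype=object)[np.argmin(d2, axis=1)]

    def to_json_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "centroids": {k: v.tolist() for k, v in self.centroids.items()},
            "eigenvalues": self.eigenvalues.tolist(),
        }


@dataclass
class PairwiseAccuracyMatrix:
    """Symmetric pairwise classification accuracies (diagonal undefined)."""

    frame: pd.DataFrame

    def accuracy(self, a: str, b: str) -> float:
        return float(self.frame.loc[a, b])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(json.loads(self.frame.to_json()), fh, indent=2)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    #: fitted per-sample probabilities of the positive class (diagnostics)
    probabilities: np.ndarray | None = None
    labels: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


# ---------------------------------------------------------------------------
# Canonical discriminant
# ---------------------------------------------------------------------------

def fit_canonical_discriminant(
    table: FeatureTable,
    shrinkage: float = DEFAULT_SHRINKAGE,
    max_variables: int = MAX_CANONICAL_VARIABLES,
) -> DiscriminantModel:
    """Fit canonical axes maximizing between- over within-class variance.

    Features are standardized internally; the within-class scatter is
    shrunk toward its diagonal (weight ``shrinkage``) so the generalized
    eigenproblem stays well posed with 3-4 samples per class or duplicated
    features.  At most ``max_variables`` (default 3) canonical variables
    are retained.
    """
    labels = table.labels
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    X = table.X
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std
    p = Xs.shape[1]

    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    grand = Xs.mean(axis=0)
    for c in classes:
        Xc = Xs[labels == c]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        Sw += d.T @ d
        Sb += len(Xc) * np.outer(mu - grand, mu - grand)

    Sw_reg = (1.0 - shrinkage) * Sw + shrinkage * np.diag(np.diag(Sw))
    if np.linalg.cond(Sw_reg) > 1e10:
        # absolute ridge for directions with zero within-class variance
        logger.warning("near-singular within-class scatter; shrinkage applied")
        Sw_reg = Sw_reg + shrinkage * (np.trace(Sw_reg) / p + 1e-12) * np.eye(p)

    evals, evecs = linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1]
    k = min(max_variables, len(classes) - 1, p)
    W = evecs[:, order[:k]]
    evals = evals[order[:k]]

    scores = Xs @ W
    centroids = {c: scores[labels == c].mean(axis=0) for c in classes}
    return DiscriminantModel(
        weights=W,
        centroids=centroids,
        feature_names=table.feature_names,
        feature_means=mean,
        feature_stds=std,
        eigenvalues=evals,
    )


def pairwise_classify(
    table: FeatureTable,
    cv: str = "loo",
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> PairwiseAccuracyMatrix:
    """Pairwise tissue-classification accuracies.

    For each unordered class pair the discriminant is fit on that pair
    only and samples are scored by nearest centroid in canonical space.
    ``cv='loo'`` (default) refits with each sample held out;
    ``cv='resubstitution'`` scores the training samples directly.
    """
    if cv not in ("loo", "resubstitution"):
        raise ValueError(f"unknown cv spec {cv!r}")
    classes = sorted(set(table.labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    mat = pd.DataFrame(np.nan, index=classes, columns=classes, dtype=float)
    for a, b in itertools.combinations(classes, 2):
        sub = table.subset([a, b])
        y = sub.labels
        if cv == "resubstitution":
            model = fit_canonical_discriminant(sub, shrinkage)
            pred = model.classify(sub.X)
            acc = float(np.mean(pred == y))
        else:
            hits = 0
            for i in range(len(sub.frame)):
                train = FeatureTable(
                    sub.frame.drop(index=i).reset_index(drop=True),
                    sub.label_column,
                    sub.id_column,
                )
                if min(np.sum(train.labels == a), np.sum(train.labels == b)) < 2:
                    raise ValueError(
                        "leave-one-out needs at least 3 samples per class"
                    )
                model = fit_canonical_discriminant(train, shrinkage)
                pred = model.classify(sub.X[i : i + 1])
                hits += int(pred[0] == y[i])
            acc = hits / len(sub.frame)
        mat.loc[a, b] = mat.loc[b, a] = acc
    return PairwiseAccuracyMatrix(frame=mat)


# ---------------------------------------------------------------------------
# ROC and group statistics
# ---------------------------------------------------------------------------

def roc_from_logistic(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_label=None,
    ridge_c: float = 1.0,
    fit_model: bool = True,
) -> ROCResult:
    """ROC curve from a logistic model of class membership.

    Fits an L2-penalized logistic regression of the binary label on the
    supplied scores (canonical variables or any feature subset), sweeps
    the predicted probability over thresholds, and integrates the AUC by
    the trapezoid rule.  The ridge penalty keeps perfectly separated data
    fittable (a warning is logged in that case).

    With ``fit_model=False`` a single supplied score column is used
    directly as the ranking statistic (no refit); note the refit AUC is
    invariant to a sign flip of the scores (the coefficient flips with
    them), whereas the raw-score AUC maps to 1 - AUC.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two classes, got {uniq.tolist()}")
    if positive_label is None:
        positive_label = uniq[1]
    y = (labels == positive_label).astype(int)

    if fit_model:
        model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=5000)
        model.fit(scores, y)
        prob = model.predict_proba(scores)[:, 1]
        lo = model.decision_function(scores)
        if np.min(lo[y == 1], initial=np.inf) > np.max(lo[y == 0], initial=-np.inf):
            logger.warning(
                "classes perfectly separated; ridge penalty keeps AUC defined"
            )
    else:
        if scores.shape[1] != 1:
            raise ValueError("fit_model=False requires a single score column")
        prob = scores[:, 0]

    fpr, tpr, thresholds = roc_curve(y, prob)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        probabilities=prob, labels=y,
    )


def group_comparison(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """One-way ANOVA plus pairwise Fisher LSD tests.

    The LSD statistic for groups i, j is
        t = |mean_i - mean_j| / sqrt(MSE (1/n_i + 1/n_j)),
    with MSE the pooled within-group variance and N - k error degrees of
    freedom.  The unprotected version is computed (no ANOVA gate), whose
    per-pair type-I error under the null is the nominal alpha.

    Returns a dict with ``anova_p``, ``pairwise`` {(a, b): p}, and
    ``significant`` {(a, b): bool at alpha}.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    N = sum(a.size for a in arrays)
    k = len(arrays)
    mse = sum((a.size - 1) * a.var(ddof=1) for a in arrays) / (N - k)
    if mse <= 0:
        raise ValueError("degenerate zero within-group variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = stats.f_oneway(*arrays)
    pairwise: dict[tuple[str, str], float] = {}
    for (ga, a), (gb, b) in itertools.combinations(zip(names, arrays), 2):
        t = abs(a.mean() - b.mean()) / np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        p = 2.0 * stats.t.sf(t, N - k)
        pairwise[(ga, gb)] = float(p)
    return {
        "anova_p": float(anova.pvalue),
        "pairwise": pairwise,
        "significant": {pair: p < alpha for pair, p in pairwise.items()},
    }
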