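"""Linear discriminant classification of lunar birth quarter from traits.

Gaussian equal-covariance discriminant: per-trait standardization, class
means, pooled within-class covariance (ridge-regularized if singular),
posteriors under either the training class frequencies or an equal
("uninformative") prior. Includes leave-one-out cross-validation with
per-fold restandardization, confusion/adjacency accounting, and cohort
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .lunar import QUARTER_ORDER, LunarQuarter

__all__ = [
    "LdaModel",
    "ConfusionMatrix",
    "fit",
    "predict",
    "loocv",
    "adjacency_fraction",
    "assign_cohort",
    "compare_distributions",
]


def _as_labels(y) -> list[LunarQuarter]:
    out = []
    for v in y:
        if isinstance(v, LunarQuarter):
            out.append(v)
        else:
            out.append(LunarQuarter[str(v)])
    return out


@dataclass(frozen=True)
class LdaModel:
    """Fitted discriminant: standardization, class means, pooled covariance."""

    class_labels: tuple[LunarQuarter, ...]
    class_means: np.ndarray        # (k, p), standardized space
    pooled_covariance: np.ndarray  # (p, p), standardized space
    training_priors: np.ndarray    # (k,)
    center: np.ndarray             # (p,)
    scale: np.ndarray              # (p,)
    _chol: tuple = field(repr=False, default=None)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def fit(X, y, *, ridge: float | None = None) -> LdaModel:
    """Fit the discriminant on trait rows ``X`` and quarter labels ``y``.

    Requires every quarter present with >= 2 members and no NaN. The pooled
    within-class covariance uses ``n - k`` degrees of freedom; if singular
    it is ridged by ``1e-8 * trace / p`` (or the supplied ``ridge``).
    """
    X = np.asarray(X, dtype=float)
    labels = _as_labels(y)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("X must be 2-D with one row per label")
    n, p = X.shape
    if n < 8:
        raise ValueError(f"need >= 8 training fish, got {n}")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")

    classes = tuple(q for q in QUARTER_ORDER if q in labels)
    missing = [q.name for q in QUARTER_ORDER if q not in labels]
    if missing:
        raise ValueError(f"missing classes in training data: {missing}")
    counts = np.array([sum(l == q for l in labels) for q in classes])
    if np.any(counts < 2):
        bad = [q.name for q, c in zip(classes, counts) if c < 2]
        raise ValueError(f"classes with < 2 members: {bad}")

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)  # constant trait: leave centered only
    Z = (X - center) / scale

    k = len(classes)
    means = np.zeros((k, p))
    pooled = np.zeros((p, p))
    for i, q in enumerate(classes):
        m = np.array([l == q for l in labels])
        Zi = Z[m]
        means[i] = Zi.mean(axis=0)
        D = Zi - means[i]
        pooled += D.T @ D
    pooled /= n - k

    def try_chol(S):
        try:
            return cho_factor(S, lower=True)
        except np.linalg.LinAlgError:
            return None

    chol = try_chol(pooled)
    if chol is None:
        eps = ridge if ridge is not None else 1e-8 * np.trace(pooled) / p
        pooled = pooled + eps * np.eye(p)
        chol = try_chol(pooled)
        if chol is None:
            raise ValueError("pooled covariance singular even after ridge regularization")

    return LdaModel(
        class_labels=classes,
        class_means=means,
        pooled_covariance=pooled,
        training_priors=counts / n,
        center=center,
        scale=scale,
        _chol=chol,
    )


def _log_posteriors(model: LdaModel, Z: np.ndarray, prior: str) -> np.ndarray:
    """Unnormalized Gaussian log posteriors, rows = observations."""
    if prior == "equal":
        log_prior = np.zeros(len(model.class_labels))
    elif prior == "training":
        log_prior = np.log(model.training_priors)
    else:
        raise ValueError(f"prior must be 'equal' or 'training', got {prior!r}")
    chol = model._chol or cho_factor(model.pooled_covariance, lower=True)
    lp = np.empty((Z.shape[0], len(model.class_labels)))
    for i, mu in enumerate(model.class_means):
        D = Z - mu
        sol = cho_solve(chol, D.T)
        lp[:, i] = -0.5 * np.einsum("ij,ji->i", D, sol) + log_prior[i]
    return lp


def predict(model: LdaModel, x, prior: str = "equal"):
    """Predicted quarter and the 4 posterior probabilities for one trait vector.

    Ties break deterministically in the fixed order NEW, WAXING, FULL,
    WANING (np.argmax takes the first maximum).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != model.n_features:
        raise ValueError(f"expected {model.n_features} traits, got {x.size}")
    if np.isnan(x).any():
        raise ValueError("trait vector contains NaN")
    Z = ((x - model.center) / model.scale)[None, :]
    lp = _log_posteriors(model, Z, prior)[0]
    lp -= lp.max()
    post = np.exp(lp)
    post /= post.sum()
    return model.class_labels[int(np.argmax(post))], post


def predict_many(model: LdaModel, X, prior: str = "equal"):
    """Vectorized :func:`predict` over rows of X."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait matrix contains NaN")
    Z = (X - model.center) / model.scale
    lp = _log_posteriors(model, Z, prior)
    lp -= lp.max(axis=1, keepdims=True)
    post = np.exp(lp)
    post /= post.sum(axis=1, keepdims=True)
    preds = [model.class_labels[i] for i in np.argmax(post, axis=1)]
    return preds, post


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts of true quarter (rows) vs predicted quarter (columns)."""

    counts: np.ndarray
    labels: tuple[LunarQuarter, ...] = QUARTER_ORDER

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (4, 4) or np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be a 4x4 non-negative integer matrix")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n)

    def to_frame(self) -> pd.DataFrame:
        names = [q.name for q in self.labels]
        return pd.DataFrame(self.counts, index=names, columns=names)


def loocv(X, y, prior: str = "equal"):
    """Leave-one-out cross-validation of the full fit (standardization
    recomputed in every fold, so no information leaks from the held-out fish).

    Observations whose fold cannot be fitted (a class collapsing below two
    members) are recorded as unclassifiable and counted as errors.

    Returns ``(accuracy, ConfusionMatrix, predictions)`` where predictions
    has one entry per observation (None if unclassifiable).
    """
    X = np.asarray(X, dtype=float)
    labels = _as_labels(y)
    n = X.shape[0]
    counts = {q: sum(l == q for l in labels) for q in QUARTER_ORDER}
    if any(c < 3 for c in counts.values()):
        raise ValueError(f"every class needs >= 3 members for LOOCV, got {counts}")

    order = {q: i for i, q in enumerate(QUARTER_ORDER)}
    cm = np.zeros((4, 4), dtype=int)
    preds: list[LunarQuarter | None] = []
    n_correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            model = fit(X[mask], [l for j, l in enumerate(labels) if j != i])
            pred, _ = predict(model, X[i], prior=prior)
            cm[order[labels[i]], order[pred]] += 1
            n_correct += pred == labels[i]
            preds.append(pred)
        except ValueError:
            preds.append(None)  # unclassifiable fold, counted as an error
        mask[i] = True
    return n_correct / n, ConfusionMatrix(cm), preds


def adjacency_fraction(cm: ConfusionMatrix) -> float:
    """Among misclassified fish, the fraction predicted into a quarter
    cyclically adjacent to the true one."""
    off_total = cm.n - int(np.trace(cm.counts))
    if off_total == 0:
        raise ValueError("no misclassifications: adjacency fraction undefined")
    adj = 0
    for i, true_q in enumerate(cm.labels):
        for j, pred_q in enumerate(cm.labels):
            if i != j and true_q.is_adjacent(pred_q):
                adj += int(cm.counts[i, j])
    return adj / off_total


def assign_cohort(model: LdaModel, X, prior: str = "equal") -> np.ndarray:
    """Per-quarter proportions of predicted birth quarters over a set of fish
    (ordered NEW, WAXING, FULL, WANING)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a non-empty 2-D trait matrix")
    preds, _ = predict_many(model, X, prior=prior)
    order = {q: i for i, q in enumerate(QUARTER_ORDER)}
    counts = np.zeros(4)
    for pq in preds:
        counts[order[pq]] += 1
    return counts / counts.sum()


def compare_distributions(p, q) -> float:
    """Total variation distance between two birth-quarter distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, v in (("p", p), ("q", q)):
        if v.shape != (4,) or abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
            raise ValueError(f"{name} must be 4 non-negative proportions summing to 1")
    return 0.5 * float(np.abs(p - q).sum())
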