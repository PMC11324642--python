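"""Attribute weighting: per-gene relevance scores in [0, 1] for a binary
condition label, plus the threshold selection rule.

Four scorers are provided, each min–max normalized so the top gene has
weight exactly 1:

* ``correlation`` — |Pearson r| between a gene's expression and the 0/1 label.
* ``uncertainty`` — symmetric uncertainty 2·I(G;Y)/(H(G)+H(Y)) after
  equal-frequency discretization of the gene.
* ``relief`` — the Relief update (nearest hit vs nearest miss) accumulated
  over a full deterministic pass through all samples.
* ``svm`` — |coefficient| of a linear max-margin classifier on standardized
  expression.

Genes whose weight exceeds the threshold (default 0.90), plus any gene with
weight exactly 1, are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .simdata import CONTROL, STRESS

DEFAULT_THRESHOLD = 0.90
METHODS = ("uncertainty", "relief", "correlation", "svm")


class WeightingError(ValueError):
    pass


@dataclass
class WeightTable:
    method: str
    weights: pd.Series  # gene_id -> weight in [0, 1]
    threshold: float = DEFAULT_THRESHOLD
    params: dict = field(default_factory=dict)
    raw: pd.Series | None = None  # pre-normalization weights

    @property
    def selected(self) -> set[str]:
        return select_by_threshold(self, self.threshold)


def condition_vector(design: pd.DataFrame, sample_ids) -> np.ndarray:
    """Encode the condition of each sample as 0 (control) / 1 (stress)."""
    cond = design.loc[list(sample_ids), "condition"]
    unknown = set(cond.unique()) - {CONTROL, STRESS}
    if unknown:
        raise WeightingError(f"unknown condition labels: {sorted(unknown)}")
    y = (cond == STRESS).to_numpy(dtype=int)
    if y.min() == y.max():
        raise WeightingError("both conditions must be present")
    return y


def _minmax(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        return (raw - lo) / (hi - lo)
    if hi > 0:  # all equal and nonzero: every gene is the top gene
        return np.ones_like(raw)
    return np.zeros_like(raw)


def weight_by_correlation(X: pd.DataFrame, y: np.ndarray | pd.DataFrame) -> WeightTable:
    """|Pearson r| of each gene with the 0/1 condition, min–max normalized."""
    y = _coerce_y(X, y)
    M = X.to_numpy(dtype=float)
    xc = M - M.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    raw = np.abs(np.where(sx > 0, r, 0.0))  # constant genes get weight 0
    return WeightTable("correlation", pd.Series(_minmax(raw), index=X.index), raw=pd.Series(raw, index=X.index))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def symmetric_uncertainty(g: np.ndarray, y: np.ndarray) -> float:
    """2·I(G;Y) / (H(G) + H(Y)) for two discrete vectors."""
    joint = pd.crosstab(pd.Series(g), pd.Series(y)).to_numpy(dtype=float)
    joint /= joint.sum()
    hg = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    mi = hg + hy - _entropy(joint.ravel())
    denom = hg + hy
    return 2.0 * mi / denom if denom > 0 else 0.0


def equal_frequency_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin index per value; duplicate quantile edges merged."""
    edges = np.unique(np.quantile(x, np.arange(1, bins) / bins))
    return np.digitize(x, edges, right=True)


def weight_by_uncertainty(X: pd.DataFrame, y, bins: int = 5) -> WeightTable:
    """Symmetric uncertainty of each equal-frequency-binned gene with the label."""
    if bins < 2:
        raise WeightingError("bins must be >= 2")
    y = _coerce_y(X, y)
    raw = np.empty(X.shape[0])
    M = X.to_numpy(dtype=float)
    hy = _entropy(np.bincount(y).astype(float) / len(y))
    for i in range(X.shape[0]):
        codes = equal_frequency_codes(M[i], bins)
        if codes.max() == codes.min():
            raw[i] = 0.0  # degenerate discretization: one bin
            continue
        joint = np.bincount(codes * 2 + y, minlength=2 * (codes.max() + 1)).astype(float)
        joint = joint.reshape(-1, 2) / len(y)
        hg = _entropy(joint.sum(axis=1))
        mi = hg + hy - _entropy(joint.ravel())
        raw[i] = 2.0 * mi / (hg + hy) if hg + hy > 0 else 0.0
    return WeightTable("uncertainty", pd.Series(_minmax(raw), index=X.index), params={"bins": bins}, raw=pd.Series(raw, index=X.index))


def weight_by_relief(
    X: pd.DataFrame,
    y,
    n_neighbors: int = 1,
    n_iterations: int | None = None,
) -> WeightTable:
    """Relief weights from a full pass over all samples.

    Features are min–max scaled to [0, 1]; distances are Manhattan on the
    scaled features; ties go to the lowest sample index.  Every sample is
    visited once in index order (``n_iterations`` defaults to the sample
    count and only sets the averaging denominator).
    """
    y = _coerce_y(X, y)
    n = len(y)
    for cls in (0, 1):
        if (y == cls).sum() < n_neighbors + 1:
            raise WeightingError(f"class {cls} needs >= {n_neighbors + 1} samples")
    M = X.to_numpy(dtype=float).T  # samples x genes
    span = M.max(axis=0) - M.min(axis=0)
    span[span == 0] = 1.0
    S = (M - M.min(axis=0)) / span
    if n_iterations is None:
        n_iterations = n
    D = np.abs(S[:, None, :] - S[None, :, :]).sum(axis=2)  # Manhattan
    np.fill_diagonal(D, np.inf)
    W = np.zeros(X.shape[0])
    for j in range(n):
        same = np.flatnonzero(y == y[j])
        other = np.flatnonzero(y != y[j])
        hit = same[np.argmin(D[j, same])]  # argmin takes first == lowest index
        miss = other[np.argmin(D[j, other])]
        W += (np.abs(S[j] - S[miss]) - np.abs(S[j] - S[hit])) / n_iterations
    return WeightTable(
        "relief",
        pd.Series(_minmax(W), index=X.index),
        params={"n_neighbors": n_neighbors, "n_iterations": n_iterations},
        raw=pd.Series(W, index=X.index),
    )


def weight_by_svm(X: pd.DataFrame, y, regularization: float = 1.0, max_iter: int = 100_000) -> WeightTable:
    """|hyperplane coefficient| of a linear hinge-loss SVM on standardized genes."""
    if regularization <= 0:
        raise WeightingError("regularization must be positive")
    y = _coerce_y(X, y)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise WeightingError("each class needs >= 2 samples")
    M = X.to_numpy(dtype=float).T  # samples x genes
    sd = M.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(M)
    Z[:, keep] = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    clf = LinearSVC(C=regularization, loss="hinge", max_iter=max_iter, tol=1e-6)
    clf.fit(Z, y)
    if clf.n_iter_ >= max_iter:
        raise WeightingError(f"SVM did not converge in {max_iter} iterations")
    raw = np.abs(clf.coef_.ravel())
    raw[~keep] = 0.0
    return WeightTable(
        "svm",
        pd.Series(_minmax(raw), index=X.index),
        params={"regularization": regularization},
        raw=pd.Series(raw, index=X.index),
    )


def select_by_threshold(weights: WeightTable, threshold: float = DEFAULT_THRESHOLD) -> set[str]:
    """Genes with weight > threshold, plus any gene with weight exactly 1."""
    if not 0 < threshold <= 1:
        raise WeightingError(f"threshold must be in (0, 1], got {threshold}")
    w = weights.weights
    return set(w.index[(w > threshold) | (w == 1.0)])


def weight_all_methods(X: pd.DataFrame, design: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> dict[str, WeightTable]:
    """Run all four scorers; returns method -> WeightTable."""
    y = condition_vector(design, X.columns)
    tables = {
        "uncertainty": weight_by_uncertainty(X, y),
        "relief": weight_by_relief(X, y),
        "correlation": weight_by_correlation(X, y),
        "svm": weight_by_svm(X, y),
    }
    for t in tables.values():
        t.threshold = threshold
    return tables


def _coerce_y(X: pd.DataFrame, y) -> np.ndarray:
    if isinstance(y, pd.DataFrame):
        return condition_vector(y, X.columns)
    y = np.asarray(y)
    if y.shape != (X.shape[1],):
        raise WeightingError(f"label vector length {y.shape} does not match {X.shape[1]} samples")
    if set(np.unique(y)) - {0, 1}:
        raise WeightingError("labels must be 0/1")
    if y.min() == y.max():
        raise WeightingError("both conditions must be present")
    return y.astype(int)
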