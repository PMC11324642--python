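"""Validation of a selected gene panel.

A random forest (100 trees, sqrt-p features per split, bootstrap resampling)
is trained to separate control from stress samples on the panel's normalized
expression.  Generalization is reported as the out-of-bag misclassification
rate, accuracy and the area under the ROC curve, either from out-of-bag
votes (default) or by stratified k-fold refitting.  Per-gene contributions
are exact tree-path Shapley attributions; the global ranking orders genes by
mean |phi|.  A shadow-feature confirmation loop (Boruta) iteratively compares
each gene's importance with the best importance achievable by chance, and a
final median-based rough fix adjudicates features still undecided after the
run budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._treeshap import forest_shap_values
from .weights import condition_vector

DEFAULT_TREES = 100
DEFAULT_MAX_RUNS = 100
DEFAULT_ALPHA = 0.01

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"


class ValidationError(ValueError):
    pass


@dataclass
class RFValidation:
    n_trees: int
    oob_error: float
    accuracy: float
    auc: float
    roc_points: list[tuple[float, float]]
    protocol: str
    attributions: pd.DataFrame  # samples x genes, Shapley values
    base_value: float
    importance_ranking: list[str]  # genes by mean |phi| descending
    seed: int = 0


@dataclass
class BorutaResult:
    max_runs: int
    n_runs: int
    hits: pd.Series  # feature -> hit count while undecided
    runs_tested: pd.Series  # feature -> number of runs it was undecided in
    importance_history: dict[str, list[float]]
    shadow_max_history: list[float]
    decisions: pd.Series  # Confirmed / Tentative / Rejected
    final_decisions: pd.Series | None = None
    params: dict = field(default_factory=dict)

    @property
    def confirmed(self) -> set[str]:
        d = self.final_decisions if self.final_decisions is not None else self.decisions
        return set(d.index[d == CONFIRMED])


def _check_xy(X: pd.DataFrame, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.DataFrame):
        y = condition_vector(y, X.columns)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("y must contain both classes, coded 0/1")
    return X.to_numpy(dtype=float).T, y  # samples x genes


def train_random_forest(
    X: pd.DataFrame, y, n_trees: int = DEFAULT_TREES, seed: int = 0
) -> tuple[RandomForestClassifier, float]:
    """Fit the forest and return it with its out-of-bag error."""
    M, y = _check_xy(X, y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("each class needs >= 2 samples")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model.fit(M, y)
    scores, covered = _oob_scores(model)
    oob_error = float(np.mean((scores[covered] > 0.5).astype(int) != y[covered]))
    return model, oob_error


def _oob_scores(model: RandomForestClassifier) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag class-1 probability per training sample + coverage mask."""
    dec = model.oob_decision_function_
    covered = ~np.isnan(dec).any(axis=1)
    votes = dec[:, -1].copy()
    votes[~covered] = 0.5
    return votes, covered


def evaluate_model(
    model: RandomForestClassifier,
    X: pd.DataFrame,
    y,
    protocol: str = "oob",
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, list[tuple[float, float]]]:
    """Accuracy, AUC and ROC points under the chosen protocol.

    ``oob`` scores the training samples by their out-of-bag votes; ``kfold``
    refits a clone of the model per stratified fold and scores held-out
    samples.
    """
    M, y = _check_xy(X, y)
    if len(np.unique(y)) < 2:
        raise ValidationError("evaluation labels must contain both classes")
    if protocol == "oob":
        scores, covered = _oob_scores(model)
        scores = scores.copy()
    elif protocol == "kfold":
        from sklearn.base import clone

        scores = np.zeros(len(y))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, va in skf.split(M, y):
            m = clone(model)
            m.set_params(oob_score=False)
            m.fit(M[tr], y[tr])
            scores[va] = m.predict_proba(M[va])[:, -1]
    else:
        raise ValidationError(f"unknown protocol {protocol!r}")
    accuracy = float(np.mean((scores > 0.5).astype(int) == y))
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return accuracy, auc, list(zip(fpr.tolist(), tpr.tolist()))


def shap_attributions(model: RandomForestClassifier, X: pd.DataFrame) -> tuple[pd.DataFrame, float, list[str]]:
    """Exact tree-path Shapley attributions and the global importance ranking.

    Returns (phi, base_value, ranking): phi is samples x genes and satisfies
    base_value + phi.sum(axis=1) == predicted stress probability exactly.
    """
    M = X.to_numpy(dtype=float).T
    if M.shape[1] != model.n_features_in_:
        raise ValidationError(
            f"matrix has {M.shape[1]} genes but model expects {model.n_features_in_}"
        )
    phi, base = forest_shap_values(model, M)
    frame = pd.DataFrame(phi, index=X.columns, columns=X.index)
    mean_abs = frame.abs().mean(axis=0)
    ranking = mean_abs.sort_values(ascending=False, kind="stable")
    # ties broken by gene id
    ranking = ranking.iloc[np.lexsort((ranking.index, -ranking.to_numpy()))]
    return frame, base, list(ranking.index)


def _forest_gini_importance(M: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-decrease-impurity importance of a bootstrap forest.

    Same sampling scheme as the random-forest classifier (per-tree bootstrap,
    sqrt-p features per split, Gini splits) but built as a bare tree loop, so
    the many forests of the shadow-feature loop stay cheap.
    """
    from sklearn.tree import DecisionTreeClassifier

    n = M.shape[0]
    imp = np.zeros(M.shape[1])
    for _ in range(n_trees):
        idx = rng.integers(n, size=n)
        tree = DecisionTreeClassifier(max_features="sqrt", random_state=int(rng.integers(2**31)))
        tree.fit(M[idx], y[idx], check_input=False)
        imp += tree.tree_.compute_feature_importances(normalize=True)
    return imp / n_trees


def _importance(model, M, y, kind: str, rng: np.random.Generator) -> np.ndarray:
    if kind == "gini":
        return model.feature_importances_
    if kind == "permutation":
        res = permutation_importance(
            model, M, y, n_repeats=3, random_state=int(rng.integers(2**31))
        )
        return res.importances_mean
    raise ValidationError(f"unknown importance {kind!r}")


def boruta(
    X: pd.DataFrame,
    y,
    max_runs: int = DEFAULT_MAX_RUNS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_trees: int = DEFAULT_TREES,
    importance: str = "gini",
) -> BorutaResult:
    """Shadow-feature confirmation of relevant genes.

    Each run appends a column-shuffled shadow copy of every undecided gene
    (padded to at least 5 shadows), fits a random forest on the augmented
    matrix, and scores a hit for every gene whose importance exceeds the best
    shadow importance.  Hit counts are tested against a fair coin
    (two-sided binomial, Bonferroni-corrected over the initial gene count):
    significantly many hits confirms a gene, significantly few rejects it.
    The loop stops at ``max_runs`` or when no gene is left undecided;
    survivors are Tentative.
    """
    M, y = _check_xy(X, y)
    genes = list(X.index)
    m0 = len(genes)
    rng = np.random.default_rng(seed)
    hits = np.zeros(m0, dtype=int)
    tested = np.zeros(m0, dtype=int)
    status = np.full(m0, TENTATIVE, dtype=object)
    history: dict[str, list[float]] = {g: [] for g in genes}
    shadow_max_history: list[float] = []
    n_runs = 0
    thr = alpha / m0  # Bonferroni over the initial panel
    for _ in range(max_runs):
        cols = np.flatnonzero(status == TENTATIVE)
        if cols.size == 0:
            break
        n_runs += 1
        real = M[:, cols]
        shadow_src = real if cols.size >= 5 else real[:, rng.integers(cols.size, size=5)]
        shadow = shadow_src.copy()
        for c in range(shadow.shape[1]):
            shadow[:, c] = shadow[rng.permutation(shadow.shape[0]), c]
        aug = np.hstack([real, shadow])
        if importance == "gini":
            imp = _forest_gini_importance(aug, y, n_trees, rng)
        else:
            model = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
            )
            model.fit(aug, y)
            imp = _importance(model, aug, y, importance, rng)
        real_imp = imp[: cols.size]
        shadow_max = float(imp[cols.size:].max())
        shadow_max_history.append(shadow_max)
        hits[cols] += (real_imp > shadow_max).astype(int)
        tested[cols] += 1
        for i, c in enumerate(cols):
            history[genes[c]].append(float(real_imp[i]))
        # two-sided binomial adjudication
        p_hi = stats.binom.sf(hits[cols] - 1, tested[cols], 0.5)
        p_lo = stats.binom.cdf(hits[cols], tested[cols], 0.5)
        status[cols[p_hi < thr]] = CONFIRMED
        status[cols[p_lo < thr]] = REJECTED
    return BorutaResult(
        max_runs=max_runs,
        n_runs=n_runs,
        hits=pd.Series(hits, index=genes),
        runs_tested=pd.Series(tested, index=genes),
        importance_history=history,
        shadow_max_history=shadow_max_history,
        decisions=pd.Series(status, index=genes),
        params={"alpha": alpha, "seed": seed, "n_trees": n_trees, "importance": importance},
    )


def tentative_rough_fix(result: BorutaResult) -> pd.Series:
    """Adjudicate Tentative features by the median-importance rule.

    A Tentative feature becomes Confirmed when its median importance across
    the runs it participated in exceeds the median of the per-run maximum
    shadow importances; otherwise it is Rejected.  Confirmed and Rejected
    features are unchanged.  The result is stored as ``final_decisions``.
    """
    final = result.decisions.copy()
    if (final == TENTATIVE).any():
        shadow_med = float(np.median(result.shadow_max_history))
        for g in final.index[final == TENTATIVE]:
            med = float(np.median(result.importance_history[g])) if result.importance_history[g] else 0.0
            final[g] = CONFIRMED if med > shadow_med else REJECTED
    result.final_decisions = final
    return final


def validate_panel(
    X: pd.DataFrame,
    design: pd.DataFrame,
    genes: list[str] | None = None,
    n_trees: int = DEFAULT_TREES,
    protocol: str = "oob",
    seed: int = 0,
) -> RFValidation:
    """Full panel validation: forest + OOB error + accuracy/AUC + attributions."""
    panel = X if genes is None else X.loc[list(genes)]
    y = condition_vector(design, panel.columns)
    model, oob_error = train_random_forest(panel, y, n_trees=n_trees, seed=seed)
    accuracy, auc, roc_points = evaluate_model(model, panel, y, protocol=protocol, seed=seed)
    phi, base, ranking = shap_attributions(model, panel)
    return RFValidation(
        n_trees=n_trees,
        oob_error=oob_error,
        accuracy=accuracy,
        auc=auc,
        roc_points=roc_points,
        protocol=protocol,
        attributions=phi,
        base_value=base,
        importance_ranking=ranking,
        seed=seed,
    )
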