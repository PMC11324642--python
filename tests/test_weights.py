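"""Attribute weighting: hand-traced oracles per method + the threshold rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wlgenes import refdata
from wlgenes.weights import (
    WeightingError,
    WeightTable,
    select_by_threshold,
    symmetric_uncertainty,
    weight_by_correlation,
    weight_by_relief,
    weight_by_svm,
    weight_by_uncertainty,
)


def _X(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=genes)


class TestCorrelationWeighting:
    def test_label_equal_gene_gets_weight_one_and_constant_zero(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = _X([y.astype(float), [5, 5, 5, 5, 5, 5], [1, 0, 1, 0, 1, 0]])
        w = weight_by_correlation(X, y).weights
        assert w["g0"] == 1.0
        assert w["g1"] == 0.0

    def test_matches_direct_pearson_formula(self):
        """6-sample toy vs scipy's Pearson r, then min-max normalized."""
        y = np.array([0, 0, 0, 1, 1, 1])
        rows = [[1, 2, 3, 4, 5, 6], [2, 1, 2, 1, 2, 9], [3, 1, 4, 1, 5, 9]]
        X = _X(rows)
        raw = np.array([abs(stats.pearsonr(r, y).statistic) for r in rows])
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(weight_by_correlation(X, y).weights, expected)

    def test_single_condition_errors(self):
        X = _X([[1, 2, 3, 4]])
        with pytest.raises(WeightingError):
            weight_by_correlation(X, np.array([1, 1, 1, 1]))


class TestUncertaintyWeighting:
    def test_perfectly_informative_binary_gene_has_su_one(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = _X([[1, 1, 1, 9, 9, 9], [3, 1, 4, 1, 5, 9]])
        tab = weight_by_uncertainty(X, y, bins=2)
        assert tab.weights["g0"] == 1.0

    def test_matches_brute_force_entropy_oracle(self):
        """8-sample worked table: SU from the enumerated joint distribution."""
        g = np.array([0, 0, 1, 1, 0, 1, 1, 1])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # joint counts: (g=0,y=0)=2, (g=0,y=1)=1, (g=1,y=0)=2, (g=1,y=1)=3
        p = np.array([[2, 1], [2, 3]]) / 8
        hg = -sum(q * np.log(q) for q in p.sum(axis=1))
        hy = -sum(q * np.log(q) for q in p.sum(axis=0))
        hj = -sum(q * np.log(q) for q in p.ravel())
        expected = 2 * (hg + hy - hj) / (hg + hy)
        assert symmetric_uncertainty(g, y) == pytest.approx(expected, abs=1e-12)

    def test_label_independent_gene_weight_vanishes_with_n(self):
        """Permutation oracle: mean raw SU < 0.05 at n=200 over 100 shuffles."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        y = np.array([0, 1] * 100)
        from wlgenes.weights import equal_frequency_codes

        codes = equal_frequency_codes(x, 5)
        sus = [symmetric_uncertainty(codes, rng.permutation(y)) for _ in range(100)]
        assert np.mean(sus) < 0.05

    def test_degenerate_discretization_is_zero_not_error(self):
        y = np.array([0, 0, 1, 1])
        X = _X([[7, 7, 7, 7]])
        assert weight_by_uncertainty(X, y).weights["g0"] == 0.0

    def test_too_few_bins_rejected(self):
        with pytest.raises(WeightingError):
            weight_by_uncertainty(_X([[1, 2, 3, 4]]), np.array([0, 0, 1, 1]), bins=1)


def _relief_oracle(M, y):
    """Literal Relief pass: min-max scale, nearest hit/miss by Manhattan."""
    S = (M - M.min(axis=0)) / np.where(M.max(axis=0) > M.min(axis=0), M.max(axis=0) - M.min(axis=0), 1.0)
    n = len(y)
    W = np.zeros(M.shape[1])
    for j in range(n):
        d = np.abs(S - S[j]).sum(axis=1)
        d[j] = np.inf
        hits = [i for i in range(n) if y[i] == y[j] and i != j]
        misses = [i for i in range(n) if y[i] != y[j]]
        hit = min(hits, key=lambda i: (d[i], i))
        miss = min(misses, key=lambda i: (d[i], i))
        W += (np.abs(S[j] - S[miss]) - np.abs(S[j] - S[hit])) / n
    return W


class TestReliefWeighting:
    def test_separating_feature_gets_weight_one_constant_zero(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = _X([[1, 2, 3, 7, 8, 9], [4, 4, 4, 4, 4, 4]])
        w = weight_by_relief(X, y).weights
        assert w["g0"] == 1.0
        assert w["g1"] == 0.0

    def test_matches_hand_traced_update_rule(self):
        """6-sample 3-feature toy against a literal implementation."""
        rng = np.random.default_rng(5)
        M = rng.random((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        raw = _relief_oracle(M, y)
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        got = weight_by_relief(_X(M.T), y).weights
        assert np.allclose(got, expected)

    def test_class_with_one_sample_errors(self):
        X = _X([[1, 2, 3]])
        with pytest.raises(WeightingError):
            weight_by_relief(X, np.array([0, 0, 1]))


class TestSvmWeighting:
    def test_wide_margin_single_feature(self):
        y = np.array([0, 0, 1, 1])
        X = _X([[-2, -1, 1, 2], [3, 3, 3, 3]])
        w = weight_by_svm(X, y).weights
        assert w["g0"] == 1.0
        assert w["g1"] == 0.0

    def test_duplicated_feature_matches_analytic_max_margin(self):
        """Two identical unit-variance features: the hard-margin solution
        splits the weight equally, |w1| = |w2| = sqrt(5)/2."""
        v = np.array([-3.0, -1.0, 1.0, 3.0]) / np.sqrt(5)  # mean 0, var 1
        y = np.array([0, 0, 1, 1])
        X = _X([v, v, [0.0, 0.0, 0.0, 0.0]])
        tab = weight_by_svm(X, y, regularization=1e4)
        raw = tab.raw
        assert raw["g0"] == pytest.approx(np.sqrt(5) / 2, rel=1e-3)
        assert raw["g1"] == pytest.approx(np.sqrt(5) / 2, rel=1e-3)
        assert raw["g2"] == 0.0

    def test_noise_feature_ranks_below_informative(self):
        """Pure-noise feature rarely outweighs two informative ones."""
        good = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100
            y = np.array([0, 1] * (n // 2))
            f1 = y + rng.standard_normal(n) * 0.5
            f2 = y + rng.standard_normal(n) * 0.5
            noise = rng.standard_normal(n)
            w = weight_by_svm(_X([f1, f2, noise]), y).weights
            good += w["g2"] < 0.2
        assert good >= 19


class TestThresholdRule:
    def test_strictly_above_threshold_plus_the_top_gene(self):
        tab = WeightTable("correlation", pd.Series({"A": 1.0, "B": 0.95, "C": 0.89}))
        assert select_by_threshold(tab, 0.90) == {"A", "B"}

    def test_top_gene_always_passes_even_alone(self):
        tab = WeightTable("svm", pd.Series({"A": 1.0, "B": 0.2, "C": 0.1}))
        assert select_by_threshold(tab, 0.99) == {"A"}

    def test_published_correlation_column_all_pass(self):
        """The 21 published correlation weights all clear the 0.90 cut-off."""
        genes, weights = zip(*refdata.WEIGHT_TABLES["correlation"])
        tab = WeightTable("correlation", pd.Series(weights, index=list(genes)))
        assert select_by_threshold(tab, 0.90) == set(genes)
        assert len(genes) == 21

    def test_invalid_threshold_rejected(self):
        tab = WeightTable("relief", pd.Series({"A": 1.0}))
        with pytest.raises(WeightingError):
            select_by_threshold(tab, 1.01)


def test_all_methods_bounded_with_top_weight_one(small_logexpr):
    X, design, y = small_logexpr
    for fn in (weight_by_correlation, weight_by_uncertainty, weight_by_relief, weight_by_svm):
        w = fn(X, y).weights
        assert w.min() >= 0.0 and w.max() == 1.0


def test_selection_precision_signal_vs_permuted_labels():
    """Selected genes are planted DE genes under signal; arbitrary under
    permuted labels (min-max keeps a top gene either way, so the informative
    contrast is precision, not count)."""
    from wlgenes import normalize, simdata

    rng = np.random.default_rng(99)
    methods = {
        "uncertainty": weight_by_uncertainty,
        "relief": weight_by_relief,
        "correlation": weight_by_correlation,
        "svm": weight_by_svm,
    }
    prec = {m: [] for m in methods}
    null_prec = {m: [] for m in methods}
    for seed in range(10):
        cfg = simdata.SimConfig(n_genes=500, seed=seed, de_fraction=0.04, lfc_sd=2.0)
        ds = simdata.generate_dataset(cfg)
        X = normalize.log_transform(normalize.normalize(ds.counts)[0])
        y = (ds.design["condition"] == "stress").to_numpy().astype(int)
        yp = rng.permutation(y)
        de = set(ds.truth.de_genes)
        for m, fn in methods.items():
            s = fn(X, y).selected
            prec[m].append(len(s & de) / max(len(s), 1))
            sp = fn(X, yp).selected
            null_prec[m].append(len(sp & de) / max(len(sp), 1))
    for m in methods:
        assert np.mean(prec[m]) >= 0.9, m
        assert np.mean(null_prec[m]) <= 0.3, m


def test_strong_planted_genes_rank_top_decile_every_method():
    """Across 25 seeds the largest planted effects sit in every method's
    top weight decile."""
    from wlgenes import normalize, simdata

    methods = (weight_by_uncertainty, weight_by_relief, weight_by_correlation, weight_by_svm)
    success = np.zeros(len(methods))
    n_seeds = 25
    for seed in range(n_seeds):
        cfg = simdata.SimConfig(n_genes=500, seed=seed, de_fraction=0.04, lfc_sd=2.0)
        ds = simdata.generate_dataset(cfg)
        X = normalize.log_transform(normalize.normalize(ds.counts)[0])
        y = (ds.design["condition"] == "stress").to_numpy().astype(int)
        de = ds.truth.de_genes
        top_planted = sorted(de, key=lambda g: -abs(de[g]))[:3]
        for k, fn in enumerate(methods):
            ranks = fn(X, y).weights.rank(ascending=False)
            success[k] += all(ranks[g] <= 50 for g in top_planted)
    assert (success >= 0.9 * n_seeds).all()
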