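"""Fisher-z machinery, dz statistic, class labels, pair scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wlgenes import refdata
from wlgenes.dgca import (
    PEARSON,
    SPEARMAN,
    CorrelationResult,
    DGCAError,
    classify_pair,
    condition_correlation,
    correlation_variance,
    dgca_all_pairs,
    dgca_pairs,
    dz_statistic,
    fisher_z,
    records_to_frame,
    top_pairs,
)
from conftest import make_design


class TestConditionCorrelation:
    def test_published_pair_p_value(self):
        """r = -0.715110 at n = 18 gives the published p = 0.00085."""
        rng = np.random.default_rng(0)
        # construct an 18-sample vector pair with exactly that correlation
        x = rng.standard_normal(18)
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        z = rng.standard_normal(18)
        zc = z - z.mean()
        zc -= (zc @ xs) * xs  # centered and orthogonal to x
        zs = zc / np.linalg.norm(zc)
        r = -0.715110
        y = r * xs + np.sqrt(1 - r * r) * zs
        res = condition_correlation(x, y, PEARSON)
        assert res.r == pytest.approx(r, abs=1e-9)
        assert res.p == pytest.approx(0.00085, abs=1e-4)

    def test_agrees_with_scipy_pearsonr_and_spearmanr(self, rng):
        x = rng.standard_normal(12)
        y = 0.4 * x + rng.standard_normal(12)
        rp = condition_correlation(x, y, PEARSON)
        sp = stats.pearsonr(x, y)
        assert rp.r == pytest.approx(sp.statistic, abs=1e-12)
        assert rp.p == pytest.approx(sp.pvalue, rel=1e-9)
        rs = condition_correlation(x, y, SPEARMAN)
        ss = stats.spearmanr(x, y)
        assert rs.r == pytest.approx(ss.statistic, abs=1e-12)

    def test_t_based_p_matches_permutation_oracle(self, rng):
        """n=8 toy: the t-derived p sits within Monte-Carlo error of a
        permutation p (20000 label permutations)."""
        x = rng.standard_normal(8)
        y = 0.9 * x + 0.6 * rng.standard_normal(8)
        res = condition_correlation(x, y)
        n_perm = 20000
        idx = np.argsort(rng.random((n_perm, 8)), axis=1)
        perm_r = np.array([abs(np.corrcoef(x, y[i])[0, 1]) for i in idx])
        p_perm = (1 + np.sum(perm_r >= abs(res.r))) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) <= max(4 * se, 0.005)

    def test_constant_vector_errors(self):
        with pytest.raises(DGCAError, match="constant"):
            condition_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_samples_errors(self):
        with pytest.raises(DGCAError, match="n >= 4"):
            condition_correlation([1, 2, 3], [3, 2, 1])


class TestFisherZ:
    def test_zero_and_oddness(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(-0.3) == -fisher_z(0.3)

    def test_high_precision_value(self):
        """Check against arbitrary-precision evaluation of atanh."""
        import sympy

        r = "0.9854799"
        expected = float(sympy.atanh(sympy.Rational(9854799, 10**7)).evalf(30))
        assert fisher_z(float(r)) == pytest.approx(expected, abs=1e-14)

    def test_round_trip_identity(self):
        r = np.linspace(-0.999, 0.999, 41)
        assert np.allclose(np.tanh(fisher_z(r)), r, atol=1e-12)

    def test_clamps_at_unity_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)


class TestVarianceAndDz:
    @pytest.mark.parametrize(
        "n, method, expected",
        [(18, PEARSON, 1 / 15), (18, SPEARMAN, 1.06 / 15), (4, PEARSON, 1.0)],
    )
    def test_variance_formula(self, n, method, expected):
        assert correlation_variance(n, method) == pytest.approx(expected, abs=1e-15)

    def test_variance_needs_n_above_three(self):
        with pytest.raises(DGCAError):
            correlation_variance(3)

    def test_equal_correlations_give_zero_dz_unit_p(self):
        dz, p = dz_statistic(0.5, 18, 0.5, 18)
        assert dz == 0.0
        assert p == 1.0

    def test_condition_swap_antisymmetry(self):
        dz1, p1 = dz_statistic(-0.2, 18, 0.9, 20)
        dz2, p2 = dz_statistic(0.9, 20, -0.2, 18)
        assert dz1 == pytest.approx(-dz2, abs=1e-14)
        assert p1 == pytest.approx(p2, abs=1e-15)

    @pytest.mark.parametrize("row", refdata.TOP_PAIRS, ids=lambda r: f"{r['gene1']}-{r['gene2']}")
    def test_reproduces_published_dz_and_p(self, row):
        dz, p = dz_statistic(row["control_cor"], 18, row["stress_cor"], 18)
        assert dz == pytest.approx(row["zScoreDiff"], abs=5e-3)
        assert p == pytest.approx(row["pValDiff"], rel=0.03)


class TestClassLabels:
    @pytest.mark.parametrize("row", refdata.TOP_PAIRS, ids=lambda r: f"{r['gene1']}-{r['gene2']}")
    def test_published_rows_classified_identically(self, row):
        label = classify_pair(
            CorrelationResult(row["control_cor"], row["control_pVal"], 18),
            CorrelationResult(row["stress_cor"], row["stress_pVal"], 18),
        )
        assert label == row["classes"]

    def test_threshold_boundaries(self):
        a = CorrelationResult(0.9, 1e-8, 18)
        b = CorrelationResult(-0.5, 0.04, 18)
        # p >= threshold renders "0": a vanishing threshold zeroes all signs,
        # a permissive one keeps every sign
        assert classify_pair(a, b, sig_threshold=1e-10) == "0/0"
        assert classify_pair(a, b, sig_threshold=0.05) == "+/-"
        assert classify_pair(a, b, sig_threshold=0.01) == "+/0"


class TestPairScans:
    def test_pair_count_is_m_choose_2(self, rng):
        for m, expected in ((2, 1), (36, 630)):
            X = pd.DataFrame(
                rng.standard_normal((m, 36)),
                index=[f"g{i}" for i in range(m)],
                columns=make_design(18, 18).index,
            )
            recs = dgca_all_pairs(X, make_design(18, 18))
            assert len(recs) == expected

    def test_vectorized_scan_matches_per_pair_scipy(self, rng):
        design = make_design(9, 9)
        X = pd.DataFrame(
            rng.standard_normal((5, 18)),
            index=[f"g{i}" for i in range(5)],
            columns=design.index,
        )
        recs = dgca_all_pairs(X, design)
        cond = (design["condition"] == "stress").to_numpy()
        for r in recs:
            a = X.loc[r.gene1].to_numpy()
            b = X.loc[r.gene2].to_numpy()
            rc = stats.pearsonr(a[~cond], b[~cond])
            rw = stats.pearsonr(a[cond], b[cond])
            assert r.control.r == pytest.approx(rc.statistic, abs=1e-12)
            assert r.control.p == pytest.approx(rc.pvalue, rel=1e-9)
            assert r.stress.r == pytest.approx(rw.statistic, abs=1e-12)
            expected_dz = (np.arctanh(rw.statistic) - np.arctanh(rc.statistic)) / np.sqrt(2 / 6)
            assert r.dz == pytest.approx(expected_dz, abs=1e-10)

    def test_dz_invariant_under_affine_rescaling(self, rng):
        design = make_design(9, 9)
        X = pd.DataFrame(
            rng.standard_normal((2, 18)),
            index=["a", "b"],
            columns=design.index,
        )
        base = dgca_all_pairs(X, design)[0]
        X2 = X * 7.0 + 3.0
        scaled = dgca_all_pairs(X2, design)[0]
        assert scaled.dz == pytest.approx(base.dz, abs=1e-12)

    def test_insufficient_condition_samples_error(self, rng):
        design = make_design(3, 15)
        X = pd.DataFrame(rng.standard_normal((3, 18)), columns=design.index)
        with pytest.raises(DGCAError, match=">= 4"):
            dgca_all_pairs(X, design)

    def test_planted_block_has_top_dz(self):
        """Strongly contrasted planted pairs out-rank null pairs."""
        from wlgenes import simdata

        cfg = simdata.SimConfig(
            n_genes=12, n_control=18, n_stress=18, seed=0, de_fraction=0.0,
            dc_blocks=[(4, 0.0, 0.95)], output_mode="gaussian",
        )
        ds = simdata.generate_dataset(cfg)
        recs = dgca_all_pairs(ds.counts, ds.design)
        planted = {(p["gene1"], p["gene2"]) for p in ds.truth.dc_pairs}
        ranked = sorted(recs, key=lambda r: -abs(r.dz))
        assert (ranked[0].gene1, ranked[0].gene2) in planted


class TestTopPairs:
    def _toy_records(self):
        design = make_design(9, 9)
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.standard_normal((4, 18)),
            index=list("abcd"),
            columns=design.index,
        )
        return dgca_all_pairs(X, design)

    def test_k_larger_than_count_returns_all(self):
        recs = self._toy_records()
        assert top_pairs(recs, k=100) == sorted(
            recs, key=lambda r: (r.p_diff, -abs(r.dz), r.gene1, r.gene2)
        )

    def test_cutoff_filters_strictly(self):
        recs = self._toy_records()
        cut = np.median([r.p_diff for r in recs])
        kept = top_pairs(recs, p_cutoff=cut)
        assert all(r.p_diff < cut for r in kept)
        assert len(kept) == sum(r.p_diff < cut for r in recs)

    def test_frame_mirrors_published_columns(self):
        frame = records_to_frame(self._toy_records())
        assert list(frame.columns) == [
            "gene1", "gene2", "control_cor", "control_pVal",
            "stress_cor", "stress_pVal", "zScoreDiff", "pValDiff", "Classes",
        ]


def test_null_type_one_error_is_nominal():
    """Fraction of null pairs with p_diff < 0.01 matches the nominal rate."""
    rng = np.random.default_rng(7)
    n_pairs = 2000
    design = make_design(18, 18)
    X = pd.DataFrame(
        rng.standard_normal((2 * n_pairs, 36)),
        index=[f"g{i}" for i in range(2 * n_pairs)],
        columns=design.index,
    )
    pairs = [(f"g{2*i}", f"g{2*i+1}") for i in range(n_pairs)]
    recs = dgca_pairs(X, design, pairs)
    frac = np.mean([r.p_diff < 0.01 for r in recs])
    se = np.sqrt(0.01 * 0.99 / n_pairs)
    assert abs(frac - 0.01) <= 3 * se
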