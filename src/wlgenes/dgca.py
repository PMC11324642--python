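"""Differential gene correlation analysis (DGCA).

For each gene pair the correlation is computed separately under control and
stress, mapped through the Fisher z-transformation

    z = atanh(r) = (1/2) * ln((1 + r) / (1 - r)),

whose sampling variance is 1/(n-3) for Pearson and 1.06/(n-3) for Spearman
correlations.  The change in correlation between conditions is summarized by
the standardized difference

    dz = (z_stress - z_control) / sqrt(var_control + var_stress)

with a two-tailed p-value from the standard normal distribution.  Each pair
is also labelled with a class "c/s" where each side is "0" if that
condition's correlation is non-significant (p >= sig_threshold) and the sign
of r otherwise — e.g. "0/+" marks a pair uncorrelated in control that gains
a positive correlation under stress.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import CONTROL, STRESS

PEARSON = "pearson"
SPEARMAN = "spearman"
DEFAULT_SIG_THRESHOLD = 0.05
_CLAMP = 1.0 - 1e-12


class DGCAError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str = PEARSON


@dataclass(frozen=True)
class DGCAPairRecord:
    gene1: str
    gene2: str
    control: CorrelationResult
    stress: CorrelationResult
    z_control: float
    z_stress: float
    var_control: float
    var_stress: float
    dz: float
    p_diff: float
    classes: str


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df."""
    r = np.clip(r, -_CLAMP, _CLAMP)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def condition_correlation(x, y, method: str = PEARSON) -> CorrelationResult:
    """Correlation of two expression vectors with its t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DGCAError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise DGCAError(f"need n >= 4 samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DGCAError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DGCAError("constant vector")
    if method == SPEARMAN:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != PEARSON:
        raise DGCAError(f"unknown method {method!r}")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(max(r, -1.0), 1.0)
    p = float(_corr_p(np.array(r), n))
    return CorrelationResult(r=r, p=p, n=n, method=method)


def fisher_z(r):
    """Fisher z-transform; |r| clamped just inside 1 with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > _CLAMP):
        warnings.warn("correlation at or beyond +/-1 clamped for Fisher z", RuntimeWarning, stacklevel=2)
        r = np.clip(r, -_CLAMP, _CLAMP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def correlation_variance(n: int, method: str = PEARSON) -> float:
    """Variance of the Fisher z-score: 1/(n-3) Pearson, 1.06/(n-3) Spearman."""
    if n <= 3:
        raise DGCAError(f"z-score variance needs n >= 4, got {n}")
    if method == PEARSON:
        return 1.0 / (n - 3)
    if method == SPEARMAN:
        return 1.06 / (n - 3)
    raise DGCAError(f"unknown method {method!r}")


def dz_statistic(
    r_control: float, n_control: int, r_stress: float, n_stress: int, method: str = PEARSON
) -> tuple[float, float]:
    """Standardized z-score difference and its two-tailed normal p-value."""
    zc = fisher_z(r_control)
    zw = fisher_z(r_stress)
    var = correlation_variance(n_control, method) + correlation_variance(n_stress, method)
    dz = (zw - zc) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(dz))
    return float(dz), float(p)


def _sign_label(r: float, p: float, sig_threshold: float) -> str:
    if p >= sig_threshold:
        return "0"
    return "+" if r > 0 else "-"


def classify_pair(
    control: CorrelationResult,
    stress: CorrelationResult,
    sig_threshold: float = DEFAULT_SIG_THRESHOLD,
) -> str:
    """Render the differential-correlation class "control/stress"."""
    return (
        f"{_sign_label(control.r, control.p, sig_threshold)}/"
        f"{_sign_label(stress.r, stress.p, sig_threshold)}"
    )


def _split_conditions(X: pd.DataFrame, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cond = design.loc[list(X.columns), "condition"]
    M = X.to_numpy(dtype=float)
    Xc = M[:, (cond == CONTROL).to_numpy()]
    Xw = M[:, (cond == STRESS).to_numpy()]
    if Xc.shape[1] < 4 or Xw.shape[1] < 4:
        raise DGCAError(
            f"each condition needs >= 4 samples, got {Xc.shape[1]} control / {Xw.shape[1]} stress"
        )
    return Xc, Xw


def _rowwise_rank(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, M)


def pairwise_correlations(M: np.ndarray, pairs: np.ndarray, method: str = PEARSON) -> np.ndarray:
    """Correlation for each (i, j) row pair of M, vectorized."""
    if method == SPEARMAN:
        M = _rowwise_rank(M)
    Mc = M - M.mean(axis=1, keepdims=True)
    norm = np.sqrt((Mc**2).sum(axis=1))
    norm[norm == 0] = np.nan
    U = Mc / norm[:, None]
    r = (U[pairs[:, 0]] * U[pairs[:, 1]]).sum(axis=1)
    return np.clip(r, -1.0, 1.0)


def dgca_pairs(
    X: pd.DataFrame,
    design: pd.DataFrame,
    pairs: list[tuple[str, str]],
    method: str = PEARSON,
    sig_threshold: float = DEFAULT_SIG_THRESHOLD,
) -> list[DGCAPairRecord]:
    """DGCA records for an explicit list of gene-id pairs (vectorized)."""
    Xc, Xw = _split_conditions(X, design)
    nc, nw = Xc.shape[1], Xw.shape[1]
    pos = {g: i for i, g in enumerate(X.index)}
    idx = np.array([(pos[a], pos[b]) for a, b in pairs], dtype=int)
    rc = pairwise_correlations(Xc, idx, method)
    rw = pairwise_correlations(Xw, idx, method)
    if np.isnan(rc).any() or np.isnan(rw).any():
        bad = np.flatnonzero(np.isnan(rc) | np.isnan(rw))[0]
        raise DGCAError(f"constant vector in pair {pairs[bad]}")
    pc = _corr_p(rc, nc)
    pw = _corr_p(rw, nw)
    var_c = correlation_variance(nc, method)
    var_w = correlation_variance(nw, method)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        zc = fisher_z(rc)
        zw = fisher_z(rw)
    dz = (zw - zc) / np.sqrt(var_c + var_w)
    p_diff = 2.0 * stats.norm.sf(np.abs(dz))
    records = []
    for k, (a, b) in enumerate(pairs):
        ctrl = CorrelationResult(float(rc[k]), float(pc[k]), nc, method)
        strs = CorrelationResult(float(rw[k]), float(pw[k]), nw, method)
        records.append(
            DGCAPairRecord(
                gene1=a,
                gene2=b,
                control=ctrl,
                stress=strs,
                z_control=float(zc[k]),
                z_stress=float(zw[k]),
                var_control=var_c,
                var_stress=var_w,
                dz=float(dz[k]),
                p_diff=float(p_diff[k]),
                classes=classify_pair(ctrl, strs, sig_threshold),
            )
        )
    return records


def dgca_all_pairs(
    X: pd.DataFrame,
    design: pd.DataFrame,
    genes: list[str] | None = None,
    method: str = PEARSON,
    sig_threshold: float = DEFAULT_SIG_THRESHOLD,
) -> list[DGCAPairRecord]:
    """All m·(m-1)/2 unordered-pair records for a gene panel."""
    if genes is None:
        genes = list(X.index)
    if len(genes) < 2:
        raise DGCAError("need at least 2 genes")
    missing = [g for g in genes if g not in X.index]
    if missing:
        raise DGCAError(f"genes not in matrix: {missing[:5]}")
    pairs = list(combinations(genes, 2))
    return dgca_pairs(X.loc[genes], design, pairs, method, sig_threshold)


def top_pairs(
    records: list[DGCAPairRecord],
    k: int | None = None,
    p_cutoff: float | None = None,
) -> list[DGCAPairRecord]:
    """Most differentially correlated pairs.

    Sorted by p_diff ascending, ties broken by |dz| descending then by gene
    ids; returns the first *k* records, or all with p_diff < p_cutoff.
    """
    if not records:
        raise DGCAError("no records")
    ranked = sorted(records, key=lambda r: (r.p_diff, -abs(r.dz), r.gene1, r.gene2))
    if p_cutoff is not None:
        return [r for r in ranked if r.p_diff < p_cutoff]
    if k is None:
        raise DGCAError("give k or p_cutoff")
    return ranked[:k]


def records_to_frame(records: list[DGCAPairRecord]) -> pd.DataFrame:
    """Tabular view mirroring the published pair-table columns."""
    return pd.DataFrame(
        {
            "gene1": [r.gene1 for r in records],
            "gene2": [r.gene2 for r in records],
            "control_cor": [r.control.r for r in records],
            "control_pVal": [r.control.p for r in records],
            "stress_cor": [r.stress.r for r in records],
            "stress_pVal": [r.stress.p for r in records],
            "zScoreDiff": [r.dz for r in records],
            "pValDiff": [r.p_diff for r in records],
            "Classes": [r.classes for r in records],
        }
    )


def adjust_p_values(records: list[DGCAPairRecord], method: str = "fdr_bh") -> pd.Series:
    """Optional Benjamini-Hochberg adjustment of the pair p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.array([r.p_diff for r in records])
    return pd.Series(multipletests(p, method=method)[1], name="pAdjDiff")
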