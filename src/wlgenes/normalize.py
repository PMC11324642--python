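"""Median-of-ratios count normalization.

Per-sample size factors are the median, over genes whose counts are positive
in every sample, of that sample's count divided by the gene's geometric mean
across samples.  Counts divided by the size factor are comparable across
sequencing depths and library compositions.  Size factors are rescaled to
geometric mean 1 so normalized values stay on the counts scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class NormalizationError(ValueError):
    pass


def validate_counts(counts: pd.DataFrame) -> None:
    """Check count-matrix invariants: unique ids, >= 2 samples, entries >= 0."""
    if counts.index.has_duplicates:
        raise NormalizationError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise NormalizationError("duplicate sample ids in count matrix")
    if counts.shape[1] < 2:
        raise NormalizationError("count matrix needs at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise NormalizationError("counts must be non-negative")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample, geometric mean rescaled to 1.

    Genes with a zero count in any sample are excluded (their geometric mean
    is zero and the ratio undefined).
    """
    validate_counts(counts)
    K = counts.to_numpy(dtype=float)
    eligible = (K > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError("no gene with all-positive counts")
    logK = np.log(K[eligible])
    log_geomean = logK.mean(axis=1)
    # median of ratios == exp(median of log ratios); log form is stabler
    log_s = np.median(logK - log_geomean[:, None], axis=0)
    log_s -= log_s.mean()  # rescale to geometric mean 1
    return pd.Series(np.exp(log_s), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, s: pd.Series | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample's counts by its size factor.

    Returns ``(normalized, size_factors)``.  If *s* is omitted it is computed
    from *counts*.
    """
    validate_counts(counts)
    if s is None:
        s = size_factors(counts)
    else:
        s = pd.Series(s)
        if len(s) != counts.shape[1]:
            raise NormalizationError(
                f"{len(s)} size factors for {counts.shape[1]} samples"
            )
        if not s.index.equals(counts.columns):
            s = pd.Series(np.asarray(s, dtype=float), index=counts.columns)
        if (s <= 0).any():
            raise NormalizationError("size factors must be strictly positive")
    return counts.div(s, axis=1), s


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) of a normalized matrix — the default downstream input."""
    return np.log2(normalized + 1.0)


def reference_means(counts: pd.DataFrame) -> pd.Series:
    """Per-gene geometric mean across samples (0 where any count is 0)."""
    K = counts.to_numpy(dtype=float)
    out = np.zeros(K.shape[0])
    pos = (K > 0).all(axis=1)
    out[pos] = np.exp(np.log(K[pos]).mean(axis=1))
    return pd.Series(out, index=counts.index, name="geometric_mean")
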