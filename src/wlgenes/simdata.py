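"""Synthetic two-condition count datasets with planted signal.

Emulates a pooled waterlogging-stress RNA-seq design: several studies
contribute control and stress samples, counts are negative-binomial with
per-sample size factors and per-study batch shifts, a fraction of genes is
differentially expressed, and designated gene blocks carry condition-specific
pairwise correlation (the structure differential gene correlation analysis is
meant to detect).

Two output modes are provided.  ``counts`` mode produces the realistic integer
count matrix.  ``gaussian`` mode returns the latent log2 expression directly
(no count noise, no size factors), so the planted correlations hold exactly in
population and downstream statistics can be tested sharply.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
STRESS = "stress"

#: |rho| below this floor is treated as undetectable when deriving the
#: expected differential-correlation class for ground truth.
DETECTABILITY_FLOOR = 0.3


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass(frozen=True)
class DCBlock:
    """A gene block with planted per-condition pairwise correlation."""

    size: int
    rho_control: float
    rho_stress: float


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror the pooled cucumber waterlogging design this package
    targets: 20,144 genes and 18 control + 18 stress samples contributed by
    three studies (3/9/6 samples per condition).
    """

    n_genes: int = 20_144
    n_control: int = 18
    n_stress: int = 18
    n_studies: int = 3
    seed: int = 0
    de_fraction: float = 0.05
    lfc_sd: float = 2.0
    dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    study_shift_sd: float = 0.25
    dc_blocks: Sequence[DCBlock | tuple[int, float, float]] = field(default_factory=list)
    #: also give correlation-block genes a differential-expression effect, so
    #: they pass the upstream selectors and reach the correlation analysis
    blocks_are_de: bool = False
    output_mode: str = "counts"
    #: mean of the per-gene log2 baseline expression
    log2_mean: float = 5.0
    #: spread of per-gene baseline expression across genes (log2 units)
    log2_sd: float = 2.0
    #: per-sample latent biological noise, log2 units
    latent_sd: float = 0.7
    #: per-condition samples per study; default splits like the pooled design
    study_sizes: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.dc_blocks = [b if isinstance(b, DCBlock) else DCBlock(*b) for b in self.dc_blocks]
        self.validate()

    def validate(self) -> None:
        if self.n_control < 4 or self.n_stress < 4:
            raise SimConfigError(
                "n_control and n_stress must be >= 4 (z-score variance needs n > 3); "
                f"got {self.n_control}/{self.n_stress}"
            )
        if self.output_mode not in ("counts", "gaussian"):
            raise SimConfigError(f"output_mode must be 'counts' or 'gaussian', got {self.output_mode!r}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise SimConfigError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise SimConfigError(f"size_factor_range must satisfy 0 < lo <= hi, got {self.size_factor_range}")
        if self.dispersion < 0:
            raise SimConfigError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.n_studies < 1:
            raise SimConfigError("n_studies must be >= 1")
        for blk in self.dc_blocks:
            if blk.size < 2:
                raise SimConfigError(f"dc_block size must be >= 2, got {blk.size}")
            for rho in (blk.rho_control, blk.rho_stress):
                if not -1.0 < rho < 1.0:
                    raise SimConfigError(f"every rho must lie in (-1, 1), got {rho}")
        if sum(b.size for b in self.dc_blocks) > self.n_genes:
            raise SimConfigError("sum of dc_block sizes exceeds n_genes")
        if self.study_sizes is not None:
            sizes = list(self.study_sizes)
            if len(sizes) != self.n_studies or any(s < 0 for s in sizes):
                raise SimConfigError("study_sizes must list one non-negative count per study")


class GroundTruth(NamedTuple):
    """Machine-readable record of the planted signal."""

    de_genes: dict[str, float]  # gene id -> planted log2 fold change
    dc_pairs: list[dict]  # gene1, gene2, rho_control, rho_stress, expected_class
    size_factors: pd.Series  # per-sample scale, 1.0 everywhere in gaussian mode


class Dataset(NamedTuple):
    counts: pd.DataFrame  # genes x samples
    design: pd.DataFrame  # index sample_id; columns condition, study
    truth: GroundTruth


def _expected_sign(rho: float, floor: float = DETECTABILITY_FLOOR) -> str:
    if abs(rho) < floor:
        return "0"
    return "+" if rho > 0 else "-"


def expected_class(rho_control: float, rho_stress: float, floor: float = DETECTABILITY_FLOOR) -> str:
    """Class label ("0/+", "+/-", ...) a pair should receive at large n."""
    return f"{_expected_sign(rho_control, floor)}/{_expected_sign(rho_stress, floor)}"


def _study_assignment(cfg: SimConfig) -> tuple[list[str], list[str]]:
    """Condition and study label per sample (controls first)."""
    if cfg.study_sizes is not None:
        per_study = list(cfg.study_sizes)
    elif cfg.n_studies == 3 and cfg.n_control == 18 and cfg.n_stress == 18:
        per_study = [3, 9, 6]  # the pooled design's per-condition split
    else:
        base = cfg.n_control // cfg.n_studies
        per_study = [base + (1 if i < cfg.n_control % cfg.n_studies else 0) for i in range(cfg.n_studies)]
    conditions = [CONTROL] * cfg.n_control + [STRESS] * cfg.n_stress

    def spread(n: int) -> list[str]:
        out: list[str] = []
        sizes = per_study
        if sum(sizes) != n:  # stress arm may differ in size; rescale round-robin
            base = n // cfg.n_studies
            sizes = [base + (1 if i < n % cfg.n_studies else 0) for i in range(cfg.n_studies)]
        for i, s in enumerate(sizes):
            out.extend([f"study{i + 1}"] * s)
        return out

    studies = spread(cfg.n_control) + spread(cfg.n_stress)
    return conditions, studies


def generate_dataset(config: SimConfig) -> Dataset:
    """Generate one synthetic dataset plus its ground truth.

    The latent log2 expression of gene *i* in sample *j* is

        l_ij = b_i + batch(study_j, i) + lfc_i * [j in stress] + latent_sd * u_ij

    where the standardized residual ``u`` is white noise except inside a
    declared correlation block, where ``u_ij = s_i * (sqrt(|rho|) * f_j +
    sqrt(1 - |rho|) * e_ij)`` with a per-sample factor ``f`` shared by the
    block and per-gene sign flags ``s_i``, so that the population correlation
    of a pair equals ``s_i * s_k * |rho|`` exactly.  In ``counts`` mode the
    matrix is NB(mean = size_factor * 2**l, variance = mu + dispersion * mu²).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_control + cfg.n_stress
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{j:02d}" for j in range(n_samples)]
    conditions, studies = _study_assignment(cfg)
    stress_mask = np.array([c == STRESS for c in conditions])

    baseline = rng.normal(cfg.log2_mean, cfg.log2_sd, size=cfg.n_genes)

    # batch effect: per (study, gene) log2 shift; correlation-block genes are
    # exempt so their planted pair correlation is exact (a per-gene batch
    # pattern would add uncorrelated variance and attenuate every rho)
    study_names = sorted(set(studies))
    study_idx = np.array([study_names.index(s) for s in studies])
    batch = rng.normal(0.0, cfg.study_shift_sd, size=(len(study_names), cfg.n_genes))
    batch[:, : sum(b.size for b in cfg.dc_blocks)] = 0.0

    # differential expression
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    if cfg.blocks_are_de:
        block_idx = np.arange(sum(b.size for b in cfg.dc_blocks))
        de_idx = np.union1d(de_idx, block_idx)
    lfc = np.zeros(cfg.n_genes)
    if de_idx.size:
        lfc[de_idx] = rng.normal(0.0, cfg.lfc_sd, size=de_idx.size)
        if cfg.blocks_are_de:
            # block genes get a random sign but magnitude exactly lfc_sd:
            # an equally-strong planted panel that reliably reaches the
            # selectors without any one gene dominating
            blk = np.arange(sum(b.size for b in cfg.dc_blocks))
            sign = np.where(lfc[blk] >= 0, 1.0, -1.0)
            lfc[blk] = sign * cfg.lfc_sd

    # standardized residuals, with correlation blocks planted up front
    resid = rng.standard_normal((cfg.n_genes, n_samples))
    dc_pairs: list[dict] = []
    row = 0
    for blk in cfg.dc_blocks:
        idx = np.arange(row, row + blk.size)
        row += blk.size
        f = rng.standard_normal(n_samples)  # shared per-sample factor
        eps = rng.standard_normal((blk.size, n_samples))
        pair_rho: dict[str, np.ndarray] = {}
        for key, cond_mask, rho in ((CONTROL, ~stress_mask, blk.rho_control), (STRESS, stress_mask, blk.rho_stress)):
            # negative rho realised by alternating per-gene sign flags
            # (a block of >2 genes cannot be mutually negatively correlated;
            # adjacent pairs get -|rho|, same-sign pairs +|rho|)
            signs = np.ones(blk.size)
            if rho < 0:
                signs[1::2] = -1.0
            a = math.sqrt(abs(rho))
            b = math.sqrt(1.0 - abs(rho))
            resid[np.ix_(idx, np.flatnonzero(cond_mask))] = signs[:, None] * (
                a * f[cond_mask][None, :] + b * eps[:, cond_mask]
            )
            pair_rho[key] = np.outer(signs, signs) * abs(rho)
        for u in range(blk.size):
            for v in range(u + 1, blk.size):
                rc = float(pair_rho[CONTROL][u, v])
                rw = float(pair_rho[STRESS][u, v])
                dc_pairs.append(
                    {
                        "gene1": gene_ids[idx[u]],
                        "gene2": gene_ids[idx[v]],
                        "rho_control": float(rc),
                        "rho_stress": float(rw),
                        "expected_class": expected_class(rc, rw),
                    }
                )

    latent = (
        baseline[:, None]
        + batch[study_idx, :].T
        + lfc[:, None] * stress_mask[None, :]
        + cfg.latent_sd * resid
    )

    design = pd.DataFrame({"condition": conditions, "study": studies}, index=pd.Index(sample_ids, name="sample_id"))

    if cfg.output_mode == "gaussian":
        values = pd.DataFrame(latent, index=gene_ids, columns=sample_ids)
        truth = GroundTruth(
            de_genes={gene_ids[i]: float(lfc[i]) for i in de_idx},
            dc_pairs=dc_pairs,
            size_factors=pd.Series(1.0, index=sample_ids, name="size_factor"),
        )
        return Dataset(values, design, truth)

    lo, hi = cfg.size_factor_range
    size_factors = rng.uniform(lo, hi, size=n_samples)
    mu = size_factors[None, :] * np.exp2(latent)
    if cfg.dispersion > 0:
        # NB via gamma-poisson mixture: var = mu + dispersion * mu^2
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    matrix = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids)
    truth = GroundTruth(
        de_genes={gene_ids[i]: float(lfc[i]) for i in de_idx},
        dc_pairs=dc_pairs,
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
    )
    return Dataset(matrix, design, truth)


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write counts TSV, metadata TSV and ground-truth JSON to *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "ground_truth.json",
    }
    counts = dataset.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(paths["counts"], sep="\t")
    meta = dataset.design.reset_index()
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    truth = {
        "de_genes": dataset.truth.de_genes,
        "dc_pairs": dataset.truth.dc_pairs,
        "size_factors": {k: float(v) for k, v in dataset.truth.size_factors.items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
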