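"""Pipeline orchestration and consensus set algebra.

Runs the full selection chain — median-of-ratios normalization, the four
attribute-weighting selectors, L1 logistic selection, differential gene
correlation analysis on the union panel, and random-forest / attribution /
shadow-feature validation — and reports the named gene sets and their
intersections.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dgca, io, lasso, normalize, validate, weights
from .weights import condition_vector

log = logging.getLogger("wlgenes")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, defaulting to the published protocol."""

    weight_threshold: float = 0.90
    sig_threshold: float = 0.05  # per-condition correlation significance
    p_diff_cutoff: float = 0.01  # differential-correlation significance
    top_k_pairs: int = 10
    lasso_folds: int = 10
    n_trees: int = 100
    boruta_max_runs: int = 100
    boruta_alpha: float = 0.01
    boruta_scope: str = "full"  # full | union | panel
    correlation_method: str = "pearson"
    log_transform: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.weight_threshold <= 1:
            raise ConfigError(f"weight_threshold must be in (0, 1], got {self.weight_threshold}")
        if not 0 < self.sig_threshold < 1:
            raise ConfigError(f"sig_threshold must be in (0, 1), got {self.sig_threshold}")
        if not 0 < self.p_diff_cutoff < 1:
            raise ConfigError(f"p_diff_cutoff must be in (0, 1), got {self.p_diff_cutoff}")
        if self.boruta_scope not in ("full", "union", "panel"):
            raise ConfigError(f"boruta_scope must be full/union/panel, got {self.boruta_scope!r}")
        if self.lasso_folds < 2 or self.n_trees < 1 or self.boruta_max_runs < 1:
            raise ConfigError("lasso_folds >= 2, n_trees >= 1, boruta_max_runs >= 1 required")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg


@dataclass
class SelectionReport:
    """Named gene sets per stage with their cardinalities and provenance."""

    method_sets: dict[str, list[str]]
    lasso_set: list[str]
    union_set: list[str]
    dgca_top_genes: list[str]
    boruta_confirmed: list[str]
    n_pairs: int
    n_significant_pairs: int
    intersections: dict[str, dict]
    validation: dict | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        # self-consistency: cardinalities recomputed from the sets
        d["cardinalities"] = {
            **{f"weights_{m}": len(s) for m, s in self.method_sets.items()},
            "lasso": len(self.lasso_set),
            "union": len(self.union_set),
            "dgca_top_genes": len(self.dgca_top_genes),
            "boruta_confirmed": len(self.boruta_confirmed),
        }
        return d


def union_selected(method_sets: dict[str, set[str]], lasso_set: set[str]) -> set[str]:
    """Union of the per-method selections and the L1-selected genes."""
    out: set[str] = set(lasso_set)
    for s in method_sets.values():
        out |= set(s)
    return out


def intersect(set_a, set_b) -> tuple[set[str], int]:
    """Exact intersection and its cardinality."""
    common = set(set_a) & set(set_b)
    return common, len(common)


def genes_in_top_pairs(records) -> set[str]:
    """Distinct gene ids appearing in any of the given pair records."""
    if not records:
        raise dgca.DGCAError("no pair records")
    out: set[str] = set()
    for r in records:
        out.add(r.gene1)
        out.add(r.gene2)
    return out


def _hash(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv().encode()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.md5(payload).hexdigest()[:10]


def _log_stage(stage: str, params: dict, output) -> None:
    log.info("stage=%s params=%s output_hash=%s", stage, params, _hash(output))


def run_pipeline(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> SelectionReport:
    """Execute the full selection chain and assemble the consensus report.

    Stages: normalize -> four attribute weightings -> L1 logistic selection
    -> union U -> all-pairs DGCA on U -> top pairs -> top-pair gene set D ->
    random-forest validation with attributions on D -> shadow-feature
    confirmation.  Reruns with the same inputs and config are byte-identical.
    """
    config = config or PipelineConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in ("lasso", "rf", "boruta")}

    normalized, size_factors = normalize.normalize(counts)
    X = normalize.log_transform(normalized) if config.log_transform else normalized
    _log_stage("normalize", {"log_transform": config.log_transform}, size_factors.to_dict())

    tables = weights.weight_all_methods(X, design, threshold=config.weight_threshold)
    method_sets = {m: t.selected for m, t in tables.items()}
    _log_stage("weights", {"threshold": config.weight_threshold}, {m: sorted(s) for m, s in method_sets.items()})

    y = condition_vector(design, X.columns)
    Z = lasso.standardize(X)
    lasso_result = lasso.cross_validate_lambda(Z, y, folds=config.lasso_folds, seed=seeds["lasso"])
    lasso_set = lasso_result.selected_genes("1se")
    _log_stage("lasso", {"folds": config.lasso_folds, "lambda_1se": lasso_result.lambda_1se}, sorted(lasso_set))

    union = union_selected(method_sets, lasso_set)

    records: list = []
    top: list = []
    panel: set[str] = set()
    n_significant = 0
    if len(union) >= 2:
        records = dgca.dgca_all_pairs(
            X,
            design,
            genes=sorted(union),
            method=config.correlation_method,
            sig_threshold=config.sig_threshold,
        )
        n_significant = sum(r.p_diff < config.p_diff_cutoff for r in records)
        top = dgca.top_pairs(records, k=config.top_k_pairs)
        panel = genes_in_top_pairs(top)
    _log_stage("dgca", {"panel": len(union), "top_k": config.top_k_pairs}, sorted(panel))

    validation = None
    if len(panel) >= 2:
        v = validate.validate_panel(X, design, genes=sorted(panel), n_trees=config.n_trees, seed=seeds["rf"])
        validation = {
            "n_trees": v.n_trees,
            "oob_error": v.oob_error,
            "accuracy": v.accuracy,
            "auc": v.auc,
            "protocol": v.protocol,
            "importance_ranking": v.importance_ranking,
            "base_value": v.base_value,
            "seed": v.seed,
        }
    _log_stage("validate", {"n_trees": config.n_trees}, validation)

    scope_genes = {
        "full": list(X.index),
        "union": sorted(union),
        "panel": sorted(panel),
    }[config.boruta_scope]
    boruta_confirmed: set[str] = set()
    if len(scope_genes) >= 2:
        bres = validate.boruta(
            X.loc[scope_genes],
            y,
            max_runs=config.boruta_max_runs,
            alpha=config.boruta_alpha,
            seed=seeds["boruta"],
            n_trees=config.n_trees,
        )
        validate.tentative_rough_fix(bres)
        boruta_confirmed = bres.confirmed
    _log_stage("boruta", {"scope": config.boruta_scope, "max_runs": config.boruta_max_runs}, sorted(boruta_confirmed))

    inter_union_boruta, n_ub = intersect(union, boruta_confirmed)
    inter_panel_boruta, n_pb = intersect(panel, boruta_confirmed)
    report = SelectionReport(
        method_sets={m: sorted(s) for m, s in method_sets.items()},
        lasso_set=sorted(lasso_set),
        union_set=sorted(union),
        dgca_top_genes=sorted(panel),
        boruta_confirmed=sorted(boruta_confirmed),
        n_pairs=len(records),
        n_significant_pairs=n_significant,
        intersections={
            "union_and_boruta": {"genes": sorted(inter_union_boruta), "n": n_ub},
            "top_pair_genes_and_boruta": {"genes": sorted(inter_panel_boruta), "n": n_pb},
        },
        validation=validation,
        provenance={
            "seed": config.seed,
            "stage_seeds": seeds,
            "weight_threshold": config.weight_threshold,
            "sig_threshold": config.sig_threshold,
            "p_diff_cutoff": config.p_diff_cutoff,
            "lambda_1se": lasso_result.lambda_1se,
            "lambda_min": lasso_result.lambda_min,
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
        },
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_matrix(X, outdir / "normalized.tsv")
        size_factors.rename("size_factor").to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
        for m, t in tables.items():
            frame = t.weights.rename("weight").to_frame()
            frame["selected"] = frame.index.isin(list(method_sets[m]))
            frame.to_csv(outdir / f"weights_{m}.tsv", sep="\t")
        pd.DataFrame(
            {
                "lambda": lasso_result.lambda_grid,
                "cv_mean": lasso_result.cv_mean,
                "cv_se": lasso_result.cv_se,
                "n_nonzero": (lasso_result.coef_paths != 0).sum(axis=1),
            }
        ).to_csv(outdir / "lasso_cv.tsv", sep="\t", index=False)
        io.write_gene_list(lasso_set, outdir / "lasso_genes.txt")
        io.write_gene_list(union, outdir / "union_genes.txt")
        if records:
            dgca.records_to_frame(records).to_csv(outdir / "dgca_pairs.tsv", sep="\t", index=False)
        io.write_gene_list(panel, outdir / "top_pair_genes.txt")
        io.write_json(report.to_dict(), outdir / "report.json")
    return report
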