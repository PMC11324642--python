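"""TSV/JSON readers and writers for the pipeline's standard formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simdata import CONTROL, STRESS


class FormatError(ValueError):
    pass


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample count TSV (first column gene_id, header = sample ids)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"counts file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 sample columns")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, condition, study."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = set(df["condition"]) - {CONTROL, STRESS}
    if bad:
        raise FormatError(f"{path}: unknown conditions {sorted(bad)}")
    if "study" not in df.columns:
        df["study"] = "study1"
    return df.set_index("sample_id")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gene list not found: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "gene_id") -> Path:
    path = Path(path)
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
    return path


def write_gene_list(genes, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(sorted(genes)) + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path
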