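"""Readers and writers for the pipeline's plain-text formats.

Expression matrices, probability tables, catalogues and enrichment curves
travel as TSV (gene IDs may contain commas in annotation dumps, so TSV over
CSV; headers are mandatory).  Gene lists are one ID per line; stage metadata
is a two-column TSV (stage, is_adult); configuration is YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_list",
    "write_gene_list",
    "read_stage_metadata",
    "write_stage_metadata",
    "read_probability_table",
    "write_probability_table",
    "read_catalogue",
    "write_catalogue",
    "read_config_file",
    "write_json",
]

_FLOAT_FMT = "%.10g"  # fixed format keeps reruns byte-identical


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x stage TSV (first column gene_id, stages in temporal order).

    Rejects duplicate gene IDs, missing cells and negative values, naming the
    offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # wrong column counts, unreadable cells
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    if df.index.name != "gene_id":
        raise ParseError(f"{path}: line 1: first column must be named 'gene_id'")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: line 1: no stage columns")
    if not all(df.dtypes.apply(pd.api.types.is_numeric_dtype)):
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        raise ParseError(f"{path}: non-numeric values in column(s) {bad}")
    if df.index.has_duplicates:
        pos = int(df.index.duplicated().argmax())
        raise ParseError(f"{path}: line {pos + 2}: duplicate gene ID {df.index[pos]!r}")
    if df.isna().any(axis=None):
        pos = int(df.isna().any(axis=1).to_numpy().argmax())
        raise ParseError(f"{path}: line {pos + 2}: missing value")
    if (df.to_numpy() < 0).any():
        pos = int((df < 0).any(axis=1).to_numpy().argmax())
        raise ParseError(f"{path}: line {pos + 2}: negative expression value")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one ID per line; blank lines ignored."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines()]
    ids = [i for i in ids if i]
    seen: set[str] = set()
    for k, gid in enumerate(ids):
        if gid in seen:
            raise ParseError(f"{path}: duplicate gene ID {gid!r}")
        seen.add(gid)
    return ids


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{gid}\n" for gid in sorted(ids)))


def read_stage_metadata(path: str | Path) -> pd.DataFrame:
    """Stage sidecar: columns ``stage`` and ``is_adult`` (0/1), temporal order."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["stage", "is_adult"]:
        raise ParseError(f"{path}: line 1: expected columns 'stage' and 'is_adult'")
    if not df["is_adult"].isin([0, 1]).all():
        raise ParseError(f"{path}: is_adult must be 0 or 1")
    return df


def write_stage_metadata(stages: Iterable[str], adult_indices: Iterable[int],
                         path: str | Path) -> None:
    stages = list(stages)
    adult = set(int(i) for i in adult_indices)
    df = pd.DataFrame({"stage": stages,
                       "is_adult": [int(i in adult) for i in range(len(stages))]})
    df.to_csv(path, sep="\t", index=False)


def read_probability_table(path: str | Path) -> pd.DataFrame:
    df = read_expression_tsv(path)  # same shape contract: gene_id + numeric columns
    if ((df.to_numpy() < 0) | (df.to_numpy() > 1)).any():
        raise ParseError(f"{path}: probabilities must lie in [0, 1]")
    return df


def write_probability_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("gene_id").to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_catalogue(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != ["mean_probability"]:
        raise ParseError(f"{path}: expected columns gene_id, mean_probability")
    return df["mean_probability"]


def write_catalogue(mean_probability: pd.Series, path: str | Path) -> None:
    frame = mean_probability.rename("mean_probability").rename_axis("gene_id")
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_config_file(path: str | Path) -> dict:
    """YAML or JSON mapping, chosen by suffix (.json vs anything else)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
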