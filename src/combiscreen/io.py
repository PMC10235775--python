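"""Readers and writers for the pipeline's plain-text interchange formats.

Plates travel as tidy CSV (well, role, drug, dose, replicate, od); count and
expression matrices as TSV with genes in rows and a header of sample ids;
survival tables as TSV (sample, time, event); gene lists as one id per line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_plate",
    "write_plate",
    "read_matrix",
    "write_matrix",
    "read_survival",
    "write_survival",
    "read_groups",
    "write_groups",
    "read_gene_list",
    "write_gene_list",
]


def read_plate(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_plate(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)


def read_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_survival(path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    missing = required - set(surv.columns)
    if missing:
        raise ValueError(f"survival table is missing column(s): {sorted(missing)}")
    if not set(surv["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return surv


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def read_groups(path) -> pd.Series:
    """Two-column sample -> group TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("group map needs two columns: sample, group")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")


def write_groups(groups: pd.Series, path) -> None:
    groups.rename_axis("sample").rename("group").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
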