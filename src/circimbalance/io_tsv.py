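"""Plain-TSV readers and writers for all pipeline artifacts.

Every writer emits a header line; count matrices are written with
features as rows and samples as columns, per-tool call tables as
BED-like TSV (chrom, start, end, strand, tool, then per-sample counts).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from circimbalance.containers import CountMatrix


def write_counts(counts: "CountMatrix | pd.DataFrame", path) -> None:
    frame = counts.data if isinstance(counts, CountMatrix) else counts
    frame.to_csv(path, sep="\t", index_label="feature")


def read_counts(path, rna_class: str | None = None) -> "pd.DataFrame | CountMatrix":
    frame = pd.read_csv(path, sep="\t", index_col="feature")
    if rna_class is None:
        return frame
    return CountMatrix(frame, rna_class)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_tool_calls(calls: Mapping[str, pd.DataFrame], directory) -> list[Path]:
    directory = Path(directory)
    paths = []
    for tool, table in calls.items():
        out = table.copy()
        out.insert(4, "tool", tool)
        path = directory / f"tool_calls_{tool}.tsv"
        out.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_tool_calls(paths) -> dict[str, pd.DataFrame]:
    calls = {}
    for path in paths:
        table = pd.read_csv(path, sep="\t")
        if "tool" not in table.columns:
            raise ValueError(f"{path}: call table lacks a 'tool' column")
        for tool, sub in table.groupby("tool"):
            calls[str(tool)] = sub.drop(columns="tool").reset_index(drop=True)
    return calls


def write_gene_model(gene_model: pd.DataFrame, path) -> None:
    gene_model.to_csv(path, sep="\t", index=False)


def read_gene_model(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path, index_label: str | None = None) -> None:
    frame.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
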