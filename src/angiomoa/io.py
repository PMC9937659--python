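"""TSV readers/writers for the pipeline's external file formats.

All tables are tab-separated with a header row and row names in the first
column. Floats serialize with Python's shortest-repr formatting so identical
runs produce byte-identical files; the +inf odds-ratio sentinel serializes
as the string "inf".
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import ActivityMatrix
from .expression import ExpressionDataset


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_activity_matrix(path: str | Path, activity_cutoff: float = 0.5) -> ActivityMatrix:
    return ActivityMatrix(read_matrix(path), activity_cutoff=activity_cutoff)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: expected a 'label' column")
    return df["label"]


def read_expression_dataset(directory: str | Path,
                            expression: str = "expression.tsv",
                            samples: str = "samples.tsv",
                            probe_map: str = "probe_map.tsv") -> ExpressionDataset:
    d = Path(directory)
    values = read_matrix(d / expression)
    sheet = pd.read_csv(d / samples, sep="\t", index_col=0)
    sheet["is_control"] = sheet["is_control"].astype(bool)
    pmap = pd.read_csv(d / probe_map, sep="\t", index_col=0)["gene_id"]
    return ExpressionDataset(values=values, samples=sheet, probe_map=pmap)
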