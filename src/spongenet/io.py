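"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices are features x samples TSV with a header row of sample
IDs; metadata is one row per sample; interaction tables are two-column
``regulator<TAB>target`` TSV; gene sets travel as GMT; networks are exported
as SIF for Cytoscape-style consumers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

FEATURE_CLASSES = ("mRNA", "lncRNA", "miRNA")

#: fixed float format for every TSV we write, so reruns are byte-identical
FLOAT_FORMAT = "%.10g"


@dataclasses.dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with per-feature class labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids. Counts or
        normalized values depending on context.
    feature_class
        Series mapping feature id -> one of :data:`FEATURE_CLASSES`.
    """

    values: pd.DataFrame
    feature_class: pd.Series

    def __post_init__(self) -> None:
        self.feature_class = self.feature_class.reindex(self.values.index)
        unknown = set(self.feature_class.dropna()) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def of_class(self, cls: str) -> "ExpressionMatrix":
        """Submatrix restricted to one feature class."""
        keep = self.feature_class[self.feature_class == cls].index
        return ExpressionMatrix(self.values.loc[keep], self.feature_class.loc[keep])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        cols = [s for s in samples if s in self.values.columns]
        return ExpressionMatrix(self.values[cols], self.feature_class)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = matrix.values.copy()
    out.insert(0, "class", matrix.feature_class.values)
    out.to_csv(path, sep="\t", index_label="feature", float_format=FLOAT_FORMAT)
    return path


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature")
    cls = df.pop("class")
    return ExpressionMatrix(df, cls)


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metadata.to_csv(path, sep="\t", index_label="sample")
    return path


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample")
    if "lnm" in meta.columns:
        meta["lnm"] = meta["lnm"].astype("boolean")
    return meta


def write_interaction_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[["regulator", "target"]].to_csv(path, sep="\t", index=False)
    return path


def read_interaction_tsv(path: str | Path, source: str | None = None) -> pd.DataFrame:
    """Load a 2-column interaction table, dropping duplicate pairs.

    Returns a DataFrame with columns regulator/target and a ``source``
    attribute in ``.attrs``; duplicates are dropped (count in
    ``.attrs['n_duplicates_dropped']``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["regulator", "target"]:
        raise ValueError(
            f"{path}: expected header 'regulator<TAB>target', got {list(df.columns)}"
        )
    return dedup_interactions(df, source or Path(path).stem)


def dedup_interactions(df: pd.DataFrame, source: str) -> pd.DataFrame:
    df = df.copy()
    for col in ("regulator", "target"):
        df[col] = df[col].astype(str).str.strip()
    n0 = len(df)
    df = df.drop_duplicates(subset=["regulator", "target"]).reset_index(drop=True)
    df.attrs["source"] = source
    df.attrs["n_duplicates_dropped"] = n0 - len(df)
    return df


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            genes = list(genes)
            fh.write("\t".join([name, description, *genes]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    from gseapy.parser import read_gmt as _read_gmt

    return {k: list(v) for k, v in _read_gmt(str(path)).items()}


def write_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> Path:
    """Write (source, interaction-type, target) triples as SIF."""
    path = Path(path)
    with open(path, "w") as fh:
        for src, kind, dst in edges:
            fh.write(f"{src}\t{kind}\t{dst}\n")
    return path
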