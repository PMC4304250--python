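"""Readers and writers for the pipeline's file formats.

Expression matrices are genes x samples, either plain tab-separated text
(first column gene ids, header row sample ids) or GCT 1.2.  Clinical tables
are CSV.  Gene sets use the tab-delimited GMT convention
(name, description, members...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. pathways read from a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV or GCT.

    GCT files are detected by the ``#1.2`` version line; everything else is
    treated as plain TSV with gene ids in the first column.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene identifiers")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write a genes x samples matrix as TSV or GCT 1.2."""
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical CSV keyed by ``sample_id``."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table must have a sample_id column")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and at least one member")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
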