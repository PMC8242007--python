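"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are tab-separated with gene identifiers in the first
column and a header row of sample identifiers; sample metadata is CSV;
gene sets are GMT (name, description, then members, tab-separated); the
tissue atlas is TSV with tissue labels in the first column.  Gene and
sample identifiers are opaque strings matched exactly across files.  All
writers emit deterministic orderings (genes and samples in input order,
gene sets sorted by name) so outputs are diffable, and floats with 17
significant digits so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("amniotx")

_FLOAT_FMT = "%.17g"

REQUIRED_METADATA_COLUMNS = ("sample_id", "group", "batch", "time_to_delivery")


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene identifiers with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what}: {dups[:5]}")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV into a DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    _check_unique(df.index, "gene identifiers")
    _check_unique(df.columns, "sample identifiers")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    if not np.isfinite(values).all():
        raise ValueError(f"non-finite expression values in {path}")
    logger.info("read expression %s: %d genes x %d samples", path, *df.shape)
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata CSV and validate required columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} missing required columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(pd.Index(df["sample_id"]), "sample identifiers")
    ttd = df["time_to_delivery"].to_numpy(dtype=float)
    if not (ttd > 0).all():
        raise ValueError("time_to_delivery must be strictly positive (weeks)")
    return df


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


def read_atlas(path: str | Path) -> pd.DataFrame:
    """Read a tissues x genes linear-scale reference atlas TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    _check_unique(df.index, "tissue labels")
    _check_unique(df.columns, "gene identifiers")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError(f"negative atlas values in {path}")
    return df.astype(float)


def write_atlas(atlas, path: str | Path) -> None:
    frame = atlas.values if hasattr(atlas, "tissues") else atlas
    frame.to_csv(path, sep="\t", index_label="tissue", float_format=_FLOAT_FMT)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
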