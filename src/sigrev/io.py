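"""Plain-text readers and writers for every format the pipeline touches.

Formats
-------
expression TSV   genes x samples; first column ``gene``, header = sample ids
groups TSV       two columns ``sample``, ``group``
ortholog TSV     two columns ``mouse_symbol``, ``human_symbol``
DEG TSV          columns ``gene``, ``logfc``, ``t``, ``p``, ``direction`` (+ extras)
RNK              two columns, no header: gene, real-valued score
GMT              name <TAB> description <TAB> member genes...
GRP query        two sections introduced by ``> up`` and ``> down``, one gene per line
manifest TSV     columns ``instance_id``, ``perturbagen``, ``cell_line``, ``path``

All writers emit byte-deterministic output for a fixed input (no timestamps,
fixed float formatting).
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError

FLOAT_FMT = "%.10g"


def _read_table(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except FileNotFoundError as exc:
        raise DataError(f"missing input file: {path}") from exc


# ---------------------------------------------------------------- expression

def write_expression(values: pd.DataFrame, path: str | os.PathLike) -> None:
    values.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"duplicate gene symbols in {path}: {dups}")
    return df


def write_groups(groups: pd.Series, path: str | os.PathLike) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample")


def read_groups(path: str | os.PathLike) -> pd.Series:
    df = _read_table(path, index_col=0)
    if "group" not in df.columns:
        raise DataError(f"groups file {path} lacks a 'group' column")
    return df["group"].astype(str)


# ----------------------------------------------------------------- orthologs

def write_ortholog_map(pairs: pd.DataFrame, path: str | os.PathLike) -> None:
    pairs[["mouse_symbol", "human_symbol"]].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path, dtype=str)
    missing = {"mouse_symbol", "human_symbol"} - set(df.columns)
    if missing:
        raise DataError(f"ortholog map {path} lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------- DEG tables

def write_deg_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_deg_table(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path, index_col=0)
    required = {"logfc", "p", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"DEG table {path} lacks columns {sorted(missing)}")
    return df


# ----------------------------------------------------------------------- RNK

def write_rnk(scores: pd.Series, path: str | os.PathLike) -> None:
    scores.to_csv(path, sep="\t", header=False, float_format=FLOAT_FMT)


def read_rnk(path: str | os.PathLike) -> pd.Series:
    df = _read_table(path, header=None, names=["gene", "score"],
                     dtype={"gene": str})
    if df["gene"].duplicated().any():
        raise DataError(f"duplicate genes in RNK file {path}")
    return pd.Series(df["score"].to_numpy(float), index=df["gene"])


# ----------------------------------------------------------------------- GMT

def write_gmt(sets: Iterable[tuple[str, str, Sequence[str]]],
              path: str | os.PathLike) -> None:
    """Write ``(name, description, members)`` triples as GMT lines."""
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | os.PathLike) -> list[tuple[str, str, list[str]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"malformed GMT line in {path}: {line[:60]!r}")
            out.append((fields[0], fields[1], fields[2:]))
    return out


# ----------------------------------------------------------------- GRP query

def write_query_grp(up: Sequence[str], down: Sequence[str],
                    path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("> up\n")
        fh.writelines(g + "\n" for g in up)
        fh.write("> down\n")
        fh.writelines(g + "\n" for g in down)


def read_query_grp(path: str | os.PathLike) -> tuple[list[str], list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line.lstrip("> ").lower()
                current = sections.setdefault(name, [])
            elif current is None:
                raise DataError(f"query file {path}: gene before section header")
            else:
                current.append(line)
    for side in ("up", "down"):
        if side not in sections:
            raise DataError(f"query file {path} lacks a '> {side}' section")
    return sections["up"], sections["down"]


# -------------------------------------------------------------- DB manifest

def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path, dtype=str)
    required = {"instance_id", "perturbagen", "cell_line", "path"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"manifest {path} lacks columns {sorted(missing)}")
    return df
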