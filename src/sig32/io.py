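"""Readers and writers for the package's file dialects.

One dialect per object: tab-separated matrices (first column = row id,
header row = column ids), GMT for gene sets, edge-list TSV for networks,
CSV for clinical tables, JSON for models. Values round-trip at full
precision (Python's shortest-repr float formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLINICAL_REQUIRED, GeneNetwork, MutationMatrix, PathwayDB, validate_clinical
from .errors import ParseError


def _read_table(path: str | Path, sep: str, index_name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ParseError(f"{path}: duplicate column ids")
    df.index.name = index_name
    return df


# -- expression matrices (genes x samples, TSV) --------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, "\t", "gene_id")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# -- mutation matrices (patients x genes, TSV) + type labels (CSV) -------------


def read_mutations(matrix_path: str | Path, types_path: str | Path) -> MutationMatrix:
    df = _read_table(matrix_path, "\t", "patient_id")
    types = pd.read_csv(types_path)
    for col in ("patient_id", "cancer_type"):
        if col not in types.columns:
            raise ParseError(f"{types_path}: missing column {col!r}")
    types = types.set_index("patient_id")["cancer_type"]
    missing = [p for p in df.index if p not in types.index]
    if missing:
        raise ParseError(f"{types_path}: no cancer type for patient {missing[0]!r}")
    values = df.to_numpy(dtype=float)
    return MutationMatrix(
        values=values.astype(int),
        patient_ids=list(df.index),
        gene_ids=list(df.columns),
        cancer_type=types.loc[df.index].to_numpy(),
    )


def write_mutations(mm: MutationMatrix, matrix_path: str | Path, types_path: str | Path) -> None:
    mm.to_frame().rename_axis("patient_id").to_csv(matrix_path, sep="\t")
    pd.DataFrame({"patient_id": mm.patient_ids, "cancer_type": mm.cancer_type}).to_csv(
        types_path, index=False
    )


# -- gene networks (edge-list TSV) ---------------------------------------------


def read_network(path: str | Path, genes: list[str] | None = None) -> GeneNetwork:
    edges = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b"):
        if col not in edges.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if genes is None:
        genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    index = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)))
    for line, (a, b) in enumerate(zip(edges["gene_a"], edges["gene_b"]), start=2):
        if a not in index or b not in index:
            raise ParseError(f"{path}:{line}: edge references unknown gene")
        A[index[a], index[b]] = 1.0
        A[index[b], index[a]] = 1.0
    return GeneNetwork(genes=genes, adjacency=A)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    net.edge_list().to_csv(path, sep="\t", index=False)


# -- pathway databases (GMT) ----------------------------------------------------


def read_gmt(path: str | Path) -> PathwayDB:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, _desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
    return PathwayDB(sets=sets)


def write_gmt(db: PathwayDB, path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in db.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# -- clinical tables (CSV) -------------------------------------------------------


def read_clinical(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    for col in CLINICAL_REQUIRED:
        if col not in table.columns:
            raise ParseError(f"{path}: clinical table is missing column {col!r}")
    return validate_clinical(table)


def write_clinical(table: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(table).to_csv(path, index=False)


# -- models (JSON) ----------------------------------------------------------------


def write_model_json(payload: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_model_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
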