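"""Core in-memory containers.

Expression matrices and clinical tables are plain pandas objects (genes x
samples DataFrames, one clinical row per sample); the containers here wrap
the structures that carry extra invariants: binary mutation matrices with a
cancer-type label per patient, gene-gene interaction networks, and pathway
databases (named gene sets with a 0/1 membership matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: Columns a clinical table must carry (extra covariate columns are allowed).
CLINICAL_REQUIRED = ("sample_id", "time_months", "event")


@dataclass
class MutationMatrix:
    """Binary somatic-mutation matrix (patients x genes) with one cancer type per patient."""

    values: np.ndarray
    patient_ids: list[str]
    gene_ids: list[str]
    cancer_type: np.ndarray  # one label per patient

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cancer_type = np.asarray(self.cancer_type, dtype=object)
        n, m = self.values.shape
        if len(self.patient_ids) != n or len(self.gene_ids) != m:
            raise InputError("mutation matrix shape does not match id lists")
        if len(self.cancer_type) != n:
            raise InputError("need exactly one cancer-type label per patient")
        if len(set(self.patient_ids)) != n or len(set(self.gene_ids)) != m:
            raise InputError("duplicate patient or gene ids in mutation matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise InputError("mutation matrix entries must be 0/1")

    @property
    def types(self) -> list[str]:
        """Cancer types in first-appearance order."""
        return list(pd.unique(pd.Series(self.cancer_type)))

    def type_indicator(self) -> tuple[np.ndarray, list[str]]:
        """Patients x types 0/1 indicator U (one 1 per row) and the type order."""
        types = self.types
        idx = {t: j for j, t in enumerate(types)}
        U = np.zeros((len(self.patient_ids), len(types)))
        for i, t in enumerate(self.cancer_type):
            U[i, idx[t]] = 1.0
        return U, types

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.gene_ids)


@dataclass
class GeneNetwork:
    """Undirected gene-gene interaction network as a symmetric adjacency matrix."""

    genes: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape != (len(self.genes), len(self.genes)):
            raise InputError("adjacency shape does not match gene list")
        if not np.allclose(A, A.T):
            raise InputError("adjacency must be symmetric")
        if (A < 0).any():
            raise InputError("adjacency must be non-negative")
        np.fill_diagonal(A, 0.0)
        self.adjacency = A

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))

    @property
    def laplacian(self) -> np.ndarray:
        """Combinatorial graph Laplacian L = D - A (rows sum to zero)."""
        return self.degree - self.adjacency

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.genes), k=1)
        mask = self.adjacency[iu, ju] > 0
        return pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in iu[mask]],
                "gene_b": [self.genes[j] for j in ju[mask]],
            }
        )


@dataclass
class PathwayDB:
    """Named gene sets (a pathway database) with a genes x pathways membership matrix."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise InputError(f"pathway {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise InputError(f"pathway {name!r} lists a gene twice")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def membership_matrix(self, gene_ids: list[str]) -> np.ndarray:
        """0/1 prior membership matrix V0 (genes x pathways) over the given gene universe."""
        index = {g: i for i, g in enumerate(gene_ids)}
        V0 = np.zeros((len(gene_ids), len(self.sets)))
        for j, genes in enumerate(self.sets.values()):
            for g in genes:
                if g in index:
                    V0[index[g], j] = 1.0
        return V0


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table schema; returns the table unchanged."""
    for col in CLINICAL_REQUIRED:
        if col not in table.columns:
            raise InputError(f"clinical table is missing required column {col!r}")
    if table["sample_id"].duplicated().any():
        raise InputError("clinical table has duplicate sample ids")
    if (table["time_months"] < 0).any():
        raise InputError("survival times must be non-negative")
    if not table["event"].isin((0, 1)).all():
        raise InputError("event indicator must be 0/1")
    return table
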