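"""Network-regularized non-negative matrix tri-factorization.

A binary somatic-mutation matrix X (patients x genes) is factored as
X ~ U S V', where U is *fixed* to the patient-to-cancer-type 0/1 indicator,
S >= 0 holds cancer-type x pathway association scores, and V >= 0 holds
gene x pathway memberships tethered to a pathway-database prior V0 and
smoothed along a gene-gene interaction network. The objective is

    F(S, V) = ||X - U S V'||_F^2 + lam_S ||S||_F^2
              + lam_L tr(V' L V) + lam_0 ||V - V0||_F^2,   S, V >= 0,

with L = D - A the combinatorial graph Laplacian. Alternating multiplicative
updates (the standard majorize-minimize scheme for this family) keep both
factors non-negative and make the objective non-increasing:

    S <- S * (U'XV) / (U'U S V'V + lam_S S)
    V <- V * (X'US + lam_L A V + lam_0 V0) / (V S'U'U S + lam_L D V + lam_0 V)

Rows of S are identified with cancer types because U is not learned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

_EPS = 1e-12


@dataclass
class Lambdas:
    """Regularization weights: ridge on S, network (Laplacian) weight, prior tether."""

    lam_S: float = 1.0
    lam_L: float = 1.0
    lam_0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lam_S, self.lam_L, self.lam_0) < 0:
            raise InputError("regularization weights must be non-negative")


@dataclass
class TriFactorModel:
    U: np.ndarray  # patients x types, fixed 0/1 indicator
    S: np.ndarray  # types x pathways, >= 0
    V: np.ndarray  # genes x pathways, >= 0
    types: list[str]
    pathway_names: list[str]
    lambdas: Lambdas
    objective_trace: np.ndarray
    converged: bool
    seed: int

    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.types, columns=self.pathway_names)


def _objective(
    X: np.ndarray, U: np.ndarray, S: np.ndarray, V: np.ndarray,
    L: np.ndarray, V0: np.ndarray, lam: Lambdas,
) -> float:
    resid = X - U @ S @ V.T
    return float(
        np.sum(resid * resid)
        + lam.lam_S * np.sum(S * S)
        + lam.lam_L * np.sum(V * (L @ V))
        + lam.lam_0 * np.sum((V - V0) ** 2)
    )


def fit_trifactor(
    X: np.ndarray,
    type_labels: np.ndarray | list[str],
    V0: np.ndarray,
    L: np.ndarray,
    lambdas: Lambdas | tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    types: list[str] | None = None,
    pathway_names: list[str] | None = None,
    validate_binary: bool = True,
    init_S: np.ndarray | None = None,
    init_V: np.ndarray | None = None,
) -> TriFactorModel:
    """Fit the tri-factorization with U fixed to the cancer-type indicator.

    Stops when the relative objective change drops below ``tol`` or after
    ``max_iter`` alternating updates; the objective is recorded after every
    iteration (monotone non-increasing by construction).
    """
    X = np.asarray(X, dtype=float)
    if validate_binary and not np.isin(X, (0.0, 1.0)).all():
        raise InputError("mutation matrix X must be binary 0/1")
    if (X < 0).any():
        raise InputError("mutation matrix X must be non-negative")
    V0 = np.asarray(V0, dtype=float)
    if not np.isin(V0, (0.0, 1.0)).all():
        raise InputError("pathway prior V0 must be binary 0/1")
    if (V0.sum(axis=0) == 0).any():
        raise InputError("pathway prior V0 has an all-zero pathway column")
    lam = lambdas if isinstance(lambdas, Lambdas) else Lambdas(*lambdas)

    labels = pd.Series(list(type_labels))
    if types is None:
        types = list(pd.unique(labels))
    type_idx = {t: j for j, t in enumerate(types)}
    U = np.zeros((X.shape[0], len(types)))
    for i, t in enumerate(labels):
        U[i, type_idx[t]] = 1.0

    n_genes, n_pathways = V0.shape
    if X.shape[1] != n_genes or L.shape != (n_genes, n_genes):
        raise InputError("X, V0 and L disagree on the number of genes")
    if pathway_names is None:
        pathway_names = [f"PW{j + 1:02d}" for j in range(n_pathways)]

    D = np.diag(np.diag(L)).copy()
    A = D - L  # L = D - A

    rng = np.random.default_rng(seed)
    V = (V0 + 0.01) if init_V is None else np.asarray(init_V, dtype=float).copy()
    S = (
        rng.uniform(0.01, 0.1, size=(len(types), n_pathways))
        if init_S is None
        else np.asarray(init_S, dtype=float).copy()
    )
    UtU = U.T @ U  # diagonal: patients per type
    UtX = U.T @ X

    trace = [_objective(X, U, S, V, L, V0, lam)]
    converged = False
    for _ in range(max_iter):
        # S update
        numer = UtX @ V
        denom = UtU @ S @ (V.T @ V) + lam.lam_S * S + _EPS
        S = S * (numer / denom)
        # V update
        US = U @ S
        numer = X.T @ US + lam.lam_L * (A @ V) + lam.lam_0 * V0
        denom = V @ (US.T @ US) + lam.lam_L * (D @ V) + lam.lam_0 * V + _EPS
        V = V * (numer / denom)
        obj = _objective(X, U, S, V, L, V0, lam)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break

    return TriFactorModel(
        U=U, S=S, V=V, types=types, pathway_names=list(pathway_names),
        lambdas=lam, objective_trace=np.asarray(trace), converged=converged, seed=seed,
    )
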