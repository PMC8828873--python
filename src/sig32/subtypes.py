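"""Molecular subtype discovery: consensus clustering over NMF restarts.

Each NMF run factors the non-negative signature-gene expression matrix
(genes x samples) as X ~ W H with multiplicative Frobenius updates from a
seeded random initialization and assigns every sample to its argmax metagene.
Consensus over ``n_runs`` restarts per candidate k yields a samples x samples
co-clustering matrix M_k; final labels cut an average-linkage dendrogram of
1 - M_k at k clusters. Stability diagnostics are the cophenetic correlation
coefficient, the CDF of consensus entries, and the delta (incremental) area
under that CDF; the codified k-selection rule takes the k with the largest
cophenetic coefficient (ties towards smaller k), with every diagnostic
exported so users can override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from ._seeds import child_seed
from .errors import InputError

_EPS = 1e-12


@dataclass
class NMFRun:
    W: np.ndarray  # genes x k
    H: np.ndarray  # k x samples
    k: int
    seed: int
    objective: float  # final squared Frobenius loss
    objective_trace: np.ndarray
    labels: np.ndarray  # 1..k per sample (argmax metagene)


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]  # per-k samples x samples matrix
    cophenetic: dict[int, float]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # (grid, CDF values)
    area: dict[int, float]
    delta_area: dict[int, float]
    linkage: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    labels: dict[int, np.ndarray] = field(default_factory=dict)  # final labels per k

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_range,
                "cophenetic": [self.cophenetic[k] for k in self.k_range],
                "area": [self.area[k] for k in self.k_range],
                "delta_area": [self.delta_area[k] for k in self.k_range],
            }
        )


def nmf(
    X: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFRun:
    """Multiplicative-update Frobenius NMF with a seeded random initialization.

    The squared-Frobenius objective is recorded every iteration and is
    non-increasing (the classical majorize-minimize guarantee). Sample labels
    are the argmax metagene per column of H.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise InputError(
            "NMF needs a non-negative matrix; shift the input above zero first "
            "(no silent shifting is applied)"
        )
    if k < 1:
        raise InputError("k must be >= 1")
    m, n = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(m, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale

    def loss() -> float:
        resid = X - W @ H
        return float(np.sum(resid * resid))

    trace = [loss()]
    for _ in range(max_iter):
        H = H * ((W.T @ X) / (W.T @ W @ H + _EPS))
        W = W * ((X @ H.T) / (W @ (H @ H.T) + _EPS))
        trace.append(loss())
        if trace[-2] > 0 and abs(trace[-2] - trace[-1]) / trace[-2] < tol:
            break
    labels = np.argmax(H, axis=0) + 1
    return NMFRun(
        W=W, H=H, k=k, seed=seed, objective=trace[-1],
        objective_trace=np.asarray(trace), labels=labels,
    )


def _connectivity(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_cluster(
    X: np.ndarray | pd.DataFrame,
    k_range: range | list[int] = range(2, 8),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    subsample_frac: float = 1.0,
    cdf_bins: int = 100,
) -> ConsensusResult:
    """Consensus matrices and stability diagnostics for each candidate k.

    For each k, ``n_runs`` NMF restarts with distinct child seeds (optionally
    on random sample subsets of fraction ``subsample_frac``) are aggregated
    into a consensus matrix; final labels cut the average-linkage dendrogram
    of 1 - M_k at k. The cophenetic coefficient correlates the 1 - M_k
    distances with the dendrogram's cophenetic distances; CDF areas use the
    trapezoid rule over ``cdf_bins`` bins on [0, 1].
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    k_range = list(k_range)
    if n_runs < 2:
        raise InputError("n_runs must be >= 2")
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise InputError(f"k_range must lie within [2, {n - 1}]")
    if not 0 < subsample_frac <= 1:
        raise InputError("subsample_frac must lie in (0, 1]")

    result = ConsensusResult(
        k_range=k_range, consensus={}, cophenetic={}, cdf={}, area={}, delta_area={}
    )
    grid = np.linspace(0.0, 1.0, cdf_bins + 1)
    prev_area = 0.0
    for k in k_range:
        co_count = np.zeros((n, n))
        pair_count = np.zeros((n, n))
        for r in range(n_runs):
            run_seed = child_seed(seed, f"nmf-k{k}-run{r}")
            if subsample_frac < 1.0:
                rng = np.random.default_rng(child_seed(seed, f"subsample-k{k}-run{r}"))
                size = max(k + 1, int(round(subsample_frac * n)))
                idx = np.sort(rng.choice(n, size=size, replace=False))
            else:
                idx = np.arange(n)
            run = nmf(X[:, idx], k, seed=run_seed, max_iter=max_iter, tol=tol)
            conn = _connectivity(run.labels)
            co_count[np.ix_(idx, idx)] += conn
            pair_count[np.ix_(idx, idx)] += 1.0
        M = np.divide(co_count, pair_count, out=np.zeros((n, n)), where=pair_count > 0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0

        dist = 1.0 - M
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        Z = linkage(condensed, method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
        coph_dists = cophenet(Z)
        if condensed.std() < _EPS or coph_dists.std() < _EPS:
            rho = 1.0  # perfectly stable 0/1 consensus: all distances tie
        else:
            rho = float(np.corrcoef(condensed, coph_dists)[0, 1])

        upper = M[np.triu_indices(n, k=1)]
        cdf_vals = np.searchsorted(np.sort(upper), grid, side="right") / upper.size
        area = float(np.trapezoid(cdf_vals, grid))

        result.consensus[k] = M
        result.linkage[k] = Z
        result.labels[k] = labels
        result.cophenetic[k] = rho
        result.cdf[k] = (grid, cdf_vals)
        result.area[k] = area
        result.delta_area[k] = area if k == k_range[0] else area - prev_area
        prev_area = area
    return result


def select_k(result: ConsensusResult | pd.DataFrame) -> int:
    """Codified k-selection: the k with maximum cophenetic coefficient.

    Exact ties go to the smaller k. Accepts either a ConsensusResult or a
    diagnostics table with columns (k, cophenetic), so a user can apply the
    rule to externally computed diagnostics or override by inspection.
    """
    if isinstance(result, ConsensusResult):
        table = result.diagnostics()
    else:
        table = result
    if len(table) < 1:
        raise InputError("no diagnostics to select from")
    table = table.sort_values("k")
    best = table.loc[table["cophenetic"].idxmax()]
    # idxmax returns the first maximum in sorted-k order: ties -> smaller k
    return int(best["k"])


def order_groups(
    labels: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 60.0,
) -> tuple[np.ndarray, dict]:
    """Renumber clusters 1..k by prognosis: Group 1 = best 5-year survival.

    Groups are ordered by descending Kaplan-Meier survival at ``horizon``
    months. If any group has no events, the ordering falls back to mean
    follow-up time (descending) with a warning.
    """
    from lifelines import KaplanMeierFitter

    labels = np.asarray(labels)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.unique(labels)
    if any(event[labels == g].sum() == 0 for g in groups):
        warnings.warn("a group has no events; ordering groups by mean follow-up instead of KM")
        key = {g: -time[labels == g].mean() for g in groups}
    else:
        key = {}
        for g in groups:
            kmf = KaplanMeierFitter()
            kmf.fit(time[labels == g], event[labels == g])
            key[g] = -float(kmf.predict(horizon))
    ordered = sorted(groups, key=lambda g: (key[g], g))
    mapping = {old: new + 1 for new, old in enumerate(ordered)}
    return np.asarray([mapping[g] for g in labels]), mapping
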