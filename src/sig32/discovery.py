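"""Pathway ranking, permutation significance, signature extraction, enrichment.

Cancer-type-specific pathway rankings come from the rows of the
tri-factorization score matrix S. Empirical significance attaches a
permutation p value to every (type, pathway) score by refitting the model on
mutation matrices in which each patient's mutation vector has been shuffled
across genes (per-patient burden preserved), followed by Benjamini-Hochberg
adjustment within each cancer type. The gene signature is the union of the
member genes of the top-ranked significant pathways, and a one-sided Fisher
exact test provides pathway over-representation statistics for gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed
from .containers import PathwayDB
from .errors import InputError
from .trifactor import Lambdas, TriFactorModel, fit_trifactor


@dataclass
class PathwayRanking:
    """Per-pathway association scores for one cancer type, best first."""

    cancer_type: str
    table: pd.DataFrame  # columns: pathway, score, rank [, p, q]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def rank_pathways(model: TriFactorModel, cancer_type: str) -> PathwayRanking:
    """Rank pathways for one cancer type by descending association score.

    Ties are broken by pathway index (stable sort), so duplicated pathway
    columns receive ranks in their database order.
    """
    if cancer_type not in model.types:
        raise KeyError(f"unknown cancer type {cancer_type!r}")
    scores = model.S[model.types.index(cancer_type)]
    order = np.argsort(-scores, kind="stable")
    table = pd.DataFrame(
        {
            "pathway": [model.pathway_names[i] for i in order],
            "score": scores[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return PathwayRanking(cancer_type=cancer_type, table=table)


def _permute_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle each patient's mutation vector across genes independently."""
    keys = rng.random(X.shape)
    return np.take_along_axis(X, np.argsort(keys, axis=1), axis=1)


def permutation_fdr(
    X: np.ndarray,
    type_labels: np.ndarray | list[str],
    V0: np.ndarray,
    L: np.ndarray,
    lambdas: Lambdas | tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_perm: int = 1000,
    seed: int = 0,
    max_iter: int = 500,
    perm_max_iter: int | None = None,
    tol: float = 1e-6,
    pathway_names: list[str] | None = None,
) -> tuple[TriFactorModel, pd.DataFrame]:
    """Empirical pathway significance by refitting on permuted mutation data.

    For each of ``n_perm`` permutations every patient's mutation vector is
    shuffled across genes and the tri-factorization refit; the empirical p
    for a (type, pathway) pair uses add-one smoothing,
    p = (1 + #{permuted score >= observed}) / (1 + n_perm). q values are
    Benjamini-Hochberg adjusted within each cancer type.

    Returns the observed model plus a tidy table (cancer_type, pathway,
    score, rank, p, q). ``perm_max_iter`` (default: same as ``max_iter``)
    caps the refit iterations.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    perm_max_iter = max_iter if perm_max_iter is None else perm_max_iter
    model = fit_trifactor(
        X, type_labels, V0, L, lambdas,
        max_iter=max_iter, tol=tol, seed=child_seed(seed, "observed-fit"),
        pathway_names=pathway_names,
    )
    counts = np.zeros_like(model.S)
    perm_rng = np.random.default_rng(child_seed(seed, "permutations"))
    for b in range(n_perm):
        Xp = _permute_rows(np.asarray(X, dtype=float), perm_rng)
        perm_model = fit_trifactor(
            Xp, type_labels, V0, L, lambdas,
            max_iter=perm_max_iter, tol=tol,
            seed=child_seed(seed, f"perm-fit-{b}"), types=model.types,
            pathway_names=model.pathway_names,
        )
        counts += perm_model.S >= model.S
    pvals = (1.0 + counts) / (1.0 + n_perm)

    rows = []
    for t_idx, t in enumerate(model.types):
        q = bh_adjust(pvals[t_idx])
        ranking = rank_pathways(model, t).table
        for j, name in enumerate(model.pathway_names):
            rows.append(
                {
                    "cancer_type": t,
                    "pathway": name,
                    "score": model.S[t_idx, j],
                    "rank": int(ranking.loc[ranking["pathway"] == name, "rank"].iloc[0]),
                    "p": pvals[t_idx, j],
                    "q": q[j],
                }
            )
    return model, pd.DataFrame(rows)


def attach_significance(ranking: PathwayRanking, fdr_table: pd.DataFrame) -> PathwayRanking:
    """Merge permutation p/q values into a ranking table."""
    sub = fdr_table.loc[fdr_table["cancer_type"] == ranking.cancer_type, ["pathway", "p", "q"]]
    table = ranking.table.merge(sub, on="pathway", how="left")
    return PathwayRanking(cancer_type=ranking.cancer_type, table=table)


def select_signature(
    ranking: PathwayRanking,
    pathways: PathwayDB,
    top_n: int = 3,
    fdr_cutoff: float = 0.05,
) -> list[str]:
    """Union of member genes of top-ranked significant pathways.

    A pathway contributes iff its rank is <= ``top_n`` AND its BH q value is
    below ``fdr_cutoff``. Genes are ordered by (best contributing pathway
    rank, gene id) and de-duplicated. Returns an empty list (with a warning)
    if no pathway passes.
    """
    if top_n < 1:
        raise InputError("top_n must be >= 1")
    table = ranking.table
    if "q" not in table.columns:
        raise InputError("ranking has no q values; run permutation_fdr first")
    passing = table[(table["rank"] <= top_n) & (table["q"] < fdr_cutoff)].sort_values("rank")
    if passing.empty:
        warnings.warn("no pathway passed the rank/FDR filter; signature is empty")
        return []
    signature: list[str] = []
    for _, row in passing.iterrows():
        for gene in sorted(pathways.sets[row["pathway"]]):
            if gene not in signature:
                signature.append(gene)
    return signature


def overrepresentation_test(
    gene_list: list[str],
    pathways: PathwayDB,
    universe: list[str],
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test of a gene list against each set.

    The 2x2 table for a set counts in-list/in-set membership over the
    universe; q values are BH-adjusted across sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise InputError("empty gene universe")
    query = set(gene_list)
    if not query <= universe_set:
        raise InputError("gene list contains genes outside the universe")
    rows = []
    for name, members in pathways.sets.items():
        in_set = set(members) & universe_set
        a = len(query & in_set)
        b = len(query) - a
        c = len(in_set) - a
        d = len(universe_set) - a - b - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"pathway": name, "overlap": a, "set_size": len(in_set), "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
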