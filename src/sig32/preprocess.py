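"""Expression preprocessing: log2 + quantile normalization, probe collapsing,
empirical-Bayes batch adjustment, and signature intersection.

Quantile normalization replaces each sample's values by the across-sample
mean of the sorted values at the same rank, so every normalized column has an
identical value multiset; ties receive the mean of the reference values over
their tied ranks. Probes mapping to the same gene are averaged; genes with
any missing value are excluded, never imputed. Cross-cohort harmonization
uses parametric empirical-Bayes location-scale adjustment (the ComBat model,
via scanpy) with each cohort/platform as one batch and no covariates, after
which per-gene grand means are restored exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import CoverageError, InputError


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization of a (features x samples) matrix.

    Idempotent: the output's columns all share one sorted-value multiset
    (the rank-wise mean of the input's sorted columns), so a second
    application reproduces the output exactly.
    """
    values = df.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties: mean of the reference values across the tied ranks
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def log2_quantile_normalize(
    probes: pd.DataFrame,
    already_log: bool = False,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """log2-transform raw intensities then quantile-normalize across samples.

    Raw values must be strictly positive after adding ``pseudocount`` (use
    ``pseudocount=1`` for RNA-seq TPM inputs); ``already_log`` skips the
    transform for data that is on the log2 scale.
    """
    if already_log:
        logged = probes.astype(float)
    else:
        shifted = probes.astype(float) + pseudocount
        bad = shifted <= 0
        if bad.to_numpy().any():
            cells = [
                f"({r}, {c})" for r, c in zip(*np.nonzero(bad.to_numpy()))
            ][:5]
            raise InputError(
                "non-positive values cannot be log2-transformed; first offending "
                f"cells (row, col indices): {', '.join(cells)}"
            )
        logged = np.log2(shifted)
    return quantile_normalize(logged)


def collapse_probes(probes: pd.DataFrame, probe_to_gene: pd.Series | dict) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples by averaging probes.

    Unmapped probes are dropped with a warning. A gene with a missing probe
    value in any sample is excluded entirely (missing values are never
    imputed), so the result is complete.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise InputError("empty probe-to-gene mapping")
    mapped = probes.index.intersection(mapping.index)
    if len(mapped) < len(probes.index):
        dropped = len(probes.index) - len(mapped)
        warnings.warn(f"dropping {dropped} unmapped probes")
    sub = probes.loc[mapped]
    genes = mapping.loc[mapped]
    collapsed = sub.groupby(genes.to_numpy()).mean()
    incomplete = sub.isna().groupby(genes.to_numpy()).any().any(axis=1)
    collapsed = collapsed.loc[~incomplete.loc[collapsed.index]]
    collapsed.index.name = "gene_id"
    return collapsed


def batch_adjust(matrices: list[pd.DataFrame], batches: list[str]) -> pd.DataFrame:
    """Harmonize cohorts with parametric empirical-Bayes location-scale adjustment.

    ``matrices`` are genes x samples tables (one per cohort); ``batches``
    names each cohort's batch. Output covers the shared gene set with the
    batch mean/variance effects removed; per-gene grand means across all
    samples are restored exactly after adjustment. Requires >= 2 samples per
    batch. With a single batch the concatenated matrix is returned unchanged.
    """
    if len(matrices) != len(batches):
        raise InputError("need one batch label per matrix")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    if len(common) == 0:
        raise InputError("no genes shared across cohorts")
    parts, labels = [], []
    for m, b in zip(matrices, batches):
        if m.shape[1] < 2:
            raise InputError(f"batch {b!r} has fewer than 2 samples; variance undefined")
        parts.append(m.loc[common])
        labels.extend([b] * m.shape[1])
    combined = pd.concat(parts, axis=1)
    if combined.columns.duplicated().any():
        raise InputError("duplicate sample ids across cohorts")
    if len(set(labels)) == 1:
        return combined

    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=combined.to_numpy(dtype=float).T,
        obs=pd.DataFrame({"batch": pd.Categorical(labels)}, index=combined.columns),
        var=pd.DataFrame(index=combined.index),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch")
    adjusted = pd.DataFrame(adata.X.T, index=combined.index, columns=combined.columns)
    # restore per-gene grand means (EB shrinkage leaves a small residual shift)
    adjusted = adjusted.add(combined.mean(axis=1) - adjusted.mean(axis=1), axis=0)
    return adjusted


def intersect_signature(
    expression: pd.DataFrame,
    signature: list[str],
    coverage_floor: float = 0.8,
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict an expression matrix to the signature genes, in signature order.

    Returns (matrix, missing genes). Raises ``CoverageError`` when fewer than
    ``coverage_floor`` of the signature genes are present.
    """
    if not signature:
        raise InputError("empty signature")
    present = [g for g in signature if g in expression.index]
    missing = [g for g in signature if g not in expression.index]
    coverage = len(present) / len(signature)
    if coverage < coverage_floor:
        raise CoverageError(
            f"only {len(present)}/{len(signature)} signature genes present "
            f"({coverage:.1%} < floor {coverage_floor:.0%}); missing: {missing}"
        )
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}")
    return expression.loc[present], missing
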