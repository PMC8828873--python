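"""The statistical layer: Kaplan-Meier/log-rank, multivariable Cox,
treatment-adjusted (g-computation) KM curves, bootstrap lasso-Cox inference,
Pearson chi-square contingency tests, and one-way ANOVA.

Conventions fixed here: Cox partial likelihood uses Efron tie handling;
categorical covariates expand against a named reference level (reference
hazard ratio = 1 by construction); chi-square tests are uncorrected Pearson
with rows carrying missing categories excluded before the table is built;
bootstrap p values use add-one smoothing, p = 2 min(frac <= 0, frac >= 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_seed
from .errors import FitError, InputError


@dataclass
class CoxResult:
    summary: pd.DataFrame  # term, hazard_ratio, ci_lower, ci_upper, p
    reference_levels: dict
    model: object  # fitted lifelines CoxPHFitter
    design: pd.DataFrame


# -- Kaplan-Meier + log-rank -----------------------------------------------------


def km_logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[pd.DataFrame, float, float]:
    """Product-limit curves per group and the unweighted log-rank test.

    Returns (tidy curves with columns time/survival/group, chi-square
    statistic with df = #groups - 1, p value).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    groups = pd.unique(pd.Series(group))
    if len(groups) < 2:
        raise InputError("log-rank needs at least two groups")
    if event.sum() == 0:
        raise InputError("log-rank needs at least one event")
    curves = []
    for g in groups:
        m = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m])
        sf = kmf.survival_function_
        curves.append(
            pd.DataFrame(
                {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy(), "group": g}
            )
        )
    res = multivariate_logrank_test(time, group, event)
    return pd.concat(curves, ignore_index=True), float(res.test_statistic), float(res.p_value)


def km_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Kaplan-Meier survival estimate at a fixed horizon."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    return float(kmf.predict(horizon))


# -- Cox proportional hazards ------------------------------------------------------


def _expand_design(covariates: pd.DataFrame, reference: dict | None) -> tuple[pd.DataFrame, dict]:
    """Dummy-code categorical covariates against named reference levels."""
    reference = dict(reference or {})
    parts = []
    refs: dict = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(s.astype(float).rename(col))
            continue
        levels = sorted(pd.unique(s.astype(str)))
        ref = str(reference.get(col, levels[0]))
        if ref not in levels:
            raise InputError(f"reference level {ref!r} not present in covariate {col!r}")
        refs[col] = ref
        for lev in levels:
            if lev == ref:
                continue
            parts.append((s.astype(str) == lev).astype(float).rename(f"{col}[{lev}]"))
    design = pd.concat(parts, axis=1)
    for col in design.columns:
        if design[col].nunique() < 2:
            raise InputError(f"covariate {col!r} is constant")
    return design, refs


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
    reference: dict | None = None,
    alpha: float = 0.05,
) -> CoxResult:
    """Multivariable Cox PH fit (Efron ties) with Wald CIs and p values.

    Categorical covariates are expanded against a reference level (the
    lexically first level unless ``reference`` names one); the reference
    hazard ratio is 1 by construction and is not a row of the summary.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    design, refs = _expand_design(covariates.reset_index(drop=True), reference)
    if event.sum() < design.shape[1]:
        raise InputError("fewer events than covariates")
    df = design.copy()
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise FitError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "term": s.index,
            "hazard_ratio": s["exp(coef)"].to_numpy(),
            "ci_lower": s[f"exp(coef) lower {100 * (1 - alpha):g}%"].to_numpy(),
            "ci_upper": s[f"exp(coef) upper {100 * (1 - alpha):g}%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return CoxResult(summary=summary, reference_levels=refs, model=cph, design=design)


# -- adjusted (g-computation) KM curves ---------------------------------------------


def adjusted_km(
    time: np.ndarray,
    event: np.ndarray,
    treatment: np.ndarray,
    covariates: pd.DataFrame | None = None,
    reference: dict | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted marginal survival curves per treatment level.

    Fits one Cox model with treatment + covariates; then, for each treatment
    level, sets every subject's treatment to that level, predicts the
    individual survival curves, and averages them (g-computation marginal
    curves). Levels with no subjects are skipped with a warning. Returns a
    tidy frame (time, survival, treatment).
    """
    treatment = pd.Series(np.asarray(treatment).astype(str), name="treatment")
    cov = pd.DataFrame({"treatment": treatment})
    if covariates is not None:
        cov = pd.concat([cov, covariates.reset_index(drop=True)], axis=1)
    fit = cox_fit(time, event, cov, reference=reference)
    cph = fit.model

    out = []
    for level in sorted(treatment.unique()):
        if (treatment == level).sum() == 0:  # defensive: unique() implies > 0
            warnings.warn(f"treatment level {level!r} has no subjects; skipped")
            continue
        design = fit.design.copy()
        for col in design.columns:  # overwrite the treatment dummies, keep covariates
            if col.startswith("treatment["):
                design[col] = 1.0 if col == f"treatment[{level}]" else 0.0
        surv = cph.predict_survival_function(design)
        marginal = surv.mean(axis=1)
        out.append(
            pd.DataFrame(
                {"time": marginal.index.to_numpy(), "survival": marginal.to_numpy(), "treatment": level}
            )
        )
    return pd.concat(out, ignore_index=True)


# -- bootstrap lasso-Cox --------------------------------------------------------------


def _partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray) -> float:
    """Breslow partial log-likelihood (model-selection utility)."""
    eta = X @ beta
    order = np.argsort(-time)  # descending: cumulative sums give risk sets
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    # risk set of t_i: all subjects with t >= t_i; with descending sort these
    # are the first positions up to the last index sharing t_i
    pll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        denom = log_cum[j]
        for k in range(i, j + 1):
            if e_o[k]:
                pll += eta_o[k] - denom
        i = j + 1
    return float(pll)


def lasso_cox_bootstrap(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    n_alphas: int = 50,
    cv_folds: int = 5,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap inference for lasso-penalized Cox coefficients.

    Each of ``B`` bootstrap resamples (with replacement) refits a lasso-Cox
    path (``n_alphas`` log-spaced penalties) with the penalty chosen by
    ``cv_folds``-fold cross-validated partial likelihood inside the resample.
    The empirical distribution of each coefficient yields its percentile CI,
    a hazard-ratio point estimate (exp of the bootstrap median) and a
    two-sided empirical p for H0: beta_j = 0 with add-one smoothing.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if B < 1:
        raise InputError("B must be >= 1")
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, p = X.shape

    # one shared penalty grid, estimated on the full data
    base = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas)
    base.fit(X, Surv.from_arrays(event, time))
    grid = np.asarray(base.alphas_)

    def fit_path(Xs, ts, es):
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=grid, fit_baseline_model=False)
        model.fit(Xs, Surv.from_arrays(es, ts))
        coefs = np.asarray(model.coef_)
        if coefs.shape[1] == len(grid):
            return coefs
        # the solver may stop early on a resample: map its alphas onto the grid
        fitted_alphas = np.asarray(model.alphas_)
        cols = [int(np.argmin(np.abs(fitted_alphas - a))) for a in grid]
        return coefs[:, cols]

    rng_master = np.random.default_rng(child_seed(seed, "bootstrap"))
    draws = np.zeros((B, p))
    kept = 0
    attempts = 0
    while kept < B and attempts < 20 * B:
        attempts += 1
        idx = rng_master.integers(0, n, size=n)
        ts, es, Xs = time[idx], event[idx], X[idx]
        if es.sum() < max(3, cv_folds):
            continue
        try:
            fold_rng = np.random.default_rng(child_seed(seed, f"folds-{attempts}"))
            fold_id = fold_rng.permutation(np.arange(n) % cv_folds)
            cv_pll = np.zeros(len(grid))
            for f in range(cv_folds):
                tr, te = fold_id != f, fold_id == f
                if es[tr].sum() == 0 or es[te].sum() == 0:
                    continue
                coefs = fit_path(Xs[tr], ts[tr], es[tr])
                for a in range(len(grid)):
                    cv_pll[a] += _partial_loglik(Xs[te], ts[te], es[te], coefs[:, a])
            best = int(np.argmax(cv_pll))
            coefs_full = fit_path(Xs, ts, es)
            draws[kept] = coefs_full[:, best]
            kept += 1
        except (ArithmeticError, ValueError):
            continue
    if kept < B:
        raise FitError(f"only {kept}/{B} bootstrap resamples fit successfully")

    lo_q, hi_q = 100 * alpha_level / 2, 100 * (1 - alpha_level / 2)
    rows = []
    for j, name in enumerate(names):
        d = draws[:, j]
        frac_le = (1 + (d <= 0).sum()) / (B + 1)
        frac_ge = (1 + (d >= 0).sum()) / (B + 1)
        rows.append(
            {
                "term": name,
                "hazard_ratio": float(np.exp(np.median(d))),
                "ci_lower": float(np.exp(np.percentile(d, lo_q))),
                "ci_upper": float(np.exp(np.percentile(d, hi_q))),
                "p": float(min(1.0, 2 * min(frac_le, frac_ge))),
            }
        )
    return pd.DataFrame(rows)


# -- contingency tables / ANOVA ---------------------------------------------------------


def contingency(
    clinical: pd.DataFrame,
    row: str,
    col: str,
    missing: tuple = ("Missing", "missing", "NA", ""),
) -> pd.DataFrame:
    """r x c count table of two categorical columns, dropping missing rows first."""
    sub = clinical[[row, col]].copy()
    sub = sub.dropna()
    for m in missing:
        sub = sub[(sub[row] != m) & (sub[col] != m)]
    return pd.crosstab(sub[row], sub[col])


def chisq_independence(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of independence on a count table."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InputError("need an r x c table with r, c >= 2")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise InputError("counts must be non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise InputError("zero row or column marginal")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_oneway(values: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Standard one-way ANOVA F test; returns (F, p).

    Degenerate inputs with zero variance everywhere and equal group means
    give (0, 1) by convention.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    samples = [values[group == g] for g in pd.unique(pd.Series(group))]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise InputError("one-way ANOVA needs >= 2 groups with >= 2 observations each")
    if all(s.std() == 0 for s in samples):
        means = [s.mean() for s in samples]
        if np.ptp(means) == 0:
            return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*samples)
    return float(f), float(p)
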