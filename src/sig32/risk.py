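"""SVM risk scores for five-year overall survival.

A linear soft-margin SVM is trained on the two prognostic extremes of the
discovered subtypes — the best-prognosis group carries the "-" label, the
worst-prognosis group the "+" label — over the signature genes. The signed
decision value r = w.x + b is the continuous risk score: larger positive
scores indicate higher confidence of membership in the poor-prognosis class.
Scores relate to survival through a Cox proportional-hazards model with the
raw score as the single linear covariate (per-unit hazard ratios refer to raw
SVM units); the predicted five-year survival curve over a score grid uses a
Breslow baseline with approximate pointwise delta-method confidence bands on
the log cumulative hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, FitError, InputError


@dataclass
class RiskModel:
    w: np.ndarray
    b: float
    C: float
    gene_order: list[str]
    negative_class: object  # best-prognosis group
    positive_class: object  # worst-prognosis group

    def to_json(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": self.b,
            "C": self.C,
            "gene_order": list(self.gene_order),
            "negative_class": str(self.negative_class),
            "positive_class": str(self.positive_class),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "RiskModel":
        return cls(
            w=np.asarray(payload["w"], dtype=float), b=float(payload["b"]),
            C=float(payload["C"]), gene_order=list(payload["gene_order"]),
            negative_class=payload["negative_class"], positive_class=payload["positive_class"],
        )


@dataclass
class OSCurve:
    grid: np.ndarray  # risk-score grid
    os5: np.ndarray  # predicted 5-year (60-month) survival per grid point
    lo: np.ndarray
    hi: np.ndarray
    q25: float  # quartile cut points of the observed scores (type-7 quantiles)
    q75: float
    hazard_ratio: float  # per-unit HR of the score
    hr_ci: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.grid, "os5": self.os5, "lo": self.lo, "hi": self.hi})


def train_risk(
    X: np.ndarray,
    group_labels: np.ndarray | list,
    C: float = 1.0,
    gene_order: list[str] | None = None,
    negative_class=None,
    positive_class=None,
) -> RiskModel:
    """Linear SVM on the two extreme-prognosis groups (samples x genes input).

    By default the smaller group label (better prognosis) is the negative
    class and the larger the positive class, so positive scores point at the
    worst-prognosis group.
    """
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    labels = np.asarray(group_labels)
    present = sorted(pd.unique(pd.Series(labels)).tolist())
    if len(present) != 2:
        raise InputError(f"risk model needs exactly two groups, got {present}")
    neg = present[0] if negative_class is None else negative_class
    pos = present[1] if positive_class is None else positive_class
    if {neg, pos} != set(present) or neg == pos:
        raise InputError("negative/positive classes must be the two supplied groups")
    y = np.where(labels == pos, 1, -1)
    svc = SVC(kernel="linear", C=C, tol=1e-6, max_iter=100_000)
    svc.fit(X, y)
    if gene_order is None:
        gene_order = [f"f{i}" for i in range(X.shape[1])]
    return RiskModel(
        w=svc.coef_.ravel().copy(), b=float(svc.intercept_[0]), C=C,
        gene_order=list(gene_order), negative_class=neg, positive_class=pos,
    )


def score(model: RiskModel, expression: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Risk score r = w.x + b per sample.

    A DataFrame is interpreted as genes x samples and must contain every
    model gene; rows are aligned to the model's gene order. A bare array is
    taken as samples x genes already in model order.
    """
    if isinstance(expression, pd.DataFrame):
        missing = [g for g in model.gene_order if g not in expression.index]
        if missing:
            raise AlignmentError(f"expression matrix lacks model genes: {missing}")
        X = expression.loc[model.gene_order].to_numpy(dtype=float).T
        return pd.Series(X @ model.w + model.b, index=expression.columns, name="risk_score")
    X = np.asarray(expression, dtype=float)
    if X.shape[1] != model.w.size:
        raise AlignmentError("sample matrix width does not match the model gene order")
    return X @ model.w + model.b


def os5_curve(
    scores: np.ndarray | pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 60.0,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> OSCurve:
    """Predicted survival at ``horizon`` months as a function of the risk score.

    Fits Cox PH with the raw score as single covariate, computes the Breslow
    baseline cumulative hazard H0, and predicts S(horizon | r) =
    exp(-H0 exp(beta r)) over a score grid. The pointwise CI applies the
    delta method on log H(horizon | r), combining the Breslow baseline
    variance with (r - mean score)^2 Var(beta); the baseline-beta covariance
    is neglected (exact at the score mean).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from scipy.stats import norm

    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise FitError("no events: cannot fit the score-survival model")
    df = pd.DataFrame({"time": time, "event": event, "score": scores})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise FitError(f"Cox fit on risk scores failed to converge: {exc}") from exc
    beta = float(cph.params_["score"])
    var_beta = float(cph.variance_matrix_.loc["score", "score"])

    # Breslow baseline cumulative hazard at covariate 0 and its variance
    order = np.argsort(time)
    t_sorted, e_sorted, s_sorted = time[order], event[order], scores[order]
    risk = np.exp(beta * s_sorted)
    event_times = np.unique(t_sorted[e_sorted == 1])
    H0 = 0.0
    var_H0 = 0.0
    for et in event_times:
        if et > horizon:
            break
        d = int(((t_sorted == et) & (e_sorted == 1)).sum())
        denom = risk[t_sorted >= et].sum()
        H0 += d / denom
        var_H0 += d / denom**2
    if H0 <= 0:
        raise FitError("no events before the horizon")

    if grid is None:
        grid = np.linspace(scores.min(), scores.max(), 101)
    grid = np.asarray(grid, dtype=float)
    H = H0 * np.exp(beta * grid)
    logH = np.log(H)
    se_logH = np.sqrt(var_H0 / H0**2 + (grid - scores.mean()) ** 2 * var_beta)
    z = norm.ppf(1 - alpha / 2)
    os5 = np.exp(-H)
    lo = np.exp(-np.exp(logH + z * se_logH))
    hi = np.exp(-np.exp(logH - z * se_logH))

    hr = float(np.exp(beta))
    hr_ci = (float(np.exp(beta - z * np.sqrt(var_beta))), float(np.exp(beta + z * np.sqrt(var_beta))))
    q25, q75 = np.quantile(scores, [0.25, 0.75])  # numpy default = type-7 linear interpolation
    return OSCurve(grid=grid, os5=os5, lo=lo, hi=hi, q25=float(q25), q75=float(q75),
                   hazard_ratio=hr, hr_ci=hr_ci)
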