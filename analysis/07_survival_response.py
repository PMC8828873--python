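"""Survival and response statistics over the discovered subtypes.

Kaplan-Meier curves with the log-rank test across groups; multivariable Cox
(age, stage, group, and separately the risk score per unit); chi-square
association of clinical variables and of checkpoint-inhibitor response with
subtype; treatment-adjusted marginal survival curves within one group; and
bootstrap lasso-Cox inference over the same covariates.
"""

from _common import BULK, OUTDIR, get_config

import numpy as np
import pandas as pd

from sig32 import io, survival
from sig32._seeds import child_seed


def main() -> None:
    cfg = get_config()
    clinical = io.read_clinical(BULK / "clinical.csv").set_index("sample_id")
    groups = pd.read_csv(OUTDIR / "groups.csv").set_index("sample_id")["group"]
    clinical = clinical.loc[groups.index]
    scores = pd.read_csv(OUTDIR / "scores.csv").set_index("sample_id")["risk_score"]
    t = clinical["time_months"].to_numpy()
    e = clinical["event"].to_numpy()
    g = groups.to_numpy()

    curves, lr_stat, lr_p = survival.km_logrank(t, e, g)
    curves.to_csv(OUTDIR / "km_curves.csv", index=False)
    print(f"log-rank across groups: chi-square {lr_stat:.1f}, p = {lr_p:.3g}")

    cov = pd.DataFrame({"age_group": clinical["age_group"].to_numpy(),
                        "stage": clinical["stage"].to_numpy(),
                        "group": pd.Series(g).astype(str)})
    cox = survival.cox_fit(t, e, cov,
                           reference={"age_group": "<=60", "stage": "I", "group": "1"})
    cox.summary.to_csv(OUTDIR / "cox_multivariable.csv", index=False)
    print("multivariable Cox (reference: age<=60, stage I, Group 1):")
    print(cox.summary.round(3).to_string(index=False))

    cov_rs = cov.drop(columns="group").assign(risk_score=scores.loc[groups.index].to_numpy())
    cox_rs = survival.cox_fit(t, e, cov_rs, reference={"age_group": "<=60", "stage": "I"})
    cox_rs.summary.to_csv(OUTDIR / "cox_risk_score.csv", index=False)
    rs = cox_rs.summary.set_index("term").loc["risk_score"]
    print(f"risk score per unit increase: HR {rs['hazard_ratio']:.3f} "
          f"({rs['ci_lower']:.3f}, {rs['ci_upper']:.3f}), p = {rs['p']:.3g}")

    age_tab = survival.contingency(clinical.assign(group=g), "age_group", "group")
    stat, df, p = survival.chisq_independence(age_tab)
    print(f"age x group chi-square p = {p:.3g}")

    ici_clin = io.read_clinical(BULK / "ici_clinical.csv").set_index("sample_id")
    ici_groups = pd.read_csv(OUTDIR / "ici_groups.csv").set_index("sample_id")["group"]
    ici_clin = ici_clin.loc[ici_groups.index].assign(group=ici_groups.to_numpy())
    ici_clin["response_binary"] = np.where(ici_clin["response"].isin(["CR", "PR"]),
                                           "responder", "non-responder")
    tab = survival.contingency(ici_clin, "response_binary", "group")
    tab.to_csv(OUTDIR / "ici_response_table.csv")
    stat, df, p_resp = survival.chisq_independence(tab)
    rates = (tab.loc["responder"] / tab.sum(axis=0) * 100).round(1)
    print(f"checkpoint-inhibitor response by subtype: rates {rates.to_dict()} %, "
          f"chi-square p = {p_resp:.3g}")

    worst = int(g.max())
    m = g == worst
    adj = survival.adjusted_km(t[m], e[m], clinical["treatment"].to_numpy()[m],
                               covariates=pd.DataFrame(
                                   {"age_group": clinical["age_group"].to_numpy()[m]}))
    adj.to_csv(OUTDIR / "adjusted_km.csv", index=False)
    print(f"adjusted KM written for treatment levels within Group {worst}")

    design, _ = survival._expand_design(cov, {"age_group": "<=60", "stage": "I", "group": "1"})
    boot = survival.lasso_cox_bootstrap(t, e, design, B=cfg.bootstrap_B,
                                        seed=child_seed(cfg.seed, "bootstrap"))
    boot.to_csv(OUTDIR / "lasso_bootstrap.csv", index=False)
    print(f"bootstrap lasso-Cox (B = {cfg.bootstrap_B}):")
    print(boot.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
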