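"""Train the SVM risk-score model and relate scores to 5-year survival.

The linear SVM is trained on the two prognostic extremes (best-prognosis
group labelled "-", worst labelled "+"); the signed decision value is the
continuous risk score. A Cox model with the raw score as single covariate
gives the predicted 5-year overall-survival curve over the score range with
delta-method confidence bands and score-quartile cut points.
"""

from _common import BULK, OUTDIR, get_config

import numpy as np
import pandas as pd

from sig32 import io, risk


def main() -> None:
    cfg = get_config()
    matrix = io.read_expression(BULK / "expr_signature.tsv")
    clinical = io.read_clinical(BULK / "clinical.csv").set_index("sample_id")
    clinical = clinical.loc[matrix.columns]
    groups = pd.read_csv(OUTDIR / "groups.csv").set_index("sample_id")["group"]
    groups = groups.loc[matrix.columns].to_numpy()

    best, worst = int(groups.min()), int(groups.max())
    mask = (groups == best) | (groups == worst)
    model = risk.train_risk(matrix.to_numpy().T[mask], groups[mask], C=cfg.svm_C,
                            gene_order=list(matrix.index),
                            negative_class=best, positive_class=worst)
    io.write_model_json(model.to_json(), OUTDIR / "risk_model.json")

    scores = risk.score(model, matrix)
    scores.rename_axis("sample_id").reset_index().to_csv(OUTDIR / "scores.csv", index=False)
    curve = risk.os5_curve(scores.to_numpy(), clinical["time_months"].to_numpy(),
                           clinical["event"].to_numpy())
    curve.to_frame().to_csv(OUTDIR / "os5_curve.csv", index=False)

    print(f"risk model trained on Groups {best} (-) vs {worst} (+); "
          f"score range [{scores.min():.2f}, {scores.max():.2f}], "
          f"quartile cuts ({curve.q25:.2f}, {curve.q75:.2f})")
    print(f"per-unit hazard ratio of the score: {curve.hazard_ratio:.3f} "
          f"(95% CI {curve.hr_ci[0]:.3f}-{curve.hr_ci[1]:.3f})")
    mid = int(np.argmin(np.abs(curve.grid - np.median(scores))))
    print(f"predicted 5-year OS at the median score: {curve.os5[mid]:.3f} "
          f"({curve.lo[mid]:.3f}-{curve.hi[mid]:.3f})")


if __name__ == "__main__":
    main()
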