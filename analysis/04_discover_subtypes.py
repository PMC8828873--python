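"""Consensus-NMF subtype discovery on the signature expression.

Runs consensus clustering over NMF restarts for k = 2..7, reports the
cophenetic/CDF-area diagnostics, selects k by the max-cophenetic rule, and
renumbers the clusters by prognosis (Group 1 best 5-year survival). On the
planted design this selects k = 4 and recovers the simulated subtypes.
"""

from _common import BULK, OUTDIR, get_config

import pandas as pd

from sig32 import io
from sig32._seeds import child_seed
from sig32.subtypes import consensus_cluster, order_groups, select_k


def main() -> None:
    cfg = get_config()
    matrix = io.read_expression(BULK / "expr_signature.tsv")
    clinical = io.read_clinical(BULK / "clinical.csv").set_index("sample_id")
    clinical = clinical.loc[matrix.columns]

    res = consensus_cluster(matrix.to_numpy(), range(cfg.k_min, cfg.k_max + 1),
                            n_runs=cfg.n_runs, seed=child_seed(cfg.seed, "subtype"),
                            max_iter=cfg.nmf_max_iter, tol=cfg.tol)
    res.diagnostics().to_csv(OUTDIR / "diagnostics.csv", index=False)
    print(res.diagnostics().round(4).to_string(index=False))

    k = select_k(res)
    groups, _ = order_groups(res.labels[k], clinical["time_months"].to_numpy(),
                             clinical["event"].to_numpy())
    pd.DataFrame({"sample_id": matrix.columns, "group": groups}).to_csv(
        OUTDIR / "groups.csv", index=False)

    truth = pd.read_csv(BULK / "true_subtypes.csv")["true_subtype"]
    from sklearn.metrics import adjusted_rand_score

    print(f"selected k = {k}; group sizes "
          f"{pd.Series(groups).value_counts().sort_index().tolist()}")
    print(f"adjusted Rand index vs planted subtypes: "
          f"{adjusted_rand_score(truth, groups):.3f}")


if __name__ == "__main__":
    main()
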