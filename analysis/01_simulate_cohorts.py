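"""Simulate the synthetic study inputs.

Generates (a) a pan-cancer binary mutation matrix (19 types x 30 patients
each x 400 genes) with three pathways planted in the target type, plus the
matching interaction network and pathway database; (b) a 567-sample
expression cohort over the 32 planted signature genes with four subtypes of
ordered prognosis; (c) a 90-sample cohort standing in for the checkpoint-
inhibitor series. Simulated matrices are bulky and regenerable, so they land
under scratch/synthetic_study; later scripts write their summary tables to
results/synthetic_study.
"""

from _common import BULK, get_config

import pandas as pd

from sig32 import io
from sig32._seeds import child_seed
from sig32.synthetic import planted_signature, simulate_expression_cohort, simulate_pancancer


def main() -> None:
    cfg = get_config()
    design = cfg.make_design()

    pan = simulate_pancancer(design, seed=cfg.seed)
    io.write_mutations(pan.mutations, BULK / "mutations.tsv", BULK / "types.csv")
    io.write_network(pan.network, BULK / "network.tsv")
    io.write_gmt(pan.pathways, BULK / "pathways.gmt")
    print(f"mutation matrix: {pan.mutations.values.shape[0]} patients x "
          f"{pan.mutations.values.shape[1]} genes, "
          f"{len(pan.mutations.types)} cancer types")
    print(f"planted pathways in {pan.planted[0]}: {', '.join(pan.planted[1])}")

    signature = planted_signature(design, seed=cfg.seed)
    cohort = simulate_expression_cohort(design, seed=cfg.seed, signature_genes=signature)
    io.write_expression(cohort.expression, BULK / "expression.tsv")
    io.write_clinical(cohort.clinical, BULK / "clinical.csv")
    pd.DataFrame({"sample_id": cohort.expression.columns,
                  "true_subtype": cohort.true_subtype}).to_csv(
        BULK / "true_subtypes.csv", index=False)
    sizes = pd.Series(cohort.true_subtype).value_counts().sort_index()
    print(f"expression cohort: {cohort.expression.shape[1]} samples x "
          f"{cohort.expression.shape[0]} signature genes; "
          f"group sizes {sizes.tolist()}; "
          f"censoring {1 - cohort.clinical['event'].mean():.1%}")

    ici_design = design.replace(n_cohort=cfg.ici_n, subtype_proportions=cfg.ici_proportions)
    ici = simulate_expression_cohort(ici_design, seed=child_seed(cfg.seed, "ici-cohort"),
                                     signature_genes=signature)
    io.write_expression(ici.expression, BULK / "ici_expression.tsv")
    io.write_clinical(ici.clinical, BULK / "ici_clinical.csv")
    pd.DataFrame({"sample_id": ici.expression.columns,
                  "true_subtype": ici.true_subtype}).to_csv(
        BULK / "ici_true_subtypes.csv", index=False)
    print(f"checkpoint-inhibitor cohort: {ici.expression.shape[1]} samples")


if __name__ == "__main__":
    main()
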