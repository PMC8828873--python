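"""One-command end-to-end pipeline over synthetic data, with a run manifest.

Stages run in order: simulate -> discover -> preprocess -> subtype ->
classify -> risk -> survive -> report. Every stage persists its artifacts
under the configured output directory and records their SHA-256 hashes,
its child seeds and parameters in the manifest, so a run is reproducible
hash-for-hash from (config, seed) and any stage can be re-run in isolation
from its recorded inputs.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, discovery, io, preprocess, risk, subtypes, survival
from ._seeds import child_seed
from .config import AnalysisConfig
from .errors import Sig32Error
from .synthetic import planted_signature, simulate_expression_cohort, simulate_pancancer
from .trifactor import Lambdas


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, seed: int, params: dict,
                  inputs: list[Path], outputs: list[Path], elapsed: float) -> None:
        self.stages.append(
            {
                "name": name,
                "seed": seed,
                "params": params,
                "inputs": {p.name: _sha256(p) for p in inputs},
                "outputs": {p.name: _sha256(p) for p in outputs},
                "elapsed_s": round(elapsed, 3),
                "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def fingerprint(self) -> dict:
        """Deterministic view: everything except wall-clock fields."""
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stages": [
                {k: v for k, v in stage.items() if k not in ("elapsed_s", "timestamp")}
                for stage in self.stages
            ],
        }

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"version": self.version, "seed": self.seed,
                       "config": self.config, "stages": self.stages}, fh, indent=1)


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    """Execute the full synthetic study; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.make_design()
    manifest = RunManifest(version=__version__, seed=config.seed,
                           config=config.model_dump(mode="json"))

    def run_stage(name, fn, inputs, params):
        t0 = _time.perf_counter()
        try:
            outputs = fn()
        except Sig32Error as exc:
            raise Sig32Error(f"stage {name!r} failed: {exc}") from exc
        manifest.add_stage(name, child_seed(config.seed, name), params,
                           [out / i for i in inputs], outputs,
                           _time.perf_counter() - t0)
        return outputs

    # -- simulate ------------------------------------------------------------
    state: dict = {}

    def stage_simulate():
        pan = simulate_pancancer(design, seed=config.seed)
        cohort = simulate_expression_cohort(
            design, seed=config.seed,
            signature_genes=planted_signature(design, seed=config.seed),
        )
        ici_design = design.replace(
            n_cohort=config.ici_n, subtype_proportions=config.ici_proportions
        )
        ici = simulate_expression_cohort(
            ici_design, seed=child_seed(config.seed, "ici-cohort"),
            signature_genes=list(cohort.expression.index),
        )
        state.update(pan=pan, cohort=cohort, ici=ici)
        io.write_mutations(pan.mutations, out / "mutations.tsv", out / "types.csv")
        io.write_network(pan.network, out / "network.tsv")
        io.write_gmt(pan.pathways, out / "pathways.gmt")
        io.write_expression(cohort.expression, out / "expression.tsv")
        io.write_clinical(cohort.clinical, out / "clinical.csv")
        pd.DataFrame({"sample_id": cohort.expression.columns,
                      "true_subtype": cohort.true_subtype}).to_csv(
            out / "true_subtypes.csv", index=False)
        io.write_expression(ici.expression, out / "ici_expression.tsv")
        io.write_clinical(ici.clinical, out / "ici_clinical.csv")
        pd.DataFrame({"sample_id": ici.expression.columns,
                      "true_subtype": ici.true_subtype}).to_csv(
            out / "ici_true_subtypes.csv", index=False)
        return [out / f for f in (
            "mutations.tsv", "types.csv", "network.tsv", "pathways.gmt",
            "expression.tsv", "clinical.csv", "true_subtypes.csv",
            "ici_expression.tsv", "ici_clinical.csv", "ici_true_subtypes.csv")]

    run_stage("simulate", stage_simulate, [], {"design": str(design)})

    # -- discover ------------------------------------------------------------
    def stage_discover():
        pan = state["pan"]
        mm = pan.mutations
        V0 = pan.pathways.membership_matrix(mm.gene_ids)
        L = pan.network.laplacian
        model, fdr = discovery.permutation_fdr(
            mm.values, mm.cancer_type, V0, L, Lambdas(*config.lambdas),
            n_perm=config.n_perm, seed=child_seed(config.seed, "discover"),
            max_iter=config.trifactor_max_iter, perm_max_iter=config.perm_max_iter,
            tol=config.tol, pathway_names=pan.pathways.names,
        )
        target = pan.planted[0]
        ranking = discovery.attach_significance(discovery.rank_pathways(model, target), fdr)
        signature = discovery.select_signature(
            ranking, pan.pathways, top_n=config.top_n, fdr_cutoff=config.fdr_cutoff)
        state.update(ranking=ranking, signature=signature)
        ranking.table.to_csv(out / "ranking.csv", index=False)
        fdr.to_csv(out / "pathway_fdr.csv", index=False)
        (out / "signature.txt").write_text("\n".join(signature) + "\n")
        return [out / f for f in ("ranking.csv", "pathway_fdr.csv", "signature.txt")]

    run_stage("discover", stage_discover,
              ["mutations.tsv", "types.csv", "network.tsv", "pathways.gmt"],
              {"n_perm": config.n_perm, "lambdas": list(config.lambdas),
               "top_n": config.top_n, "fdr_cutoff": config.fdr_cutoff})

    # -- preprocess ----------------------------------------------------------
    def stage_preprocess():
        expr = state["cohort"].expression
        normalized = preprocess.quantile_normalize(expr)  # synthetic data is log-scale already
        matrix, missing = preprocess.intersect_signature(
            normalized, state["signature"], coverage_floor=config.coverage_floor)
        state["expr_signature"] = matrix
        io.write_expression(matrix, out / "expr_signature.tsv")
        (out / "missing_genes.txt").write_text("\n".join(missing) + "\n")
        return [out / "expr_signature.tsv", out / "missing_genes.txt"]

    run_stage("preprocess", stage_preprocess, ["expression.tsv", "signature.txt"],
              {"coverage_floor": config.coverage_floor})

    # -- subtype -------------------------------------------------------------
    def stage_subtype():
        matrix = state["expr_signature"]
        clinical = state["cohort"].clinical
        res = subtypes.consensus_cluster(
            matrix.to_numpy(), k_range=range(config.k_min, config.k_max + 1),
            n_runs=config.n_runs, seed=child_seed(config.seed, "subtype"),
            max_iter=config.nmf_max_iter, tol=config.tol)
        k = subtypes.select_k(res)
        groups, mapping = subtypes.order_groups(
            res.labels[k], clinical["time_months"].to_numpy(), clinical["event"].to_numpy())
        state.update(consensus=res, k=k, groups=groups)
        res.diagnostics().to_csv(out / "diagnostics.csv", index=False)
        pd.DataFrame({"sample_id": matrix.columns, "group": groups}).to_csv(
            out / "groups.csv", index=False)
        outputs = [out / "diagnostics.csv", out / "groups.csv"]
        if config.write_consensus:
            for kk, M in res.consensus.items():
                path = out / f"consensus_k{kk}.tsv"
                pd.DataFrame(M, index=matrix.columns, columns=matrix.columns).to_csv(
                    path, sep="\t")
                outputs.append(path)
        return outputs

    run_stage("subtype", stage_subtype, ["expr_signature.tsv", "clinical.csv"],
              {"k_range": [config.k_min, config.k_max], "n_runs": config.n_runs})

    # -- classify ------------------------------------------------------------
    def stage_classify():
        matrix = state["expr_signature"]
        groups = state["groups"]
        X = matrix.to_numpy().T
        ensemble = classify.train_pairwise(
            X, groups, C=config.svm_C, feature_names=list(matrix.index))
        report = classify.loocv(X, groups, C=config.svm_C)
        ici_expr, _ = preprocess.intersect_signature(
            state["ici"].expression, list(matrix.index), coverage_floor=config.coverage_floor)
        ici_labels, ici_probs = classify.predict_subtype(ensemble, ici_expr.to_numpy().T)
        state.update(ensemble=ensemble, cv_report=report, ici_groups=ici_labels)
        io.write_model_json(ensemble.to_json(), out / "classifier.json")
        pd.DataFrame({"class": list(report.per_class_auc),
                      "auc": list(report.per_class_auc.values())}).to_csv(
            out / "cv_auc.csv", index=False)
        pd.DataFrame({"sample_id": ici_expr.columns, "group": ici_labels}).to_csv(
            out / "ici_groups.csv", index=False)
        return [out / f for f in ("classifier.json", "cv_auc.csv", "ici_groups.csv")]

    run_stage("classify", stage_classify, ["expr_signature.tsv", "groups.csv"],
              {"C": config.svm_C})

    # -- risk ----------------------------------------------------------------
    def stage_risk():
        matrix = state["expr_signature"]
        groups = state["groups"]
        clinical = state["cohort"].clinical
        best, worst = int(groups.min()), int(groups.max())
        mask = (groups == best) | (groups == worst)
        model = risk.train_risk(
            matrix.to_numpy().T[mask], groups[mask], C=config.svm_C,
            gene_order=list(matrix.index), negative_class=best, positive_class=worst)
        scores = risk.score(model, matrix)
        curve = risk.os5_curve(
            scores.to_numpy(), clinical["time_months"].to_numpy(),
            clinical["event"].to_numpy())
        state.update(risk_model=model, scores=scores, curve=curve)
        io.write_model_json(model.to_json(), out / "risk_model.json")
        scores.rename_axis("sample_id").reset_index().to_csv(out / "scores.csv", index=False)
        curve.to_frame().to_csv(out / "os5_curve.csv", index=False)
        return [out / f for f in ("risk_model.json", "scores.csv", "os5_curve.csv")]

    run_stage("risk", stage_risk, ["expr_signature.tsv", "groups.csv", "clinical.csv"],
              {"C": config.svm_C})

    # -- survive -------------------------------------------------------------
    def stage_survive():
        clinical = state["cohort"].clinical
        groups = state["groups"]
        t = clinical["time_months"].to_numpy()
        e = clinical["event"].to_numpy()
        curves, lr_stat, lr_p = survival.km_logrank(t, e, groups)
        curves.to_csv(out / "km_curves.csv", index=False)

        cov = pd.DataFrame({
            "age_group": clinical["age_group"], "stage": clinical["stage"],
            "group": pd.Series(groups).astype(str)})
        cox = survival.cox_fit(t, e, cov, reference={"age_group": "<=60", "stage": "I",
                                                     "group": "1"})
        cox.summary.to_csv(out / "cox_multivariable.csv", index=False)

        # risk score per-unit HR in the same multivariable setting
        cov_rs = cov.copy()
        cov_rs = cov_rs.drop(columns=["group"])
        cov_rs["risk_score"] = state["scores"].to_numpy()
        cox_rs = survival.cox_fit(t, e, cov_rs, reference={"age_group": "<=60", "stage": "I"})
        cox_rs.summary.to_csv(out / "cox_risk_score.csv", index=False)

        age_tab = survival.contingency(
            clinical.assign(group=groups), "age_group", "group")
        chi_rows = [("age_x_group", *survival.chisq_independence(age_tab))]

        ici_clin = state["ici"].clinical.assign(group=state["ici_groups"])
        ici_clin["response_binary"] = np.where(
            ici_clin["response"].isin(["CR", "PR"]), "responder", "non-responder")
        resp_tab = survival.contingency(ici_clin, "response_binary", "group")
        if resp_tab.shape[0] == 2 and resp_tab.shape[1] >= 2:
            chi_rows.append(("response_x_group", *survival.chisq_independence(resp_tab)))
        resp_tab.to_csv(out / "ici_response_table.csv")
        pd.DataFrame(chi_rows, columns=["test", "statistic", "df", "p"]).assign(
            logrank_stat=lr_stat, logrank_p=lr_p).to_csv(out / "chisq.csv", index=False)

        # treatment-adjusted marginal curves within the worst-prognosis group
        worst = int(np.max(groups))
        m = groups == worst
        adj = survival.adjusted_km(
            t[m], e[m], clinical.loc[m, "treatment"].to_numpy(),
            covariates=clinical.loc[m, ["age_group"]].reset_index(drop=True))
        adj.to_csv(out / "adjusted_km.csv", index=False)

        boot_design, _ = survival._expand_design(cov, {"age_group": "<=60", "stage": "I",
                                                       "group": "1"})
        boot = survival.lasso_cox_bootstrap(
            t, e, boot_design, B=config.bootstrap_B,
            seed=child_seed(config.seed, "bootstrap"))
        boot.to_csv(out / "lasso_bootstrap.csv", index=False)
        state.update(logrank_p=lr_p, cox=cox, cox_rs=cox_rs, chi_rows=chi_rows)
        return [out / f for f in (
            "km_curves.csv", "cox_multivariable.csv", "cox_risk_score.csv",
            "ici_response_table.csv", "chisq.csv", "adjusted_km.csv", "lasso_bootstrap.csv")]

    run_stage("survive", stage_survive, ["clinical.csv", "groups.csv", "scores.csv"],
              {"B": config.bootstrap_B})

    # -- report ---------------------------------------------------------------
    def stage_report():
        clinical = state["cohort"].clinical
        report = pd.DataFrame({
            "sample_id": clinical["sample_id"],
            "group": state["groups"],
            "risk_score": state["scores"].to_numpy(),
            "time_months": clinical["time_months"],
            "event": clinical["event"],
            "true_subtype": state["cohort"].true_subtype,
        })
        report.to_csv(out / "report.csv", index=False)
        summary = {
            "selected_k": int(state["k"]),
            "signature_size": len(state["signature"]),
            "mean_loocv_auc": state["cv_report"].mean_auc,
            "logrank_p": state["logrank_p"],
            "risk_score_per_unit_hr": float(
                state["cox_rs"].summary.set_index("term").loc["risk_score", "hazard_ratio"]),
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1)
        return [out / "report.csv", out / "summary.json"]

    run_stage("report", stage_report, ["groups.csv", "scores.csv"], {})

    manifest.write(out / "manifest.json")
    return manifest
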