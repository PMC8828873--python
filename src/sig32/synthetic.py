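"""Synthetic-cohort generator.

Every downstream stage of the pipeline (pathway discovery, subtyping,
classification, risk scoring, survival statistics) is exercised against data
with *known planted structure* generated here, standing in for the protected
study cohorts:

* a pan-cancer binary somatic-mutation matrix (patients x genes, one cancer
  type per patient) in which one target type is enriched for a few planted
  pathways, together with a gene-gene interaction network that is denser
  within pathways and a GMT-style pathway database;
* an expression cohort over the signature genes with ``k_subtypes`` planted
  low-rank subtypes (block centroids separated by ``expression_effect``
  noise-SD units), proportional-hazards exponential survival linked to
  subtype, independent uniform censoring calibrated to a target censor
  fraction, treatment assignment, and binary treatment response with
  subtype-dependent rates.

Identical (design, seed) pairs give bit-identical outputs; all stages derive
child seeds from the single design seed by stage name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._seeds import child_seed
from .containers import GeneNetwork, MutationMatrix, PathwayDB
from .errors import InvalidDesignError

# Default subtype proportions: the exact group fractions of a 567-patient
# cohort split 114/129/162/162 (the rounded percentages would not sum to 1).
_DEFAULT_PROPORTIONS = (114 / 567, 129 / 567, 162 / 567, 162 / 567)

# Response rates per subtype (fraction with radiographic response, CR/PR).
_DEFAULT_RESPONSE = (0.48, 0.08, 0.50, 0.13)


@dataclass
class SimulationDesign:
    """All knobs of the synthetic study, with the defaults used throughout.

    Mutation side: ``n_types`` cancer types with ``n_patients_per_type``
    patients each over ``n_genes`` genes; per-gene mutation probability is
    ``background_mut_rate`` except for genes of the planted pathways in the
    target type, which get ``background_mut_rate + planted_effect``.

    Expression side: ``n_cohort`` tumours over the signature genes with
    ``k_subtypes`` planted groups; group g overexpresses its own block of
    genes by ``expression_effect`` SD units over a non-negative baseline.
    Survival is exponential proportional hazards with per-group log hazard
    ratios ``subtype_log_hazards`` (0 = best-prognosis group) on a baseline
    hazard per month; censoring is independent uniform on [0, T] with T
    solved so the expected censored fraction equals ``censor_rate``.
    """

    # pan-cancer mutation matrix
    n_patients_per_type: int = 30
    n_types: int = 19
    n_genes: int = 400
    background_mut_rate: float = 0.02
    planted_effect: float = 0.30
    n_pathways: int = 20
    pathway_sizes: tuple[int, ...] = (10, 12, 10) + (12,) * 17
    pathway_overlap: float = 0.0
    n_planted: int = 3  # the first n_planted pathways are enriched in the target type
    target_type_index: int = 0
    network_p_within: float = 0.30
    network_p_background: float = 0.01

    # expression cohort
    n_cohort: int = 567
    k_subtypes: int = 4
    subtype_proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    signature_size: int = 32
    expression_effect: float = 4.0  # centroid separation, in units of noise_sd
    noise_sd: float = 1.0

    # survival / treatment / response
    subtype_log_hazards: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    baseline_hazard: float = 0.0037196  # per month; 5-year OS 0.80 in the best group
    censor_rate: float = 0.40
    age_older_probs: tuple[float, ...] = (0.623, 0.589, 0.444, 0.451)
    stage_probs: tuple[float, ...] = (0.037, 0.259, 0.669, 0.035)
    treatment_probs: tuple[float, ...] = (0.20, 0.20, 0.40, 0.20)
    response_probs: tuple[float, ...] = _DEFAULT_RESPONSE

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.pathway_sizes) != self.n_pathways:
            raise InvalidDesignError("pathway_sizes length must equal n_pathways")
        if any(s < 2 for s in self.pathway_sizes):
            raise InvalidDesignError("every pathway needs >= 2 genes")
        if not 0 <= self.pathway_overlap < 1:
            raise InvalidDesignError("pathway_overlap must lie in [0, 1)")
        for name in ("background_mut_rate", "planted_effect", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidDesignError(f"{name} must be a probability, got {v}")
        if self.background_mut_rate + self.planted_effect > 1:
            raise InvalidDesignError("background_mut_rate + planted_effect exceeds 1")
        if len(self.subtype_proportions) != self.k_subtypes:
            raise InvalidDesignError("subtype_proportions length must equal k_subtypes")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise InvalidDesignError("subtype_proportions must sum to 1")
        if len(self.subtype_log_hazards) != self.k_subtypes:
            raise InvalidDesignError("subtype_log_hazards length must equal k_subtypes")
        if len(self.response_probs) != self.k_subtypes:
            raise InvalidDesignError("response_probs length must equal k_subtypes")
        if len(self.age_older_probs) != self.k_subtypes:
            raise InvalidDesignError("age_older_probs length must equal k_subtypes")
        for name in ("response_probs", "age_older_probs", "stage_probs", "treatment_probs"):
            if any(not 0 <= p <= 1 for p in getattr(self, name)):
                raise InvalidDesignError(f"{name} entries must be probabilities")
        if self.n_planted > self.n_pathways:
            raise InvalidDesignError("n_planted exceeds n_pathways")

    def replace(self, **kwargs) -> "SimulationDesign":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PanCancerSim:
    """Pan-cancer mutation data with planted pathway enrichment in one type."""

    mutations: MutationMatrix
    network: GeneNetwork
    pathways: PathwayDB
    planted: tuple[str, list[str]]  # (target cancer type, planted pathway names)


@dataclass
class CohortSim:
    """Expression + clinical cohort with known subtype labels."""

    expression: pd.DataFrame  # signature genes x samples
    clinical: pd.DataFrame
    true_subtype: np.ndarray  # 1..k per sample, same order as expression columns


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def make_pathway_db(
    n_genes: int,
    n_pathways: int,
    pathway_sizes: tuple[int, ...],
    overlap: float = 0.0,
    seed: int = 0,
) -> PathwayDB:
    """Draw named gene sets over a universe of ``n_genes`` genes.

    With ``overlap`` o > 0, each set after the first shares, in expectation,
    a fraction o of its members with the previous set (a Binomial(size, o)
    number of genes is re-drawn from the previous set); the remaining
    members come from genes not yet used by any set.
    """
    if len(pathway_sizes) != n_pathways:
        raise InvalidDesignError("pathway_sizes length must equal n_pathways")
    if any(s < 2 for s in pathway_sizes):
        raise InvalidDesignError("every pathway needs >= 2 genes")
    if overlap == 0.0 and sum(pathway_sizes) > n_genes:
        raise InvalidDesignError(
            f"disjoint pathways need {sum(pathway_sizes)} genes but universe has {n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    unused = list(rng.permutation(genes))
    sets: dict[str, list[str]] = {}
    prev: list[str] = []
    for j, size in enumerate(pathway_sizes):
        name = f"PW{j + 1:02d}"
        shared: list[str] = []
        if overlap > 0 and prev:
            n_shared = min(int(rng.binomial(size, overlap)), len(prev), size)
            if n_shared:
                shared = list(rng.choice(prev, size=n_shared, replace=False))
        n_new = size - len(shared)
        if n_new > len(unused):
            raise InvalidDesignError("pathway sizes exceed the gene universe")
        new = unused[:n_new]
        del unused[:n_new]
        members = sorted(shared + new)
        sets[name] = members
        prev = members
    return PathwayDB(sets=sets)


def planted_signature(design: SimulationDesign, seed: int | None = None) -> list[str]:
    """Union of the planted pathways' genes, ordered by (pathway rank, gene id)."""
    seed = design.seed if seed is None else seed
    db = make_pathway_db(
        design.n_genes,
        design.n_pathways,
        design.pathway_sizes,
        design.pathway_overlap,
        child_seed(seed, "pathways"),
    )
    out: list[str] = []
    for name in db.names[: design.n_planted]:
        for g in sorted(db.sets[name]):
            if g not in out:
                out.append(g)
    return out


def simulate_pancancer(design: SimulationDesign, seed: int | None = None) -> PanCancerSim:
    """Pan-cancer mutation matrix + network + pathway database with planted signal."""
    design.validate()
    seed = design.seed if seed is None else seed
    db = make_pathway_db(
        design.n_genes,
        design.n_pathways,
        design.pathway_sizes,
        design.pathway_overlap,
        child_seed(seed, "pathways"),
    )
    genes = _gene_names(design.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    types = [f"type_{i + 1:02d}" for i in range(design.n_types)]
    target = types[design.target_type_index]
    planted_names = db.names[: design.n_planted]
    planted_genes = sorted({g for name in planted_names for g in db.sets[name]})

    n = design.n_patients_per_type * design.n_types
    rates = np.full((n, design.n_genes), design.background_mut_rate)
    cancer_type = np.repeat(types, design.n_patients_per_type)
    target_rows = cancer_type == target
    planted_cols = [gene_index[g] for g in planted_genes]
    rates[np.ix_(target_rows, planted_cols)] += design.planted_effect

    rng = np.random.default_rng(child_seed(seed, "mutations"))
    X = (rng.random(rates.shape) < rates).astype(int)
    patients = [f"P{i + 1:04d}" for i in range(n)]
    mutations = MutationMatrix(
        values=X, patient_ids=patients, gene_ids=genes, cancer_type=cancer_type
    )

    net_rng = np.random.default_rng(child_seed(seed, "network"))
    A = (net_rng.random((design.n_genes, design.n_genes)) < design.network_p_background)
    A = np.triu(A, k=1).astype(float)
    for members in db.sets.values():
        idx = [gene_index[g] for g in members]
        block = net_rng.random((len(idx), len(idx))) < design.network_p_within
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if block[a, b]:
                    A[min(idx[a], idx[b]), max(idx[a], idx[b])] = 1.0
    A = A + A.T
    network = GeneNetwork(genes=genes, adjacency=A)
    return PanCancerSim(
        mutations=mutations, network=network, pathways=db, planted=(target, planted_names)
    )


def _allocate_groups(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder allocation of n samples to groups (deterministic sizes)."""
    raw = np.asarray(proportions) * n
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for j in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[j] += 1
    return np.repeat(np.arange(1, len(proportions) + 1), sizes)


def _censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Uniform-censoring horizon T with expected censored fraction = censor_rate."""

    def frac_censored(T: float) -> float:
        lam = rates * T
        return float(np.mean((1.0 - np.exp(-lam)) / lam))

    lo, hi = 1e-9, 1e9
    return brentq(lambda T: frac_censored(T) - censor_rate, lo, hi, xtol=1e-9)


def simulate_expression_cohort(
    design: SimulationDesign,
    seed: int | None = None,
    signature_genes: list[str] | None = None,
) -> CohortSim:
    """Expression + clinical cohort with planted subtypes over the signature genes.

    Group sizes follow the design proportions exactly (largest-remainder
    rounding); sample order is a seeded shuffle so groups are interleaved.
    Expression is non-negative by construction: block centroids sit
    ``4 * noise_sd`` above zero and group g's own block is raised a further
    ``expression_effect * noise_sd``; Gaussian noise is clipped at zero.
    """
    design.validate()
    if design.k_subtypes < 2:
        raise InvalidDesignError("need at least two subtypes")
    seed = design.seed if seed is None else seed
    if signature_genes is None:
        genes = [f"SIG{i + 1:02d}" for i in range(design.signature_size)]
    else:
        genes = list(signature_genes)
    n_genes, n, k = len(genes), design.n_cohort, design.k_subtypes

    rng = np.random.default_rng(child_seed(seed, "cohort"))
    subtype = _allocate_groups(n, design.subtype_proportions)
    subtype = subtype[rng.permutation(n)]

    # block centroids over the signature: near-equal contiguous gene blocks
    bounds = np.linspace(0, n_genes, k + 1).astype(int)
    base = 4.0 * design.noise_sd
    lift = design.expression_effect * design.noise_sd
    centroids = np.full((k, n_genes), base)
    for g in range(k):
        centroids[g, bounds[g] : bounds[g + 1]] += lift
    values = centroids[subtype - 1].T  # genes x samples
    values = values + rng.normal(0.0, design.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    expression = pd.DataFrame(values, index=genes, columns=samples)

    surv_rng = np.random.default_rng(child_seed(seed, "survival"))
    rates = design.baseline_hazard * np.exp(np.asarray(design.subtype_log_hazards)[subtype - 1])
    death = surv_rng.exponential(1.0 / rates)
    if design.censor_rate > 0:
        horizon = _censor_horizon(rates, design.censor_rate)
        censor = surv_rng.uniform(0.0, horizon, size=n)
        event = (death <= censor).astype(int)
        time = np.minimum(death, censor)
    else:
        event = np.ones(n, dtype=int)
        time = death

    clin_rng = np.random.default_rng(child_seed(seed, "clinical"))
    older = clin_rng.random(n) < np.asarray(design.age_older_probs)[subtype - 1]
    stage = clin_rng.choice(
        ["I", "II", "III", "IV"], size=n, p=np.asarray(design.stage_probs) / sum(design.stage_probs)
    )
    treatment = clin_rng.choice(
        ["none", "FU", "FU+platinum", "FU+other"],
        size=n,
        p=np.asarray(design.treatment_probs) / sum(design.treatment_probs),
    )
    responder = clin_rng.random(n) < np.asarray(design.response_probs)[subtype - 1]
    recist = np.where(
        responder,
        np.where(clin_rng.random(n) < 0.3, "CR", "PR"),
        np.where(clin_rng.random(n) < 0.4, "SD", "PD"),
    )

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time_months": time,
            "event": event,
            "age_group": np.where(older, ">60", "<=60"),
            "stage": stage,
            "treatment": treatment,
            "response": recist,
        }
    )
    return CohortSim(expression=expression, clinical=clinical, true_subtype=subtype)
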