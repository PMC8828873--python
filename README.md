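# sig32

Gastric adenocarcinoma lacks reliable biomarkers for prognosis and for
predicting benefit from adjuvant chemotherapy or immune checkpoint
inhibition. One published route to such a biomarker chains together five
analyses: rank cancer-type-specific altered pathways from pan-cancer somatic
mutations with a network-regularized non-negative tri-factorization; take the
union of the member genes of the top-ranked significant pathways as a
32-gene expression signature; discover molecular subtypes by consensus-NMF
clustering of the signature expression; classify new tumours into those
subtypes with an all-pairs linear-SVM ensemble; and turn the subtype
structure into a continuous risk score for five-year overall survival, with
a statistical layer (log-rank, Cox, adjusted Kaplan–Meier, bootstrap
lasso-Cox, chi-square) establishing prognostic and predictive value.

`sig32` is a tested reimplementation of that whole chain for computational
oncologists who want to run, audit or extend it. The clinical cohorts behind
the published signature are access-controlled, so the package ships a
first-class synthetic-cohort generator that plants known structure at the
study's scale — 19 cancer types, a 567-sample expression cohort with four
subtypes of ordered prognosis, a 90-sample checkpoint-inhibitor series —
and every stage is validated by recovering what was planted. Statistics that
depend only on published count tables are reproduced exactly.

## The models

**Pathway discovery.** A binary somatic-mutation matrix X (patients × genes)
is factored as X ≈ U S Vᵀ with U fixed to the patient→cancer-type indicator,
S ≥ 0 the cancer-type × pathway association scores, and V ≥ 0 gene–pathway
memberships tethered to a pathway-database prior V₀ and smoothed on a
gene–gene interaction network with Laplacian L = D − A:

```
min_{S,V ≥ 0}  ‖X − U S Vᵀ‖²_F + λ_S‖S‖²_F + λ_L tr(Vᵀ L V) + λ_0‖V − V₀‖²_F
```

solved by alternating multiplicative updates (objective provably
non-increasing). Pathways are ranked per cancer type by the rows of S;
empirical p values come from refitting on permuted mutation data (each
patient's mutation vector shuffled across genes, 1000 permutations by
default) with Benjamini–Hochberg adjustment within type. The signature is
the union of the member genes of the top-3 pathways with q < 0.05.

**Subtyping.** Consensus clustering over seeded NMF restarts (Frobenius
multiplicative updates) for k = 2–7; stability diagnostics are the
cophenetic correlation coefficient, the CDF of consensus-matrix entries and
its incremental (delta) area; k is selected by the max-cophenetic rule and
groups are renumbered by prognosis (Group 1 = best 5-year Kaplan–Meier
survival).

**Classification.** K(K−1)/2 soft-margin linear SVMs (C = 1), one per class
pair; decision values map to pairwise win probabilities through a logistic
link with slope 1/median|training decision value|, and class-membership
probabilities aggregate pairwise wins with uniform weights. Evaluated by
leave-one-out cross-validation with one-vs-rest AUC.

**Risk score.** A linear SVM trained on the best-prognosis ("−") vs
worst-prognosis ("+") groups; the signed decision value r = w·x + b is the
risk score. Cox proportional hazards with the raw score as single covariate
plus a Breslow baseline yields predicted 5-year overall survival over the
score range with delta-method confidence bands and score-quartile regions.

## Worked example

The numbered scripts under `analysis/` run the synthetic study end to end,
printing what each stage found and writing tables to
`results/synthetic_study/` (bulky simulated matrices go to `scratch/`):

```
python analysis/01_simulate_cohorts.py    --seed 1
python analysis/02_discover_pathways.py   --seed 1
python analysis/03_preprocess_expression.py --seed 1
python analysis/04_discover_subtypes.py   --seed 1
python analysis/05_classify_subtypes.py   --seed 1
python analysis/06_risk_scores.py         --seed 1
python analysis/07_survival_response.py   --seed 1
```

Selected output at seed 1:

```
top 5 pathways for type_01 (n_perm=200):
pathway    score  rank        p        q
   PW03 0.424725     1 0.004975 0.033167
   PW02 0.408179     2 0.004975 0.033167
   PW01 0.385171     3 0.004975 0.033167
   PW16 0.032394     4 0.965174 1.000000
signature: 32 genes from the top-3 pathways at FDR < 0.05
...
selected k = 4; group sizes [114, 129, 162, 162]
adjusted Rand index vs planted subtypes: 1.000
6 pairwise models; mean LOOCV one-vs-rest AUC = 1.000
per-unit hazard ratio of the score: 1.905 (95% CI 1.656-2.191)
log-rank across groups: chi-square 99.3, p = 2.25e-21
checkpoint-inhibitor response by subtype: rates {1: 52.4, 2: 8.3, 3: 57.1, 4: 25.8} %
```

The three planted pathways rank 1–3 with the smallest attainable empirical p
(1/201) and pass FDR; their 32-gene union is recovered; the k-selection rule
returns the planted k = 4 with perfectly recovered labels; the risk score
separates prognosis (per-unit HR ≈ 1.9); and the planted subtype-dependent
response rates (48/8/50/13%) reappear in the classified external cohort.

The same chain is available as a one-command pipeline with a reproducibility
manifest (`sig32 run --seed 1 --outdir DIR`), and each stage as a CLI
subcommand (`sig32 simulate|discover|preprocess|subtype|classify|risk|survive`).

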