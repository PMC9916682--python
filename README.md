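# shine-ecgem

Plasma-metabolomics phenotyping of trauma patients and contextualization of an
endothelial-cell genome-scale metabolic model (GEM).

Severe trauma triggers shock-induced endotheliopathy (SHINE): circulating
catecholamines damage the endothelium, and the metabolic state of the
~10¹² endothelial cells in contact with blood leaves a readable signature in
plasma. This package implements the full analysis chain that turns a panel of
quantified plasma metabolite concentrations into inferred intracellular
endothelial metabolism:

1. **Preprocessing** — exclude metabolites undetectable in >30% of samples,
   impute the rest with iterative random forests, log2 + Pareto scale, drop
   perfectly correlated metabolites, remove multivariate outliers outside the
   95% Hotelling-T² ellipse on the leading principal-component planes.
2. **Phenotyping** — complete-linkage hierarchical clustering into metabolic
   phenotypes A–D (D = succinate-high, the high-mortality group) and PLS-DA
   variable-importance (VIP) ranking of discriminant metabolites.
3. **Contextualization** — flux-sample the baseline GEM; constrain each
   measured exchange reaction to FC·(Q1, Q3), its sampled interquartile
   interval scaled by the phenotype/healthy mean fold change; relax minimally
   to feasibility when needed.
4. **Validation** — leave-one-out cross-validation over constrained
   exchanges: re-sample with one constraint reset to baseline, compare the
   predicted flux population against the constraint (Welch t-test,
   Benjamini–Hochberg FDR) and summarize accuracy as R² of predicted means
   versus held-out interval midpoints.
5. **Task analysis** — score metabolic tasks (ATP from glycolysis,
   malonyl-CoA synthesis, TCA NADH, thioredoxin reduction, …) on each
   phenotype model by FBA, normalize rows into [−1.5, 1.5], cluster task
   activities, and compute between-phenotype activity ratios.
6. **Clinical report** — endotheliopathy-of-trauma classification
   (syndecan-1 ≥ 40 ng/mL), D-versus-rest Kruskal-Wallis/chi-square tests,
   Kaplan-Meier survival, and median[IQR]/n(%) summary tables.

Everything runs on shipped synthetic inputs: a ~40-reaction toy
endothelial-like network, a 12-task catalog, and a seeded cohort generator
(99 patients in three injury-severity strata + 20 healthy controls,
62 metabolites, four planted phenotypes, planted missingness, a perfectly
correlated metabolite pair, planted outliers, and survival calibrated to the
published per-phenotype mortality). The core model objects are
`MetabolicNetwork` (stoichiometry + bounds; FBA and hit-and-run flux sampling
act on it) and `ContextualizedModel` (scaled bounds + relaxation log). See
`docs/methods.md` for the science and all conventions.

## Worked example

```python
import shine_ecgem as se
from shine_ecgem.contextualize import FoldChangeVector
from shine_ecgem.synthetic import derive_two_phenotype_design

toy = se.build_toy_ecgem()
baseline = se.sample_fluxes(toy, 500, seed=42)          # hit-and-run
designs = derive_two_phenotype_design(toy, baseline)    # A-like vs D-like plasma

models = {}
for name, fc in designs.items():
    mapping = {m: r for m, r in se.METABOLITE_EXCHANGE_MAP.items() if m in fc}
    models[name] = se.contextualize(toy, baseline, FoldChangeVector(fc, mapping))
    report = se.loo_crossvalidate(models[name], n_samples=300, seed=5)
    print(name, "validation R2 =", round(report.r_squared, 3))

tam = se.task_activity_matrix({k: m.network for k, m in models.items()},
                              se.build_toy_task_catalog(),
                              bases={k: m.base_network for k, m in models.items()})
for task in ("atp_glycolysis", "malonylcoa_synthesis", "tca_nadh"):
    r = se.task_ratio(tam.raw, task, "A_like", "D_like")
    print(task, "A/D =", round(r.value, 2))
```

prints

```
A_like validation R2 = 0.978
D_like validation R2 = 0.983
atp_glycolysis A/D = 1.46
malonylcoa_synthesis A/D = 0.84
tca_nadh A/D = 0.84
```

Reading: both contextualized models predict their held-out exchange fluxes
accurately (R² ≳ 0.97); the glycolysis-dominated A-like model generates
~1.5× more ATP from glycolysis than the catabolic D-like model, while
malonyl-CoA synthesis and TCA NADH production — fed by fatty-acid/amino-acid
carbon — run higher in the D-like model (ratios < 1).

The full pipeline, from cohort simulation to Kaplan-Meier curves, is one
call (or `shine-ecgem run --seed 7 --outdir run7` from the shell):

```python
from shine_ecgem.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(seed=7, outdir="run7"))
print(manifest["stages"]["phenotyping"]["sizes"])
# {'A': 32, 'C': 24, 'D': 21, 'B': 17}
print({p: round(s, 3) for p, s in
       manifest["stages"]["clinical_report"]["survival_30d"].items()})
# {'C': 0.667, 'B': 0.647, 'A': 0.75, 'D': 0.238}
```

Phenotype D — succinate-high, most injured, highest catecholamine and
syndecan-1 levels — retains ~24% 30-day survival, versus 65–75% elsewhere.

## Layout

```
src/shine_ecgem/
  network.py        stoichiometric model, JSON/SBML I/O, FBA, feasibility
  sampling.py       seeded hit-and-run flux sampling
  synthetic.py      toy network, task catalog, cohort generator
  preprocess.py     missingness filter, RF imputation, log2+Pareto, outliers
  phenotyping.py    hierarchical clustering, letters, PLS-DA VIP, heatmap
  contextualize.py  quartile bounds × fold changes, minimal relaxation
  validate.py       leave-one-out exchange cross-validation, BH adjustment
  tasks.py          task evaluation, normalization, clustering, ratios
  clinical.py       EoT rule, group tests, Kaplan-Meier, summary tables
  reference.py      published cohort counts and covariate medians (inputs)
  pipeline.py       end-to-end orchestration with a run manifest
  cli.py            `shine-ecgem` command-line interface
```
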