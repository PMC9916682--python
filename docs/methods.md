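# Methods

This note documents the models, conventions, numerical choices and known
limitations of `shine-ecgem`. The package implements an analysis chain for
trauma plasma metabolomics: phenotype discovery from quantified plasma
metabolite concentrations, contextualization of an endothelial-cell
genome-scale metabolic model (GEM) per phenotype, leave-one-out validation of
the contextualized models, metabolic-task activity scoring, and clinical
statistics of the phenotypes.

## Constraint-based model and conventions

A metabolic network is a stoichiometric matrix `S` with per-reaction flux
bounds `lb ≤ v ≤ ub` (mmol·gDW⁻¹·h⁻¹). Steady state (`S·v = 0`) is assumed
throughout. Exchange reactions move a single boundary-compartment metabolite
across the system boundary; **uptake is negative flux, secretion positive**
(the standard constraint-based convention, fixed at load time). Flux balance
analysis (FBA) solves `max/min v_obj` subject to those constraints with
SciPy's bundled HiGHS solver; infeasible or unbounded programs are reported
through an explicit status, never silently. FBA vertices are generally
degenerate: downstream code uses only objective values or sampled
distributions, never a unique-flux assumption.

Feasibility diagnosis solves a slack LP (minimize total L1 bound widening over
a designated relaxable set) whose positive slacks form a minimal-repair
certificate. The feasibility tolerance is `tol_feas = 1e-6` everywhere.

## Flux sampling

Steady-state fluxes satisfy `v = N·x` for a null-space basis `N` of `S`, so
the feasible set is the polytope `{x : lb ≤ N·x ≤ ub}`. Samples are drawn by
hit-and-run: from an interior starting point (found by a Chebyshev-style LP
that maximizes uniform clearance from the non-degenerate bounds), a random
Gaussian direction is drawn, the admissible segment inside the polytope is
computed exactly, and the next point is uniform on that segment. Defaults:
warm-up of `100 × n_reactions` steps and thinning of 10, both configurable.
The generator is `numpy.random.default_rng(seed)`; identical seeds give
bit-identical sample matrices. Degenerate (zero-width) directions are handled
by treating near-fixed bounds as equalities; a fully degenerate polytope
yields the single feasible point.

Hit-and-run mixes geometrically but the warm-up/thinning defaults are
pragmatic, not certified; sampled marginals are mildly non-uniform near sharp
vertices. The sample mean of a 1-D polytope `[2, 6]` recovers the interval
midpoint within Monte-Carlo error, which is the calibration the tests pin.

## Preprocessing of quantified concentrations

Pipeline order is fixed (one pass, no refit loop):

1. **Missingness filter** — metabolites undetected in strictly more than 30%
   of samples are excluded.
2. **Imputation** — iterative random-forest regression (missForest-style):
   missing cells start at column medians; columns are revisited in ascending
   missingness order, each regressed on all others, until convergence or 10
   rounds (scikit-learn `IterativeImputer` with a seeded
   `RandomForestRegressor`). Observed cells are never modified.
3. **Normalization** — per cell `log2`, then Pareto scaling per metabolite:
   `(x − mean)/√sd` with mean and sample SD (ddof 1) of the log2 values.
   Constant columns map to zero with a warning. After Pareto scaling a
   column's variance equals its pre-scaling SD.
4. **Perfect-correlate removal** — for each pair with `|r| ≥ 0.999` the later
   column is dropped (the threshold operationalizes "correlated 1:1"; the
   synthetic fumarate/malate analog pair is the motivating case).
5. **Outlier removal** — PCA on the normalized matrix; a sample is flagged
   when its Hotelling T² on the (PC1, PC2) or (PC1, PC3) score plane exceeds
   the classical F-based 95% ellipse,
   `T²crit = p(n−1)(n+1)/(n(n−p)) · F(0.95; p, n−p)` with `p = 2`. Outlier
   detection runs on the log2+Pareto matrix (whether the original analysis
   used Pareto-scaled or autoscaled data is not stated; this is the declared
   choice). With two overlapping planes the family-wise false-positive rate
   on clean Gaussian data is ≈ 5–9%, which the tests check by Monte Carlo.

Fold changes must be ratios of means on the measurement scale, so the
pipeline retains the raw-scale imputed matrix (outliers removed, correlates
kept) alongside the normalized matrix.

## Phenotype discovery

Agglomerative clustering with Euclidean distance and complete linkage on the
normalized patient matrix, cut to exactly `k` clusters (`k = 4` by default;
configurable). SciPy's linkage is deterministic given input order, merging the
lowest-index pair on ties.

Cluster letters encode biology, not size: clusters are ranked by their mean of
a marker metabolite (succinate by default) and lettered A (lowest) through D
(highest). This fixes D = succinate-high — the high-mortality phenotype — and
gives a reproducible, declared rule for the remaining letters.

Discriminant metabolites are ranked by VIP scores from a PLS-DA fit
(scikit-learn PLS regression on one-hot class labels, 2 components by
default):

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )

where `SSY_a = (t_aᵀt_a)(q_aᵀq_a)` is the Y-variance captured by component
`a`. Mean squared VIP equals 1 by construction.

## GEM contextualization

Per phenotype, one contextualized model is built from three ingredients:

1. **Baseline quartiles** — the unconstrained network is flux-sampled once;
   each exchange reaction receives the interquartile interval (Q1, Q3) of its
   sampled flux distribution. Quantiles use linear interpolation (NumPy
   default / R type 7), the single convention used repo-wide for quartiles,
   medians and IQRs.
2. **Fold changes** — `FC = mean(phenotype)/mean(healthy)` per metabolite on
   raw (unnormalized, imputed) concentrations; the phenotype mean is taken
   over that cluster's patients. A non-positive healthy mean is an error, not
   an epsilon. Metabolites without an exchange mapping are reported as
   unmapped, never silently dropped.
3. **Bound scaling** — each mapped exchange's interval becomes
   `(min, max)(FC·Q1, FC·Q3)`, preserving ordering under any sign pattern;
   unmapped exchanges keep their baseline quartile interval. The constrained
   set is the boundary exchange reactions of measured plasma metabolites
   ("transport" and "exchange" are used interchangeably for these boundary
   reactions). Both quartiles are multiplied by FC — the literal reading —
   rather than rescaling the interval around a center.

If the constrained model is infeasible, an L1-minimal slack LP widens only
the constrained exchange bounds (internal reactions are never relaxed, which
keeps the base network's biology intact) and logs every widened reaction.
Each widened bound is padded by `1e-3` beyond the minimal slack: exactly
minimal relaxation leaves a zero-volume polytope face on which the sampler
cannot start. Healthy-control variance is not used beyond the means; it plays
no stated computational role in the parameterization.

## Leave-one-out cross-validation

For each constrained exchange `r`: rebuild the contextualized model with
`r`'s bounds reset to the base network's bounds, re-sample the polytope, and
record `r`'s flux population. That population is compared with `r`'s
population in the fully constrained model by Welch's two-sample t-test (no
variance-equality guarantee between sampled populations); p-values are
Benjamini–Hochberg adjusted across exchanges. Global accuracy is the R² of
predicted means (LOO sample means) against the midpoints of the held-out
constraint intervals. Exchanges whose value is stoichiometrically forced by
the remaining constraints are predicted exactly (R² = 1 within tolerance).
Whether a small q-value should be read as "agreement" or "difference" is
ambiguous in this design; the report therefore carries both the q-values and
the R², and the R² is the accuracy headline. An infeasible leave-one-out
model is recorded as a failed prediction, not raised. The per-reaction flux
is the quantity entering the t-test — the only reading that yields one
p-value per exchange.

## Metabolic tasks

A task is (sources, products, objective reaction, optional whitelist). Task
evaluation builds a working copy of the model: every exchange loses its
uptake (lower bound → 0) except the task's sources, which keep the model's
(contextualized) bounds; secretion stays open at the base network's capacity
so forced by-products can always leave; whitelisted inorganic exchanges
(O2, CO2, water by default; anaerobic tasks exclude O2) keep their base
bounds; each product gains a demand sink. The task activity is the FBA
optimum of the objective — 0 with a "blocked" flag when feasible but
unproductive, an explicit status when infeasible. Activity never exceeds the
open-model optimum of the same objective, and tightening a source bound
weakly decreases every task that uses it.

The tasks × models activity matrix is row-normalized by a linear min-max map
onto [−1.5, 1.5] (attained at the row extrema; constant rows map to zero with
a flag). The plausible alternative — z-scores clipped at ±1.5 — is rejected
because attained bounds are the natural reading of a fixed display range; the
linear map is also idempotent. Task rows are clustered with complete-linkage
Euclidean clustering; a zero denominator in a between-model activity ratio is
reported as a flagged infinity, not an exception.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline needs, deterministically from
a seed.

**Toy endothelial network** (32 metabolites, 40 reactions): glucose uptake,
lumped glycolysis (2 ATP + 2 pyruvate per glucose), lactate fermentation,
methylglyoxal and pentose-phosphate (ribose-5-phosphate + NADPH) side
branches, pyruvate dehydrogenase, lumped TCA (NADH + GTP-level ATP),
succinate oxidation, oxidative phosphorylation (2.5 ATP/NADH), fatty-acid
β-oxidation (8 acetyl-CoA + 14 reducing equivalents per palmitate-like unit,
2 ATP activation cost), malonyl-CoA (acetyl-CoA carboxylase) and
palmitoleate synthesis, acetoacetate formation, pooled amino-acid catabolism,
and an NADPH-consuming thioredoxin cycle. Internal capacities sit above any
attainable exchange flux so task activities are uptake-limited; substrate
exchange bounds leave headroom above the sampled flux quartiles so that
scaled intervals remain inside the base bounds. Carbon/redox stoichiometry is
deliberately lumped, not elementally balanced.

**Task catalog**: 12 tasks spanning three archetypes — glycolytic (ATP from
glycolysis, ATP from glucose, methylglyoxal, lactate, ribose-5-phosphate,
acetoacetate), catabolic (palmitoleate, malonyl-CoA, TCA NADH, amino-acid
catabolism, β-oxidation) and redox (thioredoxin reductase). The anaerobic
glycolytic ATP yield of the toy network is exactly 2 per glucose.

**Cohort**: 99 patients in three injury-severity strata (20/40/39 with
ISS < 16, 16–25, > 25) plus 20 healthy controls, 62 plasma metabolites.
Concentrations are log-normal with shared σ_log = 0.4 (natural log) around
deterministic per-metabolite baselines; units are arbitrary and only fold
structure is meaningful. Four phenotypes are planted with exact sizes
33/17/24/21 (A–D) and per-phenotype mean log2 shifts on ~20 discriminant
metabolites (glycolytic markers high in A and D, lipid markers in B,
long-chain fatty acids in C). The succinate analog carries a monotone
A < B < C < D gradient with the phenotype-D shift fixed at +1 log2 versus
healthy (fold change 2 in expectation); its spread makes it the designed top
discriminator, as in the cohort being emulated. Effect sizes were chosen so
the planted structure is strong but not trivial — complete-linkage recovery
sits at ARI ≳ 0.93, not 1.0 for every seed. Fumarate is generated as exactly
0.8 × malate (the perfectly correlated pair). Eight designated metabolites
are masked missing at rate 0.45 (comfortably beyond the 30% exclusion rule
for any seed), all others at 1%. Four outlier patients are displaced by
6 score-SDs along each of the two leading principal axes of the patient
log-concentration matrix — detectable on the PC1–2 ellipse by construction.

Clinical covariates are drawn from phenotype-conditional distributions whose
location parameters are the published per-phenotype medians (ISS, GCS, blood
pressure, heart rate, base excess, lactate, glucose, catecholamines,
syndecan-1, soluble thrombomodulin, transfusion products); ISS values honor
the exact stratum counts and are paired to phenotypes by a severity-weighted
matching so phenotype D is the most injured. The endotheliopathy flag is
computed from simulated syndecan-1 with the ≥ 40 ng/mL rule, making flag and
biomarker consistent by construction. Survival uses a constant per-phenotype
daily hazard calibrated so expected 30-day mortality matches the published
percentages (76.2% for D); deaths are geometric, censoring at day 30. A
time-varying hazard would be more realistic but is not described by the
emulated study.

**Two-phenotype contrast design.** For the directional experiments, stylized
fold-change targets (glucose/lactate/acetoacetate elevated in the A-like
profile; fatty acid, amino acids and succinate elevated with glucose reduced
in the D-like profile) are projected onto fold changes consistent with a
steady-state flux of the toy network: a weighted-L1 LP finds the flux vector
closest to the target exchange fluxes with unmapped exchanges held in their
baseline interquartile box and each scaled interval required to stay inside
the base bounds. Plasma fold changes of a real phenotype obey mass balance;
an incoherent FC table would validate poorly for reasons that have nothing to
do with the method. Ten plasma metabolites map to toy exchanges (glucose,
lactate, palmitate, alanine, succinate, acetoacetate, palmitoleate,
methylglyoxal, ribose, bicarbonate).

**What passing tests do not show.** The generator is multivariate log-normal
with MCAR missingness and a point-mass correlation structure; real plasma
metabolomics has correlated biochemical modules, intensity-dependent
missingness, batch and drift effects, and heavier tails. Recovery results on
the emulation therefore demonstrate the pipeline's correctness, not its field
performance. The headline magnitudes of the emulated study (13-fold
glycolytic ATP contrast, 8.5-fold malonyl-CoA decrease, validation R² up to
0.999) depend on the full 3006-reaction endothelial GEM and unreleased
patient-level data; on the toy design this package reproduces directions, not
magnitudes. For malonyl-CoA synthesis specifically, the toy catalog sources
the task from fatty-acid/amino-acid carbon, so the catabolic (D-like) model
scores *higher* — the published patient-data direction is the opposite and is
not desk-reproducible.

## Clinical statistics

Group contrasts compare phenotype D against the other phenotypes pooled:
Kruskal-Wallis for numeric variables, Pearson chi-square for categorical
(no Yates continuity correction by default, as is standard for contingency
tables beyond 2×2; the policy is a flag echoed in each result). Survival uses
the Kaplan-Meier product-limit estimator (lifelines), right-censored at 30
days. Summary tables show median [Q1, Q3] for numeric variables and n (%) for
categorical ones, under the repo-wide quantile convention. Published count
tables are kept in `shine_ecgem.reference` and re-derived rates (e.g. the
92% share of ≤72-h deaths in phenotype D, from 12 of 13) are computed, never
hard-coded as results.

## Problem sizes and determinism

Default problem sizes — 500 baseline flux samples, 300 samples per
leave-one-out model, 2000 simulated patients for survival recovery — were
chosen so each stage's Monte-Carlo error is far below the effect being
measured while a full run stays interactive. Every stochastic component
(cohort generation, imputation, sampling, validation) takes an explicit seed,
and the pipeline manifest records all parameters and seeds of a run.

## Known limitations

* The hit-and-run sampler is exact in its constraints but its uniformity is
  asymptotic; quartiles of short runs carry sampler noise into the
  contextualized bounds.
* Relaxation minimizes total L1 slack, which concentrates widening on few
  reactions; an L∞ or weighted variant would spread it differently. Only
  constrained exchanges are ever relaxed.
* The FC-times-both-quartiles rule can force uptake or secretion (interval
  excluding zero); that is faithful to the construction but means a
  contextualized model is not a relaxation of the baseline model.
* The planted cohort effect sizes (up to ~6-fold versus healthy) are what
  make four clusters recoverable at n = 95, but they exceed the toy network's
  dynamic range: in the full-pipeline per-phenotype models several
  glucose-fed tasks saturate at pathway capacity and their heatmap rows are
  flagged constant. Directional task conclusions therefore come from the
  two-phenotype contrast design, whose fold changes are kept inside the toy's
  feasible range by construction.
* PLS-DA VIP ranks depend on the component count (default 2); ranks beyond
  the top few are not stable across seeds.
* The D-vs-rest clinical contrast follows the published table's footnote; no
  omnibus 4-group tests or multiple-testing control across clinical variables
  are performed.
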