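"""Synthetic inputs: toy endothelial-like network, task catalog, patient cohort.

Everything the pipeline consumes can be generated here, deterministically from
a seed:

* :func:`build_toy_ecgem` — a ~40-reaction endothelial-cell-like network with
  glycolysis, its methylglyoxal and pentose-phosphate side branches, lactate
  fermentation, TCA + oxidative phosphorylation, fatty-acid β-oxidation,
  palmitoleate/malonyl-CoA synthesis, acetoacetate formation, amino-acid
  catabolism and an NADPH-consuming thioredoxin cycle.
* :func:`build_toy_task_catalog` — metabolic tasks probing those pathways.
* :func:`simulate_cohort` — a trauma cohort (99 patients in three injury
  strata + 20 healthy controls, 62 plasma metabolites) with four planted
  phenotypes, phenotype-specific clinical covariates and survival calibrated
  to the published group statistics, planted high-missingness metabolites,
  one perfectly correlated metabolite pair, and planted multivariate outliers.

Concentration units are arbitrary; only fold structure across groups carries
meaning. Log-scale shifts between phenotypes and healthy controls are
expressed in log2 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .network import MetabolicNetwork, Metabolite, Reaction
from .tasks import MetabolicTask

LN2 = math.log(2.0)

# --------------------------------------------------------------------------
# toy endothelial-like metabolic network
# --------------------------------------------------------------------------

#: structural counts of the toy network, fixed by the builder
TOY_MANIFEST = {"metabolites": 32, "reactions": 40, "exchanges": 12}

#: ATP per glucose through anaerobic glycolysis in the toy network
TOY_GLYCOLYTIC_ATP_YIELD = 2.0

#: plasma metabolite (cohort panel name) -> toy exchange reaction
METABOLITE_EXCHANGE_MAP = {
    "glucose": "EX_glc",
    "lactate": "EX_lac",
    "palmitate": "EX_fa",
    "alanine": "EX_aa",
    "succinate": "EX_succ",
    "acetoacetate": "EX_acac",
    "palmitoleate": "EX_pmtl",
    "methylglyoxal": "EX_mglx",
    "ribose": "EX_r5p",
    "bicarbonate": "EX_co2",
}


def build_toy_ecgem() -> MetabolicNetwork:
    """Deterministic toy endothelial-cell network (32 metabolites, 40 reactions)."""
    e = [("glc_e", "glucose"), ("lac_e", "lactate"), ("fa_e", "fatty acid"),
         ("aa_e", "amino acid pool"), ("succ_e", "succinate"), ("o2_e", "oxygen"),
         ("co2_e", "carbon dioxide"), ("h2o_e", "water"),
         ("mglx_e", "methylglyoxal"), ("acac_e", "acetoacetate"),
         ("pmtl_e", "palmitoleate"), ("r5p_e", "ribose-5-phosphate")]
    c = [("glc_c", "glucose"), ("pyr_c", "pyruvate"), ("lac_c", "lactate"),
         ("r5p_c", "ribose-5-phosphate"), ("mglx_c", "methylglyoxal"),
         ("accoa_c", "acetyl-CoA"), ("acac_c", "acetoacetate"),
         ("fa_c", "fatty acid"), ("pmtl_c", "palmitoleate"),
         ("malcoa_c", "malonyl-CoA"), ("aa_c", "amino acid pool"),
         ("succ_c", "succinate"), ("atp_c", "ATP"), ("nadh_c", "NADH"),
         ("nadph_c", "NADPH"), ("trxox_c", "thioredoxin (ox)"),
         ("trxrd_c", "thioredoxin (red)"), ("o2_c", "oxygen"),
         ("co2_c", "carbon dioxide"), ("h2o_c", "water")]
    mets = [Metabolite(i, n, "e") for i, n in e] + \
           [Metabolite(i, n, "c") for i, n in c]

    def ex(rid, met, lb, ub):
        return Reaction(rid, {met: -1.0}, lb, ub, "exchange")

    def tr(rid, stoich, lb=0.0, ub=1000.0):
        return Reaction(rid, stoich, lb, ub, "transport")

    def rx(rid, stoich, lb=0.0, ub=1000.0, subsystem=None):
        return Reaction(rid, stoich, lb, ub, "internal", subsystem)

    rxns = [
        # exchanges (uptake = negative flux); substrate bounds leave headroom
        # above the internal pathway capacities so sampled uptake
        # distributions sit in the interior of the box
        ex("EX_glc", "glc_e", -25.0, 0.0),
        ex("EX_lac", "lac_e", 0.0, 1000.0),
        ex("EX_fa", "fa_e", -6.0, 0.0),
        ex("EX_aa", "aa_e", -10.0, 0.0),
        ex("EX_succ", "succ_e", -8.0, 1000.0),
        ex("EX_o2", "o2_e", -1000.0, 0.0),
        ex("EX_co2", "co2_e", 0.0, 1000.0),
        ex("EX_h2o", "h2o_e", 0.0, 1000.0),
        ex("EX_mglx", "mglx_e", 0.0, 1000.0),
        ex("EX_acac", "acac_e", 0.0, 1000.0),
        ex("EX_pmtl", "pmtl_e", 0.0, 1000.0),
        ex("EX_r5p", "r5p_e", 0.0, 1000.0),
        # transport
        tr("GLCt", {"glc_e": -1, "glc_c": 1}),
        tr("LACt", {"lac_c": -1, "lac_e": 1}),
        tr("FAt", {"fa_e": -1, "fa_c": 1}),
        tr("AAt", {"aa_e": -1, "aa_c": 1}),
        tr("SUCCt", {"succ_e": -1, "succ_c": 1}, -1000.0, 1000.0),
        tr("O2t", {"o2_e": -1, "o2_c": 1}),
        tr("CO2t", {"co2_c": -1, "co2_e": 1}),
        tr("H2Ot", {"h2o_c": -1, "h2o_e": 1}),
        tr("MGLXt", {"mglx_c": -1, "mglx_e": 1}),
        tr("ACACt", {"acac_c": -1, "acac_e": 1}),
        tr("PMTLt", {"pmtl_c": -1, "pmtl_e": 1}),
        tr("R5Pt", {"r5p_c": -1, "r5p_e": 1}),
        # lumped internal pathways; capacities sit above any attainable
        # exchange flux so that task activities are uptake-limited
        rx("GLYC", {"glc_c": -1, "pyr_c": 2, "atp_c": 2}, 0, 30,
           subsystem="glycolysis"),
        rx("LDH", {"pyr_c": -1, "lac_c": 1}, 0, 60, subsystem="glycolysis"),
        rx("MGLXS", {"glc_c": -1, "mglx_c": 2}, 0, 30, subsystem="glycolysis"),
        rx("PPP", {"glc_c": -1, "r5p_c": 1, "nadph_c": 2, "co2_c": 1}, 0, 30,
           subsystem="pentose phosphate"),
        rx("PDH", {"pyr_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, 60,
           subsystem="TCA"),
        rx("TCA", {"accoa_c": -1, "co2_c": 2, "nadh_c": 4, "atp_c": 1}, 0, 80,
           subsystem="TCA"),
        rx("SUCCDH", {"succ_c": -1, "co2_c": 2, "nadh_c": 2}, 0, 10,
           subsystem="TCA"),
        rx("OXPHOS", {"nadh_c": -1, "o2_c": -0.5, "atp_c": 2.5, "h2o_c": 1},
           0, 400, subsystem="oxidative phosphorylation"),
        rx("FAOX", {"fa_c": -1, "atp_c": -2, "accoa_c": 8, "nadh_c": 14},
           0, 8, subsystem="beta oxidation"),
        rx("AADEG", {"aa_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, 12,
           subsystem="amino acid catabolism"),
        rx("ACC", {"accoa_c": -1, "atp_c": -1, "malcoa_c": 1}, 0, 60,
           subsystem="lipogenesis"),
        rx("PMTLS", {"accoa_c": -1, "malcoa_c": -7, "nadph_c": -14, "pmtl_c": 1},
           0, 4, subsystem="lipogenesis"),
        rx("ACACS", {"accoa_c": -2, "acac_c": 1}, 0, 20, subsystem="ketogenesis"),
        rx("TRXR", {"trxox_c": -1, "nadph_c": -1, "trxrd_c": 1}, 0, 60,
           subsystem="redox"),
        rx("TRXO", {"trxrd_c": -1, "trxox_c": 1}, 0, 60, subsystem="redox"),
        rx("ATPM", {"atp_c": -1}, 0, 1000, subsystem="maintenance"),
    ]
    return MetabolicNetwork(mets, rxns, objective=("ATPM", "max"))


#: default whitelisted inorganic exchanges for task evaluation
DEFAULT_TASK_WHITELIST = ("o2_e", "co2_e", "h2o_e")


def build_toy_task_catalog() -> list[MetabolicTask]:
    """Metabolic tasks resolvable in the toy network (≥ 10, three archetypes)."""
    anaerobic = ("co2_e", "h2o_e")
    T = MetabolicTask
    return [
        T("atp_glycolysis", "ATP generation from anaerobic glycolysis",
          sources=("glc_e",), products=("atp_c",), objective="ATPM",
          whitelist=anaerobic, archetype="glycolytic"),
        T("atp_glucose_total", "ATP from glucose (glycolysis + TCA)",
          sources=("glc_e",), products=("atp_c",), objective="ATPM",
          archetype="glycolytic"),
        T("methylglyoxal_synthesis", "methylglyoxal from glucose",
          sources=("glc_e",), products=("mglx_c",), objective="DM_mglx_c",
          archetype="glycolytic"),
        T("lactate_from_glucose", "lactate secretion from glucose",
          sources=("glc_e",), products=("lac_c",), objective="DM_lac_c",
          whitelist=anaerobic, archetype="glycolytic"),
        T("ribose5p_synthesis", "ribose-5-phosphate via the pentose branch",
          sources=("glc_e",), products=("r5p_c",), objective="DM_r5p_c",
          archetype="glycolytic"),
        T("acetoacetate_synthesis", "acetoacetate from glucose-derived acetyl-CoA",
          sources=("glc_e",), products=("acac_c",), objective="DM_acac_c",
          archetype="glycolytic"),
        T("palmitoleate_synthesis", "palmitoleate from mixed carbon sources",
          sources=("glc_e", "fa_e", "aa_e"), products=("pmtl_c",),
          objective="DM_pmtl_c", archetype="catabolic"),
        T("malonylcoa_synthesis", "malonyl-CoA from fatty-acid/amino-acid carbon",
          sources=("fa_e", "aa_e"), products=("malcoa_c",),
          objective="DM_malcoa_c", archetype="catabolic"),
        T("tca_nadh", "TCA-cycle NADH from catabolic substrates",
          sources=("fa_e", "aa_e", "succ_e"), products=("nadh_c",),
          objective="DM_nadh_c", whitelist=anaerobic, archetype="catabolic"),
        T("amino_acid_catabolism", "amino-acid degradation to acetyl-CoA",
          sources=("aa_e",), products=(), objective="AADEG",
          archetype="catabolic"),
        T("beta_oxidation", "fatty-acid β-oxidation flux",
          sources=("fa_e",), products=(), objective="FAOX",
          archetype="catabolic"),
        T("thioredoxin_reductase", "NADPH-dependent thioredoxin reduction",
          sources=("glc_e",), products=(), objective="TRXR",
          archetype="redox"),
    ]


def two_phenotype_fold_changes() -> dict[str, dict[str, float]]:
    """Target plasma fold changes (vs healthy) for the two-phenotype design.

    ``A_like`` emulates a glycolysis-dominated plasma profile (glucose and
    glycolytic end products elevated), ``D_like`` a catabolic profile
    (fatty-acid, amino-acid and succinate elevated, glucose reduced). These
    are stylized *targets*; :func:`derive_two_phenotype_design` projects them
    onto fold changes consistent with a steady-state flux of the toy network.
    """
    return {
        "A_like": {"glucose": 1.5, "lactate": 1.5, "acetoacetate": 1.4,
                   "palmitate": 0.8, "alanine": 0.8, "succinate": 0.9,
                   "palmitoleate": 1.0, "methylglyoxal": 1.3, "ribose": 1.2,
                   "bicarbonate": 1.0},
        "D_like": {"glucose": 0.7, "lactate": 1.2, "acetoacetate": 0.7,
                   "palmitate": 1.6, "alanine": 1.6, "succinate": 1.8,
                   "palmitoleate": 1.4, "methylglyoxal": 0.8, "ribose": 0.9,
                   "bicarbonate": 1.1},
    }


def derive_two_phenotype_design(network: MetabolicNetwork, samples,
                                mapping: dict[str, str] | None = None,
                                targets: dict[str, dict[str, float]] | None = None,
                                ) -> dict[str, dict[str, float]]:
    """Mass-balance-coherent fold changes realizing the two-phenotype targets.

    For each design, the target exchange fluxes (target FC × baseline
    interquartile midpoint) are projected onto the closest steady-state flux
    vector (L1 distance over the mapped exchanges) with unmapped exchanges
    held in their baseline interquartile intervals and the scaled quartile
    interval of every mapped exchange required to stay within the base
    network's bounds. The returned fold change of each mapped metabolite is
    achieved-flux / baseline-midpoint, so the per-design midpoints are
    jointly consistent with mass balance.
    """
    from scipy.optimize import linprog

    from .contextualize import transport_quartiles

    mapping = dict(mapping or METABOLITE_EXCHANGE_MAP)
    targets = targets or two_phenotype_fold_changes()
    quart = transport_quartiles(samples, network.exchange_ids()).quartiles
    mid = {r: 0.5 * (q1 + q3) for r, (q1, q3) in quart.items()}
    rids = network.reaction_ids
    ridx = {r: i for i, r in enumerate(rids)}
    S = network.stoichiometric_matrix()
    base_lb, base_ub = network.bounds_arrays()

    designs: dict[str, dict[str, float]] = {}
    for name, mult in targets.items():
        mapped = [(m, mapping[m]) for m in mult if m in mapping]
        n, k = len(rids), len(mapped)
        # weight deviations relative to target magnitude so small exchanges
        # are not sacrificed to large ones
        weights = np.array([1.0 / max(abs(mult[m] * mid[r]), 0.1)
                            for m, r in mapped])
        c = np.concatenate([np.zeros(n), weights])
        A_eq = np.hstack([S, np.zeros((S.shape[0], k))])
        b_eq = np.zeros(S.shape[0])
        A_ub = np.zeros((2 * k, n + k))
        b_ub = np.zeros(2 * k)
        bounds = [(base_lb[i], base_ub[i]) for i in range(n)] + [(0, None)]
        bounds = bounds[:n] + [(0.0, None)] * k
        for row, (met, rid) in enumerate(mapped):
            i = ridx[rid]
            t = mult[met] * mid[rid]
            A_ub[row, i] = 1.0
            A_ub[row, n + row] = -1.0
            b_ub[row] = t
            A_ub[k + row, i] = -1.0
            A_ub[k + row, n + row] = -1.0
            b_ub[k + row] = -t
            # keep the scale factor s = v/mid in (0, s_max] so that
            # s·(Q1, Q3) stays within the base bounds, and on the target's
            # side of 1 so deliberate reductions/elevations keep their sign
            q1, q3 = quart[rid]
            s_max = math.inf
            if q1 < 0:
                s_max = min(s_max, base_lb[i] / q1)
            if q3 > 0:
                s_max = min(s_max, base_ub[i] / q3)
            s_lo, s_hi = 0.05, s_max
            if mult[met] > 1.0:
                s_lo = min(1.0, s_max)
            elif mult[met] < 1.0:
                s_hi = min(1.0, s_max)
            m = mid[rid]
            if abs(m) > 1e-9 and math.isfinite(s_hi):
                lo_v, hi_v = sorted((s_lo * m, s_hi * m))
                bounds[i] = (max(bounds[i][0], lo_v), min(bounds[i][1], hi_v))
        for rid_other, (q1, q3) in quart.items():
            if rid_other not in {r for _, r in mapped}:
                bounds[ridx[rid_other]] = (q1, q3)
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"design projection LP failed for {name!r}")
        fc = {}
        for met, rid in mapped:
            m = mid[rid]
            fc[met] = float(res.x[ridx[rid]] / m) if abs(m) > 1e-9 else 1.0
        designs[name] = fc
    return designs


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

_PANEL_NAMED = [
    "succinate", "malate", "fumarate", "lactate", "glucose", "pyruvate",
    "citrate", "alanine", "glutamine", "glutamate", "glycine", "serine",
    "palmitate", "oleate", "linoleate", "alpha_linolenate",
    "docosatetraenoate", "docosapentaenoate", "propionylcarnitine",
    "acetoacetate", "hydroxybutyrate", "methylglyoxal", "palmitoleate",
    "arginine", "leucine", "isoleucine", "valine", "phenylalanine",
    "tyrosine", "tryptophan", "methionine", "threonine", "lysine",
    "histidine", "proline", "asparagine", "aspartate", "taurine",
    "creatinine", "citrulline", "ornithine", "carnitine", "acetylcarnitine",
    "butyrylcarnitine", "myristate", "stearate", "arachidonate", "glycerol",
    "ribose", "urate", "betaine", "choline", "alpha_ketoglutarate",
    "bicarbonate",
    # low-abundance compounds with planted high missingness
    "cholate", "uridine", "inosine", "sarcosine", "dimethylglycine",
    "oxaloacetate", "isocitrate", "malonate",
]

DEFAULT_HIGH_MISSING = tuple(_PANEL_NAMED[-8:])

#: per-phenotype mean log2 shift vs healthy for discriminant metabolites
DISCRIMINANT_SHIFTS: dict[str, tuple[float, float, float, float]] = {
    # (A, B, C, D)
    "succinate":          (-3.0, -1.5, 0.0, 1.0),
    "malate":             (0.2, 0.4, 0.8, 1.6),
    "lactate":            (2.4, 0.8, 1.4, 2.8),
    "glucose":            (2.0, 0.6, 1.0, 2.6),
    "pyruvate":           (2.2, 0.4, 0.8, 1.8),
    "acetoacetate":       (2.4, 0.3, 0.5, 0.2),
    "hydroxybutyrate":    (2.2, 0.4, 0.6, 0.3),
    "methylglyoxal":      (1.8, 0.2, 0.4, 0.2),
    "alanine":            (1.6, 0.3, 0.5, 1.2),
    "glutamine":          (1.8, 0.2, 0.3, 0.5),
    "palmitate":          (0.5, 2.4, 0.4, 2.0),
    "oleate":             (0.4, 2.2, 0.5, 1.8),
    "linoleate":          (0.2, 2.0, 0.4, 0.6),
    "alpha_linolenate":   (0.3, 2.1, 0.6, 0.7),
    "docosatetraenoate":  (0.2, 0.3, 2.8, 0.8),
    "docosapentaenoate":  (0.3, 0.2, 3.0, 0.6),
    "propionylcarnitine": (0.4, 0.3, 2.4, 0.6),
    "taurine":            (0.2, 0.3, 2.2, 0.4),
    "citrate":            (0.3, 0.4, 0.6, 1.8),
    "glutamate":          (0.3, 0.2, 0.4, 1.6),
}

#: ratio tying the perfectly correlated pair: fumarate = 0.8 × malate
FUMARATE_MALATE_RATIO = 0.8


@dataclass
class CohortSpec:
    """Design of the synthetic cohort; defaults emulate the study conditions."""

    seed: int
    n_per_iss_stratum: tuple[int, int, int] = (20, 40, 39)
    n_healthy: int = 20
    metabolites: tuple[str, ...] = tuple(_PANEL_NAMED)
    phenotype_counts: dict[str, int] = field(
        default_factory=lambda: dict(reference.PHENOTYPE_SIZES))
    shifts_log2: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DISCRIMINANT_SHIFTS))
    sigma_log: float = 0.4           # log-normal noise sd (natural log)
    high_missing: tuple[str, ...] = DEFAULT_HIGH_MISSING
    high_missing_rate: float = 0.45  # > 0.30 with margin
    base_missing_rate: float = 0.01
    n_outliers: int = 4
    outlier_sigma_multiple: float = 6.0
    hazards: dict[str, float] = field(
        default_factory=lambda: {p: reference.daily_hazard_30d(p)
                                 for p in reference.PHENOTYPES})

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.base_missing_rate <= 1
                and 0 <= self.high_missing_rate <= 1):
            raise ValueError("missingness rates must be in [0, 1]")
        if sum(self.phenotype_counts.values()) + self.n_outliers != self.n_patients:
            raise ValueError(
                "phenotype counts + outliers must equal patient count")
        unknown = set(self.high_missing) - set(self.metabolites)
        if unknown:
            raise ValueError(f"high-missing metabolites not in panel: {unknown}")

    @property
    def n_patients(self) -> int:
        return sum(self.n_per_iss_stratum)


@dataclass
class GeneratedCohort:
    """Synthetic cohort: concentrations, clinical table and ground truth."""

    concentrations: pd.DataFrame   # (patients + healthy) × metabolites, NaN = missing
    cohort: pd.DataFrame           # patients × clinical covariates
    true_phenotypes: pd.Series     # patient id -> planted phenotype
    outlier_ids: list[str]
    healthy_ids: list[str]
    spec: CohortSpec

    @property
    def patient_ids(self) -> list[str]:
        return list(self.true_phenotypes.index)

    def patient_concentrations(self) -> pd.DataFrame:
        return self.concentrations.loc[self.patient_ids]

    def healthy_concentrations(self) -> pd.DataFrame:
        return self.concentrations.loc[self.healthy_ids]


def _base_log_levels(metabolites: tuple[str, ...]) -> np.ndarray:
    # deterministic spread of abundance scales (arbitrary units)
    return np.array([math.log(10.0) + 0.5 * (i % 7)
                     for i in range(len(metabolites))])


def simulate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Generate the cohort defined by ``spec``; same seed ⇒ identical output."""
    rng = np.random.default_rng(spec.seed)
    mets = list(spec.metabolites)
    n_pat = spec.n_patients
    patient_ids = [f"P{i + 1:03d}" for i in range(n_pat)]
    healthy_ids = [f"H{i + 1:03d}" for i in range(spec.n_healthy)]

    # planted phenotype labels: exact counts for the core cohort, outliers extra
    outlier_ids = sorted(rng.choice(patient_ids, size=spec.n_outliers,
                                    replace=False).tolist())
    core_ids = [p for p in patient_ids if p not in outlier_ids]
    labels = []
    for pheno in reference.PHENOTYPES:
        labels += [pheno] * spec.phenotype_counts[pheno]
    rng.shuffle(labels)
    phenotype = {}
    for pid, lab in zip(core_ids, labels):
        phenotype[pid] = lab
    props = np.array([spec.phenotype_counts[p] for p in reference.PHENOTYPES],
                     dtype=float)
    props /= props.sum()
    for pid in outlier_ids:
        phenotype[pid] = rng.choice(reference.PHENOTYPES, p=props)
    true_phenotypes = pd.Series({p: phenotype[p] for p in patient_ids},
                                name="phenotype")

    # log-normal concentrations with phenotype-specific log2 mean shifts
    mu0 = _base_log_levels(spec.metabolites)
    shift = np.zeros((n_pat, len(mets)))
    pheno_index = {p: i for i, p in enumerate(reference.PHENOTYPES)}
    for j, met in enumerate(mets):
        if met in spec.shifts_log2:
            per_pheno = spec.shifts_log2[met]
            for i, pid in enumerate(patient_ids):
                shift[i, j] = per_pheno[pheno_index[phenotype[pid]]] * LN2
    log_pat = mu0 + shift + rng.normal(0.0, spec.sigma_log, (n_pat, len(mets)))
    log_hlt = mu0 + rng.normal(0.0, spec.sigma_log,
                               (spec.n_healthy, len(mets)))

    # tie the perfectly correlated pair (raw fumarate = ratio × malate)
    if "malate" in mets and "fumarate" in mets:
        jm, jf = mets.index("malate"), mets.index("fumarate")
        log_pat[:, jf] = log_pat[:, jm] + math.log(FUMARATE_MALATE_RATIO)
        log_hlt[:, jf] = log_hlt[:, jm] + math.log(FUMARATE_MALATE_RATIO)

    # planted outliers: displacement along the two leading principal axes
    if spec.n_outliers:
        centered = log_pat - log_pat.mean(axis=0)
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        score_sd = svals / math.sqrt(n_pat - 1)
        out_rows = [patient_ids.index(p) for p in outlier_ids]
        for axis in (0, 1):
            log_pat[out_rows] += (spec.outlier_sigma_multiple
                                  * score_sd[axis] * vt[axis])

    conc = np.exp(np.vstack([log_pat, log_hlt]))

    # missingness mask (MCAR per metabolite)
    rates = np.full(len(mets), spec.base_missing_rate)
    for met in spec.high_missing:
        rates[mets.index(met)] = spec.high_missing_rate
    mask = rng.random(conc.shape) < rates
    conc = np.where(mask, np.nan, conc)
    concentrations = pd.DataFrame(conc, index=patient_ids + healthy_ids,
                                  columns=mets)

    cohort = _simulate_clinical(spec, rng, patient_ids, true_phenotypes)
    return GeneratedCohort(concentrations, cohort, true_phenotypes,
                           outlier_ids, healthy_ids, spec)


def _simulate_clinical(spec: CohortSpec, rng: np.random.Generator,
                       patient_ids: list[str],
                       phenotypes: pd.Series) -> pd.DataFrame:
    """Phenotype-conditional clinical covariates and 30-day survival."""
    n = len(patient_ids)
    med = reference.COVARIATE_MEDIANS

    # ISS pool with exact stratum counts, paired to phenotype severity
    lo, mid, hi = spec.n_per_iss_stratum
    iss_pool = np.concatenate([
        rng.integers(4, 16, size=lo),
        rng.integers(16, 26, size=mid),
        rng.integers(26, 58, size=hi),
    ])
    severity = {"A": 1.0, "B": 1.6, "C": 1.8, "D": 3.0}
    sev_score = np.array([severity[phenotypes[p]] for p in patient_ids])
    sev_score = sev_score + rng.normal(0.0, 0.8, n)
    order_patients = np.argsort(-sev_score)
    order_iss = np.argsort(-(iss_pool + rng.normal(0.0, 6.0, n)))
    iss = np.empty(n, dtype=int)
    iss[order_patients] = iss_pool[order_iss]

    def lognorm(var: str, sigma: float) -> np.ndarray:
        mu = np.array([math.log(med[var][phenotypes[p]]) for p in patient_ids])
        return np.exp(mu + rng.normal(0.0, sigma, n))

    def normal(var: str, sd: float, lo_=None, hi_=None) -> np.ndarray:
        center = np.array([med[var][phenotypes[p]] for p in patient_ids])
        x = center + rng.normal(0.0, sd, n)
        return np.clip(x, lo_, hi_)

    gcs = np.clip(np.round(normal("gcs", 4.0)), 3, 15).astype(int)
    sbp = normal("sbp", 18.0, 50, 220)
    heart_rate = normal("heart_rate", 15.0, 40, 200)
    base_excess = normal("base_excess", 4.0, -30, 10)
    lactate = lognorm("lactate", 0.5)
    glucose = lognorm("glucose", 0.3)
    epinephrine = lognorm("epinephrine", 0.9)
    norepinephrine = lognorm("norepinephrine", 0.9)
    stm = lognorm("stm", 0.35)
    syndecan1 = lognorm("syndecan1", 0.9)

    tf_rate = {p: reference.TRANSFUSED_4H[p] / reference.PHENOTYPE_SIZES[p]
               for p in reference.PHENOTYPES}
    transfused = np.array([rng.random() < tf_rate[phenotypes[p]]
                           for p in patient_ids])
    units = {}
    for product, med_units in reference.TRANSFUSION_MEDIANS.items():
        loc = np.array([max(med_units[phenotypes[p]], 0.5)
                        for p in patient_ids])
        u = np.round(np.exp(np.log(loc) + rng.normal(0.0, 0.7, n)))
        zero_prone = loc <= 0.5
        u[zero_prone & (rng.random(n) < 0.7)] = 0.0
        u[~transfused] = 0.0
        units[product] = u

    # survival: constant per-phenotype daily hazard, censoring at 30 days
    hazards = np.array([spec.hazards[phenotypes[p]] for p in patient_ids])
    death_day = rng.geometric(hazards)
    event = death_day <= reference.FOLLOW_UP_DAYS
    time = np.where(event, death_day, reference.FOLLOW_UP_DAYS)

    table = pd.DataFrame({
        "phenotype": [phenotypes[p] for p in patient_ids],
        "iss": iss,
        "gcs": gcs,
        "sbp": sbp,
        "heart_rate": heart_rate,
        "base_excess": base_excess,
        "lactate": lactate,
        "glucose": glucose,
        "epinephrine": epinephrine,
        "norepinephrine": norepinephrine,
        "stm": stm,
        "syndecan1": syndecan1,
        "transfused_4h": transfused,
        "rbc_4h": units["rbc_4h"],
        "plasma_4h": units["plasma_4h"],
        "platelets_4h": units["platelets_4h"],
        "eot": syndecan1 >= reference.EOT_SYNDECAN1_THRESHOLD,
        "survival_day": time,
        "death": event,
    }, index=pd.Index(patient_ids, name="sample_id"))
    return table


# --------------------------------------------------------------------------
# writers (CSV / JSON interfaces)
# --------------------------------------------------------------------------

def write_cohort(cohort: GeneratedCohort, outdir) -> dict[str, str]:
    """Write concentrations, clinical table and truth labels as CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "concentrations": outdir / "concentrations.csv",
        "cohort": outdir / "cohort.csv",
        "true_phenotypes": outdir / "true_phenotypes.csv",
    }
    cohort.concentrations.to_csv(paths["concentrations"], index_label="sample_id")
    cohort.cohort.to_csv(paths["cohort"])
    truth = cohort.true_phenotypes.to_frame()
    truth["outlier"] = truth.index.isin(cohort.outlier_ids)
    truth.to_csv(paths["true_phenotypes"], index_label="sample_id")
    return {k: str(v) for k, v in paths.items()}


def write_task_catalog(tasks: list[MetabolicTask], path) -> None:
    rows = [{
        "task_id": t.id, "description": t.description,
        "sources": ";".join(t.sources), "products": ";".join(t.products),
        "objective_reaction": t.objective,
        "whitelist": ";".join(t.whitelist) if t.whitelist is not None else "",
        "archetype": t.archetype or "",
    } for t in tasks]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_task_catalog(path) -> list[MetabolicTask]:
    df = pd.read_csv(path, keep_default_na=False)
    tasks = []
    for _, r in df.iterrows():
        tasks.append(MetabolicTask(
            id=r["task_id"], description=r["description"],
            sources=tuple(s for s in str(r["sources"]).split(";") if s),
            products=tuple(s for s in str(r["products"]).split(";") if s),
            objective=r["objective_reaction"],
            whitelist=tuple(
                s for s in str(r.get("whitelist", "")).split(";") if s) or None,
            archetype=r.get("archetype") or None,
        ))
    return tasks
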