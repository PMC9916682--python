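"""Published clinical reference values for the 95-patient trauma cohort.

These are the printed group sizes, outcome counts and covariate medians for
the four plasma metabolic phenotypes (A–D). They serve two roles:

* calibration targets for the synthetic cohort generator (phenotype
  proportions, per-phenotype mortality hazards, covariate location
  parameters), and
* inputs to the cohort arithmetic helpers in :mod:`shine_ecgem.clinical`
  (mortality shares, transfusion and endotheliopathy rates).

Units: SBP mmHg, heart rate bpm, base excess mEq/L, lactate and glucose
mg/dL, catecholamines pg/mL, syndecan-1 and sTM ng/mL.
"""

from __future__ import annotations

PHENOTYPES = ("A", "B", "C", "D")

#: patients per phenotype after outlier removal (n = 95)
PHENOTYPE_SIZES = {"A": 33, "B": 17, "C": 24, "D": 21}

#: deaths within 24 h / 72 h / 30 days per phenotype
DEATHS_24H = {"A": 1, "B": 0, "C": 0, "D": 11}
DEATHS_72H = {"A": 1, "B": 0, "C": 0, "D": 12}
DEATHS_30D = {"A": 10, "B": 5, "C": 4, "D": 16}

#: patients transfused within 4 h of admission
TRANSFUSED_4H = {"A": 15, "B": 8, "C": 13, "D": 19}

#: patients with endotheliopathy of trauma (syndecan-1 ≥ 40 ng/mL)
EOT_POSITIVE = {"A": 16, "B": 10, "C": 13, "D": 19}

#: median clinical covariates per phenotype
COVARIATE_MEDIANS: dict[str, dict[str, float]] = {
    "iss":            {"A": 21.0, "B": 25.0, "C": 25.0, "D": 34.0},
    "gcs":            {"A": 15.0, "B": 15.0, "C": 14.5, "D": 3.0},
    "sbp":            {"A": 132.0, "B": 119.0, "C": 111.0, "D": 98.0},
    "heart_rate":     {"A": 96.0, "B": 93.0, "C": 101.0, "D": 112.0},
    "base_excess":    {"A": -5.0, "B": -3.0, "C": -6.0, "D": -13.0},
    "lactate":        {"A": 2.3, "B": 3.7, "C": 3.7, "D": 9.8},
    "glucose":        {"A": 134.0, "B": 173.0, "C": 145.0, "D": 229.0},
    "epinephrine":    {"A": 271.0, "B": 262.0, "C": 230.0, "D": 2240.0},
    "norepinephrine": {"A": 1180.0, "B": 1180.0, "C": 741.0, "D": 3460.0},
    "stm":            {"A": 6.46, "B": 6.32, "C": 5.93, "D": 7.06},
    "syndecan1":      {"A": 34.4, "B": 49.5, "C": 42.3, "D": 190.0},
}

#: median transfusion units (RBC / plasma / platelets within 4 h, transfused patients)
TRANSFUSION_MEDIANS = {
    "rbc_4h":       {"A": 2.0, "B": 1.5, "C": 2.0, "D": 12.0},
    "plasma_4h":    {"A": 3.0, "B": 1.0, "C": 4.0, "D": 14.0},
    "platelets_4h": {"A": 0.0, "B": 0.0, "C": 0.0, "D": 12.0},
}

#: syndecan-1 threshold (ng/mL) defining endotheliopathy of trauma
EOT_SYNDECAN1_THRESHOLD = 40.0

#: follow-up horizon in days
FOLLOW_UP_DAYS = 30


def mortality_30d_fraction(phenotype: str) -> float:
    """Published 30-day mortality fraction of a phenotype."""
    return DEATHS_30D[phenotype] / PHENOTYPE_SIZES[phenotype]


def daily_hazard_30d(phenotype: str) -> float:
    """Constant daily death hazard reproducing the 30-day mortality."""
    m = mortality_30d_fraction(phenotype)
    return 1.0 - (1.0 - m) ** (1.0 / FOLLOW_UP_DAYS)
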