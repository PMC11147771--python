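"""Default parameter tables for adult T-ALL molecular subtyping.

The numbers here encode the published characteristics of a 230-patient adult
T-ALL cohort: subgroup frequencies among the 209 classifiable samples,
per-subgroup molecular-response (MRD) category rates after consolidation I,
3-year overall-survival point estimates, the immunophenotype mix of each
subgroup, the driver-fusion spectrum, and the oncogene panels that define
each subgroup on expression level.  They parameterize both the synthetic
cohort generator and the rule-based labeling / assignment machinery.
"""

from __future__ import annotations

# Canonical subgroup labels, ordered by cohort frequency (descending).
SUBGROUPS: tuple[str, ...] = (
    "HOXA",
    "TLX1",
    "LYL1/LMO2",
    "TAL1/LMO",
    "TLX3",
    "LMO1",
    "HOXA13",
    "NKX2",
    "TAL2",
)

UNCLASSIFIED = "unclassified"

# Classifiable samples per subgroup out of 209 (230 minus 21 unclassified).
SUBGROUP_COUNTS: dict[str, int] = {
    "HOXA": 50,
    "TLX1": 44,
    "LYL1/LMO2": 32,
    "TAL1/LMO": 30,
    "TLX3": 26,
    "LMO1": 15,
    "HOXA13": 7,
    "NKX2": 4,
    "TAL2": 1,
}

_N_CLASSIFIED = sum(SUBGROUP_COUNTS.values())  # 209

SUBGROUP_PROPORTIONS: dict[str, float] = {
    k: v / _N_CLASSIFIED for k, v in SUBGROUP_COUNTS.items()
}

# MRD response-category probabilities (MolCR, MolIMR, MolFail) per subgroup,
# taken from the observed per-subgroup counts among the 139 evaluable
# patients.  HOXA13 had no evaluable patient; it is given the same poor-risk
# profile as LYL1/LMO2 (a modeling choice, see docs/methods.md).
MRD_PROBS: dict[str, tuple[float, float, float]] = {
    "TLX1": (37 / 39, 0 / 39, 2 / 39),
    "HOXA": (24 / 37, 9 / 37, 4 / 37),
    "TAL1/LMO": (11 / 22, 6 / 22, 5 / 22),
    "TLX3": (9 / 18, 5 / 18, 4 / 18),
    "LMO1": (9 / 11, 0 / 11, 2 / 11),
    "LYL1/LMO2": (3 / 9, 4 / 9, 2 / 9),
    "NKX2": (1.0, 0.0, 0.0),
    "TAL2": (0.0, 1.0, 0.0),
    "HOXA13": (3 / 9, 4 / 9, 2 / 9),
}

# 3-year overall survival parameterizing the exponential event-time model.
# HOXA13's published figure is a 2-year OS of 33%; under the exponential
# model that corresponds to S(36 mo) = 0.33**1.5 ~= 0.19.
OS3Y: dict[str, float] = {
    "TLX1": 0.92,
    "NKX2": 1.00,
    "LMO1": 0.92,
    "HOXA": 0.70,
    "TLX3": 0.62,
    "LYL1/LMO2": 0.55,
    "TAL1/LMO": 0.56,
    "HOXA13": 0.19,
    "TAL2": 1.00,
}

# Immunophenotype stage mix (early, thymic, mature) per subgroup, from the
# cohort table restricted to samples with known immunophenotype.
IMMUNOPHENOTYPE_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "LMO1": (0 / 15, 9 / 15, 6 / 15),
    "TLX3": (7 / 23, 10 / 23, 6 / 23),
    "TLX1": (0.0, 1.0, 0.0),
    "LYL1/LMO2": (15 / 28, 3 / 28, 10 / 28),
    "HOXA": (23 / 46, 19 / 46, 4 / 46),
    "TAL1/LMO": (2 / 28, 17 / 28, 9 / 28),
    "HOXA13": (6 / 7, 0.0, 1 / 7),
    "NKX2": (0.0, 3 / 4, 1 / 4),
    "TAL2": (1 / 3, 1 / 3, 1 / 3),
}

# Fraction of early-stage samples carrying an ETP immunophenotype (23/67).
ETP_PROB_GIVEN_EARLY = 23 / 67

# Methylation-cluster target of each subgroup.  TLX1 (and NKX2) sit in the
# thymic-associated cluster M3; TAL1-driven leukemias (TAL1/LMO, LMO1) form
# the globally hypomethylated cluster M2; the immature subgroups (HOXA,
# LYL1/LMO2, TLX3) share M1; HOXA13 and TAL2 are placed in the small M4.
METHYLATION_CLUSTER: dict[str, str] = {
    "TLX1": "M3",
    "NKX2": "M3",
    "TAL1/LMO": "M2",
    "LMO1": "M2",
    "TLX3": "M1",
    "LYL1/LMO2": "M1",
    "HOXA": "M1",
    "HOXA13": "M4",
    "TAL2": "M4",
}

METHYLATION_CLUSTERS: tuple[str, ...] = ("M1", "M2", "M3", "M4")

# Subgroup-defining oncogene panels used by the generator: genes whose
# log2 expression is elevated in samples of that subgroup.  HOXA co-expresses
# the stem-cell genes MEF2C/BAALC; LYL1/LMO2 carries the full stem signature.
GENERATOR_PANELS: dict[str, tuple[str, ...]] = {
    "TLX1": ("TLX1",),
    "TLX3": ("TLX3",),
    "NKX2": ("NKX2-1",),
    "TAL2": ("TAL2",),
    "LMO1": ("LMO1", "TAL1"),
    "TAL1/LMO": ("TAL1", "LMO2"),
    "LYL1/LMO2": ("LYL1", "LMO2", "MEF2C", "BAALC"),
    "HOXA": ("HOXA9", "HOXA10", "MEF2C", "BAALC"),
    "HOXA13": ("HOXA13", "EVX1", "HOTTIP"),
}

# Fraction of TLX1 samples that additionally co-express NKX2-1 (11/44).
TLX1_NKX2_COEXPRESSION_PROB = 11 / 44

# Driver fusions per subgroup with per-sample probabilities, derived from
# the fusion counts in the cohort (e.g. STIL::TAL1 in 14 of 30 TAL1/LMO).
DRIVER_FUSIONS: dict[str, tuple[tuple[str, float], ...]] = {
    "TLX1": (("TRB::TLX1", 15 / 44),),
    "TLX3": (("BCL11B::TLX3", 0.30),),
    "TAL1/LMO": (("STIL::TAL1", 14 / 30), ("TCF7::TAL1", 1 / 30)),
    "HOXA": (
        ("SET::NUP214", 12 / 50),
        ("KMT2A::MLLT1", 6 / 50),
        ("PICALM::MLLT10", 5 / 50),
    ),
    "HOXA13": (("MIR181A1HG::HOTTIP", 3 / 7), ("TCF7::HOXA13", 2 / 7)),
    "LYL1/LMO2": (("LMO2::STAG2", 2 / 32),),
    "NKX2": (("NKX2-1::TRB", 0.25),),
    "LMO1": (),
    "TAL2": (),
}

# Curated driver-fusion -> subgroup map used for fusion-based assignment.
DRIVER_FUSION_MAP: dict[str, str] = {
    "STIL::TAL1": "TAL1/LMO",
    "TCF7::TAL1": "TAL1/LMO",
    "TRB::TLX1": "TLX1",
    "BCL11B::TLX3": "TLX3",
    "SET::NUP214": "HOXA",
    "KMT2A::MLLT1": "HOXA",
    "PICALM::MLLT10": "HOXA",
    "MIR181A1HG::HOTTIP": "HOXA13",
    "TCF7::HOXA13": "HOXA13",
    "NKX2-1::TRB": "NKX2",
    "LMO2::STAG2": "LYL1/LMO2",
}

# Risk-group mapping.  TAL2 (n=1, no outcome stratum) has no risk assignment.
RISK_GROUPS: dict[str, str | None] = {
    "TLX1": "good",
    "NKX2": "good",
    "LMO1": "good",
    "HOXA": "intermediate",
    "LYL1/LMO2": "poor",
    "HOXA13": "poor",
    "TAL1/LMO": "poor",
    "TLX3": "poor",
    "TAL2": None,
    UNCLASSIFIED: None,
}
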