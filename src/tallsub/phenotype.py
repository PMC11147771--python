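"""Clinical rule systems: immunophenotype staging, ETP flag, MRD response
categories, molecular risk groups, and blast-content sample eligibility.

The immunophenotype rules encode the flow-cytometry antigen patterns used to
subclassify T-lineage leukemia into early, thymic and mature T-ALL.  A marker
is "positive" when its expression percentage reaches the positivity cutoff
(default 20%, the common flow-cytometry convention).  Markers annotated
"+/-" in the defining patterns are unconstrained and may be missing.

MRD (minimal residual disease) categories follow the RQ-PCR convention
relative to the 1e-4 threshold: MolCR = negative with assay sensitivity of
at least 1e-4; MolIMR = positive but below 1e-4 or not quantifiable;
MolFail = quantifiable load above 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import RISK_GROUPS, SUBGROUPS, UNCLASSIFIED

# Canonical antigen names.
T_LINEAGE_MARKERS = ("cyCD3", "CD7")
STAGE_MARKERS = ("CD5", "CD2", "sCD3", "CD4", "CD8", "CD1a")
MYELOID_STEM_MARKERS = ("CD13", "CD33", "CD34", "CD117", "HLA-DR")
ALL_MARKERS = T_LINEAGE_MARKERS + STAGE_MARKERS + MYELOID_STEM_MARKERS

DEFAULT_POSITIVITY_CUTOFF = 20.0
ETP_CD5_CUTOFF = 25.0
MRD_THRESHOLD = 1e-4

STAGES = ("early", "thymic", "mature")
UNCLASSIFIABLE = "unclassifiable"

MOLCR, MOLIMR, MOLFAIL = "MolCR", "MolIMR", "MolFail"
MRD_CATEGORIES = (MOLCR, MOLIMR, MOLFAIL)
INSUFFICIENT_SENSITIVITY = "insufficient_sensitivity"

ELIGIBILITY_THRESHOLDS = {"rnaseq": 20.0, "methylation": 60.0, "mutation_panel": 60.0}


class NotTLineageError(ValueError):
    """Raised when a profile fails the cyCD3+/CD7+ T-lineage precondition."""


@dataclass
class MarkerProfile:
    """Surface/cytoplasmic antigen expression percentages; missing = None."""

    markers: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.markers.items():
            if value is not None and not (0.0 <= value <= 100.0):
                raise ValueError(f"marker {name}={value} outside [0, 100]")

    def get(self, name: str) -> float | None:
        return self.markers.get(name)

    def is_positive(self, name: str, cutoff: float) -> bool | None:
        """Tri-state positivity: True/False, or None when the marker is missing."""
        value = self.get(name)
        if value is None:
            return None
        return value >= cutoff


@dataclass(frozen=True)
class MRDRecord:
    """One MRD measurement: leukemic load, assay sensitivity, quantifiability."""

    mrd_value: float
    sensitivity: float
    quantifiable: bool = True
    timepoint: str = "after consolidation I"

    def __post_init__(self) -> None:
        if self.mrd_value < 0:
            raise ValueError("mrd_value must be >= 0")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")


def _matches(state: bool | None, required: bool) -> bool:
    """A constrained marker matches only when observed with the required sign."""
    return state is not None and state is required


def classify_immunophenotype(
    profile: MarkerProfile, positivity_cutoff: float = DEFAULT_POSITIVITY_CUTOFF
) -> str:
    """Classify a T-lineage profile into early / thymic / mature T-ALL.

    Patterns (markers not listed, or listed as +/- in the source patterns,
    are unconstrained):

    * thymic: CD1a+
    * early (pattern A): CD1a-, CD2-, sCD3-
    * early (pattern B): CD1a-, CD5-, CD2+, sCD3-, CD4-, CD8-
    * mature: CD1a-, CD5+, CD2+

    Returns ``"unclassifiable"`` when no pattern matches (profiles with
    missing constrained markers fall here too), mirroring how cohorts carry
    samples with unknown immunophenotype.
    """
    for marker in T_LINEAGE_MARKERS:
        state = profile.is_positive(marker, positivity_cutoff)
        if state is not True:
            raise NotTLineageError(
                f"{marker} not positive: profile is not T-lineage"
            )

    pos = {m: profile.is_positive(m, positivity_cutoff) for m in STAGE_MARKERS}

    if pos["CD1a"] is True:
        return "thymic"
    if pos["CD1a"] is not False:
        return UNCLASSIFIABLE

    early_a = _matches(pos["CD2"], False) and _matches(pos["sCD3"], False)
    early_b = (
        _matches(pos["CD5"], False)
        and _matches(pos["CD2"], True)
        and _matches(pos["sCD3"], False)
        and _matches(pos["CD4"], False)
        and _matches(pos["CD8"], False)
    )
    mature = _matches(pos["CD5"], True) and _matches(pos["CD2"], True)

    if early_a or early_b:
        return "early"
    if mature:
        return "mature"
    return UNCLASSIFIABLE


def flag_etp(
    profile: MarkerProfile, positivity_cutoff: float = DEFAULT_POSITIVITY_CUTOFF
) -> bool | None:
    """ETP flag: CD5 < 25% plus co-expression of a myeloid or stem marker.

    Returns None (indeterminate) when CD5 or every myeloid/stem marker is
    missing, so an absent panel is never silently scored negative.
    """
    cd5 = profile.get("CD5")
    if cd5 is None:
        return None
    if cd5 >= ETP_CD5_CUTOFF:
        return False
    states = [profile.is_positive(m, positivity_cutoff) for m in MYELOID_STEM_MARKERS]
    if any(s is True for s in states):
        return True
    if all(s is None for s in states):
        return None
    return False


def categorize_mrd(record: MRDRecord) -> str:
    """Map an MRD record to MolCR / MolIMR / MolFail.

    A negative result measured with an assay too insensitive to support a
    molecular CR claim (sensitivity worse than 1e-4) is flagged
    ``"insufficient_sensitivity"`` rather than given a category.
    """
    if record.mrd_value == 0:
        if record.sensitivity <= MRD_THRESHOLD:
            return MOLCR
        return INSUFFICIENT_SENSITIVITY
    if not record.quantifiable:
        return MOLIMR
    if record.mrd_value > MRD_THRESHOLD:
        return MOLFAIL
    return MOLIMR


def assign_risk_group(subgroup: str) -> str | None:
    """Molecular risk group: good (TLX1, NKX2, LMO1), intermediate (HOXA),
    poor (LYL1/LMO2, HOXA13, TAL1/LMO, TLX3); TAL2 and unclassified samples
    carry no risk assignment (None)."""
    if subgroup not in RISK_GROUPS:
        raise KeyError(f"unknown subgroup label: {subgroup!r}")
    return RISK_GROUPS[subgroup]


def check_sample_eligibility(blast_pct: float, assay: str) -> bool:
    """Blast-content eligibility: >=20% for RNA-seq, >=60% for methylation
    and mutation-panel assays (thresholds inclusive)."""
    if not (0.0 <= blast_pct <= 100.0):
        raise ValueError(f"blast_pct={blast_pct} outside [0, 100]")
    if assay not in ELIGIBILITY_THRESHOLDS:
        raise KeyError(f"unknown assay {assay!r}")
    return blast_pct >= ELIGIBILITY_THRESHOLDS[assay]


def profile_from_row(row) -> MarkerProfile:
    """Build a MarkerProfile from a mapping/Series with canonical antigen keys."""
    markers: dict[str, float | None] = {}
    for name in ALL_MARKERS:
        if name in row:
            value = row[name]
            markers[name] = None if value is None or value != value else float(value)
    return MarkerProfile(markers)
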