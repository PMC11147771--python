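"""Rule-based reference labeling from oncogene overexpression and fusions.

This reproduces the procedure that creates training labels for the subtype
classifiers: each subgroup is defined by a panel of oncogenes that must all
be overexpressed (robust z-score on log2(fpkm+1) values) together with
exclusion genes that must not be, and a curated driver fusion always
overrides the expression evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DRIVER_FUSION_MAP

logger = logging.getLogger(__name__)

ROBUST_Z_EPS = 1e-8
DEFAULT_Z_THRESHOLD = 3.0

# Priority applied when several panels are satisfied simultaneously.
PANEL_PRECEDENCE = (
    "HOXA13",
    "TLX1",
    "TLX3",
    "NKX2",
    "LMO1",
    "TAL1/LMO",
    "HOXA",
    "LYL1/LMO2",
    "TAL2",
)


@dataclass(frozen=True)
class OncogenePanel:
    """Defining and exclusion gene sets of one subgroup."""

    name: str
    defining: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.defining) & set(self.excluded):
            raise ValueError(f"{self.name}: defining and excluded genes overlap")
        if not self.defining:
            raise ValueError(f"{self.name}: at least one defining gene required")


# Default panels.  NKX2 requires absence of TLX1 (TLX1 samples may co-express
# NKX2-1); TAL1/LMO excludes LMO1 (LMO1-overexpressing TAL-class samples are
# a separate entity); HOXA13 requires silent anterior HOXA genes.
DEFAULT_PANELS: tuple[OncogenePanel, ...] = (
    OncogenePanel("TLX1", ("TLX1",)),
    OncogenePanel("TLX3", ("TLX3",)),
    OncogenePanel("NKX2", ("NKX2-1",), ("TLX1",)),
    OncogenePanel("TAL2", ("TAL2",)),
    OncogenePanel("LMO1", ("LMO1",), ("TLX1", "TLX3")),
    OncogenePanel("TAL1/LMO", ("TAL1", "LMO2"), ("LMO1",)),
    OncogenePanel("LYL1/LMO2", ("LYL1", "LMO2", "MEF2C"), ("HOXA9", "TAL1")),
    OncogenePanel("HOXA", ("HOXA9", "HOXA10")),
    OncogenePanel("HOXA13", ("HOXA13", "EVX1", "HOTTIP"), ("HOXA9", "HOXA10")),
)


@dataclass(frozen=True)
class SeedLabel:
    sample_id: str
    label: str | None
    source: str | None  # "expression_rule" | "fusion_rule" | None
    score: float


def robust_z(expression_log2: pd.DataFrame) -> pd.DataFrame:
    """Per-gene robust z across samples: (x - median) / (1.4826 * MAD + eps)."""
    x = expression_log2.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    z = (x - med) / (1.4826 * mad + ROBUST_Z_EPS)
    return pd.DataFrame(z, index=expression_log2.index, columns=expression_log2.columns)


def overexpression_scores(
    expression_log2: pd.DataFrame,
    panels: tuple[OncogenePanel, ...] = DEFAULT_PANELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel scores per sample on a log2(fpkm+1) matrix (genes x samples).

    Returns two sample-by-panel frames: the panel score (minimum robust z
    over the defining genes — every defining gene must be high) and the
    maximum robust z over the exclusion genes.  A panel whose defining (or
    exclusion) genes are absent from the matrix is unevaluable and reported
    as NaN for the affected quantity.
    """
    z = robust_z(expression_log2)
    scores = pd.DataFrame(index=expression_log2.columns, dtype=float)
    excl = pd.DataFrame(index=expression_log2.columns, dtype=float)
    for panel in panels:
        missing = [g for g in panel.defining if g not in z.index]
        if missing:
            logger.warning("panel %s unevaluable: genes %s absent", panel.name, missing)
            scores[panel.name] = np.nan
        else:
            scores[panel.name] = z.loc[list(panel.defining)].min(axis=0)
        if not panel.excluded:
            excl[panel.name] = -np.inf
        else:
            present = [g for g in panel.excluded if g in z.index]
            if len(present) < len(panel.excluded):
                logger.warning(
                    "panel %s: exclusion genes %s absent",
                    panel.name,
                    sorted(set(panel.excluded) - set(present)),
                )
            excl[panel.name] = (
                z.loc[present].max(axis=0) if present else np.nan
            )
    return scores, excl


def assign_seed_label(
    sample_id: str,
    scores: pd.Series,
    exclusion_scores: pd.Series,
    sample_fusions: list[str] | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    driver_map: dict[str, str] | None = None,
) -> SeedLabel:
    """Label one sample: a curated driver fusion wins outright, otherwise the
    highest-precedence satisfied panel (score >= threshold, all exclusion
    genes < threshold); no satisfied panel -> unlabeled."""
    driver_map = DRIVER_FUSION_MAP if driver_map is None else driver_map

    if sample_fusions:
        implied = {driver_map[f] for f in sample_fusions if f in driver_map}
        if len(implied) == 1:
            label = implied.pop()
            score = float(scores.get(label, np.nan))
            return SeedLabel(sample_id, label, "fusion_rule", score)
        if len(implied) > 1:
            logger.warning("%s: conflicting driver fusions %s", sample_id, sample_fusions)

    satisfied = []
    for rank, panel in enumerate(PANEL_PRECEDENCE):
        if panel not in scores.index:
            continue
        s = scores[panel]
        e = exclusion_scores.get(panel, -np.inf)
        if np.isnan(s):
            continue  # unevaluable panel
        if s >= z_threshold and not (e >= z_threshold):
            satisfied.append((panel, float(s), rank))
    if satisfied:
        # highest score wins; the precedence order breaks ties
        panel, score, _ = min(satisfied, key=lambda t: (-t[1], t[2]))
        return SeedLabel(sample_id, panel, "expression_rule", score)
    top = float(np.nanmax(scores.to_numpy())) if scores.notna().any() else np.nan
    return SeedLabel(sample_id, None, None, top)


def seed_label_cohort(
    expression_log2: pd.DataFrame,
    fusions: pd.DataFrame | None = None,
    panels: tuple[OncogenePanel, ...] = DEFAULT_PANELS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    driver_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Seed-label every sample; returns sample_id, label, source, score."""
    scores, excl = overexpression_scores(expression_log2, panels)
    fusions_by_sample: dict[str, list[str]] = {}
    if fusions is not None and len(fusions):
        for _, row in fusions.iterrows():
            fusions_by_sample.setdefault(row["sample_id"], []).append(row["fusion"])
    rows = []
    for sample in expression_log2.columns:
        lab = assign_seed_label(
            sample,
            scores.loc[sample],
            excl.loc[sample],
            fusions_by_sample.get(sample),
            z_threshold,
            driver_map,
        )
        rows.append(
            {"sample_id": lab.sample_id, "label": lab.label, "source": lab.source,
             "score": lab.score}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def build_reference_set(
    seed_labels: pd.DataFrame, min_class_size: int = 2
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Labeled training subset with class counts and non-stratifiable flags.

    Returns (labeled subset, per-class counts, classes below min size).
    Raises if no sample carries a label.
    """
    labeled = seed_labels[seed_labels["label"].notna()]
    if labeled.empty:
        raise ValueError("no labeled samples: cannot build a reference set")
    counts = labeled["label"].value_counts()
    small = sorted(counts[counts < min_class_size].index)
    if small:
        logger.warning("non-stratifiable classes (n < %d): %s", min_class_size, small)
    return labeled, counts, small
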