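"""Tiered final subgroup assignment.

Order of evidence: (1) consensus of the two reference classifiers, (2)
curated driver fusions, (3) manual rescue by clear oncogene overexpression
plus expression-profile similarity to already-assigned samples, (4)
unclassified.  A sample is assigned by the first tier that succeeds, so the
four tiers partition the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .params import DRIVER_FUSION_MAP, SUBGROUPS, UNCLASSIFIED
from .seedlabels import (
    DEFAULT_PANELS,
    DEFAULT_Z_THRESHOLD,
    OncogenePanel,
    PANEL_PRECEDENCE,
    overexpression_scores,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_CORRELATION = 0.5

TIER_CONSENSUS = "consensus"
TIER_FUSION = "fusion"
TIER_MANUAL = "manual"
TIER_UNCLASSIFIED = "unclassified"
TIERS = (TIER_CONSENSUS, TIER_FUSION, TIER_MANUAL, TIER_UNCLASSIFIED)

# External (pediatric reference) label vocabulary -> internal nine subgroups.
DEFAULT_LABEL_MAP: dict[str, str] = {
    **{name: name for name in SUBGROUPS},
    "TAL1": "TAL1/LMO",
    "TAL1/LMO2": "TAL1/LMO",
    "LYL1": "LYL1/LMO2",
    "NKX2-1": "NKX2",
    "HOXA9": "HOXA",
}


@dataclass(frozen=True)
class FinalAssignment:
    sample_id: str
    subgroup: str  # one of the nine labels or "unclassified"
    tier: str
    internal_prediction: str | None = None
    external_prediction: str | None = None
    fusion: str | None = None
    centroid_correlation: float | None = None


def consensus_assign(
    pred_internal: str, pred_external: str, label_map: dict[str, str] | None = None
) -> str | None:
    """Agreeing predictions (after mapping the external vocabulary) win."""
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    if pred_external not in label_map:
        raise KeyError(f"external label {pred_external!r} absent from label map")
    mapped = label_map[pred_external]
    return pred_internal if mapped == pred_internal else None


def fusion_assign(
    sample_fusions: list[str], driver_map: dict[str, str] | None = None
) -> tuple[str | None, bool]:
    """Unique subgroup implied by curated driver fusions.

    Returns (subgroup or None, conflict flag); conflicting implications
    yield (None, True).
    """
    driver_map = DRIVER_FUSION_MAP if driver_map is None else driver_map
    implied = {driver_map[f] for f in sample_fusions if f in driver_map}
    if len(implied) == 1:
        return implied.pop(), False
    return None, len(implied) > 1


def manual_assign(
    sample_expression: pd.Series,
    centroids: pd.DataFrame,
    panel_scores: pd.Series,
    exclusion_scores: pd.Series,
    min_correlation: float = DEFAULT_MIN_CORRELATION,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[str | None, float | None]:
    """Manual-rescue rule: a panel satisfied at the z threshold AND maximal
    Spearman correlation (>= min_correlation) to that subgroup's centroid.

    ``centroids`` is genes x subgroup, computed from already-assigned
    samples.  Returns (subgroup or None, correlation of the candidate).
    """
    if centroids.empty:
        return None, None
    candidates = [
        p
        for p in PANEL_PRECEDENCE
        if p in panel_scores.index
        and not np.isnan(panel_scores[p])
        and panel_scores[p] >= z_threshold
        and not (exclusion_scores.get(p, -np.inf) >= z_threshold)
    ]
    if not candidates:
        return None, None
    corr = {}
    x = sample_expression.loc[centroids.index].to_numpy(dtype=float)
    for sub in centroids.columns:
        rho = spearmanr(x, centroids[sub].to_numpy(dtype=float)).statistic
        corr[sub] = float(rho) if rho == rho else -1.0
    best_sub = max(corr, key=lambda s: corr[s])
    for cand in candidates:
        if cand not in corr:
            continue
        if cand == best_sub and corr[cand] >= min_correlation:
            return cand, corr[cand]
    return None, corr.get(candidates[0])


def _centroids(
    expression: pd.DataFrame, assigned: dict[str, str], min_samples: int = 2
) -> pd.DataFrame:
    """Per-subgroup mean expression profile over already-assigned samples."""
    groups: dict[str, list[str]] = {}
    for sample, sub in assigned.items():
        groups.setdefault(sub, []).append(sample)
    cols = {}
    for sub, samples in groups.items():
        if len(samples) < min_samples:
            logger.warning("subgroup %s has %d assigned samples; no centroid", sub, len(samples))
            continue
        cols[sub] = expression[samples].mean(axis=1)
    return pd.DataFrame(cols, index=expression.index)


def assign_cohort(
    pred_internal: pd.Series,
    pred_external: pd.Series,
    expression_log2: pd.DataFrame,
    fusions: pd.DataFrame | None = None,
    label_map: dict[str, str] | None = None,
    driver_map: dict[str, str] | None = None,
    panels: tuple[OncogenePanel, ...] = DEFAULT_PANELS,
    min_correlation: float = DEFAULT_MIN_CORRELATION,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four assignment tiers to a cohort.

    ``expression_log2`` is genes x samples on the classifier scale and must
    cover every predicted sample; ``genes`` optionally restricts the feature
    space used for centroid similarity (e.g. the union of selected genes).
    Returns the assignment table and the tier histogram.
    """
    samples = list(pred_internal.index)
    missing = [s for s in samples if s not in expression_log2.columns]
    if missing:
        raise KeyError(f"samples missing from expression matrix: {missing[:5]}")

    fusions_by_sample: dict[str, list[str]] = {}
    if fusions is not None and len(fusions):
        for _, row in fusions.iterrows():
            fusions_by_sample.setdefault(row["sample_id"], []).append(row["fusion"])
    elif fusions is None:
        logger.info("no fusion table supplied; fusion tier skipped")

    results: dict[str, FinalAssignment] = {}

    # tier 1: consensus (agreeing predictions must name one of the nine
    # subgroups; placeholder predictions never assign)
    for s in samples:
        sub = consensus_assign(pred_internal[s], pred_external[s], label_map)
        if sub is not None and sub not in SUBGROUPS:
            sub = None
        if sub is not None:
            results[s] = FinalAssignment(
                s, sub, TIER_CONSENSUS, pred_internal[s], pred_external[s]
            )

    # tier 2: curated driver fusions
    for s in samples:
        if s in results:
            continue
        fl = fusions_by_sample.get(s, [])
        if not fl:
            continue
        sub, conflict = fusion_assign(fl, driver_map)
        if conflict:
            logger.warning("%s: conflicting fusion implications %s", s, fl)
        if sub is not None:
            results[s] = FinalAssignment(
                s, sub, TIER_FUSION, pred_internal[s], pred_external[s], fusion=fl[0]
            )

    # tier 3: manual rescue against centroids of tiers 1-2
    feature_genes = genes if genes is not None else list(expression_log2.index)
    expr = expression_log2.loc[[g for g in feature_genes if g in expression_log2.index]]
    centroids = _centroids(expr, {s: a.subgroup for s, a in results.items()})
    scores, excl = overexpression_scores(expression_log2, panels)
    for s in samples:
        if s in results:
            continue
        sub, rho = manual_assign(
            expr[s], centroids, scores.loc[s], excl.loc[s], min_correlation, z_threshold
        )
        if sub is not None:
            results[s] = FinalAssignment(
                s, sub, TIER_MANUAL, pred_internal[s], pred_external[s],
                centroid_correlation=rho,
            )

    # tier 4: unclassified
    for s in samples:
        if s not in results:
            results[s] = FinalAssignment(
                s, UNCLASSIFIED, TIER_UNCLASSIFIED, pred_internal[s], pred_external[s]
            )

    table = pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "subgroup": a.subgroup,
                "tier": a.tier,
                "internal_prediction": a.internal_prediction,
                "external_prediction": a.external_prediction,
                "fusion": a.fusion,
                "centroid_correlation": a.centroid_correlation,
            }
            for a in (results[s] for s in samples)
        ]
    ).set_index("sample_id")
    histogram = {tier: int((table["tier"] == tier).sum()) for tier in TIERS}
    return table, histogram
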