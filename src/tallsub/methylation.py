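"""DNA-methylation arm: CpG filtering, top-variance PCA clustering, and a
bump-hunting caller for differentially methylated regions (DMRs) with a
permutation family-wise null.

Coordinates are 0-based half-open throughout.  The bump hunter follows the
classic scheme: a per-CpG group-difference statistic, smoothing by running
mean within genomic CpG clusters (consecutive CpGs closer than ``max_gap``),
candidate regions as maximal same-sign runs above a genome-wide quantile
cutoff, and a family-wise p-value from the maximum region area over B
permutations of the sample group labels (add-one estimator, so p is never
exactly zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 500
DEFAULT_CUTOFF_QUANTILE = 0.99
DEFAULT_SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    value: float  # mean smoothed group difference
    area: float  # sum of |smoothed difference|
    fwer_p: float


def filter_cpgs(
    betas: pd.DataFrame, annotation: pd.DataFrame, maf_cutoff: float = 0.01
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop dbSNP-overlapping CpGs (MAF > cutoff) and sex-chromosome CpGs."""
    missing = betas.index.difference(annotation.index)
    if len(missing):
        raise KeyError(f"annotation missing for CpG(s): {list(missing[:5])}")
    ann = annotation.loc[betas.index]
    snp = ann["maf"].to_numpy() > maf_cutoff
    sex = ann["sex_chrom"].to_numpy().astype(bool)
    keep = ~(snp | sex)
    report = {
        "removed_maf": int(snp.sum()),
        "removed_sex": int((sex & ~snp).sum()),
        "kept": int(keep.sum()),
    }
    return betas.loc[keep], report


def top_variable_cpgs(betas: pd.DataFrame, k: int = 2000) -> pd.DataFrame:
    """Top-k rows by across-sample variance; ties broken by CpG id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(betas):
        warnings.warn(f"k={k} exceeds {len(betas)} CpGs; returning all rows")
        k = len(betas)
    var = betas.var(axis=1, ddof=1)
    order = sorted(betas.index, key=lambda c: (-var[c], c))
    return betas.loc[order[:k]]


def cluster_methylation(
    betas: pd.DataFrame, n_clusters: int = 4, n_pcs: int = 10, seed: int = 0
) -> pd.Series:
    """PCA + k-means clustering of samples; labels M1..Mk by decreasing size.

    CpGs are standardized, principal components computed over samples, and
    k-means (n_init=50, seeded) run on the top components.
    """
    n_samples = betas.shape[1]
    if n_clusters > n_samples:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n_samples} samples")
    x = betas.to_numpy(dtype=float).T  # samples x cpgs
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    n_comp = min(n_pcs, n_samples - 1, x.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=n_clusters, n_init=50, random_state=seed).fit(pcs)
    raw = pd.Series(km.labels_, index=betas.columns)
    sizes = raw.value_counts()
    rank = {old: i + 1 for i, old in enumerate(sizes.index)}
    return raw.map(lambda c: f"M{rank[c]}").rename("methylation_cluster")


def define_cpg_clusters(annotation: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> pd.Series:
    """Genomic CpG clusters: consecutive CpGs with gap <= max_gap share a
    cluster; clusters never span chromosomes.  Input must be sorted by
    position within each chromosome."""
    cluster = np.zeros(len(annotation), dtype=int)
    current = -1
    prev_chrom, prev_pos = None, None
    chroms = annotation["chrom"].to_numpy()
    positions = annotation["pos"].to_numpy()
    for i, (chrom, pos) in enumerate(zip(chroms, positions)):
        if chrom == prev_chrom:
            if pos < prev_pos:
                raise ValueError(f"positions unsorted within {chrom} at index {i}")
            if pos == prev_pos:
                warnings.warn(f"duplicate position {chrom}:{pos}")
            if pos - prev_pos > max_gap:
                current += 1
        else:
            current += 1
        cluster[i] = current
        prev_chrom, prev_pos = chrom, pos
    return pd.Series(cluster, index=annotation.index, name="cpg_cluster")


def _smooth_segments(values: np.ndarray, cluster_ids: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean within each contiguous cluster segment.

    ``values`` is (n_cpgs,) or (n_cpgs, B); the window is truncated at the
    segment boundaries, and capped at the segment length.
    """
    out = np.empty_like(values, dtype=float)
    boundaries = np.flatnonzero(np.diff(cluster_ids)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(cluster_ids)]))
    for s, e in zip(starts, ends):
        seg = values[s:e]
        L = e - s
        w = min(window, L)
        h = w // 2
        csum = np.cumsum(seg, axis=0)
        zero = np.zeros((1,) + seg.shape[1:]) if seg.ndim > 1 else np.zeros(1)
        csum = np.concatenate((zero, csum), axis=0)
        idx = np.arange(L)
        lo = np.maximum(idx - h, 0)
        hi = np.minimum(idx + h + 1, L)
        out[s:e] = (csum[hi] - csum[lo]) / (hi - lo).reshape((-1,) + (1,) * (seg.ndim - 1))
    return out


def _regions_and_max_area(
    smoothed: np.ndarray, cluster_ids: np.ndarray, cutoff: float
) -> tuple[list[tuple[int, int, float]], float]:
    """Maximal same-sign runs with |smoothed| >= cutoff, within clusters.

    Returns ([(start_idx, end_idx_exclusive, area)], max area).
    """
    mask = np.abs(smoothed) >= cutoff
    if not mask.any():
        return [], 0.0
    sign = np.sign(smoothed)
    regions = []
    max_area = 0.0
    i = 0
    n = len(smoothed)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i + 1
        while j < n and mask[j] and cluster_ids[j] == cluster_ids[i] and sign[j] == sign[i]:
            j += 1
        area = float(np.abs(smoothed[i:j]).sum())
        regions.append((i, j, area))
        max_area = max(max_area, area)
        i = j
    return regions, max_area


def bumphunt(
    betas: pd.DataFrame,
    groups: pd.Series,
    annotation: pd.DataFrame,
    cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE,
    max_gap: int = DEFAULT_MAX_GAP,
    B: int = 1000,
    seed: int = 0,
    window: int = DEFAULT_SMOOTH_WINDOW,
) -> pd.DataFrame:
    """Bump-hunting DMR caller with a permutation family-wise null.

    ``groups`` maps each sample to one of two labels (e.g. a methylation
    cluster vs "rest"); the difference statistic per CpG is
    mean beta(first group) - mean beta(second group), where the "first"
    group is the lexicographically smaller label.  Returns a BED-like frame
    of candidate regions with area and family-wise permutation p-value.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    levels = sorted(pd.unique(groups.loc[betas.columns]))
    if len(levels) != 2:
        raise ValueError(f"exactly two group labels required, got {levels}")
    g = (groups.loc[betas.columns] == levels[0]).to_numpy()
    n_a, n_b = int(g.sum()), int((~g).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")

    ann = annotation.loc[betas.index]
    order = ann.sort_values(["chrom", "pos"], kind="stable").index
    ann = ann.loc[order]
    x = betas.loc[order].to_numpy(dtype=float)
    cluster_ids = define_cpg_clusters(ann, max_gap).to_numpy()

    weights = np.where(g, 1.0 / n_a, -1.0 / n_b)
    diff = x @ weights
    smoothed = _smooth_segments(diff, cluster_ids, window)
    cutoff = float(np.quantile(np.abs(smoothed), cutoff_quantile))

    regions, _ = _regions_and_max_area(smoothed, cluster_ids, cutoff)

    rng = np.random.default_rng(seed)
    perm_weights = np.empty((len(weights), B))
    for b in range(B):
        perm_weights[:, b] = rng.permutation(weights)
    perm_diff = x @ perm_weights  # n_cpgs x B
    perm_smoothed = _smooth_segments(perm_diff, cluster_ids, window)
    null_max = np.array(
        [
            _regions_and_max_area(perm_smoothed[:, b], cluster_ids, cutoff)[1]
            for b in range(B)
        ]
    )

    rows = []
    positions = ann["pos"].to_numpy()
    chroms = ann["chrom"].to_numpy()
    for i, j, area in regions:
        fwer = float((1 + (null_max >= area).sum()) / (B + 1))
        rows.append(
            {
                "chrom": chroms[i],
                "start": int(positions[i]),
                "end": int(positions[j - 1]) + 1,
                "n_cpgs": j - i,
                "value": float(smoothed[i:j].mean()),
                "area": area,
                "fwer_p": fwer,
                "first_cpg": ann.index[i],
                "last_cpg": ann.index[j - 1],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_cpgs", "value", "area", "fwer_p",
                 "first_cpg", "last_cpg"],
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def dmrs_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """BED6+ layout: chrom, start, end, name, score(=area), strand, value,
    n_cpgs, fwer_p."""
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"],
            "end": regions["end"],
            "name": [f"dmr_{i + 1}" for i in range(len(regions))],
            "score": regions["area"],
            "strand": ".",
            "value": regions["value"],
            "n_cpgs": regions["n_cpgs"],
            "fwer_p": regions["fwer_p"],
        }
    )
    return bed
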