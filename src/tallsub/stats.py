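"""Cohort-level statistics: contingency tests, printed-rate rounding, MRD
response tables, Mann-Whitney differential expression, BH FDR, preranked
gene-set enrichment, and Kaplan-Meier survival with log-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .params import SUBGROUPS, UNCLASSIFIED
from .phenotype import MRD_CATEGORIES


def crosstab_test(table, method: str = "auto") -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) or two-sided Fisher test.

    ``method="auto"`` uses Fisher for a 2x2 table with any expected count
    below 5, chi-squared otherwise.  Returns (statistic, p); Fisher's
    statistic is the conditional odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("at least a 2x2 table required")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column")

    if method == "fisher" and t.shape != (2, 2):
        raise ValueError("Fisher test restricted to 2x2 tables")
    if method == "auto":
        if t.shape == (2, 2):
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
            method = "fisher" if (expected < 5).any() else "chi2"
        else:
            method = "chi2"

    if method == "fisher":
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return float(odds), float(p)
    if method == "chi2":
        res = sps.chi2_contingency(t, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def rate_with_paper_rounding(count: int, n: int, decimals: int = 0) -> str | None:
    """Percentage 100*count/n rounded half-away-from-zero to ``decimals``.

    This is the rounding convention of printed clinical tables (e.g. 37/39
    -> "95").  Returns None for an empty denominator.
    """
    if n == 0:
        return None
    if not (0 <= count <= n):
        raise ValueError(f"count={count} outside [0, {n}]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(count) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP)
    return f"{value:.{decimals}f}" if decimals else f"{value:.0f}"


def mrd_response_table(
    assignments: pd.Series,
    mrd_categories: pd.Series,
    stage: pd.Series | None = None,
    stage_filter: str | None = None,
) -> pd.DataFrame:
    """Per-subgroup MolCR / MolIMR / MolFail counts and printed rates.

    ``assignments`` maps sample -> subgroup (or "unclassified");
    ``mrd_categories`` maps sample -> MRD category; samples with an MRD
    category but no assignment are counted under an "unassigned" row.
    ``stage``/``stage_filter`` optionally restrict the table to one
    immunophenotype stratum.  Rows are ordered by sample count (descending);
    a "total" row covers the assigned subgroups.
    """
    mrd = mrd_categories.dropna()
    mrd = mrd[mrd.isin(MRD_CATEGORIES)]
    if stage_filter is not None:
        if stage is None:
            raise ValueError("stage series required for a stage filter")
        mrd = mrd[stage.reindex(mrd.index) == stage_filter]

    rows = {}
    for sub in SUBGROUPS:
        ids = assignments[assignments == sub].index.intersection(mrd.index)
        cats = mrd.loc[ids]
        rows[sub] = [len(ids)] + [int((cats == c).sum()) for c in MRD_CATEGORIES]
    unassigned_ids = mrd.index.difference(assignments[assignments.isin(SUBGROUPS)].index)
    cats = mrd.loc[unassigned_ids]

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n", "MolCR", "MolIMR", "MolFail"]
    ).sort_values("n", ascending=False, kind="stable")
    total = table.sum(axis=0)
    table.loc["total"] = total
    if len(unassigned_ids):
        table.loc["unassigned"] = [len(unassigned_ids)] + [
            int((cats == c).sum()) for c in MRD_CATEGORIES
        ]
    for cat in MRD_CATEGORIES:
        table[f"{cat}_rate"] = [
            rate_with_paper_rounding(int(r[cat]), int(r["n"])) if r["n"] else None
            for _, r in table.iterrows()
        ]
    return table


def mann_whitney_de(
    expression: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U between two sample groups.

    Exact p for combined n <= 12, normal approximation with tie correction
    otherwise.  ``expression`` is genes x samples (any monotone scale).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    a = expression[list(group_a)].to_numpy(dtype=float)
    b = expression[list(group_b)].to_numpy(dtype=float)
    method = "exact" if (a.shape[1] + b.shape[1]) <= 12 else "asymptotic"
    out = []
    for i, gene in enumerate(expression.index):
        xa, xb = a[i], b[i]
        if np.all(xa == xa[0]) and np.all(xb == xa[0]):
            out.append((gene, len(xa) * len(xb) / 2.0, 1.0))
            continue
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        out.append((gene, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(out, columns=["gene", "U", "p"]).set_index("gene")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    NaN p-values propagate as NaN and do not enter the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    es: float
    p: float
    n_hits: int


def _running_sum_es(ranked_genes: list[str], gene_set: set[str]) -> float:
    """Classic unweighted Kolmogorov-Smirnov running-sum enrichment score."""
    n = len(ranked_genes)
    hits = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    step = np.where(hits, 1.0 / n_hits, -1.0 / (n - n_hits))
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def preranked_enrichment(
    ranked_stats: pd.Series,
    gene_set,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked gene-set enrichment with a gene-label permutation p-value.

    ``ranked_stats`` maps gene -> ranking statistic (sorted descending
    internally).  ES is the extremum of the classic running sum; the
    two-sided p uses random gene sets of the same size (add-one estimator).
    """
    ranked = ranked_stats.sort_values(ascending=False)
    genes = list(ranked.index)
    members = set(gene_set) & set(genes)
    if len(members) < 2:
        raise ValueError("gene set shares fewer than 2 genes with the ranking")
    es = _running_sum_es(genes, members)

    rng = np.random.default_rng(seed)
    size = len(members)
    exceed = 0
    arr = np.array(genes)
    for _ in range(n_permutations):
        null_set = set(rng.choice(arr, size=size, replace=False))
        if abs(_running_sum_es(genes, null_set)) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    name = getattr(gene_set, "name", "gene_set")
    return EnrichmentResult(gene_set=name, es=es, p=float(p), n_hits=size)


def enrichment_table(
    ranked_stats: pd.Series,
    gene_sets: dict[str, set[str]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run preranked enrichment over several sets and attach BH q-values."""
    rows = []
    for i, (name, members) in enumerate(gene_sets.items()):
        res = preranked_enrichment(ranked_stats, members, n_permutations, seed + i)
        rows.append({"gene_set": name, "ES": res.es, "p": res.p, "n_hits": res.n_hits})
    df = pd.DataFrame(rows).set_index("gene_set")
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


class KMEstimate:
    """Kaplan-Meier product-limit estimate with a survival-at(t) accessor."""

    def __init__(self, times, events):
        t = np.asarray(times, dtype=float)
        if (t < 0).any():
            raise ValueError("negative survival times")
        if len(t) == 0:
            raise ValueError("empty survival data")
        self._fitter = KaplanMeierFitter()
        self._fitter.fit(t, np.asarray(events, dtype=int))

    @property
    def survival_function(self) -> pd.DataFrame:
        return self._fitter.survival_function_

    def survival_at(self, t: float) -> float:
        return float(self._fitter.predict(t))


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimator: S(0) = 1, right-continuous steps at events."""
    return KMEstimate(times, events)


def logrank(times, events, strata) -> tuple[float, float]:
    """k-sample log-rank test (chi-squared with k-1 df)."""
    t = np.asarray(times, dtype=float)
    s = np.asarray(strata)
    if len(np.unique(s)) < 2:
        raise ValueError("at least two strata required")
    res = multivariate_logrank_test(t, s, np.asarray(events, dtype=int))
    return float(res.test_statistic), float(res.p_value)


def survival_by_risk_group(
    clinical: pd.DataFrame, assignments: pd.Series
) -> pd.DataFrame:
    """3-year OS per molecular risk group (good/intermediate/poor)."""
    from .phenotype import assign_risk_group

    risk = assignments.map(lambda s: assign_risk_group(s))
    rows = []
    for group in ("good", "intermediate", "poor"):
        ids = risk[risk == group].index.intersection(clinical.index)
        if len(ids) == 0:
            rows.append({"risk_group": group, "n": 0, "os3y": np.nan})
            continue
        km = km_estimate(clinical.loc[ids, "os_months"], clinical.loc[ids, "os_event"])
        rows.append({"risk_group": group, "n": len(ids), "os3y": km.survival_at(36.0)})
    return pd.DataFrame(rows).set_index("risk_group")
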