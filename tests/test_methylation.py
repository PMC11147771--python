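import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tallsub import methylation as meth


def make_annotation(n, gap=100, chrom="chr1", start=1000, **extra):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + gap * np.arange(n),
            "maf": extra.get("maf", 0.0),
            "sex_chrom": extra.get("sex_chrom", False),
            "island_flag": extra.get("island_flag", False),
        },
        index=[f"cg{i:05d}" for i in range(n)],
    )


def brute_force_bumphunt(betas, group_mask, annotation, cutoff_quantile, max_gap, window):
    """Independent oracle: literal recomputation of smoothed differences,
    cutoff, candidate regions and areas with plain loops."""
    ann = annotation.loc[betas.index].sort_values(["chrom", "pos"], kind="stable")
    x = betas.loc[ann.index].to_numpy(dtype=float)
    diff = x[:, group_mask].mean(axis=1) - x[:, ~group_mask].mean(axis=1)

    # genomic clusters
    clusters = []
    cid = -1
    prev = None
    for chrom, pos in zip(ann["chrom"], ann["pos"]):
        if prev is None or chrom != prev[0] or pos - prev[1] > max_gap:
            cid += 1
        clusters.append(cid)
        prev = (chrom, pos)
    clusters = np.array(clusters)

    smoothed = np.empty_like(diff)
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        w = min(window, len(idx))
        h = w // 2
        for rank, i in enumerate(idx):
            lo, hi = max(0, rank - h), min(len(idx), rank + h + 1)
            smoothed[i] = diff[idx[lo:hi]].mean()

    cutoff = np.quantile(np.abs(smoothed), cutoff_quantile)
    regions = []
    i = 0
    while i < len(smoothed):
        if abs(smoothed[i]) >= cutoff:
            j = i
            while (
                j + 1 < len(smoothed)
                and abs(smoothed[j + 1]) >= cutoff
                and clusters[j + 1] == clusters[i]
                and np.sign(smoothed[j + 1]) == np.sign(smoothed[i])
            ):
                j += 1
            regions.append(
                {
                    "chrom": ann["chrom"].iloc[i],
                    "start": int(ann["pos"].iloc[i]),
                    "end": int(ann["pos"].iloc[j]) + 1,
                    "area": float(np.abs(smoothed[i : j + 1]).sum()),
                }
            )
            i = j + 1
        else:
            i += 1
    return regions, cutoff


class TestFilterCpgs:
    def test_rules(self):
        ann = make_annotation(4)
        ann.loc["cg00001", "maf"] = 0.02  # dbSNP-related, removed
        ann.loc["cg00002", "maf"] = 0.005  # boundary: kept (0.005 <= 0.01)
        ann.loc["cg00003", "sex_chrom"] = True
        betas = pd.DataFrame(0.5, index=ann.index, columns=["a", "b"])
        filtered, report = meth.filter_cpgs(betas, ann)
        assert list(filtered.index) == ["cg00000", "cg00002"]
        assert report == {"removed_maf": 1, "removed_sex": 1, "kept": 2}

    def test_missing_annotation_named(self):
        ann = make_annotation(2)
        betas = pd.DataFrame(0.5, index=["cg00000", "cgMISSING"], columns=["a"])
        with pytest.raises(KeyError, match="cgMISSING"):
            meth.filter_cpgs(betas, ann)


class TestTopVariable:
    def test_variance_ranking_oracle(self):
        betas = pd.DataFrame(
            {"a": [0, 0, 0], "b": [2, 4, 6], "c": [0, 1, 2]},
            index=["cgA", "cgB", "cgC"],
        ).T.astype(float)
        # variances across the 3 samples: cgA var([0,2,0]) etc — build directly
        betas = pd.DataFrame(
            [[0.0, 1.0, 2.0], [0.0, 2.0, 4.0], [0.0, 3.0, 6.0]],
            index=["cg1", "cg4", "cg9"], columns=["a", "b", "c"],
        )  # variances 1, 4, 9
        top = meth.top_variable_cpgs(betas, k=2)
        assert list(top.index) == ["cg9", "cg4"]

    def test_constant_rows_rank_last_and_k_capped(self):
        betas = pd.DataFrame(
            [[0.5, 0.5], [0.1, 0.9]], index=["flat", "var"], columns=["a", "b"]
        )
        with pytest.warns(UserWarning):
            top = meth.top_variable_cpgs(betas, k=10)
        assert list(top.index) == ["var", "flat"]


class TestClustering:
    def _blobs(self, n_per=12, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([0.2, 0.4, 0.6, 0.8])
        cols, truth = [], []
        for ci, c in enumerate(centers):
            for i in range(n_per):
                cols.append(rng.normal(c, 0.01, 300).clip(0, 1))
                truth.append(ci)
        betas = pd.DataFrame(
            np.array(cols).T, columns=[f"s{i}" for i in range(len(cols))]
        )
        betas.index = [f"cg{i}" for i in range(300)]
        return betas, np.array(truth)

    def test_separable_blobs_ari_one(self):
        betas, truth = self._blobs()
        labels = meth.cluster_methylation(betas, n_clusters=4, seed=1)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        assert set(labels) == {"M1", "M2", "M3", "M4"}

    def test_labels_ordered_by_cluster_size(self):
        betas, truth = self._blobs()
        extra = betas.iloc[:, :6].copy()
        extra.columns = [f"x{i}" for i in range(6)]
        big = pd.concat([betas, extra], axis=1)
        labels = meth.cluster_methylation(big, n_clusters=4, seed=1)
        sizes = labels.value_counts()
        assert list(sizes.index) == ["M1", "M2", "M3", "M4"]
        assert sizes.is_monotonic_decreasing

    def test_determinism_and_duplication_invariance(self):
        betas, truth = self._blobs(seed=5)
        l1 = meth.cluster_methylation(betas, seed=7)
        l2 = meth.cluster_methylation(betas, seed=7)
        pd.testing.assert_series_equal(l1, l2)
        doubled = pd.concat(
            [betas, betas.rename(columns=lambda c: c + "_dup")], axis=1
        )
        ld = meth.cluster_methylation(doubled, seed=7)
        for c in betas.columns:
            assert ld[c] == ld[c + "_dup"]

    def test_too_many_clusters_rejected(self):
        betas, _ = self._blobs(n_per=1)
        with pytest.raises(ValueError):
            meth.cluster_methylation(betas.iloc[:, :3], n_clusters=4)


class TestCpgClusters:
    def test_gap_arithmetic(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [1, 100, 900]}, index=["a", "b", "c"]
        )
        clusters = meth.define_cpg_clusters(ann, max_gap=500)
        assert clusters.tolist() == [0, 0, 1]  # 800 > 500 splits

    def test_chromosome_boundary_splits(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "pos": [100, 150]}, index=["a", "b"]
        )
        assert meth.define_cpg_clusters(ann, max_gap=500).tolist() == [0, 1]

    def test_singleton(self):
        ann = pd.DataFrame({"chrom": ["chr1"], "pos": [5]}, index=["a"])
        assert meth.define_cpg_clusters(ann).tolist() == [0]

    def test_duplicates_warn_and_unsorted_raises(self):
        ann = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [5, 5]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            meth.define_cpg_clusters(ann)
        bad = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [9, 5]}, index=["a", "b"])
        with pytest.raises(ValueError):
            meth.define_cpg_clusters(bad)


def implanted_block_data(seed=0, n_null=100, block=10, n_per_group=20, delta=0.3):
    rng = np.random.default_rng(seed)
    n_cpgs = n_null + block
    ann = make_annotation(n_cpgs)
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    betas = rng.uniform(0.3, 0.5, (n_cpgs, len(samples)))
    group = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)
    block_idx = slice(40, 40 + block)
    betas[block_idx, :n_per_group] += delta
    return pd.DataFrame(betas, index=ann.index, columns=samples).clip(0, 1), group, ann, block_idx


class TestBumphunt:
    def test_implanted_block_recovered_with_significant_fwer(self):
        betas, group, ann, block_idx = implanted_block_data(seed=1)
        regions = meth.bumphunt(betas, group, ann, cutoff_quantile=0.95, B=200, seed=3)
        top = regions.sort_values("area", ascending=False).iloc[0]
        assert top["fwer_p"] < 0.05
        assert top["start"] <= ann["pos"].iloc[44] <= top["end"]
        assert top["value"] > 0  # group A (lexicographically first) is hyper

    def test_brute_force_oracle_reproduces_areas(self):
        betas, group, ann, _ = implanted_block_data(seed=2)
        regions = meth.bumphunt(betas, group, ann, cutoff_quantile=0.95, B=5, seed=0)
        mask = (group.loc[betas.columns] == "A").to_numpy()
        oracle, cutoff = brute_force_bumphunt(
            betas, mask, ann, cutoff_quantile=0.95, max_gap=500, window=5
        )
        assert len(regions) == len(oracle)
        got = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
        for i, exp in enumerate(sorted(oracle, key=lambda r: (r["chrom"], r["start"]))):
            assert got.loc[i, "start"] == exp["start"]
            assert got.loc[i, "end"] == exp["end"]
            assert got.loc[i, "area"] == pytest.approx(exp["area"], rel=1e-12)

    def test_label_flip_preserves_areas_and_p(self):
        betas, group, ann, _ = implanted_block_data(seed=3)
        ra = meth.bumphunt(betas, group, ann, cutoff_quantile=0.95, B=50, seed=9)
        flipped = group.map({"A": "Z_B", "B": "A"})  # swap which group sorts first
        rb = meth.bumphunt(betas, flipped, ann, cutoff_quantile=0.95, B=50, seed=9)
        assert np.allclose(ra["area"].to_numpy(), rb["area"].to_numpy())
        assert np.allclose(ra["value"].to_numpy(), -rb["value"].to_numpy())
        assert np.allclose(ra["fwer_p"].to_numpy(), rb["fwer_p"].to_numpy())

    def test_fwer_never_zero_and_b1_bounds(self):
        betas, group, ann, _ = implanted_block_data(seed=4)
        regions = meth.bumphunt(betas, group, ann, cutoff_quantile=0.95, B=1, seed=0)
        assert set(np.round(regions["fwer_p"], 6)) <= {0.5, 1.0}
        big = meth.bumphunt(betas, group, ann, cutoff_quantile=0.95, B=100, seed=0)
        assert (big["fwer_p"] > 0).all()

    def test_regions_disjoint_sorted_constant_sign(self):
        betas, group, ann, _ = implanted_block_data(seed=5)
        regions = meth.bumphunt(betas, group, ann, cutoff_quantile=0.90, B=5, seed=0)
        assert (regions["end"] > regions["start"]).all()
        prev_end = -1
        for _, r in regions.iterrows():
            assert r["start"] >= prev_end
            prev_end = r["end"]

    def test_small_group_rejected(self):
        betas, group, ann, _ = implanted_block_data(seed=6)
        group.iloc[1:20] = "B"  # leaves a single A
        with pytest.raises(ValueError):
            meth.bumphunt(betas, group, ann, B=5)

    def test_null_family_wise_error_calibrated(self):
        """With random group labels, the probability of any region reaching
        family-wise p < 0.05 stays inside the binomial 95% band around 0.05
        over 200 replicate datasets."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            n_cpgs, n_samples = 60, 24
            ann = make_annotation(n_cpgs)
            betas = pd.DataFrame(
                rng.uniform(0.3, 0.7, (n_cpgs, n_samples)),
                index=ann.index, columns=[f"s{i}" for i in range(n_samples)],
            )
            group = pd.Series(
                ["A"] * (n_samples // 2) + ["B"] * (n_samples // 2),
                index=betas.columns,
            )
            regions = meth.bumphunt(betas, group, ann, cutoff_quantile=0.95, B=100,
                                    seed=rep)
            hits += int((regions["fwer_p"] < 0.05).any())
        # binomial 95% CI for p=0.05, n=200: roughly [4, 17] successes
        assert 1 <= hits <= 18
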