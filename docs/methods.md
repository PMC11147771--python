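# Methods

This note documents the models and procedures implemented in `tallsub`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not emulate.

## Cohort model

The package targets the structure of a large, homogeneously treated adult
T-ALL cohort: nine molecular subgroups defined by oncogene overexpression
(HOXA, TLX1, LYL1/LMO2, TAL1/LMO, TLX3, LMO1, HOXA13, NKX2, TAL2, at
frequencies 50/44/32/30/26/15/7/4/1 among 209 classifiable of 230
patients), four DNA-methylation clusters (M1–M4) aligned with the
subgroups, per-subgroup molecular response (MRD) rates after consolidation
I, and subgroup-dependent overall survival.

## Synthetic data generator

The generator (`tallsub.cohort`) is first-class, tested code.  It draws
hidden subgroup labels from the published frequencies and emits:

* **Expression** (genes × samples, fpkm-like).  Background genes have a
  per-gene log2 baseline ~ N(3, 1) shared by all samples; subgroup-defining
  oncogenes instead have a *silent* baseline ~ N(−3, 0.5).  This departs
  from a uniform N(3, 1) baseline deliberately: the defining oncogenes of
  T-ALL subgroups are categorically unexpressed outside their subgroup
  (e.g. *TLX3* is absent from all non-TLX3 samples), and a high, noisy
  baseline would make "overexpression" a quantitative rather than
  categorical signal — the robust-z scorer (below) then cannot separate
  subgroups at any realistic effect size because the cohort-wide MAD is
  inflated by the overexpressing fraction itself.  Samples of a subgroup
  add the panel effect (default **5 log2 units**, ~32-fold) to their panel
  genes; per-measurement noise is N(0, 1) on the log2 scale.  HOXA13
  samples elevate *HOXA13*, *EVX1* and *HOTTIP* while anterior HOXA genes
  stay silent; 25% of TLX1 samples co-express *NKX2-1*.  Each subgroup
  additionally perturbs a fixed 20% of background genes by N(0, 1)
  ("expression program", derived deterministically from the subgroup name),
  giving same-subgroup samples the correlated transcriptional context that
  real subgroups have; without it, expression-profile similarity carries no
  information beyond the panel genes and the manual-rescue tier cannot
  work.
* **Fusions.**  At most one driver fusion per sample (driver lesions are
  mutually exclusive), drawn from the subgroup's spectrum at the published
  per-subgroup rates (e.g. STIL::TAL1 in 14/30 TAL1/LMO samples,
  SET::NUP214 in 12/50 HOXA samples, MIR181A1HG::HOTTIP in 3/7 HOXA13).
* **Methylation** (CpG × samples, beta in [0, 1]).  Per-site bimodal
  baseline (Beta mixture), Gaussian noise (sd 0.05), clipping to [0, 1].
  Cluster M2 (the TAL1-fusion cluster) is shifted by −0.2 over
  CpG-island-flagged sites, reproducing its global island hypomethylation.
  One 10-CpG block per cluster is shifted by +0.3 in that cluster's
  samples and recorded as ground truth for the DMR caller.  Site
  annotation carries chrom, 0-based position, MAF and sex-chromosome /
  island flags; ~2% of sites sit on chrX and ~10% carry a nonzero MAF so
  the filters are exercised.
* **Clinical.**  Immunophenotype stage drawn from the subgroup's observed
  early/thymic/mature mix; antigen percentages are drawn to *satisfy* the
  stage rule (so stage and markers round-trip exactly); 34% of early-stage
  samples are ETP (CD5 < 25% plus a myeloid/stem marker).  MRD categories
  are drawn from the subgroup's published rates and back-converted into
  (value, sensitivity, quantifiable) triples that re-categorize exactly:
  MolCR → value 0 at sensitivity 10⁻⁴; MolIMR → value in (10⁻⁶, 10⁻⁴),
  non-quantifiable with probability 0.5; MolFail → value log-uniform in
  (10⁻⁴, 10⁻¹).  Survival is exponential with rate −ln(os3y)/36 months and
  administrative censoring at 60 months.  HOXA13's published survival
  figure is a 2-year OS of 33%; it is converted to the 3-year parameter
  0.19 under the exponential model so the os3y field keeps one meaning.
  HOXA13 has no published MRD row (no evaluable patient); it receives the
  LYL1/LMO2 (poor-risk) response profile.

**What the generator does not emulate:** read-level data, copy-number
structure, batch effects, realistic CpG linkage beyond block structure,
gene-length/GC biases, dependence between MRD response and survival within
a subgroup, or competing risks.  Passing tests therefore demonstrate that
the *procedures* are correct under the stated statistical structure, not
that the classifier would reach the same accuracy on real sequencing data.

## Seed labeling

Overexpression is scored per gene as a robust z across samples,
(x − median)/(1.4826·MAD + ε) with ε = 10⁻⁸ guarding zero-MAD genes, on
log2(fpkm+1) values.  A subgroup panel is satisfied when the *minimum* z
over its defining genes reaches the threshold (default 3.0) and every
exclusion gene stays below it (NKX2 excludes TLX1; TAL1/LMO excludes LMO1;
HOXA13 excludes the anterior HOXA genes).  A curated driver fusion always
wins over expression evidence.  Among several satisfied panels the highest
panel score wins, with a fixed precedence order (HOXA13 > TLX1 > TLX3 >
NKX2 > LMO1 > TAL1/LMO > HOXA > LYL1/LMO2 > TAL2) breaking ties.

At the generator defaults (effect 5, noise 1, n = 500) seed labels agree
with the hidden truth for ≥ 95% of samples.  *Limitation:* at a weaker
effect of 4 log2 units the recovery drops to ~88%; with a threshold of 3
robust-z units and cohort-wide MAD estimation, a 4-unit effect simply is
not "clear overexpression" once the overexpressing fraction (up to ~25% of
the cohort for one gene) inflates the scale estimate.

## Subtype classifier

Features are the shared genes of the two reference cohorts (lexicographic
order, duplicates collapsed to the highest-mean row), on the log2(fpkm+1)
scale (a raw-fpkm flag exists).  Feature selection fits an L1-penalized
multinomial logistic regression along a descending penalty path and picks
the penalty minimizing the inner-10-fold cross-validated multinomial
deviance (a one-standard-error rule is available by flag).  The standalone
selector uses a glmnet-like path of 100 penalties down to 1% of the
smallest all-zero penalty; inside the outer cross-validation the default
path is coarser (30 penalties down to 10%, looser solver tolerance) — the
nested 10×10 scheme is otherwise an order of magnitude slower while
selecting the same oncogene panels on synthetic cohorts.  The path walk
stops early once the CV deviance has clearly passed its minimum.  An
empty selection (intercept-only optimum) falls back to the full feature
space for the forest.

The classifier is a random forest with 500 trees and √p features per
split (the published analysis names the algorithm but no hyperparameters).
Cross-validation is 10-fold, randomized and stratified; per fold, feature
selection and training see only the 90% split, and predictions are
recorded for the untouched 10%.  Classes with fewer than k members are
excluded and flagged (mirroring reference classes of size 1–4).  The fold
partition can be pinned externally, which is how the no-leakage property
is asserted.  Prediction imputes missing genes at the training median and
refuses when more than half the selected genes are absent; probability
ties resolve to the lexicographically first class.

## Tiered assignment

Tier 1 assigns samples whose two classifier predictions agree after
mapping the external vocabulary onto the internal one (many-to-one map,
e.g. "TAL1" → TAL1/LMO).  Tier 2 assigns by a unique curated-driver
implication; conflicting implications assign nothing and are flagged.
Tier 3 (manual rescue) requires a satisfied oncogene panel *and* maximal
Spearman correlation ≥ 0.5 to the centroid of the already-assigned samples
of that subgroup (centroids need ≥ 2 samples).  Everything else is
unclassified.  Fusion evidence is ranked above manual rescue because a
recurrent driver fusion is mechanistically definitive while profile
similarity is a soft criterion.  The tiers partition the cohort by
construction; on consistently generated synthetic data the final label
never contradicts a sample's driver fusion.

## Methylation arm

Filtering removes CpGs with dbSNP MAF > 0.01 and sex-chromosome CpGs
(dasen-style array normalization is chemistry-specific and out of scope; a
between-sample quantile normalization stand-in exists but is off for
synthetic betas).  Clustering standardizes the top-2000-variance CpGs,
projects samples onto the top 10 principal components, and runs k-means
(k = 4, n_init = 50, seeded); clusters are renamed M1..M4 by decreasing
size.

The DMR caller follows the classic bump-hunting scheme.  Genomic CpG
clusters join consecutive CpGs closer than 500 bp.  The per-CpG statistic
is the difference of group mean betas, smoothed by a centered running mean
(window 5, truncated at cluster boundaries; running mean rather than loess
for auditability — a brute-force oracle in the test suite reproduces every
area exactly).  The cutoff is the 0.99 genome-wide quantile of the
absolute smoothed statistic (0.95 in the small-fixture tests, where a
60–110-CpG panel makes the 0.99 quantile degenerate); candidate regions
are maximal same-sign runs above the cutoff, scored by their area
Σ|smoothed|.  The null records the maximum region area in each of B
(default 1000) permutations of the sample group labels — permuting labels
globally preserves the CpG correlation structure — and the family-wise
p-value is (1 + #{null ≥ observed})/(B + 1), which is never zero.
One-vs-rest is the default contrast; pairwise contrasts are a flag.

## Statistics layer

Pearson χ² without continuity correction; two-sided Fisher for 2×2 tables
(summing tables with probability ≤ observed), chosen automatically when an
expected count falls below 5.  Published-table percentages are reproduced
by half-away-from-zero rounding of 100·count/n.  Differential expression
uses the Mann–Whitney U test (exact for combined n ≤ 12, tie-corrected
normal approximation otherwise) — the published DESeq2-based analysis is
deliberately replaced by the cohort's own single-gene test convention,
since variance-stabilizing-transform internals are out of scope.
Benjamini–Hochberg FDR propagates NaNs.  Preranked enrichment uses the
classic unweighted running-sum enrichment score (+1/|S| on hits,
−1/(N−|S|) on misses, extremum by absolute value) with a two-sided
gene-label permutation p (add-one estimator) and BH q across sets.
Survival is Kaplan–Meier with k-sample log-rank tests; times are in
months, 3-year OS = S(36).

## Numerical and edge-case choices

* Eligibility thresholds are inclusive (≥ 20% blasts for RNA-seq, ≥ 60%
  for methylation and mutation panels).
* Marker positivity cutoff 20% (configurable); ETP's CD5 cutoff is 25%.
* A negative MRD result measured at sensitivity worse than 10⁻⁴ returns an
  `insufficient_sensitivity` flag instead of a category; an MRD value
  exactly 10⁻⁴ is MolIMR (MolFail requires strictly > 10⁻⁴).
* TAL2 (cohort size 1, no outcome stratum) has no risk group; profiles
  matching no immunophenotype pattern return `unclassifiable` rather than
  raising.
* Robust z with zero MAD is finite via ε; constant genes score 0.
* k-means label renaming breaks size ties by original cluster index;
  top-variance ranking breaks variance ties by CpG id.
* All stochastic components take explicit integer seeds; every pipeline
  stage is a pure function of (inputs, parameters, seed).

## Problem sizes

The shipped tests and the acceptance script use n = 450 (classifier CV),
n = 500 (seed-label recovery), n = 230 (assignment tiers), n = 120 /
2000–3000 CpGs (methylation), B = 100–200 permutations with 70–110-CpG
panels and 100–200 replicate null datasets (DMR calibration), and
n = 5000 (survival recovery) — sizes at which the Monte-Carlo error of
each check is comfortably below its assertion margin.
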