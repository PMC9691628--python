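# Methods

This note records the statistical model behind each stage of the pipeline,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the choices made where the design was genuinely open.

## Study design and scope

The pipeline targets epigenome-wide association analyses of monozygotic
(MZ) twin pairs discordant for a trait, profiled by MeDIP-seq (methylated
DNA immunoprecipitation sequencing), where read coverage in a genomic
window proxies methylation density.  Three discordance definitions are
built in:

| comparison | rule | boundary behavior |
|---|---|---|
| physical activity | one twin ≥ 150 MVPA min/week, co-twin < 150 | (150, 149) discordant; (150, 150) concordant |
| walkability | one twin in {car dependent, somewhat walkable}, co-twin in {very walkable, walker's paradise} | Walk Score bins 0–49 / 50–69 / 70–89 / 90–100; the bin edges are configuration, not a published constant |
| BMI | within-pair difference ≥ 5 kg/m² | difference exactly 5 is discordant |

Samples mapping below 70% are removed together with their co-twin, so the
retained set always consists of complete pairs.  Male and female pairs are
hard-partitioned before any statistic is computed; no mixed-sex test can be
produced.  The pipeline starts from per-window read counts (or BED read
intervals); read QC, trimming and alignment are upstream of its scope.

## Window counts

The genome is tiled into non-overlapping 1000 bp windows (terminal windows
truncated and flagged).  Reads are assigned to exactly one window by their
midpoint — an unambiguous, count-conserving rule chosen because the
fragment-extension behavior of coverage pipelines is tool-specific;
midpoint assignment is this package's documented convention.  RPKM is
count / (window kb × library size / 10⁶) using the true window length;
library size is total mapped reads and can exceed the grid-assigned sum.
Top-N selection (default N = 100 000) ranks windows by mean RPKM across
samples with ties broken by genomic order.

## Per-window exact test

The two-group comparison is the classic conditional negative-binomial
exact test for count data:

* NB parameterization: Var = μ + φμ², φ = 0 is Poisson.  The same
  convention is used by the simulator, so recovery tests are meaningful.
* Counts are scaled to the geometric-mean library size and group-summed,
  with the scaled sums rounded to integers for the enumeration.  This
  replaces the quantile-adjustment pseudo-counts of reference count-test
  implementations; it is validated by calibration tests (uniform null
  p-values, dispersion recovery) rather than by count-identity with any
  external tool.
* Under the null both groups share the per-sample mean μ̂₀ = T/(n_A+n_B);
  the group sums are NB(n_A μ̂₀, φ/n_A) and NB(n_B μ̂₀, φ/n_B) (a sum of n
  iid NB(μ, φ) is NB(nμ, φ/n)).  The two-sided p-value is the total
  conditional probability of splits no more likely than the observed one
  ("probability-ordering" two-sided rule; the doubling rule was rejected
  because probability ordering is exactly checkable by enumeration).
  Floating-point ties are included with a 1e−12 relative tolerance, which
  matters only for exactly symmetric splits.
* φ < 1e−10 switches to the Poisson log-pmf: at r = 1/φ beyond ~1e10 the
  gammaln differences lose precision, and the Poisson conditional is
  exactly the binomial exact test on (s_A, T) with success probability
  n_A/(n_A+n_B), which is the correct limit.
* Common dispersion is pooled method-of-moments on library-scaled counts:
  within each group E[v − m] = φm² per window, so
  φ̂ = max(0, Σ(v − m) / Σm²) pooled over windows and groups.  Simulation
  tests recover φ = 0.2 within ±0.05 at 10k windows.  With one sample per
  group the moments are undefined and a `dispersion_override` is required.
* log₂ fold change is high-arm over low-arm normalized means with a 0.5
  pseudo-count; group label swap negates it exactly and leaves p unchanged.
* FDR: Benjamini–Hochberg across all tested windows of a comparison
  (via statsmodels).  Thresholding on q is left to configuration because
  no specific FDR cut is built into the method.

Twin pairing is intentionally **not** modeled in the test: the design
compares the low and high discordance arms as independent groups.  The
simulator plants within-pair correlation precisely so the test suite can
show the unpaired analysis remains calibrated (in fact conservative) under
it — the shared pair baseline inflates φ̂ and shifts both arms together.

Known property: a discrete exact test has an atom at p = 1 (the modal
split) of roughly the maximal conditional pmf — about 3% at 30 reads/window
with 8 vs 8 samples.  Tail behavior near p < 0.05 is calibrated (the
fraction below 0.05 sits in its binomial interval), but the full p-value
distribution deviates from Uniform(0,1) by that atom, so
distribution-level uniformity statistics (e.g. Kolmogorov–Smirnov at large
window counts) will flag it.  This is a property of every discrete exact
test, not an implementation defect.

## DMR calling (seed-and-extend)

Windows with p below the seed threshold (default 1e−4) found regions;
edges extend to a fixed point while any window with p below the extension
threshold (default 0.1) lies within the gap distance (default 1000 bp) of
the current span, and seeds bridged by extension windows merge.  "Within
1000 bp" is read strictly — edge-to-edge distance **less than** 1000 bp —
so on a uniform 1 kb grid extension chains only through adjacent windows.
The alternative reading (distance ≤ 1000 bp, letting extension jump one
full intervening window) was implemented and rejected: each DMR side then
has a ~P(p < 0.1) = 10% chance of a two-window boundary jump, which
destroys boundary accuracy on planted regions (measured ~80% of regions
with both boundaries within one window, versus ~100% under the strict
reading).  A DMR records its span, total and significant window counts,
minimum p, CpG density over the span, and the log₂ fold change of its most
significant window (one value per region, matching the tabular convention;
a mean-over-seeds alternative is available via `fc_method`).

Per-threshold summary tables re-run the caller at each seed threshold
(1e−3 … 1e−7 by default) and report all-window and multiple-window (≥ 2
seed windows) counts; counts are monotonically non-increasing with
stringency by construction.

## Annotation and overlaps

* CpG density is CG-dinucleotide count × 100 / span length, recomputed
  from the reference sequence; integer-binned histograms support
  density-distribution summaries.
* Gene association: a region links to every gene whose body expanded by
  10 kb on both sides overlaps it by ≥ 1 bp.  Measuring from the gene body
  (not the TSS) is the only parameter-free reading of "within 10 kb of a
  gene" that covers distal and proximal promoter regions on either strand.
  Intergenic regions are retained unannotated.
* Cluster flags: runs of ≥ 3 DMRs spanning ≤ 2 Mb (both configurable) are
  flagged.  These defaults are explicit configuration for a criterion that
  is inherently visual; they claim nothing about any published threshold.
* Functional categories come from a user-supplied gene→category table
  (live pathway-database lookups are out of scope); unmapped genes count
  as "unknown", so category counts conserve the number of gene links.
* Overlap semantics: two regions overlap when they share ≥ 1 bp; percent
  overlaps use the first (strict) set as denominator, and a member
  overlapping several regions of the other set counts once.  The three-way
  Venn assigns every DMR of every set a membership pattern, so each set's
  marginal equals its cardinality.  Extended overlap re-calls the other
  comparison's DMRs at a relaxed seed threshold (default 0.05) before
  intersecting; because relaxing the threshold only adds seeds, extended
  overlap is monotone in the relaxation.

## Correlation-network stage

Profiles are the RPKM values of the top-N windows (samples × windows).
Raw linear RPKM is used rather than a log transform: on simulated studies
the log transform reduced module recovery, because the multiplicative
module drivers produce shared high-leverage deviations that strengthen
linear-scale correlations.

* **Adjacency**: a_ij = |cor(x_i, x_j)|^β, unsigned; β defaults to 6 for
  female runs and 9 for male runs.  β is taken as given configuration; no
  scale-free fit is performed.  Zero-variance windows are dropped with a
  warning.
* **TOM**: TOM_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
  l_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu; dissimilarity
  1 − TOM feeds average-linkage hierarchical clustering.  The matrix
  implementation is verified against a triple-loop oracle to 1e−12.
* **Module cut**: the reference "dynamic hybrid" tree cut is intricate and
  under-specified; this package uses a simpler, testable rule.  A
  dendrogram branch is a module when it (i) has ≥ `min_module_size` = 30
  leaves, (ii) completes below the 0.99 quantile of merge heights, and
  (iii) is separated from the rest of the tree by a branch gap — the
  distance between the height at which the branch completes and the height
  at which it merges with anything else — of at least
  `min_branch_depth` = 0.005.  Among nested qualifying branches the
  largest gap wins (the module core).  The gap criterion is what makes
  noise yield no modules: a structureless dendrogram's merge heights form
  a continuum, so no branch has a real gap.  Measured regimes that set the
  default: pure-noise branch gaps stay below ~1e−3 at ≥ 32 samples (below
  ~4e−3 at 16 samples), while genuine planted modules (r = 0.7 drivers, 50
  windows, 40 samples) show gaps from ~0.008 upward.  At 16-sample
  cohorts occasional small noise modules can clear 0.005 — a documented
  limitation; module-trait filtering at p < 0.001 removes them in
  practice.  The dendrogram root is admitted as a single module only when
  the whole input is globally tight (completes below 0.97 absolute TOM
  dissimilarity), which matters for blockwise runs where a block may
  consist entirely of one module.
* **No reassignment**: windows outside selected module cores stay grey;
  there is no post-hoc nearest-module reassignment (mirroring a
  reassignment threshold of zero).  Consequently weak modules may carry a
  grey fringe of true members — module recovery is scored by adjusted Rand
  index, not exact membership.
* **Eigengene**: first left singular vector of the z-scored (ddof = 1)
  member profiles, unit norm, sign fixed so the mean correlation with
  members is non-negative.  Verified against an eigendecomposition oracle
  and invariant to member order and affine member rescaling.
* **Merging**: the closest eigengene pair merges while 1 − cor < 0.25,
  recomputing eigengenes each round, so chains collapse to a fixed point
  deterministically (ties break by label order).
* **Module–trait correlation**: Pearson r between eigengene and numeric
  trait across samples, two-sided p from t = r√(n−2)/√(1−r²) on n−2 df.
  All samples are treated as independent (twin pairing ignored at this
  stage, matching the design it implements).  Constant traits give NaN.
  Categorical traits enter as integer codes (codebook written next to the
  traits table).  The p < 0.001 filtered view drops modules and traits
  with no significant entry.  At very small n (≈10) the t-based p and a
  label-permutation p can differ by a few 1e−3 in the tails; the closed
  form is the reported value.
* **Blockwise driver**: above `max_block_size` = 15 000 windows, windows
  are pre-clustered by k-means on their standardized sample-space profiles
  (oversize clusters split recursively, seed-deterministic), modules are
  detected per block, and the global eigengene merge reunites modules
  split across blocks.

## Synthetic-data generator

The generator produces a complete study — reference FASTA, window grid
with exact CpG counts, twin cohort, counts, gene models, category table,
and ground truth — from one seed; fixing the seed fixes every output byte.

Count model for sample s, window w:

    count ~ NB(μ_w · lib_s · exp(pair_s + Δ_ws + m_ws), φ)

* μ_w: mean depth scaled by (0.3 + 0.7·CpG_w/mean CpG) and a log-normal
  wobble (σ = 0.2) — MeDIP coverage tracks CpG density.
* lib_s ~ Uniform(0.7, 1.3): ±30% library-size variation; the recorded
  library size is the column sum (every simulated read is in the grid).
* pair_s ~ Normal(0, 0.3): log-normal baseline shared within a pair — the
  correlation structure the unpaired test does not model.
* Δ_ws = log2fc·ln2 on planted DMR windows for samples in the high arm of
  pairs discordant for the DMR's trait.
* m_ws: module windows load (loading ≈ 0.5) on a driver
  d_s = sign·r·z(trait_s) + √(1−r²)·noise, so the module eigengene
  correlates ≈ r with its trait.

Defaults are the package's standard desk-scale study: 16 pairs per sex,
4 × 2.5 Mb chromosomes (10 000 windows), mean depth 30 reads/window,
φ = 0.1, 20 planted DMRs of 1–5 windows at log₂FC 2, three 50-window
latent modules at r = 0.7, discordance fractions 0.40 / 0.30 / 0.15 for
activity / walkability / BMI (near the reported cohort proportions).  The
first pair of each sex is discordant on every trait and carries the
published example magnitudes (MVPA 66/266 min, walkability 25.7/82.0,
BMI 28.4/35.2), so classifier boundaries are always exercised.  Planted
DMRs keep a five-window buffer from each other and never overlap module
windows, keeping recovery attributable.  Reference windows cycle target
densities of 1–10 CpG/100 bp; backgrounds use the {A, T, G} alphabet so
planted CG dinucleotides are the exact CpG count.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: fragment-level MeDIP enrichment chemistry and
fragment-size effects, mappability and GC bias, CpG-island spatial
structure (densities are i.i.d. across windows), age/cell-composition
covariates, missing data, and realistic trait distributions beyond the
anchored magnitudes.  Recovery results certify the algorithms against
their own generative assumptions, not field performance.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use these standard sizes,
chosen so a complete run finishes in well under an hour on one CPU while
keeping Monte-Carlo noise small: exhaustive exact-test enumeration for
totals ≤ 60; 500-case Poisson-limit grid; 20 000-window null study with
8 vs 8 samples; 20 planted DMRs at depth 30; TOM oracles on 6–10 nodes;
three 50-window modules over 5 000 windows with 40 samples; 100 000 label
permutations per correlation fixture; end-to-end runs on the 10 000-window
default study.

## Known limitations

* The exact test's discreteness makes distribution-level uniformity
  checks fail at large window counts (atom at p = 1), although tail
  calibration holds; see above.
* Dispersion is a single common φ per comparison (optional shrinkage
  machinery exists but defaults to common-only); strongly window-specific
  dispersion is absorbed conservatively.
* Module detection reports cores; fringe members of weak modules stay
  grey, and at 16-sample cohorts small spurious modules can appear.
* TMM-style compositional normalization is out of scope (library-size
  scaling only), as are GLM/multi-factor designs and signed networks.
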