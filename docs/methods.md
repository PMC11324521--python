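# Methods

This note documents the models, estimators and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical conventions that matter for reproducing results.

## Quality control and normalization

Barcode metrics are computed once on the raw matrix: total UMI counts,
number of detected features (count > 0), percent of counts in a
user-supplied mitochondrial gene set, percent in a hemoglobin set, and
*complexity* = log10(n_features)/log10(total_counts). Complexity is
undefined (and fails the filter) for barcodes with fewer than 2 total counts
or no expressed gene, which avoids dividing by log10(1) = 0. A barcode is
kept iff total ≥ 1,000, features ≥ 800, mito % < 15, hemoglobin % < 5 and
complexity > 0.8 (strict inequalities on the percentage and complexity
bounds; all thresholds configurable). A gene is kept iff it has ≥ 10 counts
across ≥ 10 distinct barcodes. Both filters are single-pass on the raw
matrix — removal of a barcode never re-triggers gene filtering and vice
versa — so the kept sets are order-independent by construction. Note that a
gene with fewer than 10 total counts can never reach 10 distinct barcodes,
so the two gene rules are nested on that side.

Depth normalization uses median-library-size factors: s_c = total_c /
median(total). Pooled deconvolution factors (scran-style) are deliberately
not reimplemented; for the synthetic data used here, library size is the
only depth confounder, and the downstream scores depend only on ratios of
group means, which any cell-wise scaling of this form serves equally. One
consequence worth knowing: depth normalization introduces a composition
effect — if a handful of genes carry a large share of a cell's counts and
change between conditions, the size factors absorb part of that change and
group-mean ratios are biased toward zero. The validation configurations keep
perturbed genes a small fraction of the library (as in real data), where the
bias is negligible.

HVG selection ranks genes by the variance of log1p-normalized expression,
ties broken lexicographically by gene id so selection is deterministic; the
method is intentionally simple since no particular HVG statistic is baked
into the downstream scores. Scaling standardizes each gene with the
population (ddof = 0) standard deviation and caps values at +10 with no
lower cap; zero-variance genes map to zeros.

## Ligand–receptor database handling

The pair table needs `ligand` and `receptor` columns. Reversed duplicates —
(A,B) present together with (B,A) — collapse to the first-seen orientation.
Pairs are dropped when either gene is absent from the matrix (with a
warning) or expressed in fewer than 10% of all analyzed cells, the fraction
being computed on the pooled cell set (not per condition). Multi-subunit
complexes are out of scope; complex resources should be split to gene-level
pairs upstream.

## LRI permutation test

Observed scores are products of per-(cell type, condition) arithmetic means
of the **non-log** normalized matrix (a log1p matrix can be supplied, but
products of log-scale means have no clean interpretation). Cell-type labels
are permuted within each condition stratum by default, because scores are
defined per condition and shuffling across conditions would mix two
exchangeability questions; a global-shuffle mode is available. One shared
permutation sequence, fixed by the seed, serves every record — this is what
makes end-to-end determinism cheap and means recomputation is O(n_perm)
group-mean passes rather than per-record work. p = (number of permuted
scores ≥ observed)/n_perm exactly; zero p-values are possible and are only
clamped where a downstream logarithm needs them. An optional
(count+1)/(n_perm+1) estimator is off by default. The z-score is
(observed − permutation mean)/permutation sd (population sd; defined as 0
when the sd is 0, e.g. for a constant matrix). BH correction pools all
(sender, receiver, pair, condition) records into a single vector.

## Condition-differential test

LRIDiffScore = (log2(Lmean_cKO/Lmean_control) + log2(Rmean_cKO/Rmean_control))/2,
with ε = 1e-9 added to every mean inside the ratios; with ε = 0 a
structurally zero mean yields an undefined, flagged record rather than ±∞.
The score is exactly antisymmetric under swapping the condition roles.
Condition labels are permuted within each cell-type stratum by default,
preserving per-type group sizes (a global mode exists). The tail of the
permutation distribution is taken on the observed side of zero.

The tail fraction itself is then **doubled** (capped at 1) to form the
reported p. This choice deserves a paragraph: selecting the tail after
seeing the sign of the observed score makes the raw tail fraction uniform on
(0, 0.5) under a symmetric null — a nominal 0.05 threshold would reject 10%
of true nulls. Doubling restores a uniform null distribution (verified
empirically here to a rejection rate of ~0.05 and KS distance < 0.03 from
uniform at ~2,400 null records), while the direction of change is carried by
the score's sign. The raw one-tailed fraction remains available via
`PermutationConfig(condition_tail="one_sided")` for comparison with
pipelines that define the p that way. BH pools all (sender, receiver, pair)
records.

Condition order matters for the sign convention: functions take
`conditions=(control, treatment)` and default to lexicographic order when
unspecified, so passing the tuple explicitly is recommended.

## Significance filter

A differential record is significant when (a) its LRIScore p.adj is ≤ 0.05
in at least one condition, (b) its differential p.adj is ≤ 0.05, and (c)
|LRIDiffScore| ≥ 1. A directional variant replaces (c) with score ≥ 1.
Geometry of the score worth knowing: one partner changing 4-fold with the
other unchanged gives |diff| exactly 1, i.e. the magnitude gate sits on the
boundary of strong single-partner shifts.

## Pseudobulk differential expression

Counts are summed per (group, sample); the grand total is conserved. The
two-group test is a negative-binomial Wald test: DESeq-style
median-of-ratios size factors; per-gene method-of-moments dispersion from
Var(K/s) = q/s + αq² with an n/(n−2) degrees-of-freedom correction and a
floor of 1e-8; a log-link NB GLM (intercept + group indicator, offset
log s) fitted by vectorized IRLS across all genes simultaneously; Wald
z = LFC/SE against the normal reference; BH over tested genes. Group means
of zero are floored at half a count over the group's summed size factors so
fits stay finite. Because the raw gene-wise dispersion estimate is noisy at
pseudobulk sample sizes (and underestimation inflates type-I error), the
working dispersion is the maximum of the gene-wise estimate and a parametric
mean-dispersion trend α(μ) = a₀ + a₁/μ fitted across genes — a conservative
form of the trend-moderation used by established bulk DE tools. Measured
type-I error at 4+4 samples over 2,000 null genes is ~0.04 with 4-fold
sensitivity ≥ 0.96. This is deliberately a plain, documented NB Wald test:
no shrinkage of fold changes, no outlier refitting, and no intent to
reproduce any specific DE tool's decimals.

One-vs-many aggregation takes the arithmetic mean of per-comparison log2FCs,
combines the per-comparison **adjusted** p-values with Fisher's method
(−2Σln p on χ²(2k); zeros clamped to the smallest positive double), and
counts comparisons with log2FC > 2. Combining adjusted p-values is
statistically unconventional but is the documented behavior of the
aggregation this package reproduces; `use_adjusted=False` combines raw
p-values instead. Genes enter testing only when expressed in ≥ 20% of cells
of the respective group in either condition (10% variant available).

Radial-plot preparation emits, per (cell type, condition) quadrant, every
gene of the filtered universe, with negative log2FCs clipped to 0 and their
adjusted p reset to 1.

## Pseudotime gene modules

Pseudotime is an input (trajectory inference is out of scope; the generator
supplies true pseudotime, and a rank-along-a-marker fallback exists for
demos). Cells sort by (pseudotime, cell id) — the id tie-break makes binning
deterministic — and split into 21 bins of equal cell numbers, the remainder
going to the earliest bins; the assignment is invariant to any strictly
monotone transform of pseudotime. Per-gene profiles are per-bin means
z-scaled across bins (bin-then-z; z-then-bin is the natural alternative and
can be obtained by scaling before calling). Zero-variance profiles are
dropped and reported. Edges connect gene pairs with Pearson r strictly
above 0.5, weighted by r; Leiden clustering (RB-modularity, resolution 1,
seeded) yields modules, with isolated genes labeled "unclustered". Module
summaries report per-bin member means with a 95% normal band
mean ± 1.96·sd/√m (population sd, so single-gene modules get a zero-width,
flagged band); the same normal band across cells is available per gene.

## Synthetic data generator

Counts are gamma-Poisson: K ~ NB(mean = s_c · μ[g, type, condition, t],
size θ) with Var = μ + μ²/θ. Defaults: baseline mean 0.5 expected counts
per gene per cell, θ = 2 (strong overdispersion typical of UMI data at this
expression level), log-normal per-gene (σ = 1.0) and per-(gene, type)
(σ = 0.8) factors so cell types have genuine marker structure for label
permutations to detect, and log-normal size factors (σ = 0.3) normalized to
unit mean. Ligand/receptor genes (planted and background) get a fixed
baseline of 2.0 with a 2-fold sender/receiver elevation
(`marker_elevation`) applied in both conditions — ligands are expressed by
their sender population, which is what gives the cell-type permutation test
real signal — while planted fold factors multiply the relevant
(type, condition) means only. Trajectory modules multiply means of lineage
cells by a profile of true pseudotime t ~ U(0,1): logistic in t with
midpoint 0.5 (up/down), Gaussian bump at 0.5 (σ = 0.15), or flat, spanning
an 8-fold range by default. Cells are assigned uniformly to samples within
their condition.

The generator emulates: NB overdispersion, library-size variation, type- and
gene-level mean structure, two-condition planted communication shifts, and
smooth temporal programs. It does **not** emulate batch effects, doublets,
ambient RNA, donor hierarchies, zero-inflation beyond NB, or gene–gene
correlation within a cell beyond shared means — so passing tests demonstrate
correctness and calibration of the statistics under the stated model, not
robustness to those artifacts in real data.

## Validation configurations

The acceptance checks use problem sizes chosen to give stable Monte-Carlo
estimates at interactive runtimes: exact-enumeration comparison on 6 cells /
2 types / C(6,3)=20 assignments against 5,000 sampled permutations; null
calibration on 2,000 cells, 300 genes, 50 pairs, 1,000 permutations, three
replicates; planted recovery with 20 interactions (true diff 1.2/1.5/2.0,
ligand = receptor fold = 2^diff) at 200 cells/type/condition over 2,000
genes; DGE calibration on 4+4 pseudobulk samples over 2,000 genes; module
recovery with three 50-gene programs among 500 noise genes over 1,000
lineage cells. Planted-recovery accuracy is reported as mean absolute error
of the diff score: at 200 cells/group and θ = 2 the per-record sampling sd
is ~0.08–0.1, so aggregate error is the meaningful precision statement.
Module-recovery ARI is computed over the genes that carry a planted program
(noise genes have no true module label).

## Known limitations

- Median-library-size normalization carries the composition bias discussed
  above; for heavily perturbed libraries, supply externally computed factors.
- The NB Wald test is unmoderated beyond the dispersion trend; with fewer
  than 3 samples per group its inference is unreliable (a warning is
  emitted at 1).
- Permutation p-values have resolution 1/n_perm; significance claims at
  p.adj ≤ 0.05 across thousands of records need n_perm ≥ a few thousand.
- LR complexes, pathway aggregation and spatial constraints are out of
  scope.
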