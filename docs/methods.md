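# Methods

This note documents the statistical procedures implemented in
`lineagescreen`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic generators do and do not emulate, and
the design decisions taken where several readings were defensible. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## Bulk screen scoring (`bulk_screen`)

**Model.** A screen is a guides × samples integer count matrix; each sample
is one sorted population in one arm (Cas9 or non-Cas9) of one
differentiation system, possibly in replicate. Biological replicates are
merged by summing counts. The per-guide lineage score for a population pair
(A, B) is the difference of log2 CPMs, s = log2CPM(B) − log2CPM(A),
computed separately per arm. Guides only produce knockouts in the Cas9 arm,
so the non-Cas9 scores form an empirical background: the Cas9 scores are
centered and scaled by the background mean and standard deviation
(ddof = 1), two-sided standard-normal tail probabilities are attached, and
BH-adjusted within each comparison. These probabilities are calibrated
against the *pooled* background, not per guide; guides with atypically low
abundance have wider sampling noise than the pooled σ, which is an inherent
property of the scheme, not an implementation artifact. Gene-level calls
(≥ 50 % of guides significant) absorb most of that heterogeneity, which is
what the null-calibration and specificity checks in `tests/test_acceptance.py`
quantify.

**Normalization.** TMM factors are estimated on NTC guides only. A
deliberate subtlety: the M- and A-values of the NTC rows are computed
against the **full-sample library sizes**, not the NTC-subset column sums.
Subset-internal library sizes would cancel any compositional shift between
targeting guides and controls — exactly the signal NTC-anchored
normalization exists to preserve (a screen in which many targeting guides
genuinely deplete would otherwise push a spurious shift into every score).
Parameters follow the method's conventional defaults: reference sample =
the one whose upper-quartile subset abundance is closest to the mean;
log-ratio trim 0.30; magnitude (A) trim 0.05; inverse-asymptotic-variance
weights; trim ties broken by midpoint (average) ranks; factors rescaled to
geometric mean 1. The implementation agrees with an independent direct
evaluation of the formula to 1e-9 and with edgeR's `calcNormFactors` to the
printed precision on frozen fixtures.

**Log CPM.** Counts are transformed as
log2((count + p_j) / (L_j + 2 p_j) · 1e6) with L_j the effective library
size (column sum × factor) and p_j = 0.5 · L_j / mean(L) a library-size-
scaled prior count, so equal proportions map to equal values at any depth
and zero counts remain finite. Guides with zero counts in both populations
are retained; a minimum-count filter exists in config but defaults to off.

**Multiple testing.** BH is implemented directly with the canonical step-up
arithmetic q_(i) = min_{j≥i} min(1, p_(j)·m/j) so that it matches the
definition exactly (bit-for-bit); it is cross-checked against statsmodels
to 1e-12. The family is all guides of one comparison in the Cas9 arm —
each comparison is an independent screen readout. Whether one should pool
across systems instead is not determined by the scheme itself; per-
comparison adjustment is the default and the family is easy to change
upstream of `bh_adjust`.

**Background choice.** The non-Cas9 background uses *all* guides of the
non-Cas9 arm (targeting + NTC), since no effective knockout occurs there;
an NTC-only background is available via `background_ntc_only`.

## Single-cell statistics (`sc_perturb`)

**QC.** Per sample, the 90th percentiles of UMIs and detected genes are
computed once over all cells; cells below 20 % of either percentile are
removed, with absolute floors of 1,000 UMIs and 500 genes (the floors and
the percentile rule combine via max). Cells above 10 % mitochondrial reads
are removed; exactly 10 % is kept (strict inequality). Thresholds are never
re-estimated after filtering, so the filter is idempotent on its own kept
set when the thresholds are passed back in.

**Guide assignment.** A cell is assigned the guide carrying ≥ 75 % of its
guide UMIs; with several detected guides at most one can reach that
fraction, and cells with no guide reaching it (or no guide reads at all)
stay unassigned. For permissive thresholds ≤ 0.5 the lexicographically
smallest top guide breaks ties, keeping assignment order-independent.

**Minor-label cleanup.** Within each cluster, cell-type labels carried by
fewer than 10 % of the cluster's cells are reassigned to the cluster's
modal label (modal ties break lexicographically and are logged); exactly
10 % is untouched.

**Enrichment.** For each (target sgRNA, cell type, NTC guide), the 2×2
table (target, NTC) × (in type, out of type) is tested with the two-sided
Fisher exact test (point-probability rule, as in the standard
implementations). Cell types with fewer than 5 NTC cells are excluded, as
are cell types whose NTC share is below 25 %. The 25 % rule's denominator
is ambiguous in prose ("less than 25 % NTCs"); it is implemented as the
NTC fraction *of the cell type's cells* and exposed in config
(`min_ntc_fraction`) — with few targets per batch this reading is
attainable, and it is the stricter guard against enrichment artifacts in
clusters dominated by knockouts. The odds ratio is reported as the sample
OR (a·d)/(b·c); when any cell is zero, the reported log2 OR uses the
Haldane–Anscombe +0.5 on all four cells, while the p-value is always
computed on the raw counts. q-values are BH over all emitted tests of the
dataset. Tests run per sgRNA, not pooled per gene; the (gene, cell type)
summary is the mean log2 OR and the percentage of significant
(sgRNA × NTC) tests.

**Viability.** Day-14 cells per target and pre-infection pool reads per
target are CPM-transformed with a 0.5 pseudo-count and each normalized to
the NTC value; lfc = log2(pool_norm / day14_norm), so positive values mean
loss of knockout-bearing cells relative to NTCs and the NTC row is 0 by
construction. The prose defines this score only through its sign
convention; the formula direction here is the one that honors it.

## Trajectory (`trajectory`)

PCA is deterministic (SVD with the largest-|loading| sign convention) and
returns the explained-variance spectrum for elbow inspection; the default
of 8 components mirrors the elbow choice used in the source workflow.
Query cells are projected with the reference loadings — the shared-basis
contract replaces the joint batch-aligned PCA of the original workflow,
since batch alignment is out of scope here.

Diffusion pseudotime on the reference (NTC) cells: Gaussian kernel on the
symmetrized kNN graph (k = 30) with per-cell adaptive bandwidth (distance
to the ⌈k/2⌉-th neighbor), density normalization (α = 1), and the
symmetric conjugate of the row-stochastic operator. The top n_dcs = 10
non-trivial eigencomponents — largest *algebraic* eigenvalues, i.e. the
slow diffusion modes, not large-magnitude oscillatory ones — are
accumulated with weights λ/(1−λ), and pseudotime is the diffusion distance
from the root in that space; the root maps to 0. Eigenvector signs are
fixed and the Lanczos start vector is constant, so results are
bit-reproducible. A disconnected kNN graph is an error (naming the
component sizes), not a silent per-component computation.

Transfer assigns each query cell the arithmetic mean pseudotime of its
k = 15 nearest reference cells (Euclidean, first 8 PCs); the transferred
value is therefore always inside its neighbors' range. Coordinate
projection works the same way with k = 20 on the reference 2-D
coordinates. Per-branch scaling maps pseudotime affinely to [0, 1]
(degenerate branches to 0) and is applied after transfer, following the
order of operations in the source description.

## Peak rules (`peaks`)

Differential peaks: |log2 FC| > 0.75 and adjusted P < 0.01, both strict,
plus abundance floors of 2 CPM and 10 reads required in **both** compared
conditions (the stricter reading of "in the compared conditions"). The
three-way classes: gained (LFC > 1 → leukemic), lost (LFC < −1 → normal),
shared (|LFC| < 0.5 → common). Peaks in the 0.5–1.0 magnitude gap are
reported as `unclassified` rather than silently dropped or merged, since
their treatment is unspecified. Intervals are 0-based half-open internally;
1-based input is converted with an explicit flag.

## Synthetic data (`simulate`)

The bulk generator draws guide pool abundances log-normal(0, 1) — a
generic pooled-library dispersion — shared by both arms, multiplies
population-B Cas9-arm abundances of an effect gene's guides by 2^δ, and
samples reads multinomially at fixed depth per replicate (default
2 × 10^6, two replicates, 200 genes × 4 guides + 200 NTCs). It captures
exactly the error source the scoring scheme is built around (sampling
noise against an effect-free arm) and deliberately omits
infection/culture overdispersion, guide-efficiency variation and
chimeric reads; calibration results on it therefore bound the sampling
component of the real error, not the biological one.

The single-cell generator draws one true guide per cell, negative-binomial
guide UMIs (mean 20, dispersion 0.5, floored at 1) plus a Poisson ambient
pool spread uniformly over all guides — parameters chosen so the 75 % rule
is stressed near its boundary at moderate ambient rates. Cell-type
membership reweights baseline probabilities by the designed odds ratio and
renormalizes, which yields exactly the designed OR when a single type is
modified. QC covariates place passing cells safely above the adaptive
thresholds and failing cells (designed fraction, default 7 %) in a
low-depth or high-mito mode, so the removed fraction tracks the design.
The trajectory is a smooth injective curve in PC space (two post-split
branches that are mirror images, hence equal arc-length speed) with
isotropic Gaussian noise (σ = 0.05) and latent time uniform on [0, 1]. It
is not a transcriptome simulator: expression content exists only to
exercise QC, PCA, pseudotime and assignment.

All generators take a single seed, return their truth object alongside the
data, and are byte-reproducible.

## Problem sizes and numerical choices

The shipped checks use the design sizes above (1,000 guides × 20 or 10
seeds for calibration/recovery; 1,000 cells per target × 20 seeds for OR
recovery; 2,000 + 2,000 cells × 20 seeds for pseudotime; an exhaustive
sweep of 2×2 tables with margins ≤ 30 in the test suite and ≤ 20 in the
acceptance script), chosen as the smallest sizes at which the measured
quantities are stable across seeds. Degenerate inputs fail loudly
(zero-spread background, empty TMM subset, disconnected graphs,
k exceeding the reference size, NaN p-values) rather than returning
defaults.

## Known limitations

* The guide-level probabilities are calibrated against the pooled
  background; per-guide calibration would require abundance-dependent
  variance modeling, which the scheme intentionally avoids.
* The shared-PCA-basis contract for query projection assumes batches have
  been harmonized upstream; none of the modules corrects batch effects.
* Branch labels are inputs everywhere; no branch detection is performed.
* The enrichment module treats cluster/cell-type labels as given; label
  transfer, clustering and doublet removal are out of scope.
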