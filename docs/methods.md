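# Methods

This document states the models implemented by `hotregions`, the parameters
they expose, what the synthetic data generator does and does not emulate, the
numerical choices that pin down exact results, and the known limitations.

## 1. Region calling (`hotregions.calling`)

**Model.** Peak summits are pooled across many ChIP-seq experiments. Summit
density is counted in sliding windows (width `window_size` = 500 bp, step
`step` = 50 bp, 0-based half-open `[start, start + window)`), per chromosome;
the final windows are truncated at the chromosome end. The density track is
reduced to its local maxima with non-maximum suppression: a window is a
candidate only if its count equals the maximum over every window whose start
lies within ± `suppression_span`/2 of its own (so no retained window is
dominated by a neighbour), candidates are then selected greedily by
descending count with ascending-position tie-break (leftmost equal maximum
wins), and each selection suppresses its neighbourhood. The result is
idempotent and zero-count windows are never returned.

Retained windows are ranked genome-wide by summit count ("TF occupancy").
The occupancy percentile is the mean-rank percentile, `rank / n × 100` with
mean rank for ties. A region is **HOT** iff its percentile is strictly above
`hot_percentile` (99), **MILD** above `mild_percentile` (75) but not HOT,
**COLD** otherwise. Control regions for modelling are sampled below
`control_ceiling_percentile` (85).

**Parameters.** `window_size=500`, `step=50`, `suppression_span=2000`
(human) or `1000` (other species — used for the megabase-scale synthetic
genomes), `hot_percentile=99`, `mild_percentile=75`,
`control_ceiling_percentile=85`.

## 2. Sequence features (`hotregions.features`)

Each region is represented by 339 features computed on a 2000 bp window
centred on the region midpoint (clipped at chromosome ends):

* all 2-, 3- and 4-mer frequencies (16 + 64 + 256): counts over the N-free
  length-k windows divided by the number of such windows;
* `cpg_freq` = (count(C) + count(G)) / L with L the nominal window width
  (2000), so edge-clipped windows share a denominator;
* `cpg_oe` = N(CG) · L / (N(C) · N(G)) with L the actual sequence length
  (the Gardiner-Garden observed/expected form); 0 when C or G is absent;
* `gc_skew` = (G − C) / (G + C); 0 when the window has no G or C.

Features are computed on the reference strand only. Matrices are
column-standardized with the population (ddof = 0) standard deviation;
zero-variance columns are left at 0 and reported.

## 3. Discrimination model (`hotregions.model`)

**Model.** Penalized logistic regression with the elastic-net penalty,
fit per dataset on standardized features of HOT regions versus an equal
number of controls sampled below the 85th occupancy percentile, optionally
CpG-island-matched (the number of CGI-overlapping controls is
`round(|HOT| × HOT CGI-overlap fraction)`). Implementation: scikit-learn
`LogisticRegression(solver="saga")` with `C = 1 / (n·λ)` mapping to the
glmnet per-observation penalty, walked along a geometric λ path (15 points
from `λ_max = max|Xᵀ(y − ȳ)| / (n·α)` down to `10⁻³ λ_max`) with warm
starts, strongest penalty first.

**Selection and reporting.** λ is chosen at the minimum mean out-of-fold
deviance over 10 stratified CV folds; `cv_auc` is the mean per-fold
out-of-fold rank-based AUC at the chosen λ; the reported model is the refit
on all data at that λ. Variable importance is `100·|coef| / max|coef|`
per model, averaged across models with missing features counting 0; the
top-10 features feed a 2-component PCA on the standardized submatrix.

**Parameters.** `alpha=0.5` (mixing), `folds=10`, `n_lambdas=15`,
`max_iter=5000`, `tol=1e-4`, seeded fold assignment.

## 4. Signal enrichment (`hotregions.enrichment`)

Per-region enrichment is `log2((ip_cpm + ε) / (control_cpm + ε))` where
CPM = overlap count / library size × 10⁶, a read overlaps a region on any
≥ 1 bp intersection, and ε defaults to the mean one-read CPM of the two
libraries. Per-bp tracks use difference-array coverage (CPM-scaled) and
elementwise log2 with ε = 1.

Profile heatmaps: windows are sampled per occupancy stratum
((0, 75], (75, 99], (99, 100], 3000 each, shortfalls recorded), each
window's per-bp track is averaged into 50 equal bins (windows whose width
is not a multiple of 50 are padded symmetrically with missing values;
off-chromosome parts are missing), rows are ordered by descending
occupancy, and the whole matrix is winsorized at its own 0.5th/99th
percentiles. Reads can be extended to 200 bp in a stranded fashion
(`+`: `[start, start+200)`, `−`: `[end−200, end)`, clipped; library size
unchanged). Score agreement between two region scorings uses Spearman
rank correlation with mid-rank ties.

## 5. Methylation dynamics (`hotregions.methylation`)

Per region and cell type, methylation is the unweighted mean of per-CpG
methylated fractions at positions in `[start, end)`; regions covering no
CpG are missing and excluded. Per cell type a region set is summarized by
the median and IQR (linear-interpolation quantiles) of its region means.
The headline comparison is
`median over cell types(IQR of non-HOT CpG islands) / median over cell
types(IQR of HOT regions)`, where non-HOT CpG islands have zero overlap
with any HOT region; the ratio is infinite when every HOT IQR is 0.

## 6. Synthetic data (`hotregions.simulate`)

Every analysis has a generator that plants known truth and emits files in
the same formats the analysis reads (FASTA, narrowPeak, BED6, per-CpG
tables), plus `truth.json`.

* **Genome**: i.i.d. bases at GC 0.41 with CpG depletion (each CG keeps its
  G with probability 0.25, otherwise the G becomes A/T), giving the
  human-like background CpG O/E ≈ 0.25. Two locus classes are planted on a
  jittered non-overlapping grid: `hot` loci (GC 0.60, no CpG depletion —
  HOT regions are the densest promoter CpG islands) and ordinary `cgi`
  loci (GC 0.50, CpG keep 0.55). Loci are 1500 bp so they dominate the
  2000 bp feature window.
* **Peaks**: per experiment, each hot locus receives a summit with
  probability `p_hot` = 0.6 (cgi loci `p_cgi` = 0.03), jittered by a
  truncated normal (SD 50 bp, ±3 SD), over a homogeneous Poisson background
  of 20 summits/Mb.
* **Reads**: the control library is uniform; the IP library is uniform plus
  a multinomial excess over the planted loci whose mass is
  `x_r = (fc − 1)·q_r / (1 − Σq)` with `q_r` the probability a uniform read
  intersects region r, so the expected CPM ratio is exactly `2^log2_fc`.
* **Methylation**: per region and cell type, a mean is drawn from a Beta
  distribution numerically matched (least squares on the quartiles) to a
  planted (median, IQR) — HOT (0.05, 0.05), non-HOT CGI (0.05, 0.18),
  planted IQR ratio 3.6 — with clipped Gaussian per-CpG noise (SD 0.02) at
  10 evenly spaced CpGs per region shared across cell types.
* **Truth**: planted loci with kinds, probabilities, fold change,
  methylation parameters, and the list of k-mers the hot-locus sequence
  model enriches ≥ 1.5× over the background model (estimated from the
  generators themselves).

**Not emulated**: sequencing error, mappability, GC bias, fragment-length
distributions, diploid genomes, antibody quality differences between
experiments, chromatin-state covariates.

## 7. Problem sizes (the package's own choices)

The default bundle is 5 chromosomes × 1 Mb, 40 planted hot loci, 150 cgi
loci, 100 experiments, 10⁶-read libraries, 20 cell types. At these
conditions the caller retains ≈ 4200 regions, so the strict top-1% HOT set
(≈ 42 regions) contains all 40 planted loci plus a couple of background
regions — the planted loci are the top percentile by construction. The
bundle builds in ≈ 7 s and the full pipeline runs end to end in ≈ 25 s on
one CPU; the whole synthetic analysis sits far below the 10-minute budget.
Cell-type count 20 was chosen by a power analysis of the IQR-ratio
estimator (sd ≈ 0.24 at 20 cell types against a ±20% band of halfwidth
0.72, a ≈ 3σ margin).

## 8. Numerical choices

* Coordinates are 0-based half-open everywhere, on disk and in memory.
* Occupancy percentile uses mean ranks (`scipy.stats.rankdata`,
  "average") and strict `>` thresholds; all-equal occupancies yield zero
  HOT regions.
* Quantiles are linear-interpolation (NumPy default, type 7).
* Standardization uses the population standard deviation (ddof = 0).
* The elastic-net deviance is the mean out-of-fold binomial log loss; AUC
  is rank-based (Mann–Whitney).
* Interval overlap counting uses sorted `searchsorted` arithmetic
  (`count = n − #starts ≥ end − #ends ≤ start`), exact for half-open
  intervals.
* All generators take explicit integer seeds; bundle sub-seeds derive from
  one master seed through `numpy.random.SeedSequence.spawn` reduced mod
  2³¹.

## 9. Limitations

* The classifier is a linear model on k-mer composition; it cannot express
  positional or strand-specific motif structure.
* cv_auc on ~80-row training sets has a sampling SD of a few hundredths;
  single-seed values should be read with that uncertainty.
* The enrichment estimator's ε pseudocount biases log2 ratios toward 0 for
  regions with few reads; the planted-recovery property documents the bias
  as < 0.05 at ≥ 500 expected reads/region.
* The methylation comparison treats cell types as exchangeable replicates;
  no covariance between cell types is modelled.
* No multiple-testing machinery: the package quantifies and visualizes; it
  does not assign significance to individual regions.
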