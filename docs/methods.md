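# Methods

## Scope and model

`spathet` quantifies intratumor heterogeneity in spatially resolved
single-cell proteomics (multiplexed immunofluorescence) at two scales.  The
input is a per-cell table per tissue sample: cell id, sample id, centroid
(x, y), segmented area, a slide-registration quality score in [0, 1], and one
nonnegative intensity per marker.  Markers are grouped into small ordered
panels ("hallmark sets"); the marker order within a set is arbitrary but
fixed, because the state code depends on it.

**Quality filtering.**  Cells with quality score strictly greater than 0.85
are retained (the threshold is configurable).  "Above" is read literally: a
score exactly at the threshold is removed.

**Ordinal quantization.**  Each marker is quantized into low (0), medium (1),
high (2) at its empirical 33rd and 67th quantiles, computed with linear
interpolation between order statistics.  The boundary convention is
upper-half-open: `v ≤ q33 → 0`, `q33 < v ≤ q67 → 1`, `v > q67 → 2`; with tied
data, ties at a threshold consistently fall in the lower level.  Thresholds
are fit by default over all quality-passing cells of the cohort (both
subject groups pooled): heterogeneity comparisons across samples require a
common state definition.  Per-sample thresholds are available
(`scope="per-sample"`) and recorded in all outputs; note that per-sample
tertiles on a molecularly uniform sample force approximate 1/3 level
occupancy and hence inflate its apparent diversity — another reason the
cohort scope is the default.  A constant marker (q33 = q67) is flagged
degenerate and maps every cell to level 0, adding no spurious diversity.

**Molecular states and heterogeneity.**  A cell's molecular state over an
m-marker set is `code = Σ_j level_j · 3^j` (j = 0 least significant), a
bijection onto {0, …, 3^m − 1}; `Nm = 3^m`.  Sample-level molecular
heterogeneity is the normalized Shannon entropy of state frequencies,
`−Σ Pm_i ln Pm_i / ln Nm`, summing over observed states (0·ln 0 := 0).  It is
0 when all cells share a state and 1 for the uniform distribution over all
Nm states.  Natural logarithms are used throughout; normalization makes the
base irrelevant.

**Neighbor graph and spatial heterogeneity.**  Cells are approximated as
circles, `r = sqrt(area/π)`.  Two cells of one sample are neighbors when
`dist < 1.3 · (r_i + r_j)` (strict).  Candidate pairs come from a k-d tree
queried at the maximal contact distance `1.3 · 2 r_max` and are filtered by
the exact pairwise rule, so the edge set is identical to the O(n²)
computation at every n (tested to n = 500).  A cell's spatial state is the
number of its neighbors in exactly the same molecular state (all markers
equal; zero neighbors is a valid state).  Spatial heterogeneity is
`−Σ_k Ps_k ln Ps_k / ln(Z_max + 1)` over k = 0..Z_max, where Z_max is the
maximum degree observed in that sample, as measured in the tissue.  When
Z_max = 0 (all cells isolated) the formula is undefined (ln 1 = 0); only one
spatial state exists, so the metric is defined as 0.  Because Z_max is
per-sample, the metrics are comparable only as normalized quantities.
Samples are processed per tissue core; when several cores per patient exist,
`pool_by_patient` reports the per-patient mean alongside the per-core values.

## Phenotype clustering

Clustering operates on log2-transformed intensities (pseudocount 0 for
positive data, 1.0 when zeros are present).  "Trimming at both 2.5% tails"
is implemented as winsorization — values outside the per-marker 2.5th/97.5th
percentiles are clipped to the bound — so the cell set stays intact for the
downstream spatial and composition analyses; a cell-removal variant
(`mode="trim_cells"`) exists.  Standardization statistics (overall marker
mean and SD) are computed after trimming.  Zero-variance markers are flagged
and excluded.

K-means (squared-Euclidean, best of 10 random starts per K, K = 2–15 by
default) records silhouette width, the Calinski–Harabasz criterion and the
within-cluster SSE per K.  Consensus clustering subsamples once to at most
5,000 cells, then per iteration draws 80% of them without replacement and
runs K-means; the consensus matrix is co-clustering counts divided by
co-sampling counts, with never co-sampled pairs reported missing (NaN), not
zero.  Defaults (5,000 cells, 1,000 iterations, 80%) match standard
practice; tests and the acceptance script reduce iterations to 20–50, which
is sufficient for the constructed separations they check.

**Choice of K.**  The recommended K is the one with maximal *consensus
sharpness* — the fraction of pair consensus values ≤ 0.1 or ≥ 0.9 — with Ks
within 0.01 of the maximum tie-broken by silhouette.  This was a genuinely
open design point: the alternative "smallest K where the consensus CDF area
gain flattens" proved non-robust, because on clean mixtures the area gain
decays smoothly (e.g. 0.040 → 0.026 per K on a 4-blob mixture) with no
threshold that separates flattening from creep.  Sharpness peaks where pair
co-clustering is near-deterministic; the silhouette tie-break resolves
plateaus (merging two clean clusters can be as deterministic as keeping them
apart).  The report always includes the full per-K table (SSE, silhouette,
Calinski–Harabasz, consensus CDF area and gain, sharpness) plus flags:
`criteria_disagree` when the silhouette optimum differs from the
recommendation and `unreliable` when no K reaches silhouette 0.25 (a single
multivariate Gaussian blob scores well below this at any K).  The rule never
auto-selects silently.

Cluster profiles are per-cluster per-marker mean deviations from the
population mean in the analysis space (size-weighted deviations sum to zero
per marker), with the percentage of cells per cluster — the "lollipop"
rendering.  Sample compositions are per-sample cluster fractions (rows sum
to 1).

## Group comparisons and integration

All tests operate on per-subject summaries, never per-cell values.
`compare_means` is the unpaired pooled-variance Student's t-test (Welch by
flag); zero pooled variance is an error rather than a NaN.  `compare_ranks`
is the two-sided (or one-sided) Mann–Whitney U: the exact null distribution
is enumerated when both groups have ≤ 20 subjects and the data are tie-free,
otherwise the normal approximation with continuity correction is used.
P-values are reported unadjusted by default, matching standard practice for
cell-level comparisons; a Benjamini–Hochberg helper (`apply_fdr`) is
available for feature panels.  Replicate agreement (e.g. slide-to-slide) is
the Pearson correlation.

For multimodal integration, per-subject features are discretized to
low/medium/high.  "Based on the data ranges" is ambiguous between equal-width
and quantile bins, so both are implemented and labelled in the output:
`range-thirds` (default) uses three equal-width bins over [min, max],
half-open above, with the maximum assigned high; `tertiles` uses the
33rd/67th quantiles with the same upper-half-open convention as the marker
levels.  A constant feature is assigned medium and flagged.  Subjects are
then clustered agglomeratively on Euclidean distances of the ordinal (0/1/2)
vectors; the linkage is average by default (only the distance metric is
dictated by the analysis; the linkage is configurable and recorded), and the
merge tree is exported as Newick plus a leaf order.

## Synthetic-data generator

The generator emulates segmented MxIF cell tables, not images: per sample it
draws `cells_per_sample` centroids uniformly in a rectangular field
(default 1000 × 1000 units, 2000 cells — cell densities comparable to a
tissue core at the default radii), truncated-normal cell radii (mean 5,
SD 1.5, r > 0; area = πr²), uniform quality scores in [0.7, 1.0], and
log-normal marker intensities: `2^N(μ_pm, σ)` for latent phenotype p and
marker m, with σ = `marker_log_sd` = 1 on the log2 scale on which clustering
operates.  Spatial aggregation uses seeded nearest-phenotype assignment:
`n_spatial_seeds` (default 10) seed points each carry a phenotype, and a
cell takes its nearest seed's phenotype with probability 1 − scatter_prob,
else a uniformly random one.  This is exactly controllable and simpler than
a random field; scatter_prob 0 gives contiguous territories, 1 a well-mixed
tissue.  The latent phenotype is stored in a `true_phenotype` column that
every analysis operation ignores.

The default two-group design mirrors the contrast the metrics are meant to
detect: "mt-like" subjects have 2 phenotypes with scatter_prob 0.1 (few
states, aggregated), "wt-like" subjects 6 phenotypes with scatter_prob 0.9.
Phenotype marker means sit on the ordinal level grid — mean =
4 + 4·level log2 units, i.e. tri-modal marker distributions with ~4σ gaps —
with two constraints: per marker, level assignments are balanced so each
level carries ≈ 1/3 of the pooled cohort mass (cohort tertile thresholds
then fall in the gaps between intensity modes), and within a group the level
profiles are pairwise distinct on every hallmark's marker subset, so a group
with k phenotypes occupies exactly k molecular states per hallmark.  Without
these constraints the direction of the group contrast is at the mercy of
where data-driven tertiles slice the intensity modes: continuous cohort-level
phenotype means flipped the expected direction in roughly a third of cohort
seeds, an artifact of threshold placement rather than of the metric.  A
continuous-mean generator (`make_phenotype_means`, normal draws with an
enforced minimum pairwise separation in units of within-phenotype SD) is
retained for clustering ground truth, where threshold placement plays no
role.

What the generator does **not** emulate: staining/imaging rounds,
autofluorescence, segmentation error, cell-shape anisotropy, marker–marker
correlation within a phenotype, spatial intensity gradients, or multi-modal
subject features beyond what the pipeline itself derives.  Passing tests
demonstrate the correctness and calibration of the computations under a
known generative model, not biological validity on real tissue.

## Numerical and statistical choices

- Entropies: nats internally; 0·ln 0 := 0; normalized results clamped by
  construction, not post-hoc.
- Quantiles everywhere: linear interpolation between order statistics
  (the default empirical quantile), applied consistently in quantization,
  trimming and tertile discretization.
- Neighbor search: `scipy.spatial.cKDTree`, exact filtering; no
  approximation at any n.
- K-means: scikit-learn Lloyd with k-means++ starts; empty clusters cannot
  arise (the implementation relocates them); labels are 1-based.
- Reproducibility: every stochastic routine takes a seed; the pipeline fans
  one master seed out to stages via `numpy.random.SeedSequence`.  Identical
  config + seed reproduces outputs bit-for-bit.
- Validation sizes: calibration of the rank test uses 1,000 null cohorts of
  20 + 20 subjects at 60 cells per sample.  Group sizes were chosen from the
  exact null enumeration of U (achieved two-sided level 0.0491 at n = 20 vs
  0.0433 at n = 10 — the exact test is discrete and conservative), and the
  cohort count so that Monte-Carlo error keeps the estimate within ±1.5
  percentage points of the achieved level with high probability.
- Degenerate inputs: empty state assignments, Z_max = 0, constant markers,
  constant features, zero-variance replicate vectors and zero pooled
  variance all have explicit, documented behavior (error or flagged
  convention) rather than NaNs.

## Known limitations

- The heterogeneity metrics depend on the quantization scope; cross-cohort
  comparisons require refitting thresholds on the combined cohort.
- Consensus clustering stores dense m × m matrices (float32); at the default
  5,000-cell subsample this is ~100 MB per K.
- The neighbor rule is binary contact with a fixed factor of 1.3; no
  multi-scale radii or distance-weighted adjacency.
- Survival modelling, classifier training and image processing are outside
  the package's scope; the integration stage consumes precomputed
  per-subject features.
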