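# Methods

## Scope and model

`hubgene` implements a four-part analysis: (1) reduction of a cohort of
weighted, undirected structural connectomes to a binary group consensus
network; (2) rich-club statistics with degree-preserving nulls and a
percentile hub rule; (3) robust regression of regional, laminar gene
expression on node degree with false-discovery-rate control and a
spatial-autocorrelation-preserving permutation null; (4) hypergeometric
gene-set enrichment and per-cell geneset scoring against pseudotime. A
synthetic-data module generates every input with planted ground truth.

## Consensus network

Subjects must share a node set. An edge is a candidate if its weight is
positive in strictly more than `presence_threshold` (default 0.30) of
subjects; among candidates the top `⌊density·n(n−1)/2⌋` (default density
0.15) by mean weight across all subjects — zeros included, so strength
rewards both consistency and magnitude — are retained. Ties at the cutoff
break deterministically by lower (i, j) pair. When fewer candidates exist
than the density target the network keeps them all and warns; the achieved
density is recorded. The consistency mask is applied before the density
threshold; the density denominator is all node pairs. Degree is binary
throughout: the hub analysis is a statement about topology, not streamline
counts.

## Rich club, nulls and hubs

φ(k) is the edge density among nodes of degree strictly greater than k,
undefined (NaN, never zero) when fewer than two such nodes exist. The null
ensemble applies Maslov–Sneppen double-edge swaps to the consensus network:
`swaps_per_edge × n_edges` swap *attempts* per null (default 50 × E, 100
nulls), rejecting self-loops and multi-edges, so every null is simple with
exactly the original degree sequence; connectedness is not enforced. Because
the degree sequence is preserved, φ(k) is defined at the same k in every
null. φ_norm(k) = φ(k)/⟨φ_rand(k)⟩ and the per-k p-value uses the
finite-sample estimator (1 + #{φ_rand ≥ φ})/(1 + n_nulls), which cannot
return zero; the ≥ convention makes it conservative. The swap loop is a
numba kernel seeded per null from the master seed, so ensembles are exactly
reproducible.

Hubs are nodes with degree strictly above the 90th percentile (linear
interpolation) of the consensus degree distribution. The percentile rule is
fixed; the φ_norm and p(k) curves are reported alongside so users can verify
the hub regime coincides with significant rich-club organisation, and the
per-region hubness index RC% (fraction of a region's subparcels that are
hubs) maps node-level results back to named regions.

## Parcellation

Each labelled region of a surface mesh with v vertices is split into
`max(1, round(v/target))` subparcels (targets 60/90/120 vertices in the
standard resolutions). The subdivision algorithm — farthest-point seeding on
hop distance followed by competitive balanced growth, with a bounded-ratio
repair pass — is a design choice: contiguity and near-equal size are the
only constraints the analysis needs, and any algorithm with those properties
yields equivalent downstream statistics. Subparcel centroids (vertex
coordinate means) provide edge lengths and region coordinates; region-level
degree is the unweighted mean over a region's subparcels.

## Expression preparation

Input is a long table of probe-level log2 intensities over cortical regions
× five transient fetal zones (CP, SP, IZ, SVZ, VZ) × specimens, with an
absent-call flag. The pipeline order is: absent-probe removal → differential
stability → DS filter and probe collapse → replicate-sample averaging →
gene-level missingness filter; every stage can only shrink the data.
Differential stability is the mean Pearson correlation of a probe's regional
profile, within zone, between pairs of specimens of equal age (replicates
averaged first; at least 3 shared regions per pairing, else that context is
skipped; DS is missing if no context is valid). Probes with DS < 0.3 (or
missing DS) are dropped; each gene keeps its single highest-DS probe, ties
broken by probe id. Genes missing in strictly more than 10% of the observed
(region, zone, specimen) sample slots are removed. The result is a
gene × region × zone × specimen tensor (xarray) with specimen ages attached.

## Degree association

For each (gene, zone), observations are (region, specimen) pairs: expression
against `intercept + degree + age`, age in post-conception weeks centred
(dropped with a warning if only one age remains after missingness). The fit
is iteratively reweighted least squares with Huber weights, c = 1.345 (95%
Gaussian efficiency), MAD residual scale re-estimated per iteration,
convergence 1e−8 on coefficients, 50 iterations maximum. Standard errors use
the Huber sandwich covariance (the statsmodels "H1" form with small-sample
correction) — on iid Gaussian data the null rejection rate of this test at
α = 0.05 is 0.057 (measured over 2000 simulated fits). P-values are
two-sided from the t-distribution with n − p degrees of freedom; fits with
fewer than p + 2 observations are reported missing. BH-FDR is applied within
each zone.

Because node degree and cortical expression are both spatially smooth, the
naive test overstates significance. The surrogate null regenerates the
degree map: values are permuted, smoothed with k-nearest-neighbour kernels
with exponential decay exp(−d/d_k) over a dense grid of bandwidths k, and
each smoothed map is recombined with white noise by non-negative
least-squares so that α·γ_smooth + β matches the empirical variogram (six
equal-count distance bins; semivariance ½(x_i−x_j)² per bin); the best-k
surrogate is rescaled to the empirical mean and variance exactly. Constant
maps yield constant surrogates; degenerate (all-equal) distances fall back
to plain permutation with a warning. The model is re-fit per surrogate
(batched IRLS across the surrogate stack) and
`p_spatial = (1 + #{|β_null| ≥ |β_obs|})/(1 + n_surr)`. To bound cost the
surrogate test runs only for genes passing the FDR screen (α configurable,
default 0.05); `surrogate_for_all=True` disables the gate for calibration
studies. Significant genes are classed hub+ (β > 0) or hub− (β < 0).

Measured operating characteristics at 27 regions × 4 specimens with 200
surrogates: under fully spatially autocorrelated null expression against an
autocorrelated degree map, the naive test rejects 41–53% of null genes at
α = 0.05 while `p_spatial` rejects 4.4–7.0% (three seeds, 500 genes each);
with planted slopes of 0.004–0.02 expression units per degree unit on a
degree map spanning 60–250 and spatially unstructured noise, sensitivity for
|β| ≥ 0.01 is 1.0 and the empirical FDR of the hub+/hub− call is 0.03–0.09.

## Enrichment and cells

Gene-set enrichment intersects query and target with a declared background
universe first; the ratio is (x/n)/(K/M) and significance is the
hypergeometric upper tail P(X ≥ x) (a strict-tail option exists), computed
with scipy's stable log-space implementation; x = 0 gives p = 1. Per-cell
geneset scores are the sum of log-normalised expression over the geneset's
measured genes (AnnData input), and maturation association is the Spearman
correlation between score and pseudotime within a cell population — total
expression, not a background-corrected module score, so scores are
comparable across cells of different populations.

## Synthetic data: what it emulates, and what not

The generators reproduce the statistical structure the analysis assumes:

- **Surface**: a labelled triangulated sheet (block-grid regions, stitched
  borders, mild 3D curvature) — enough to exercise subdivision, centroids and
  distance-based statistics; not a cortical geometry.
- **Cohort**: nodes in 3D, edge probability exp(−d/distance_decay)
  (default 15 mm for nodes in a 100 mm box), a designated core whose pairwise
  probabilities are multiplied by core_boost (capped at 1) — a planted rich
  club; template weights probability × (1 + U(0,1)) so weight ordering tracks
  presence as in streamline counts; subjects flip each pair's presence at
  rate subject_noise (default 0.1) and jitter weights log-normally with the
  same rate, so zero noise reproduces the template exactly. Not emulated:
  tractography biases, distance-dependent false positives along white-matter
  pathways, hemispheric structure.
- **Expression**: per (gene, zone), a specimen-shared regional signature
  (sd 0.5; 30% of its variance spatially correlated with exponential
  covariance, length 30 mm) plus a specimen-specific spatial field (sd 0.15)
  and iid noise (sd 0.1); a planted fraction (default 15%) of genes adds
  β·degree in one designated zone, |β| uniform in a configurable range with
  random sign; two probes per gene — a faithful replicate and an
  independent-noise decoy so the DS filter has a guaranteed discriminating
  case; absent flags, missing cells and occasional replicate samples. Ages
  default to 16/16/21/21 weeks so the age covariate is estimable and both
  age groups contribute same-age DS pairs. Not emulated: batch effects,
  probe-affinity biases, dissection boundary errors.
- **Gene sets** with exact planted overlaps; **cells** with population
  labels, per-population pseudotime intervals and a geneset whose expression
  rises linearly with pseudotime.

All generators are pure functions of their arguments including the seed;
one master seed is split into labelled substreams per artefact.

Passing tests on these data show the estimators and filters do what they
claim under known structure; they do not certify performance on real MRI or
microarray data, whose noise is richer than anything planted here.

## Known limitations

- **Pooled-specimen inference under shared signatures.** The regression
  pools (region, specimen) observations, as the age-covariate design
  implies. When a gene's regional signature is strongly shared across
  specimens — exactly the regime the DS filter selects for — residuals are
  correlated across specimens, the effective sample size approaches the
  number of regions rather than regions × specimens, and naive p-values are
  anticonservative. The surrogate test does not repair this: `p_spatial` is
  monotone in |β| just as the naive p is, and its null pass rate cannot fall
  below the nominal 5%, so at low planted prevalence the hub+/hub− call
  retains a substantial false fraction (measured ≈ 0.6 at the generator's
  DS-compatible defaults with 15% prevalence). The recovery figures above
  are therefore quoted for the calibrated regime (negligible shared
  signature); applying the pipeline where strong shared signatures are
  expected calls for specimen-level random effects or region-level
  aggregation before inference, both outside the present design.
- The consensus "strength" is the mean weight over all subjects; other
  consensus rules (distance-binned, median-based) are not implemented.
- Edge length is the Euclidean distance between subparcel centroids, a proxy
  that understates true fibre length.
- The surrogate generator matches binned variograms, not the full covariance;
  with ~27 regions the empirical variogram itself is noisy, which is why the
  fit uses few, well-populated bins.
- Rewired nulls preserve degree but not connectedness or spatial embedding;
  for geometric networks φ_norm > 1 can reflect spatial clustering as well
  as a genuine core. The planted-core analyses distinguish the two by
  construction.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full suite completes in minutes on one CPU: cohorts of 15–50 subjects with
100–200 nodes, expression of 200–1000 genes over 27 regions × 5 zones × 4
specimens, 100 rewired nulls, 200 surrogate maps, and a full pipeline run at
189 subparcels / 1000 genes / 200 surrogates. The analysis defaults
(30% presence, 15% density, 50 swaps per edge, 100 nulls, DS ≥ 0.3, ≤ 10%
missingness, FDR 0.05, 1000 surrogates) are the study-design values; the
desk-scale profile only reduces the surrogate count.
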