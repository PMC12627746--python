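# hubgene

Rich-club hubs in developing structural brain networks and the transcriptomic
signature of hub regions.

## The problem

In diffusion-MRI connectomes, a small set of high-degree nodes ("hubs")
interconnects more densely than degree-matched chance — a *rich club* that
carries a disproportionate share of long-range communication and is
preferentially vulnerable in disorders. `hubgene` implements the full analysis
chain used to ask, for the perinatal brain: *where are the hubs, and which
genes' mid-gestation expression tracks hub location?* It is written for
researchers in network neuroscience and imaging transcriptomics who want each
stage as a tested, reusable component, with a synthetic-data module that
emulates every input (subject connectomes, laminar microarray expression, gene
sets, single cells) so the whole pipeline runs and validates without any data
downloads.

## The statistics at the core

**Consensus network.** Edges present in more than 30% of subject networks are
kept if they are among the strongest by mean weight, up to density
`⌊0.15·n(n−1)/2⌋`.

**Rich-club coefficient.** For degree threshold *k*,

```
φ(k) = 2·E>k / (N>k·(N>k − 1))
```

where `N>k` nodes have degree > k and `E>k` edges join two of them. φ(k) is
normalised by the mean coefficient of degree-sequence-preserving rewired
networks, `φ_norm(k) = φ(k) / ⟨φ_rand(k)⟩`, with an empirical p-value per k;
hubs are nodes above the 90th degree percentile.

**Degree–expression association.** Probe-level expression is cleaned
(absent-call removal; differential stability DS ≥ 0.3; one max-DS probe per
gene; ≤ 10% missingness), then for each gene and transient tissue zone
(cortical plate, subplate, intermediate, subventricular, ventricular) the
regional profile stacked over specimens is fit by Huber IRLS:

```
expression ~ intercept + β·degree + age
```

with BH-FDR within zone and a spatial-autocorrelation-preserving surrogate
null: degree maps are permuted, kNN-smoothed and variogram-matched, the model
re-fit per surrogate, and `p_spatial` read off the null coefficient
distribution. Genes with `p_FDR < 0.05` and `p_spatial < 0.05` are classed
hub+ / hub− by the sign of β.

**Enrichment.** Overlap of hub-gene sets with annotation sets uses the ratio
`(x/n)/(K/M)` and the hypergeometric tail `P(X ≥ x)`.

## Worked example

```python
import numpy as np
import hubgene as hg

# cohort of 30 synthetic connectomes with a 20-node planted core
subjects, truth = hg.gen_cohort_connectomes(
    n_subjects=30, n_nodes=200, core_size=20, core_boost=1e6,
    subject_noise=0.1, seed=7,
)
net = hg.build_consensus(subjects, presence_threshold=0.30, density=0.15)
print(f"consensus: {net.n_edges_} edges, density {net.density_:.3f}")

rc = hg.RichClub(n_nulls=100, swaps_per_edge=50, percentile=90,
                 random_state=7).fit(net)
print(f"hub threshold k = {rc.hub_threshold_:.0f}; {int(rc.hub_mask_.sum())} hubs")
print(f"max phi_norm = {np.nanmax(rc.phi_norm_):.2f}")
core = sorted(truth.planted_core_nodes)
print(f"planted core recovered as hubs: {rc.hub_mask_[core].mean():.0%}")
```

prints

```
consensus: 1000 edges, density 0.050
hub threshold k = 18; 20 hubs
max phi_norm = 2.84
planted core recovered as hubs: 100%
```

The consensus keeps the 1000 edges that survive the 30% presence filter
(the sparse geometric template caps the density below the 15% target, with a
warning); the degree distribution's top decile starts at k = 18, and the
normalised rich-club curve rises to 2.84 — high-degree nodes are nearly three
times as interconnected as degree-matched chance, and all 20 planted core
nodes are recovered as hubs. An enrichment call looks like:

```python
res = hg.geneset_overlap_test(query, target, background)
# -> x=15 of n=40 query genes in a K=75 set from M=1000: enrichment 5.0, p=3e-08
```

The full synthetic pipeline — surface, parcellation, cohort, consensus, rich
club, expression QC, association, enrichment — runs from the command line:

```sh
hubgene run --synthetic --seed 0 --out-dir out/
```

and writes one artefact per stage plus a manifest with SHA-256 hashes;
rerunning with the same seed reproduces every file byte for byte.

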