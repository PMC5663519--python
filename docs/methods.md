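# Methods

This note documents the models and numerical choices behind `ectoatlas`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the methodology was genuinely open.

## The data model

A dissected-region atlas is a genes × samples count matrix with three kinds
of samples: microdissected ectoderm fragments (region × replicate × stage),
and whole-embryo (WE) samples forming a developmental time series. The
working assumption of the whole pipeline is linear mixing: the expression
profile of a dissected sample is a non-negative combination of a small
number of latent "prototypical tissue" programs, plus count noise. The WE
samples additionally contain non-ectoderm material (mesoderm, endoderm),
which is what the ectoderm-enrichment score exploits.

## Synthetic atlas generator

`synthetic_data.GeneratorConfig` fixes the emulated study design. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes simulated |
| `n_tissues` | 5 | latent prototypical tissues K\* |
| `regions` | 7 labels | dissected regions, with an adjacency graph mirroring the dissection map (NPa–NBa, NPp–NBp, NBa–ANF.PPE, borders–NNE) |
| `replicates_per_region` | 3 | biological replicates |
| `stages` | st12.5, st14 | dissected stages |
| `we_stages` | 7 labels | WE series; includes the two dissected stage labels so enrichment ratios have stage-matched references |
| `signature_fraction` | 0.15 | fraction of genes that are tissue-specific markers |
| `signature_fold` | 64 (=2⁶) | on-tissue level over base, comfortably above the range ≥ 5 selection threshold |
| `signature_baseline` | 0.25 | off-tissue level as a fraction of base; gives marker genes a true Gini ≈ 0.78, near the 0.8 single-tissue maximum. Planting markers at the very bottom of the 0.7–0.8 signature band would make boundary losses definitional rather than informative |
| `contamination` | 0.1 | fraction of a dissected sample's mixture drawn from adjacent regions' tissues (split equally among neighbours). Replicate heterogeneity in real dissections is only known qualitatively; this is a free parameter, not an estimate |
| `nb_dispersion` | 0.05 | negative-binomial dispersion φ with Var = μ + φμ², typical of bulk RNA-seq biological replicates. φ = 0 is implemented as the exact noise-free limit (rounded expected counts) so construction tests have a deterministic oracle |
| `library_size_range` | 1e6–3e6 | total counts, drawn log-uniformly, exercising TMM correction |
| `we_nonecto_fraction` | 0.5 | WE mixture weight of the single non-ectoderm component, whose per-gene log-linear temporal trend generates the WE time courses. A fraction of genes (`mesoderm_fraction`, 5%) is dominated by this component — they are high in WE, low in dissected fragments, and must score low on ectoderm enrichment |
| `n_homeolog_pairs` etc. | 200; 0.15/0.25/0.05 | homeolog pairs and class fractions (asymmetric-L-down / asymmetric-S-down / subfunctionalized; remainder similar), reflecting the strong bias toward S-copy decrease seen in allotetraploid genomes; effect factor 4; 10% of pairs get ≥ 20% transcript-length mismatch so the length filter is exercised |

Counts are drawn as NB(mean = libsize · per-sample expression fraction,
dispersion φ); all randomness flows from one integer seed through
`numpy.random.SeedSequence`, so identical configs give bit-identical
output. `SyntheticTruth` records prototypes, mixing proportions, signature
memberships, homeolog classes and temporal trends.

**What the generator does not emulate:** read-level noise (mapping,
GC/length bias within a gene), isoforms, batch effects, spatial coordinates
beyond the region adjacency graph, or gene–gene correlation beyond the
tissue programs. Consequently, passing recovery tests demonstrates the
pipeline's correctness under linear mixing with NB noise — not robustness
to alignment artefacts or confounded designs.

## Preprocessing

Genes with < 10 counts in < 2 samples are removed. TMM scaling factors
follow the canonical definition: pairwise M/A values against a reference
sample (the one whose 75th-percentile CPM is closest to the mean),
trimming 30% of M and 5% of A values per tail, precision-weighted mean of
the surviving M values (delta-method weights), factors rescaled to
geometric mean 1. log2-CPM uses `log2((count + prior)/(libsize·factor)·1e6)`
with prior 0.5 (no value is standard; 0.5 keeps zero counts finite).
Optional voom-style precision weights (lowess fit of √sd against mean
log-count, inverse-fourth-power weights) are available and consumed only by
the homeolog differential test; every other stage uses unweighted log2-CPM.

## PCA with a permutation null

Genes are standardized across samples (ddof 1, constants dropped with a
warning), so the eigenvalues sum to the number of genes. The null permutes
each gene independently across samples — this destroys gene–gene and
gene–sample structure while preserving marginals; permuting whole sample
columns instead would leave the spectrum unchanged and test nothing.
Per-rank p-values use the add-one estimator (1 + #exceed)/(1 + N), which
cannot be zero and keeps P(p ≤ α) ≤ α exactly.

Raw rank-matched p-values are exposed, but the *significant component* flag
is sequential: a component counts as significant only while all
earlier-rank components are. Measured on i.i.d. noise, the raw
per-component rates are each ~1% at α = 1%, so "any component significant"
would fire ~10% of the time over ~11 components; the sequential rule
restores a familywise null rate of ~α, which is the property the null
calibration tests assert. Loading significance uses the two-sided empirical
α-band of the pooled null loadings of the same rank (per-permutation
quantiles averaged over permutations; permutations used for loading bands
are capped at 1,000 for memory). Silhouette curves use Euclidean distance
in the first three component scores. The paper-fidelity default is 10,000
permutations; tests use 200–1,000, which is ample for α = 1% decisions.

## NMF deconvolution

Each factorization is scikit-learn NMF: multiplicative updates, Frobenius
loss, random non-negative init, tol 1e-6, max 2,000 iterations. Choices
layered on top:

- **Rank scan**: 20 runs per candidate rank; all mixing-matrix rows pooled
  (zero rows excluded), hierarchically clustered (average linkage,
  correlation distance, cut at `rank` clusters). A rank is *robust* iff
  every cluster contains exactly one row per run and has mean within-cluster
  correlation ≥ 0.95 — a numerical stand-in for the visual tightness
  judgement; at rank K\*+2 the runs disagree and the criterion fails.
- **Median decomposition**: 100 runs; the lowest-error run is the
  reference; other runs are matched to it by Hungarian assignment on the
  Pearson correlation of mixing rows. Unaligned medians are meaningless, so
  alignment is mandatory; if > 20% of runs contain a component matching the
  reference below r = 0.5, an error advises a different rank. Before the
  elementwise median, each run's per-component scale indeterminacy
  (W·c, H/c) is fixed by normalizing mixing rows to unit norm and pushing
  the scale into W — without this the median pair does not reconstruct the
  data even when every individual run does.
- **Extension**: `W_full = argmin‖WH − X‖` per gene (one least-squares
  solve for all genes), negatives clipped to zero; rank-deficient H is an
  error. Deviation from the fitted W is reported as a percentage of each
  gene's peak expression in the fitted matrix.
- Patterns are rendered as percent-of-max (all-zero genes stay zero) on a
  white-to-blue scale.

## Gini signatures and ectoderm enrichment

The population Gini (denominator 2K²μ, no small-sample correction) is used
deliberately so the single-tissue maximum is exactly (K−1)/K = 0.8 at
K = 5, the scale the 0.7 signature cutoff refers to. Gini is computed on
rows of the extended component matrix `W_full` (per NMF-tissue), not on
region averages, since the NMF-tissues are the deconvoluted objects the
signature describes. Enrichment ratios use linear CPM with a 0.5-CPM
pseudo-count; percentile scores use average ranks for ties (all-equal input
gives all-equal scores). A gene enters a signature iff its argmax tissue,
Gini ≥ 0.7, and its best dissected-region median log2 expression is at
least the WE median. Alternative specificity indices (tau, entropy) are out
of scope.

## Co-expression groups

The expression filter keeps transcripts with one sample above 50 CPM or an
absolute CPM sum above 40 — the second disjunct is strictly weaker than the
first whenever any sample exceeds 50 and is nearly vacuous at realistic
depths; it is implemented verbatim anyway. Biweight midcorrelation uses the
canonical 9-MAD weighting; zero-MAD transcripts fall back to Pearson
standardization (standard practice). Signed adjacency ((1+bicor)/2)^power
with power 22 as default; `scale_free_fit` reports the binned
log10 p(k)–log10 k regression R², slope and mean connectivity so users can
re-derive the power per dataset. Signed TOM:
`(Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ)`.

The dynamic hybrid tree cut is deliberately simplified: average-linkage
tree, static cut at (0.95 − 0.05·deep_split) of the maximum merge height,
clusters below 15 members dissolved to group 0, optional nearest-cluster
reassignment of unassigned transcripts when their mean dissimilarity is
below the cut height (off by default, mirroring pamRespectsDendro=FALSE in
spirit). The published deep-split heuristics are not reproducible from
their description; correctness is therefore asserted as planted-partition
recovery (adjusted Rand ≥ 0.9), never label-for-label equality. Groups are
relabeled by descending size, id 1 largest, id 0 unassigned.

Enrichment uses one-sided Fisher exact tests per (group, term) with
Bonferroni-adjusted p *and* BH q-values both at 5% (the q-value method was
unspecified; BH is the standard choice). Randomized controls permute the
group labels, preserving group sizes exactly.

## Homeolog divergence

Pairs require an ortholog name mapping to exactly one .l and one .s gene;
ambiguous names are skipped and counted. Filters: relative length
difference strictly < 20% (|l₁−l₂|/max), both-copies-zero pairs dropped,
and ≥ 10 total counts across the pair (the count rule's unit was ambiguous;
total counts is the interpretation used). The per-region test is a paired
moderated t on the replicate-wise difference d = log2CPM(L) − log2CPM(S):
per-cell variances are shrunk toward a pooled prior fitted by moment
matching on log-variances (trigamma inverse by Newton iteration; infinite
prior df when variances show no excess spread), t has df + d₀ degrees of
freedom, and BH runs across all pair × region tests jointly (Bonferroni is
available). Classification: ≥ 2 same-direction significant regions with no
opposite one → asymmetric (the other copy decreased); ≥ 1 each direction →
subfunctionalized; exactly one significant region falls under neither
printed definition and is reported as "one-region", excluded from the bias
test; otherwise similar. "Similarly expressed in the other regions" is read
as "no significant opposite-direction region" — a non-significant
same-direction region does not disqualify. Subgenome bias uses the exact
two-sided binomial test; note that at the study's printed scale
(364 S-decreased of 634) the exact test gives p = 2.2 × 10⁻⁴, i.e. highly
significant but not below the sometimes-quoted 0.01% bound, which only a
one-sided normal approximation reaches.

## Seed networks and reports

Unsigned adjacency |bicor|^power keeps negative associations; each seed
retrieves its 50 most adjacent transcripts and edges are kept at Pearson
p ≤ 1e-10 (t-transform with n−2 df; the cutoff is exposed, and 1e-9 is a
reasonable looser choice). Edge sign records the correlation sign; node
colors come from the co-expression groups. Exports are GraphML plus a JSON
of node/edge tables with lossless round-trip. Gene report cards assemble
the NMF pattern, the regional average pattern, enrichment scores, the WE
time series and group membership, omitting (with a note) layers a gene is
absent from; genes outside the selected set are still covered through the
all-gene extension.

## Problem sizes and numerical conventions

Synthetic analyses in the test-suite and acceptance script use 800–2,000
genes, 16–21 dissected samples, 25–100 NMF runs, 200–1,000 permutations and
200 null datasets — sizes at which every statistical decision the pipeline
makes (rank selection, significance calls, recovery thresholds) is already
sharp. Ties in ranks use average ranks; stable sorts preserve input order
among equals; all stochastic stages take explicit integer seeds and derive
substreams via `SeedSequence`, so results are reproducible bit-for-bit.

## Known limitations

- The simplified dynamic tree cut will not reproduce published WGCNA group
  labels on real data, only partitions of comparable quality.
- The linear-mixing assumption ignores within-region heterogeneity; NMF
  components are identifiable only up to the usual scaling/permutation and
  can merge tissues whose mixing proportions are collinear across samples.
- Ectoderm enrichment requires a WE sample whose stage label matches the
  dissected stage; no interpolation between stages is attempted.
- The moderated test assumes approximately normal log2-CPM differences
  within regions; with 2 replicates per cell its power rests heavily on the
  shared prior.
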