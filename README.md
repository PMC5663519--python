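# ectoatlas

Spatial transcriptome analysis of the early vertebrate ectoderm from
microdissected-region bulk RNA-seq, for developmental biologists and
computational biologists working with region-resolved (rather than
single-cell) expression atlases.

During neurulation the dorsal ectoderm of the frog embryo regionalizes into
neural plate, neural border (the origin of the neural crest), preplacodal
and non-neural territories. Dissecting these regions at successive stages
and sequencing each fragment yields a genes × samples count matrix in which
each sample is a *mixture* of a few underlying transcriptional programs,
blurred by dissection variability and cross-contamination between adjacent
fragments. `ectoatlas` implements the complete downstream analysis of such
an atlas, together with a synthetic-data generator that reproduces its
statistical structure with known ground truth, so every stage is testable
without any sequencing data.

## Methods at the core

**Positional decoding by PCA with a permutation null.** High-variation
genes are selected per stage by the range of log2 expression (minimum range
5; variance and IQR available, compared via silhouette curves). Each gene
vector is standardized, and the eigenvalue spectrum is calibrated against a
null built by permuting every gene independently across samples (10,000
permutations by default): the p-value of eigenvalue rank *i* is the
fraction of permutations whose rank-*i* eigenvalue is at least as large,
and gene loadings outside the two-sided empirical null band are flagged.
Samples are positioned by projection; regions are summarized by barycenters
with a Voronoi tessellation (tSNE is wrapped for comparison).

**Tissue deconvolution by NMF.** The selected-gene expression matrix,
back-transformed to linear scale and normalized to per-gene maximum 1, is
factorized as `X ≈ W H` with `W ≥ 0` (genes × K prototypical tissues) and
`H ≥ 0` (K × samples mixing proportions). The rank K is chosen by a
stability scan (20 random initializations; K is accepted when the pooled
mixing-matrix rows form exactly K tight clusters, one row per run); the
reported decomposition is the elementwise median of 100 aligned runs.
`W` is then extended to *all* genes by solving `w·H = x` per gene in least
squares with negatives clipped to zero, which reproduces the fitted values
within 10% of each gene's peak expression.

**Gini tissue signatures.** A gene's concentration across the K
NMF-tissues is scored by the population Gini index
`G = Σᵢⱼ|xᵢ−xⱼ| / (2K²·mean)`, ranging from 0 (uniform) to (K−1)/K — 0.8
for five tissues. Signatures collect genes with `G ≥ 0.7`, assigned to
their argmax tissue, that also pass an ectoderm-enrichment rule against
stage-matched whole-embryo samples.

**Co-expression groups.** Filtered transcripts (≥ 50 CPM in one sample, or
CPM sum > 40) are connected by a signed adjacency
`a = ((1 + bicor)/2)^22` on the biweight midcorrelation; the signed
topological overlap dissimilarity feeds average-linkage clustering with a
dynamic cut (minimum group size 15). Group–term overrepresentation uses
one-sided Fisher exact tests with Bonferroni-adjusted p and BH q cutoffs
at 5%, against size-preserving randomized assignments as control.

**Homeolog divergence.** Pairs of .l/.s gene copies (allotetraploid
subgenomes) with comparable transcript lengths (< 20% difference) are
tested region by region with a moderated paired t-test (empirical-Bayes
variance shrinkage, BH correction across all pair × region tests) and
classified as *asymmetric* (one copy down in ≥ 2 regions, none opposite),
*subfunctionalized* (significant regions in both directions), *one-region*
or *similar*; subgenome bias among asymmetric pairs is assessed with an
exact binomial test.

## Worked example

```python
from ectoatlas.synthetic_data import GeneratorConfig, generate_atlas
from ectoatlas import preprocessing as prep, axes, nmf_spatial as nmf
from ectoatlas import signatures as sig

cfg = GeneratorConfig(n_genes=1000, n_homeolog_pairs=0,
                      stages=("st12.5",), seed=42)
counts, truth = generate_atlas(cfg)
expr = prep.to_log2_cpm(prep.filter_low_counts(counts))
diss = expr.dissected()

selection = axes.select_genes(diss, threshold=5.0)
print(f"selected {len(selection.union)} high-range genes "
      f"of {len(diss.genes)}")

pca = axes.pca_with_null(diss.subset_genes(selection.union),
                         n_permutations=1000, alpha=0.01, seed=0)
n_sig = int(pca.significant_components.sum())
print(f"significant components: {n_sig} "
      f"({pca.percent_variance[:n_sig].round(1)}% of variance)")

norm = nmf.normalize_max1(diss, selection.union)
scan = nmf.nmf_rank_scan(norm, ranks=[4, 5, 6], n_init=20, seed=0)
print("robust NMF ranks:", scan.robust_ranks())

dec = nmf.nmf_fit_median(norm, rank=5, n_runs=100, seed=0)
w_full = nmf.extend_components(nmf.normalize_max1(diss), dec.H)
dev = nmf.extension_deviation(w_full, dec, norm)
print(f"max extension deviation: {dev.max():.2f}% of peak expression")

sigs, table = sig.tissue_signatures(w_full, expr, gini_min=0.7)
print("signature sizes:", {t: len(g) for t, g in sigs.items()})
gene = sigs["NMF1"][0]
print(f"{gene} pattern:", nmf.nmf_pattern(w_full, gene).round(1).to_dict())
```

printing, step by step:

```
selected 150 high-range genes of 1000
significant components: 4 ([51.7 21.7 16.9  8.2]% of variance)
robust NMF ranks: [5]
max extension deviation: 0.28% of peak expression
signature sizes: {'NMF1': 30, 'NMF2': 30, 'NMF3': 30, 'NMF4': 30, 'NMF5': 28}
g00000 pattern: {'NMF1': 100.0, 'NMF2': 1.7, 'NMF3': 0.2, 'NMF4': 0.2, 'NMF5': 0.2}
```

Read: with five latent tissues the permutation-calibrated PCA finds exactly
four significant axes (mixing proportions have four degrees of freedom);
the rank scan accepts only the true rank 5; the all-gene extension agrees
with the fitted component matrix to a fraction of a percent; the Gini
signatures recover the planted tissue-specific genes, and a signature
gene's pattern card shows essentially exclusive expression in its tissue
(percent-of-max scale).

The same pipeline is scriptable from the shell:

```sh
ectoatlas simulate --seed 7 --out atlas/
ectoatlas preprocess --counts atlas/ --out expr/
ectoatlas axes --expr expr/ --out axes/
ectoatlas nmf --expr expr/ --genes axes/selected.txt --rank 5 --out nmf/
ectoatlas signatures --expr expr/ --wfull nmf/W_full.tsv --stage st12.5 --out sig/
ectoatlas coexpress --expr expr/ --out groups/
ectoatlas homeologs --counts atlas/ --expr expr/ --out pairs/
ectoatlas network --expr expr/ --seeds g00000 --out net/
```

Every stage reads and writes plain TSV/JSON artifacts, so stages can be
re-run independently. `ectoatlas simulate` also accepts a YAML file of
`GeneratorConfig` fields via `--config`.

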