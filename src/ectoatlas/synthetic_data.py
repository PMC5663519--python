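"""Synthetic neurula-ectoderm atlas generator with recorded ground truth.

The generator emulates the structure of a microdissected-ectoderm RNA-seq
experiment: a small number of latent prototypical tissues whose mixtures
compose each dissected-region sample, cross-contamination between adjacent
regions of the embryo, whole-embryo (WE) time-course samples carrying an
extra non-ectoderm component with log-linear temporal trends, tissue-specific
signature genes, negative-binomial count noise, and homeologous gene pairs
(.l / .s copies of the two allotetraploid subgenomes) with asymmetric
decrease or spatial subfunctionalization.

Every stochastic choice derives from a single integer seed, and the
:class:`SyntheticTruth` object records the latent prototype matrix, mixing
proportions, signature memberships, homeolog classes and temporal trends so
recovery by the analysis stages can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix

#: Default dissected regions (dorsal ectoderm at neurula stages) and the
#: adjacency of the dissection map: anterior/posterior neural plate (NPa,
#: NPp), anterior/posterior neural border (NBa, NBp), anterior neural fold
#: with preplacodal ectoderm (ANF.PPE), and anterior/posterior non-neural
#: ectoderm (NNE.a, NNE.p).
DEFAULT_REGIONS = ("NPa", "NPp", "NBa", "NBp", "ANF.PPE", "NNE.a", "NNE.p")
DEFAULT_ADJACENCY = (
    ("NPa", "NPp"), ("NPa", "NBa"), ("NPp", "NBp"), ("NBa", "NBp"),
    ("NBa", "ANF.PPE"), ("ANF.PPE", "NNE.a"), ("NBp", "NNE.p"),
    ("NNE.a", "NNE.p"),
)
#: Dominant prototypical tissue of each default region (5 tissues: neural
#: plate anterior/posterior, neural border, placodal, epidermal).
DEFAULT_REGION_TISSUE = {
    "NPa": 0, "NPp": 1, "NBa": 2, "NBp": 2,
    "ANF.PPE": 3, "NNE.a": 4, "NNE.p": 4,
}
#: Whole-embryo stage series; includes the two dissected stages so the
#: ectoderm-enrichment ratio has stage-matched WE references.
DEFAULT_WE_STAGES = ("st11", "st12", "st12.5", "st13", "st14", "st16", "st18")

NONECTO = "nonecto"


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic atlas.

    The defaults emulate the study design the pipeline targets: 7 dissected
    regions x 3 replicates at 2 neurula stages, 7 whole-embryo stages,
    5 prototypical tissues, negative-binomial dispersion 0.05 and 10%
    cross-contamination between adjacent dissected regions.
    """

    n_genes: int = 2000
    n_tissues: int = 5
    regions: tuple = DEFAULT_REGIONS
    adjacency: tuple = DEFAULT_ADJACENCY
    region_tissue: dict = None
    replicates_per_region: int = 3
    stages: tuple = ("st12.5", "st14")
    we_stages: tuple = DEFAULT_WE_STAGES
    signature_fraction: float = 0.15
    signature_fold: float = 64.0
    signature_baseline: float = 0.25
    mesoderm_fraction: float = 0.05
    contamination: float = 0.1
    we_nonecto_fraction: float = 0.5
    nb_dispersion: float = 0.05
    library_size_range: tuple = (1e6, 3e6)
    n_homeolog_pairs: int = 200
    frac_asym_l_down: float = 0.15
    frac_asym_s_down: float = 0.25
    frac_subfunctionalized: float = 0.05
    asym_factor: float = 4.0
    frac_length_mismatch: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_tissue is None:
            if tuple(self.regions) == DEFAULT_REGIONS:
                self.region_tissue = dict(DEFAULT_REGION_TISSUE)
            else:
                self.region_tissue = {r: i % self.n_tissues
                                      for i, r in enumerate(self.regions)}
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_tissues", "replicates_per_region",
                     "n_homeolog_pairs"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.n_genes < 1 or self.n_tissues < 1:
            raise ValueError("n_genes and n_tissues must be >= 1")
        if self.replicates_per_region < 1:
            raise ValueError("replicates_per_region must be >= 1")
        for name in ("signature_fraction", "signature_baseline",
                     "mesoderm_fraction",
                     "we_nonecto_fraction", "frac_asym_l_down",
                     "frac_asym_s_down", "frac_subfunctionalized",
                     "frac_length_mismatch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.contamination < 0.5:
            raise ValueError("contamination must lie in [0, 0.5)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be 0 < lo <= hi")
        class_sum = (self.frac_asym_l_down + self.frac_asym_s_down
                     + self.frac_subfunctionalized)
        if class_sum > 1.0 + 1e-12:
            raise ValueError("homeolog class fractions must sum to <= 1")
        if self.n_homeolog_pairs > self.n_genes // 2:
            raise ValueError("n_homeolog_pairs may not exceed n_genes/2")
        unknown = set(self.region_tissue) - set(self.regions)
        if unknown:
            raise ValueError(f"region_tissue refers to unknown regions "
                             f"{sorted(unknown)}")
        for t in self.region_tissue.values():
            if not 0 <= t < self.n_tissues:
                raise ValueError("region_tissue values must index tissues")

    @property
    def tissue_labels(self) -> list:
        return [f"T{i}" for i in range(self.n_tissues)]


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated atlas (the recovery oracle)."""

    prototype_matrix: pd.DataFrame    # genes x (tissues + nonecto)
    mixing_truth: pd.DataFrame        # samples x (tissues + nonecto)
    signature_membership: pd.Series   # gene -> tissue label or NaN
    homeolog_truth: pd.DataFrame      # one row per injected pair
    temporal_profile: pd.DataFrame    # genes x WE stages (multiplier)
    seed: int = 0

    def __post_init__(self) -> None:
        rowsum = self.mixing_truth.sum(axis=1).to_numpy()
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("mixing_truth rows must sum to 1")
        if (self.prototype_matrix.to_numpy() < 0).any():
            raise ValueError("prototype_matrix must be non-negative")

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.prototype_matrix.to_csv(path / "prototypes.tsv", sep="\t",
                                     index_label="gene")
        self.mixing_truth.to_csv(path / "mixing.tsv", sep="\t",
                                 index_label="sample")
        self.signature_membership.to_frame("tissue").to_csv(
            path / "signatures.tsv", sep="\t", index_label="gene")
        self.homeolog_truth.to_csv(path / "homeologs.tsv", sep="\t",
                                   index=False)
        self.temporal_profile.to_csv(path / "temporal.tsv", sep="\t",
                                     index_label="gene")
        (path / "truth.json").write_text(json.dumps({"seed": self.seed}))


def _expected_fractions(config: GeneratorConfig, prototypes: np.ndarray,
                        mixing: np.ndarray,
                        temporal: np.ndarray | None = None,
                        stage_idx: np.ndarray | None = None) -> np.ndarray:
    """Per-sample expected expression fractions q[g, s] (columns sum to 1)."""
    proto = prototypes
    q = proto @ mixing.T  # genes x samples
    if temporal is not None and stage_idx is not None:
        # scale the non-ectoderm contribution by the per-gene stage trend
        nonecto = np.outer(proto[:, -1], mixing[:, -1])
        q = q - nonecto + nonecto * temporal[:, stage_idx]
    return q / q.sum(axis=0, keepdims=True)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2.

    dispersion = 0 is the exact noise-free limit (rounded means), used by
    construction tests.
    """
    if dispersion == 0:
        return np.round(mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def generate_atlas(config: GeneratorConfig):
    """Generate a count matrix plus its ground truth.

    Returns
    -------
    (CountMatrix, SyntheticTruth)
        Dissected samples (regions x replicates x stages) followed by one
        whole-embryo sample per WE stage.  Identical config (including seed)
        yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K = config.n_tissues
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    tissue_labels = config.tissue_labels + [NONECTO]

    # --- prototype expression ------------------------------------------------
    base = rng.lognormal(mean=1.0, sigma=1.2, size=config.n_genes)
    proto = base[:, None] * rng.uniform(0.5, 2.0, size=(config.n_genes, K))
    membership = pd.Series(pd.NA, index=pd.Index(genes, name="gene"),
                           dtype="object")

    n_sig = int(round(config.signature_fraction * config.n_genes))
    n_meso = int(round(config.mesoderm_fraction * config.n_genes))
    special = rng.choice(config.n_genes, size=n_sig + n_meso, replace=False)
    sig_idx, meso_idx = special[:n_sig], special[n_sig:]
    sig_tissue = np.arange(n_sig) % K
    rng.shuffle(sig_tissue)
    for g, t in zip(sig_idx, sig_tissue):
        # marker-like profile: near-exclusive expression in one tissue
        proto[g, :] = base[g] * config.signature_baseline
        proto[g, t] = base[g] * config.signature_fold
        membership.iloc[g] = f"T{t}"

    # non-ectoderm component: neutral for most genes, dominant for
    # mesoderm-contaminant genes (high in WE, low in dissected ectoderm)
    nonecto_col = proto.mean(axis=1)
    proto = np.column_stack([proto, nonecto_col])
    for g in meso_idx:
        proto[g, :K] = base[g]
        proto[g, K] = base[g] * config.signature_fold

    # --- temporal trend of the non-ectoderm component ------------------------
    n_we = len(config.we_stages)
    slopes = rng.normal(0.0, 0.2, size=config.n_genes)
    stage_axis = np.arange(n_we) - (n_we - 1) / 2.0
    temporal = 2.0 ** (slopes[:, None] * stage_axis[None, :])

    # --- sample table and mixing proportions ---------------------------------
    sample_ids, stage_lab, region_lab, repl_lab, we_flag = [], [], [], [], []
    mix_rows = []
    neighbors = {r: [] for r in config.regions}
    for a, b in config.adjacency:
        if a in neighbors and b in neighbors:
            neighbors[a].append(b)
            neighbors[b].append(a)
    for stage in config.stages:
        for region in config.regions:
            t_dom = config.region_tissue[region]
            row = np.zeros(K + 1)
            adj = neighbors[region]
            if adj and config.contamination > 0:
                row[t_dom] += 1.0 - config.contamination
                share = config.contamination / len(adj)
                for nb in adj:
                    row[config.region_tissue[nb]] += share
            else:
                row[t_dom] = 1.0
            for rep in range(1, config.replicates_per_region + 1):
                sample_ids.append(f"{region}_{stage}_r{rep}")
                stage_lab.append(stage)
                region_lab.append(region)
                repl_lab.append(rep)
                we_flag.append(False)
                mix_rows.append(row.copy())
    for si, stage in enumerate(config.we_stages):
        row = np.zeros(K + 1)
        row[K] = config.we_nonecto_fraction
        row[:K] = (1.0 - config.we_nonecto_fraction) / K
        sample_ids.append(f"WE_{stage}")
        stage_lab.append(stage)
        region_lab.append("WE")
        repl_lab.append(1)
        we_flag.append(True)
        mix_rows.append(row)

    mixing = np.array(mix_rows)
    n_samples = len(sample_ids)
    we_stage_idx = np.full(n_samples, -1)
    for i, (flag, st) in enumerate(zip(we_flag, stage_lab)):
        if flag:
            we_stage_idx[i] = config.we_stages.index(st)

    # --- expected counts and NB draw -----------------------------------------
    lo, hi = config.library_size_range
    libsizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    q = proto @ mixing.T
    for i in range(n_samples):
        if we_stage_idx[i] >= 0:
            ne = proto[:, K] * mixing[i, K]
            q[:, i] = q[:, i] - ne + ne * temporal[:, we_stage_idx[i]]
    q = q / q.sum(axis=0, keepdims=True)
    mean = q * libsizes[None, :]
    counts = _draw_counts(rng, mean, config.nb_dispersion)

    sample_meta = pd.DataFrame(
        {"stage": stage_lab, "region": region_lab, "replicate": repl_lab,
         "is_whole_embryo": we_flag},
        index=pd.Index(sample_ids, name="sample"))
    gene_meta = pd.DataFrame(
        {"ortholog": genes, "suffix": "",
         "length": rng.integers(500, 5000, size=config.n_genes),
         "arm": "unknown"},
        index=pd.Index(genes, name="gene"))

    cm = CountMatrix(pd.DataFrame(counts, index=gene_meta.index,
                                  columns=sample_meta.index),
                     sample_meta, gene_meta)
    truth = SyntheticTruth(
        prototype_matrix=pd.DataFrame(proto, index=gene_meta.index,
                                      columns=tissue_labels),
        mixing_truth=pd.DataFrame(mixing, index=sample_meta.index,
                                  columns=tissue_labels),
        signature_membership=membership,
        homeolog_truth=pd.DataFrame(columns=["ortholog", "gene_l", "gene_s",
                                             "klass", "decreased", "factor",
                                             "length_filter_pass"]),
        temporal_profile=pd.DataFrame(temporal, index=gene_meta.index,
                                      columns=list(config.we_stages)),
        seed=config.seed)
    return cm, truth


def expected_mean_counts(config: GeneratorConfig,
                         truth: SyntheticTruth,
                         library_sizes: pd.Series) -> pd.DataFrame:
    """Analytic per-gene expected counts for a generated atlas.

    Used by tests to compare empirical Monte-Carlo means against the closed
    form of the negative-binomial mean.
    """
    proto = truth.prototype_matrix.to_numpy()
    mixing = truth.mixing_truth.to_numpy()
    K = config.n_tissues
    q = proto @ mixing.T
    for i, sample in enumerate(truth.mixing_truth.index):
        region = sample.split("_")[0]
        if region == "WE":
            stage = sample[len("WE_"):]
            ne = proto[:, K] * mixing[i, K]
            trend = truth.temporal_profile[stage].to_numpy()
            q[:, i] = q[:, i] - ne + ne * trend
    q = q / q.sum(axis=0, keepdims=True)
    mean = q * library_sizes.to_numpy()[None, :]
    return pd.DataFrame(mean, index=truth.prototype_matrix.index,
                        columns=truth.mixing_truth.index)


def inject_homeolog_pairs(counts: CountMatrix, truth: SyntheticTruth,
                          config: GeneratorConfig):
    """Designate homeologous .l/.s gene pairs and rewrite their counts.

    Pairs are drawn from non-signature genes.  Classes:

    - ``similar``: both copies share the expectation everywhere.
    - ``asym_l_down`` / ``asym_s_down``: one copy scaled down by
      ``asym_factor`` uniformly across all samples.
    - ``subfunctionalized``: each copy dominates in half of the dissected
      regions (factor applied to the other copy there).

    A fraction ``frac_length_mismatch`` of pairs receives transcript lengths
    differing by >= 20% so they fail the downstream length filter.
    """
    n_pairs = config.n_homeolog_pairs
    if n_pairs == 0:
        return counts, truth
    if 2 * n_pairs > counts.n_genes:
        raise ValueError("more homeolog pairs requested than genes available")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    eligible = np.flatnonzero(truth.signature_membership.isna().to_numpy())
    if len(eligible) < 2 * n_pairs:
        raise ValueError("not enough non-signature genes for homeolog pairs")
    chosen = rng.choice(eligible, size=2 * n_pairs, replace=False)
    l_idx, s_idx = chosen[:n_pairs], chosen[n_pairs:]

    n_l = int(round(config.frac_asym_l_down * n_pairs))
    n_s = int(round(config.frac_asym_s_down * n_pairs))
    n_sub = int(round(config.frac_subfunctionalized * n_pairs))
    klasses = (["asym_l_down"] * n_l + ["asym_s_down"] * n_s
               + ["subfunctionalized"] * n_sub
               + ["similar"] * (n_pairs - n_l - n_s - n_sub))
    rng.shuffle(klasses)
    n_mismatch = int(round(config.frac_length_mismatch * n_pairs))
    mismatch = np.zeros(n_pairs, dtype=bool)
    if n_mismatch:
        mismatch[rng.choice(n_pairs, size=n_mismatch, replace=False)] = True

    new_counts = counts.counts.copy()
    gene_meta = counts.gene_meta.copy()
    smeta = counts.sample_meta
    regions = [r for r in config.regions]
    half = set(regions[: len(regions) // 2])
    region_of = smeta["region"]
    libsizes = counts.counts.sum(axis=0).to_numpy().astype(float)
    # per-sample expected fraction of each gene (recomputed from the truth)
    mean_df = expected_mean_counts(
        config, truth, pd.Series(libsizes, index=counts.samples))

    records = []
    for j in range(n_pairs):
        gi_l, gi_s = int(l_idx[j]), int(s_idx[j])
        gl = counts.genes[gi_l]
        gs = counts.genes[gi_s]
        klass = klasses[j]
        base_mean = mean_df.iloc[gi_l].to_numpy()
        fac_l = np.ones(len(base_mean))
        fac_s = np.ones(len(base_mean))
        decreased = "none"
        if klass == "asym_l_down":
            fac_l[:] = 1.0 / config.asym_factor
            decreased = "L"
        elif klass == "asym_s_down":
            fac_s[:] = 1.0 / config.asym_factor
            decreased = "S"
        elif klass == "subfunctionalized":
            in_half = region_of.isin(half).to_numpy()
            we = smeta["is_whole_embryo"].to_numpy()
            fac_s[in_half & ~we] = 1.0 / config.asym_factor
            fac_l[~in_half & ~we] = 1.0 / config.asym_factor
        new_counts.iloc[gi_l] = _draw_counts(rng, base_mean * fac_l,
                                             config.nb_dispersion)
        new_counts.iloc[gi_s] = _draw_counts(rng, base_mean * fac_s,
                                             config.nb_dispersion)
        orth = f"orth{j:04d}"
        len_l = int(rng.integers(800, 4000))
        if mismatch[j]:
            len_s = int(round(len_l * 1.5))
        else:
            len_s = int(round(len_l * rng.uniform(0.95, 1.05)))
        gene_meta.loc[gl, ["ortholog", "suffix", "length", "arm"]] = \
            [orth, "l", len_l, "L"]
        gene_meta.loc[gs, ["ortholog", "suffix", "length", "arm"]] = \
            [orth, "s", len_s, "S"]
        records.append({"ortholog": orth, "gene_l": gl, "gene_s": gs,
                        "klass": klass, "decreased": decreased,
                        "factor": config.asym_factor,
                        "length_filter_pass": not mismatch[j]})

    new_cm = CountMatrix(new_counts, smeta, gene_meta)
    new_truth = SyntheticTruth(
        prototype_matrix=truth.prototype_matrix,
        mixing_truth=truth.mixing_truth,
        signature_membership=truth.signature_membership,
        homeolog_truth=pd.DataFrame.from_records(records),
        temporal_profile=truth.temporal_profile,
        seed=truth.seed)
    return new_cm, new_truth


def generate_annotation(config: GeneratorConfig, truth: SyntheticTruth,
                        n_background_terms: int = 30, term_size: int = 40,
                        odds_ratio: float = 8.0,
                        n_enriched_per_tissue: int = 1) -> pd.DataFrame:
    """Two-column (term, gene) annotation with planted enrichment.

    Terms named ``sig_T<k>_<i>`` oversample genes of tissue ``T<k>``'s
    ground-truth signature set by the configured odds ratio; ``bg_<i>``
    terms sample genes uniformly.  ``odds_ratio=1`` makes every term a
    uniform background term (null calibration).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    genes = truth.prototype_matrix.index.to_numpy()
    membership = truth.signature_membership
    rows = []
    for t in config.tissue_labels:
        in_sig = (membership == t).to_numpy()
        if not in_sig.any():
            continue
        w = np.where(in_sig, float(odds_ratio), 1.0)
        w = w / w.sum()
        for i in range(n_enriched_per_tissue):
            size = min(term_size, len(genes))
            members = rng.choice(genes, size=size, replace=False, p=w)
            rows += [{"term": f"sig_{t}_{i}", "gene": g} for g in members]
    for i in range(n_background_terms):
        size = min(term_size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        rows += [{"term": f"bg_{i}", "gene": g} for g in members]
    return pd.DataFrame(rows, columns=["term", "gene"])
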