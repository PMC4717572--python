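"""Synthetic GWAS + network data generator.

The real study data (genotypes and hippocampal-volume endophenotypes from
clinical cohorts) are access-restricted, so every downstream stage of the
pipeline is exercised on synthetic data that emulates the features the
methods depend on:

* per-SNP dosages with block-wise linkage disequilibrium (LD), one block per
  gene, via thresholded latent Gaussians;
* a continuous phenotype driven by four covariates (age-, sex-, education-
  and intracranial-volume-like), one tagged causal SNP per disease gene, and
  unit-variance noise;
* optionally, a cluster of mutually overlapping genes that share SNPs
  (protocadherin-alpha-like), the failure mode probed by the multi-mapping
  diagnostic;
* a weighted gene-gene functional network containing a disease module with
  elevated edge weights;
* a gold-standard gene list sampled from the disease module.

Everything is deterministic given ``SimConfig.seed``: each component draws
from a labeled child seed (see :mod:`netwas.seeds`), so components can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import GoldStandard
from .gene_scoring import GeneAnnotation
from .reprioritize import TissueNetwork
from .seeds import child_rng

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "generate_gene_models",
    "generate_cohort",
    "generate_network",
    "generate_gold_standard",
    "generate_netwas_benchmark",
]

# Fixed true covariate coefficients (age-, sex-, education-, ICV-like).
# Arbitrary but recorded so the association stage demonstrably must adjust.
COVARIATE_COEFFICIENTS = np.array([1.0, -0.5, 0.25, 0.8])


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs; defaults define the package's benchmark conditions.

    Parameters
    ----------
    n_subjects
        Cohort size. Default 800, comparable to the mid-hundreds cohorts
        typical of neuroimaging-genetics studies.
    n_genes
        Number of simulated genes (one LD block each).
    snps_per_gene
        SNPs placed uniformly inside each gene span.
    window_bp
        Half-width of the SNP-to-gene assignment window; also sets the
        minimum spacing (2x) between non-overlapping genes so windows of
        distinct genes never overlap accidentally.
    ld_rho
        Exchangeable latent correlation within an LD block, in [0, 1).
    n_disease_genes
        Size of the causal/disease-module gene set.
    effect_size
        Per-allele phenotype shift (phenotype SD units) of the one tagged
        SNP in each disease gene.
    module_edge_weight
        Network weight on every disease-module edge, in (0, 1].
    background_edge_density
        Probability of a background (non-module) edge.
    overlap_cluster_size
        If >= 2, that many genes form one mutually overlapping cluster.
    gold_fraction
        Fraction of disease-module genes annotated in the gold standard.
    seed
        Master RNG seed recorded in all outputs.
    """

    n_subjects: int = 800
    n_genes: int = 500
    snps_per_gene: int = 8
    window_bp: int = 50_000
    ld_rho: float = 0.5
    n_disease_genes: int = 50
    effect_size: float = 0.5
    module_edge_weight: float = 0.8
    background_edge_density: float = 0.02
    overlap_cluster_size: int = 0
    gold_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_genes": self.n_genes,
            "snps_per_gene": self.snps_per_gene,
            "window_bp": self.window_bp,
            "n_disease_genes": self.n_disease_genes,
            "overlap_cluster_size": self.overlap_cluster_size,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not 0.0 < self.module_edge_weight <= 1.0:
            raise ValueError(
                f"module_edge_weight must be in (0, 1], got {self.module_edge_weight}"
            )
        for name, value in [
            ("background_edge_density", self.background_edge_density),
            ("gold_fraction", self.gold_fraction),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.overlap_cluster_size > self.n_genes:
            raise ValueError(
                "overlap_cluster_size cannot exceed n_genes "
                f"({self.overlap_cluster_size} > {self.n_genes})"
            )
        if self.n_disease_genes > self.n_genes:
            raise ValueError("n_disease_genes cannot exceed n_genes")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class SyntheticCohort:
    """Synthetic genotype + phenotype data for the association stage.

    ``genotypes`` holds additive dosages in {0, 1, 2}, subjects x SNPs, with
    columns aligned to ``snp_table`` rows.  ``tagged_snps`` maps each causal
    gene to the single SNP through which it influences the phenotype.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray
    snp_table: pd.DataFrame  # columns: SNP, CHR, BP, GENE (gene of origin)
    truth: set[str] = field(default_factory=set)
    tagged_snps: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        if np.isnan(self.covariates).any():
            raise ValueError("covariates must have no missing entries")


# gene span lengths drawn uniformly from this range (bp)
_GENE_LEN_RANGE = (5_000, 30_000)
# staggered start offset and span length for the overlapping cluster
_CLUSTER_STAGGER = 2_000
_CLUSTER_SPAN = 40_000


def generate_gene_models(config: SimConfig) -> list[GeneAnnotation]:
    """Place genes on two chromosomes with non-overlapping windows, plus an
    optional cluster of mutually overlapping genes on a separate region.

    Non-cluster genes are spaced at least ``2 * window_bp`` apart so their
    assignment windows are disjoint.  Cluster genes are staggered so every
    pair of spans intersects and all share one common core interval.
    """
    config.validate()
    rng = child_rng(config.seed, "gene_models")
    n_cluster = config.overlap_cluster_size if config.overlap_cluster_size >= 2 else 0
    n_regular = config.n_genes - n_cluster
    width = max(4, len(str(config.n_genes)))

    genes: list[GeneAnnotation] = []
    n_chroms = 2 if n_regular >= 10 else 1
    cursors = {str(c + 1): 1 for c in range(n_chroms)}
    for i in range(n_regular):
        chrom = str(i % n_chroms + 1)
        length = int(rng.integers(*_GENE_LEN_RANGE))
        start = cursors[chrom]
        end = start + length - 1
        genes.append(GeneAnnotation(f"G{i + 1:0{width}d}", chrom, start, end))
        cursors[chrom] = end + 2 * config.window_bp + 1

    if n_cluster:
        # dedicated region on chromosome 1, past every regular gene's window
        base = cursors["1"] + 2 * config.window_bp
        for j in range(n_cluster):
            start = base + j * _CLUSTER_STAGGER
            end = start + _CLUSTER_SPAN - 1
            genes.append(
                GeneAnnotation(f"G{n_regular + j + 1:0{width}d}", "1", start, end)
            )
    return genes


def _simulate_block_dosages(
    rng: np.random.Generator, n_subjects: int, freqs: np.ndarray, rho: float
) -> np.ndarray:
    """Dosages for one LD block via thresholded exchangeable latent Gaussians.

    Two independent haplotype copies per subject; within each copy, SNPs share
    a block factor with loading sqrt(rho), so latent correlation is ``rho``.
    An allele is carried when the latent value falls below the allele
    frequency quantile; the dosage is the sum over the two copies.
    """
    k = len(freqs)
    thresh = stats.norm.ppf(freqs)
    dosage = np.zeros((n_subjects, k), dtype=np.int8)
    for _copy in range(2):
        common = rng.standard_normal((n_subjects, 1))
        indep = rng.standard_normal((n_subjects, k))
        z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * indep
        dosage += (z < thresh).astype(np.int8)
    return dosage


def generate_cohort(
    config: SimConfig, genes: list[GeneAnnotation]
) -> SyntheticCohort:
    """Simulate genotypes, covariates and phenotype for ``genes``.

    Each gene is one LD block of ``snps_per_gene`` SNPs placed uniformly
    inside its span, with allele frequencies uniform in [0.05, 0.5].  The
    phenotype is a fixed linear combination of four standard-normal
    covariates, plus ``effect_size`` times the dosage of one tagged SNP per
    causal gene, plus standard normal noise.
    """
    config.validate()
    if not genes:
        raise ValueError("genes must be non-empty")
    rng = child_rng(config.seed, "cohort")

    truth_rng = child_rng(config.seed, "truth")
    gene_ids = [g.gene_id for g in genes]
    truth = set(
        truth_rng.choice(gene_ids, size=config.n_disease_genes, replace=False)
    ) if config.n_disease_genes else set()

    records = []
    blocks: list[np.ndarray] = []
    tagged: dict[str, str] = {}
    snp_idx = 0
    for gene in genes:
        span = np.arange(gene.start, gene.end + 1)
        pos = np.sort(rng.choice(span, size=config.snps_per_gene, replace=False))
        freqs = rng.uniform(0.05, 0.5, size=config.snps_per_gene)
        blocks.append(
            _simulate_block_dosages(rng, config.n_subjects, freqs, config.ld_rho)
        )
        for j, p in enumerate(pos):
            snp_id = f"rs{snp_idx + j + 1}"
            records.append((snp_id, gene.chrom, int(p), gene.gene_id))
            if j == 0 and gene.gene_id in truth:
                tagged[gene.gene_id] = snp_id
        snp_idx += config.snps_per_gene

    snp_table = pd.DataFrame(records, columns=["SNP", "CHR", "BP", "GENE"])
    genotypes = np.concatenate(blocks, axis=1) if blocks else np.zeros(
        (config.n_subjects, 0), dtype=np.int8
    )

    covariates = rng.standard_normal((config.n_subjects, 4))
    phenotype = covariates @ COVARIATE_COEFFICIENTS
    if tagged:
        tag_cols = snp_table.index[snp_table["SNP"].isin(tagged.values())].to_numpy()
        phenotype = phenotype + config.effect_size * genotypes[:, tag_cols].sum(axis=1)
    phenotype = phenotype + rng.standard_normal(config.n_subjects)

    return SyntheticCohort(
        genotypes=genotypes,
        phenotype=phenotype,
        covariates=covariates,
        snp_table=snp_table,
        truth=truth,
        tagged_snps=tagged,
        seed=config.seed,
    )


def generate_network(
    config: SimConfig, genes: list[GeneAnnotation], truth: set[str]
) -> TissueNetwork:
    """Weighted functional network with an embedded disease module.

    Every pair of disease-module (truth) genes is connected with weight
    ``module_edge_weight``; every other pair receives a background edge with
    probability ``background_edge_density`` and a weight uniform in
    (0, module_edge_weight / 2).
    """
    config.validate()
    gene_ids = [g.gene_id for g in genes]
    if not truth <= set(gene_ids):
        raise ValueError("truth must be a subset of the simulated gene ids")
    rng = child_rng(config.seed, "network")
    n = len(gene_ids)
    W = np.zeros((n, n))

    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < config.background_edge_density
    weights = rng.uniform(0.0, config.module_edge_weight / 2.0, size=iu.size)
    W[iu[present], ju[present]] = weights[present]

    module_idx = np.array([i for i, g in enumerate(gene_ids) if g in truth], dtype=int)
    if module_idx.size >= 2:
        mi, mj = np.meshgrid(module_idx, module_idx, indexing="ij")
        W[mi, mj] = config.module_edge_weight

    W = np.triu(W, k=1)
    W = W + W.T
    return TissueNetwork(gene_ids=gene_ids, W=W)


def generate_gold_standard(
    truth: set[str],
    gold_fraction: float,
    seed: int,
    universe: set[str] | None = None,
    label: str = "synthetic-disease-module",
) -> GoldStandard:
    """Sample a gold standard as a uniform subset of the true disease genes.

    ``round(gold_fraction * |truth|)`` genes are drawn; the rest of the
    universe (all truth genes if no universe is given) are gold negatives.
    """
    if not 0.0 <= gold_fraction <= 1.0:
        raise ValueError("gold_fraction must be in [0, 1]")
    rng = child_rng(seed, "gold_standard")
    ordered = sorted(truth)
    n_pos = int(round(gold_fraction * len(ordered)))
    positives = set(rng.choice(ordered, size=n_pos, replace=False)) if n_pos else set()
    if universe is None:
        universe = set(truth)
    return GoldStandard(label=label, positives=positives, universe=universe | positives)


def generate_netwas_benchmark(
    n_genes: int = 1000,
    module_size: int = 50,
    labeled_fraction: float = 0.4,
    module_edge_weight: float = 0.8,
    background_edge_density: float = 0.02,
    seed: int = 0,
) -> tuple[pd.Series, TissueNetwork, GoldStandard]:
    """Benchmark for network re-prioritization: module-clustered GWAS signal.

    Builds a network of ``n_genes`` with a ``module_size``-gene disease
    module at elevated edge weight, assigns gene-level p-values so that
    ``labeled_fraction`` of module genes fall below the nominal 0.01
    threshold (log-uniform in [1e-5, 0.01)) while all remaining genes draw
    uniform p-values (so a realistic sprinkling of background genes is also
    nominally significant), and returns (gene p-values, network, gold
    standard = the full module).

    This is the study design under which network re-prioritization should
    recover the module's unlabeled members through their network features.
    """
    if not 0 < module_size <= n_genes:
        raise ValueError("module_size must be in (0, n_genes]")
    rng = child_rng(seed, "benchmark")
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    module = set(rng.choice(gene_ids, size=module_size, replace=False))

    n_labeled = int(round(labeled_fraction * module_size))
    module_sorted = sorted(module)
    labeled = set(rng.choice(module_sorted, size=n_labeled, replace=False))

    ps = pd.Series(rng.uniform(0.0, 1.0, size=n_genes), index=gene_ids)
    ps[ps <= 0.0] = np.nextafter(0.0, 1.0)
    # unlabeled module genes must not be nominally significant by chance
    unlabeled_module = sorted(module - labeled)
    ps[unlabeled_module] = rng.uniform(0.01, 1.0, size=len(unlabeled_module))
    ps[sorted(labeled)] = 10.0 ** rng.uniform(-5, np.log10(0.01), size=len(labeled))

    net_config = SimConfig(
        n_genes=n_genes,
        n_disease_genes=module_size,
        module_edge_weight=module_edge_weight,
        background_edge_density=background_edge_density,
        seed=seed,
    )
    genes = [GeneAnnotation(g, "1", 1, 2) for g in gene_ids]
    network = generate_network(net_config, genes, module)
    gold = GoldStandard(
        label="synthetic-disease-module",
        positives=module,
        universe=set(gene_ids),
    )
    return ps, network, gold
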