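"""Gene-based association scoring with an LD-aware Monte Carlo null.

Phase I of the pipeline.  SNPs are assigned to genes with a symmetric
window (default +/-50 kb around the gene span; strand is ignored).  A
gene's observed statistic is the sum of its SNPs' 1-df chi-square
statistics, obtained from the two-sided per-SNP p-values by upper-tail
quantile inversion.  The null distribution of that sum under linkage
disequilibrium is simulated by drawing z ~ MVN(0, R) — R the SNP-dosage
correlation matrix — and summing z_i^2; the Monte Carlo p-value uses the
add-one estimator (r + 1) / (n + 1), which can never be exactly zero.

Simulation effort is adaptive: a gene starts at a small stage and escalates
to larger stages only while its current p-value estimate is within 10x the
stage's resolution, bounding the relative Monte Carlo error for small
p-values without spending large simulations on clearly null genes.

Treating two-sided t-test p-values as chi-square(1) tail probabilities is
the usual large-sample equivalence (t^2 -> chi-square as df grows); it is
an approximation at small n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .assoc import SnpAssociation
from .seeds import child_rng

__all__ = [
    "GeneAnnotation",
    "GeneAssignment",
    "LdMatrix",
    "GeneScore",
    "McConfig",
    "MultiMappingCluster",
    "assign_snps",
    "chisq_from_p",
    "ld_from_genotypes",
    "repair_psd",
    "gene_p",
    "score_genes",
    "multi_mapping_diagnostic",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 50_000


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene span, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"  # stored but unused: the window is symmetric

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneAssignment:
    """SNPs falling within [start - window, end + window] of one gene,
    ordered by position.  May be empty; the gene is then unscored."""

    gene_id: str
    snp_ids: list[str]
    window_bp: int


@dataclass
class LdMatrix:
    """SNP-SNP correlation matrix, positive semidefinite after repair."""

    snp_ids: list[str]
    R: np.ndarray
    source: str = "genotypes"  # or "provided"
    repair_magnitude: float = 0.0  # largest eigenvalue adjustment applied


@dataclass
class GeneScore:
    gene_id: str
    n_snps: int
    stat: float  # observed sum of per-SNP chi-square(1) statistics
    p: float  # Monte Carlo p, (1 + exceedances) / (1 + n_sims)
    n_sims: int
    seed: int


@dataclass(frozen=True)
class McConfig:
    """Adaptive Monte Carlo staging for the gene null.

    Stages are cumulative totals; simulation escalates to the next stage
    while the current estimate is below ``escalation_factor / stage``.
    """

    stages: tuple[int, ...] = (1_000, 10_000, 100_000)
    escalation_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages or any(s <= 0 for s in self.stages):
            raise ValueError("stages must be positive")
        if list(self.stages) != sorted(self.stages):
            raise ValueError("stages must be increasing cumulative totals")


@dataclass
class MultiMappingCluster:
    """>= 2 genes linked by shared nominally significant SNPs."""

    gene_ids: list[str]
    snp_ids: list[str]


def assign_snps(
    snps: list[SnpAssociation],
    genes: list[GeneAnnotation],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[GeneAssignment]:
    """Assign each SNP to every gene whose window contains it.

    A SNP at position ``pos`` is assigned to gene ``g`` iff they share a
    chromosome and ``g.start - window_bp <= pos <= g.end + window_bp``
    (boundaries inclusive).  One SNP may map to many genes; multi-mapping is
    preserved by design and surfaced by :func:`multi_mapping_diagnostic`.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    seen: set[str] = set()
    for s in snps:
        if s.snp_id in seen:
            raise ValueError(f"duplicate SNP id: {s.snp_id}")
        seen.add(s.snp_id)

    gene_chroms = {g.chrom for g in genes}
    by_chrom: dict[str, list[SnpAssociation]] = {}
    for s in snps:
        if s.chrom not in gene_chroms:
            warnings.warn(
                f"SNP {s.snp_id} on chromosome {s.chrom!r} matches no gene; skipped",
                stacklevel=2,
            )
            continue
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom_snps in by_chrom.values():
        chrom_snps.sort(key=lambda s: (s.pos, s.snp_id))

    assignments = []
    for g in genes:
        chrom_snps = by_chrom.get(g.chrom, [])
        pos = np.fromiter((s.pos for s in chrom_snps), dtype=np.int64, count=len(chrom_snps))
        lo = np.searchsorted(pos, g.start - window_bp, side="left")
        hi = np.searchsorted(pos, g.end + window_bp, side="right")
        assignments.append(
            GeneAssignment(
                gene_id=g.gene_id,
                snp_ids=[chrom_snps[i].snp_id for i in range(lo, hi)],
                window_bp=window_bp,
            )
        )
    return assignments


def chisq_from_p(p: float) -> float:
    """Upper-tail chi-square(1) quantile of a two-sided p-value.

    Monotone decreasing in p; p = 1 maps to 0.  P-values below the smallest
    positive double are clamped (with a warning) rather than mapped to
    infinity.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    tiny = np.finfo(float).tiny
    if p < tiny:
        warnings.warn(f"p={p} below underflow threshold; clamped to {tiny}", stacklevel=2)
        p = tiny
    return float(stats.chi2.isf(p, df=1))


def repair_psd(R: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues to zero and rescale to unit diagonal.

    Returns the repaired matrix and the magnitude of the repair (the most
    negative eigenvalue clipped, as a positive number; 0.0 for an already
    PSD input within ``tol``).
    """
    R = np.asarray(R, dtype=float)
    R = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(R)
    magnitude = float(max(0.0, -vals.min()))
    if magnitude <= tol:
        return R, magnitude
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), np.finfo(float).tiny, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    logger.info("PSD repair applied; eigenvalue adjustment %.3e", magnitude)
    return (fixed + fixed.T) / 2.0, magnitude


def ld_from_genotypes(
    dosages: np.ndarray, snp_ids: list[str] | None = None
) -> LdMatrix:
    """Pearson correlation of dosage columns, with PSD repair.

    Monomorphic SNPs (zero variance) are dropped with a warning; a single
    subject is an error.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[0] < 2:
        raise ValueError("need >= 2 subjects to estimate LD")
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(dosages.shape[1])]
    if len(snp_ids) != dosages.shape[1]:
        raise ValueError("snp_ids length does not match dosage columns")

    variances = dosages.var(axis=0)
    keep = variances > 0
    if not keep.all():
        dropped = [s for s, k in zip(snp_ids, keep) if not k]
        warnings.warn(f"monomorphic SNPs dropped from LD: {dropped}", stacklevel=2)
    dosages = dosages[:, keep]
    snp_ids = [s for s, k in zip(snp_ids, keep) if k]
    if not snp_ids:
        return LdMatrix(snp_ids=[], R=np.zeros((0, 0)), source="genotypes")

    R = np.corrcoef(dosages, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    R, magnitude = repair_psd(R)
    return LdMatrix(snp_ids=snp_ids, R=R, source="genotypes", repair_magnitude=magnitude)


def _cholesky_with_jitter(R: np.ndarray, jitter: float = 1e-10, attempts: int = 3) -> np.ndarray:
    """Cholesky factor of a (near-)PSD correlation matrix, adding a small
    diagonal jitter when exact semidefiniteness defeats the factorization."""
    eps = 0.0
    for _ in range(attempts + 1):
        try:
            return np.linalg.cholesky(R + eps * np.eye(R.shape[0]))
        except np.linalg.LinAlgError:
            eps = jitter if eps == 0.0 else eps * 10.0
    raise np.linalg.LinAlgError("Cholesky failed even with jitter")


def gene_p(
    assignment: GeneAssignment,
    snp_ps: np.ndarray,
    ld: LdMatrix,
    mc: McConfig,
) -> GeneScore | None:
    """Monte Carlo gene p-value for one gene.

    ``snp_ps`` must be aligned with ``assignment.snp_ids`` and with the rows
    of ``ld.R``.  Returns ``None`` (a no-score marker) for an empty
    assignment — never a silent p = 1.
    """
    if not assignment.snp_ids:
        return None
    snp_ps = np.asarray(snp_ps, dtype=float)
    if snp_ps.shape[0] != len(assignment.snp_ids):
        raise ValueError("snp_ps not aligned with assignment")
    if ld.snp_ids != assignment.snp_ids:
        raise ValueError("LD matrix SNPs do not match assignment")

    stat = float(sum(chisq_from_p(p) for p in snp_ps))
    k = len(assignment.snp_ids)
    L = _cholesky_with_jitter(ld.R)
    rng = child_rng(mc.seed, "gene_p", 0)

    exceed = 0
    done = 0
    for stage_total in mc.stages:
        batch = stage_total - done
        if batch > 0:
            # draw in chunks to bound memory at the largest stages
            remaining = batch
            while remaining > 0:
                m = min(remaining, 50_000)
                z = rng.standard_normal((m, k)) @ L.T
                null_stats = np.einsum("ij,ij->i", z, z)
                exceed += int(np.count_nonzero(null_stats >= stat))
                remaining -= m
            done = stage_total
        p_hat = (1 + exceed) / (1 + done)
        if p_hat >= mc.escalation_factor / stage_total:
            break
    return GeneScore(
        gene_id=assignment.gene_id,
        n_snps=k,
        stat=stat,
        p=(1 + exceed) / (1 + done),
        n_sims=done,
        seed=mc.seed,
    )


def score_genes(
    snps: list[SnpAssociation],
    genes: list[GeneAnnotation],
    genotypes: np.ndarray | None = None,
    snp_order: list[str] | None = None,
    ld_matrices: dict[str, LdMatrix] | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    mc: McConfig | None = None,
) -> tuple[list[GeneScore], list[str]]:
    """Score every gene; returns (scores, unscored gene ids).

    LD comes either from ``genotypes`` (columns ordered as ``snp_order``) or
    from per-gene ``ld_matrices``.  Each gene draws its null from a child
    seed derived from the base seed and the gene's index, so scoring is
    reproducible gene-by-gene.
    """
    if mc is None:
        mc = McConfig()
    if genotypes is None and ld_matrices is None:
        raise ValueError("provide genotypes or per-gene LD matrices")
    p_by_snp = {s.snp_id: s.p for s in snps}
    col_by_snp = (
        {sid: i for i, sid in enumerate(snp_order)} if snp_order is not None else {}
    )

    assignments = assign_snps(snps, genes, window_bp)
    scores: list[GeneScore] = []
    unscored: list[str] = []
    for i, a in enumerate(assignments):
        if not a.snp_ids:
            unscored.append(a.gene_id)
            continue
        if ld_matrices is not None and a.gene_id in ld_matrices:
            ld = ld_matrices[a.gene_id]
        else:
            if genotypes is None:
                raise ValueError(f"no LD source for gene {a.gene_id}")
            cols = [col_by_snp[sid] for sid in a.snp_ids]
            ld = ld_from_genotypes(genotypes[:, cols], snp_ids=a.snp_ids)
            if ld.snp_ids != a.snp_ids:  # monomorphic SNPs were dropped
                a = GeneAssignment(a.gene_id, ld.snp_ids, a.window_bp)
                if not a.snp_ids:
                    unscored.append(a.gene_id)
                    continue
        ps = np.array([p_by_snp[sid] for sid in a.snp_ids])
        gene_mc = McConfig(
            stages=mc.stages,
            escalation_factor=mc.escalation_factor,
            seed=_gene_child_seed(mc.seed, i),
        )
        score = gene_p(a, ps, ld, gene_mc)
        assert score is not None
        scores.append(score)
    logger.info("scored %d genes; %d unscored (no SNPs)", len(scores), len(unscored))
    return scores, unscored


def _gene_child_seed(base_seed: int, gene_index: int) -> int:
    from .seeds import child_seed

    return child_seed(base_seed, "gene_scoring", gene_index)


def multi_mapping_diagnostic(
    assignments: list[GeneAssignment],
    snp_ps: dict[str, float],
    alpha_snp: float = 5e-4,
) -> list[MultiMappingCluster]:
    """Clusters of genes whose significance may be driven by shared SNPs.

    Builds the bipartite graph linking each SNP with p < ``alpha_snp`` to
    every gene it is assigned to, and reports connected components that
    contain >= 2 genes — the machine-readable version of eyeballing a
    Manhattan plot over an overlapping gene family.
    """
    if not 0.0 < alpha_snp < 1.0:
        raise ValueError("alpha_snp must be in (0, 1)")
    graph = nx.Graph()
    for a in assignments:
        for sid in a.snp_ids:
            if snp_ps.get(sid, 1.0) < alpha_snp:
                graph.add_edge(("gene", a.gene_id), ("snp", sid))
    clusters = []
    for component in nx.connected_components(graph):
        gene_ids = sorted(n[1] for n in component if n[0] == "gene")
        snp_ids = sorted(n[1] for n in component if n[0] == "snp")
        if len(gene_ids) >= 2:
            clusters.append(MultiMappingCluster(gene_ids=gene_ids, snp_ids=snp_ids))
    clusters.sort(key=lambda c: c.gene_ids)
    return clusters
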