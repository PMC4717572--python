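"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain: PLINK ``.qassoc``-style TSV for SNP
associations (a minimal SNP/CHR/BP/P dialect is also accepted, so the
pipeline can start from external summary statistics), BED for gene models
(0-based half-open on disk, converted to 1-based inclusive on read),
3-column TSV edge lists for networks, one gene id per line for gold
standards, and CSV for result tables.  Floats are written at 12 significant
digits so reruns diff cleanly.  Every writer/reader pair is a round-trip
identity on valid data.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import SnpAssociation
from .evaluate import GoldStandard, QqData
from .gene_scoring import GeneAnnotation, GeneScore
from .reprioritize import AggregateRanking, TissueNetwork

__all__ = [
    "read_assoc_table",
    "write_assoc_table",
    "read_gene_bed",
    "write_gene_bed",
    "read_network",
    "write_network",
    "read_gold_standard",
    "write_gold_standard",
    "read_gene_scores",
    "write_gene_scores",
    "write_combined_results",
    "read_combined_results",
    "write_snp_table",
    "write_cohort",
    "read_cohort",
    "write_permuted_rankings",
    "read_permuted_rankings",
    "write_qq_data",
    "write_evaluation_report",
]

_FLOAT_FMT = "%.12g"

_QASSOC_COLS = ["SNP", "CHR", "BP", "BETA", "SE", "P"]
_MINIMAL_COLS = ["SNP", "CHR", "BP", "P"]


def read_assoc_table(path: str | Path) -> list[SnpAssociation]:
    """Read a qassoc-dialect or minimal (SNP, CHR, BP, P) association TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols == _QASSOC_COLS:
        minimal = False
    elif cols == _MINIMAL_COLS:
        minimal = True
    else:
        raise ValueError(
            f"{path}: unrecognized header {cols}; expected {_QASSOC_COLS} or {_MINIMAL_COLS}"
        )
    records: list[SnpAssociation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            snp_id = str(row.SNP)
            p = float(row.P)
            pos = int(row.BP)
            beta = np.nan if minimal else float(row.BETA)
            se = np.nan if minimal else float(row.SE)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{path}: line {i}: p={p} outside (0, 1]")
        if snp_id in seen:
            raise ValueError(f"{path}: line {i}: duplicate SNP id {snp_id}")
        seen.add(snp_id)
        records.append(
            SnpAssociation(snp_id=snp_id, chrom=str(row.CHR), pos=pos, p=p, beta=beta, se=se)
        )
    return records


def write_assoc_table(snps: list[SnpAssociation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "SNP": [s.snp_id for s in snps],
            "CHR": [s.chrom for s in snps],
            "BP": [s.pos for s in snps],
            "BETA": [s.beta for s in snps],
            "SE": [s.se for s in snps],
            "P": [s.p for s in snps],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read genes from BED (chrom, start, end, gene_id), 0-based half-open;
    internal coordinates are 1-based inclusive."""
    genes = []
    seen: set[str] = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}: line {i}: expected >= 4 BED columns")
        chrom, start0, end0, gene_id = fields[:4]
        strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "unknown"
        if gene_id in seen:
            raise ValueError(f"{path}: line {i}: duplicate gene id {gene_id}")
        seen.add(gene_id)
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=chrom,
                start=int(start0) + 1,
                end=int(end0),
                strand=strand,
            )
        )
    return genes


def write_gene_bed(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in {"+", "-"} else "."
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")


def read_network(path: str | Path) -> TissueNetwork:
    """Read a 3-column (gene_a, gene_b, weight) edge list into a network."""
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}: line {i}: expected 3 columns")
        a, b, w_str = fields
        try:
            w = float(w_str)
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: bad weight {w_str!r}") from exc
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"{path}: line {i}: weight {w} outside [0, 1]")
        if a == b:
            warnings.warn(f"{path}: line {i}: self-loop {a} dropped", stacklevel=2)
            nodes.add(a)
            continue
        key = (a, b) if a < b else (b, a)
        if key in edges and edges[key] != w:
            raise ValueError(
                f"{path}: line {i}: duplicate edge {key} with conflicting weights "
                f"{edges[key]} vs {w}"
            )
        edges[key] = w
        nodes.update(key)
    gene_ids = sorted(nodes)
    idx = {g: i for i, g in enumerate(gene_ids)}
    W = np.zeros((len(gene_ids), len(gene_ids)))
    for (a, b), w in edges.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return TissueNetwork(gene_ids=gene_ids, W=W)


def write_network(network: TissueNetwork, path: str | Path) -> None:
    iu, ju = np.nonzero(np.triu(network.W, k=1))
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            a, b = network.gene_ids[i], network.gene_ids[j]
            if b < a:
                a, b = b, a
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT % network.W[i, j]}\n")


def read_gold_standard(
    path: str | Path, universe: set[str] | None = None, label: str | None = None
) -> GoldStandard:
    """Read a gold standard: one gene id per line, ``#`` comments allowed."""
    path = Path(path)
    positives = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            positives.add(line)
    if universe is None:
        universe = set(positives)
    return GoldStandard(
        label=label or path.stem, positives=positives, universe=universe | positives
    )


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gold standard: {gold.label}\n")
        for g in sorted(gold.positives):
            fh.write(f"{g}\n")


def write_gene_scores(
    scores: list[GeneScore],
    path: str | Path,
    genes: list[GeneAnnotation] | None = None,
) -> None:
    """Per-gene results CSV: gene, chr, nSNPs, Test_Statistic, P, n_sims, seed."""
    chrom = {g.gene_id: g.chrom for g in genes} if genes else {}
    df = pd.DataFrame(
        {
            "gene": [s.gene_id for s in scores],
            "chr": [chrom.get(s.gene_id, "NA") for s in scores],
            "nSNPs": [s.n_snps for s in scores],
            "Test_Statistic": [s.stat for s in scores],
            "P": [s.p for s in scores],
            "n_sims": [s.n_sims for s in scores],
            "seed": [s.seed for s in scores],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gene_scores(path: str | Path) -> list[GeneScore]:
    df = pd.read_csv(path)
    return [
        GeneScore(
            gene_id=str(r.gene),
            n_snps=int(r.nSNPs),
            stat=float(r.Test_Statistic),
            p=float(r.P),
            n_sims=int(r.n_sims),
            seed=int(r.seed),
        )
        for r in df.itertuples(index=False)
    ]


def write_combined_results(aggregate: AggregateRanking, path: str | Path) -> None:
    """Aggregate NetWAS ranking CSV: gene, summed_rank, mean_rank, final_rank."""
    rows = []
    for final_rank, gene in enumerate(aggregate.order, start=1):
        rows.append(
            {
                "gene": gene,
                "summed_rank": int(aggregate.summed_rank[gene]),
                "mean_rank": aggregate.mean_rank[gene],
                "final_rank": final_rank,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_combined_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_snp_table(snp_table: pd.DataFrame, path: str | Path) -> None:
    snp_table[["SNP", "CHR", "BP"]].to_csv(path, sep="\t", index=False)


def write_cohort(cohort, directory: str | Path) -> None:
    """Write cohort matrices as plain TSV: genotypes (subjects x SNPs with
    SNP-id header), and phenotype + covariates in one table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geno = pd.DataFrame(cohort.genotypes, columns=list(cohort.snp_table["SNP"]))
    geno.to_csv(directory / "genotypes.tsv", sep="\t", index=False)
    pheno = pd.DataFrame(
        {
            "phenotype": cohort.phenotype,
            **{
                f"covariate_{j}": cohort.covariates[:, j]
                for j in range(cohort.covariates.shape[1])
            },
        }
    )
    pheno.to_csv(directory / "phenotype.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    write_snp_table(cohort.snp_table, directory / "snps.tsv")


def read_cohort(directory: str | Path):
    """Read a cohort written by :func:`write_cohort`.  Missing values are
    rejected; the truth set and tagged SNPs are not stored on disk."""
    from .simulate import SyntheticCohort

    directory = Path(directory)
    geno = pd.read_csv(directory / "genotypes.tsv", sep="\t")
    pheno = pd.read_csv(directory / "phenotype.tsv", sep="\t")
    snp_table = pd.read_csv(directory / "snps.tsv", sep="\t", dtype={"CHR": str})
    if geno.isna().any().any() or pheno.isna().any().any():
        raise ValueError(f"{directory}: missing values are not supported")
    covar_cols = [c for c in pheno.columns if c.startswith("covariate_")]
    return SyntheticCohort(
        genotypes=geno.to_numpy(dtype=np.int8),
        phenotype=pheno["phenotype"].to_numpy(dtype=float),
        covariates=pheno[covar_cols].to_numpy(dtype=float),
        snp_table=snp_table,
    )


def write_permuted_rankings(rankings: list[pd.Series], path: str | Path) -> None:
    """Permuted-run gene scores, one column per permutation."""
    df = pd.DataFrame({f"perm_{j}": r for j, r in enumerate(rankings)})
    df.index.name = "gene"
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_permuted_rankings(path: str | Path) -> list[pd.Series]:
    df = pd.read_csv(path, index_col="gene")
    return [df[c] for c in df.columns]


def write_qq_data(qq: QqData, path: str | Path) -> None:
    df = pd.DataFrame({"expected": qq.expected, "observed": qq.observed})
    with open(path, "w") as fh:
        fh.write(f"# lambda = {_FLOAT_FMT % qq.lambda_inflation}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_evaluation_report(comparison, path_csv: str | Path, path_txt: str | Path) -> None:
    rows = []
    for res in (comparison.gwas, comparison.netwas):
        rows.append(
            {
                "method": res.method,
                "auc": res.auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ci_level": res.ci_level,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
            }
        )
    rows.append(
        {
            "method": "netwas_permuted_mean",
            "auc": comparison.permuted_mean_auc,
            "ci_low": comparison.permuted_band[0],
            "ci_high": comparison.permuted_band[1],
            "ci_level": comparison.gwas.ci_level,
            "n_pos": comparison.gwas.n_pos,
            "n_neg": comparison.gwas.n_neg,
        }
    )
    pd.DataFrame(rows).to_csv(path_csv, index=False, float_format=_FLOAT_FMT)
    with open(path_txt, "w") as fh:
        fh.write(
            "Gene-ranking evaluation against gold standard\n"
            f"  GWAS ranking AUC:   {comparison.gwas.auc:.4f} "
            f"[{comparison.gwas.ci_low:.4f}, {comparison.gwas.ci_high:.4f}]\n"
            f"  NetWAS ranking AUC: {comparison.netwas.auc:.4f} "
            f"[{comparison.netwas.ci_low:.4f}, {comparison.netwas.ci_high:.4f}]\n"
            f"  Permuted-label NetWAS mean AUC: {comparison.permuted_mean_auc:.4f} "
            f"band [{comparison.permuted_band[0]:.4f}, {comparison.permuted_band[1]:.4f}]\n"
            f"  NetWAS > GWAS: {comparison.netwas_above_gwas}\n"
            f"  NetWAS above permuted band: {comparison.netwas_above_permuted_band}\n"
            f"  GWAS above permuted band: {comparison.gwas_above_permuted_band}\n"
        )
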