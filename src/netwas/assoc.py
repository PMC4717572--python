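"""Per-SNP association testing by ordinary least squares with covariates.

Each SNP is tested one at a time: phenotype regressed on an intercept, the
additive dosage (0/1/2 coding, the PLINK ``--linear`` convention) and the
four covariates, with a two-sided t-test on the dosage coefficient at
n - 6 degrees of freedom.  Computation uses the Frisch-Waugh-Lovell
partialling-out identity: phenotype and dosages are residualized on
(intercept, covariates) once, and each SNP's coefficient then comes from a
univariate regression on its residualized dosage — algebraically identical
to the full per-SNP OLS fit, but one matrix product for the whole panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SnpAssociation", "snp_association"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpAssociation:
    """One row of a GWAS summary table."""

    snp_id: str
    chrom: str
    pos: int
    p: float
    beta: float = np.nan
    se: float = np.nan

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"SNP {self.snp_id}: p must be in (0, 1], got {self.p}")
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1 (1-based)")


def _check_design(covariates: np.ndarray, n: int) -> np.ndarray:
    """Validate the (intercept | covariates) design; name collinear columns."""
    X = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        names = ["intercept"] + [f"covariate_{j}" for j in range(covariates.shape[1])]
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    return X


def snp_association(cohort) -> list[SnpAssociation]:
    """GWAS of a quantitative phenotype: OLS per SNP, covariate-adjusted.

    Monomorphic SNPs get p = 1 and beta = 0 with a logged warning.  Missing
    genotype or covariate values are rejected, not imputed.
    """
    y = np.asarray(cohort.phenotype, dtype=float)
    G = np.asarray(cohort.genotypes, dtype=float)
    C = np.asarray(cohort.covariates, dtype=float)
    n = y.shape[0]
    n_covar = C.shape[1]
    df = n - (2 + n_covar)  # intercept + dosage + covariates
    if df < 1:
        raise ValueError(f"too few subjects: n={n} with {n_covar} covariates")
    if np.isnan(G).any() or np.isnan(C).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")

    X = _check_design(C, n)
    # residualize phenotype and all dosages on (intercept, covariates)
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)

    sxx = np.einsum("ij,ij->j", G_res, G_res)
    mono = (G.var(axis=0) == 0) | (sxx <= 0)
    if mono.any():
        ids = [cohort.snp_table["SNP"].iloc[j] for j in np.flatnonzero(mono)]
        logger.warning("monomorphic SNPs assigned p=1: %s", ids)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, (G_res.T @ y_res) / np.where(mono, 1.0, sxx))
        rss = np.einsum("i,i->", y_res, y_res) - beta**2 * sxx
        sigma2 = np.clip(rss, 0.0, None) / df
        se = np.sqrt(np.where(mono, np.nan, sigma2 / np.where(mono, 1.0, sxx)))
        tstat = np.where(mono, 0.0, beta / se)
    p = np.where(mono, 1.0, 2.0 * stats.t.sf(np.abs(tstat), df=df))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = cohort.snp_table
    return [
        SnpAssociation(
            snp_id=str(table["SNP"].iloc[j]),
            chrom=str(table["CHR"].iloc[j]),
            pos=int(table["BP"].iloc[j]),
            p=float(p[j]),
            beta=float(beta[j]),
            se=float(se[j]) if not mono[j] else np.nan,
        )
        for j in range(G.shape[1])
    ]
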