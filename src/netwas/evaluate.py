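"""Evaluation of gene rankings against a gold standard.

AUC is the probability that a randomly chosen gold-positive gene outranks a
randomly chosen negative, computed as the Mann-Whitney U statistic with
mid-rank tie correction (ties count one half).  Uncertainty comes from a
percentile bootstrap over genes (each resampled gene carries its label), and
the permutation null is summarized by the bootstrap confidence band for the
mean AUC across permuted-label runs.  Calibration of gene p-values is
checked with quantile-quantile data and a genomic-inflation-style lambda:
the ratio of the median observed chi-square(1) statistic to the null
chi-square(1) median (computed by quantile inversion at run time, not
hard-coded).

Every method is evaluated on one common gene universe — the intersection of
the gold-standard universe with the genes each ranking covers — so AUC
differences reflect ranking quality, not coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seeds import child_rng

__all__ = [
    "GoldStandard",
    "EvalResult",
    "QqData",
    "MethodComparison",
    "ranking_from_pvalues",
    "ranking_from_aggregate",
    "roc_auc",
    "bootstrap_ci",
    "permutation_band",
    "qq_inflation",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    """Known disease genes (positives) within an evaluation universe."""

    label: str
    positives: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.positives <= self.universe:
            raise ValueError("gold positives must be a subset of the universe")


@dataclass
class EvalResult:
    method: str
    auc: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    n_pos: int
    n_neg: int
    seed: int


@dataclass
class QqData:
    """Sorted observed p-values vs. uniform expected quantiles, plus lambda."""

    observed: np.ndarray
    expected: np.ndarray
    lambda_inflation: float


@dataclass
class MethodComparison:
    gwas: EvalResult
    netwas: EvalResult
    permuted_mean_auc: float
    permuted_band: tuple[float, float]
    netwas_above_gwas: bool = field(init=False)
    netwas_above_permuted_band: bool = field(init=False)
    gwas_above_permuted_band: bool = field(init=False)

    def __post_init__(self) -> None:
        self.netwas_above_gwas = self.netwas.auc > self.gwas.auc
        self.netwas_above_permuted_band = self.netwas.auc > self.permuted_band[1]
        self.gwas_above_permuted_band = self.gwas.auc > self.permuted_band[1]


def ranking_from_pvalues(gene_ps) -> pd.Series:
    """Scores for AUC from p-values: smaller p means more disease-like."""
    ps = pd.Series(gene_ps, dtype=float) if not isinstance(gene_ps, pd.Series) else gene_ps
    return -ps.astype(float)


def ranking_from_aggregate(aggregate) -> pd.Series:
    """Scores for AUC from a summed-rank aggregate (smaller is better)."""
    return -aggregate.summed_rank.astype(float)


def _scores_and_labels(
    ranking: pd.Series, gold: GoldStandard
) -> tuple[np.ndarray, np.ndarray]:
    ranking = pd.Series(ranking, dtype=float) if not isinstance(ranking, pd.Series) else ranking
    genes = sorted(gold.universe & set(ranking.index))
    if not genes:
        raise ValueError("ranking and gold-standard universe do not intersect")
    scores = ranking.reindex(genes).to_numpy(dtype=float)
    labels = np.array([g in gold.positives for g in genes])
    if not labels.any():
        raise ValueError("no gold positives in the evaluation universe")
    if labels.all():
        raise ValueError("no gold negatives in the evaluation universe")
    return scores, labels


def _auc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)  # mid-ranks on ties
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(ranking, gold: GoldStandard) -> float:
    """Mid-rank AUC of a gene ranking (higher score = more disease-like)
    against the gold standard, over universe ∩ ranked genes."""
    scores, labels = _scores_and_labels(ranking, gold)
    return _auc_midrank(scores, labels)


def bootstrap_ci(
    ranking,
    gold: GoldStandard,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    method: str = "ranking",
) -> EvalResult:
    """Percentile bootstrap CI for the AUC, resampling genes with labels.

    Replicates that draw only one class are redrawn (count logged).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    scores, labels = _scores_and_labels(ranking, gold)
    auc = _auc_midrank(scores, labels)
    rng = child_rng(seed, "bootstrap_auc")
    n = scores.size
    reps = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
            redraws += 1
        reps[b] = _auc_midrank(scores[idx], lab)
    if redraws:
        logger.info("bootstrap: %d single-class replicates redrawn", redraws)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    if not lo <= auc <= hi:
        logger.info(
            "point AUC %.4f outside percentile interval [%.4f, %.4f]", auc, lo, hi
        )
    return EvalResult(
        method=method,
        auc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_boot=n_boot,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
        seed=seed,
    )


def permutation_band(
    permuted_rankings,
    gold: GoldStandard,
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(mean AUC, band low, band high) for permuted-label runs.

    The band is the bootstrap percentile CI for the mean AUC over the
    permutations.
    """
    permuted_rankings = list(permuted_rankings)
    if len(permuted_rankings) < 30:
        raise ValueError("need >= 30 permuted rankings for a stable band")
    aucs = np.array(sorted(roc_auc(r, gold) for r in permuted_rankings))
    rng = child_rng(seed, "permutation_band")
    means = rng.choice(aucs, size=(n_boot, aucs.size), replace=True).mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(aucs.mean()), float(lo), float(hi)


def qq_inflation(gene_ps) -> QqData:
    """QQ data and inflation lambda for a set of gene p-values.

    lambda = median(chi2_1 quantile of observed p) / chi2_1 median; 1 under
    perfect calibration, > 1 when small p-values are enriched.
    """
    ps = np.sort(np.asarray(pd.Series(gene_ps, dtype=float).to_numpy()))
    if ps.size < 20:
        raise ValueError("need >= 20 p-values")
    if ps[0] <= 0.0 or ps[-1] > 1.0:
        raise ValueError("p-values must be in (0, 1]")
    n = ps.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    chi_obs = stats.chi2.isf(ps, df=1)
    lam = float(np.median(chi_obs) / stats.chi2.isf(0.5, df=1))
    return QqData(observed=ps, expected=expected, lambda_inflation=lam)


def compare_methods(
    gwas_ranking,
    netwas_ranking,
    permuted_rankings,
    gold: GoldStandard,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> MethodComparison:
    """AUC + CI for GWAS and NetWAS rankings plus the permutation band,
    all on the common universe, with the qualitative ordering flags."""
    gwas_ranking = pd.Series(gwas_ranking, dtype=float)
    netwas_ranking = pd.Series(netwas_ranking, dtype=float)
    if set(gwas_ranking.index) != set(netwas_ranking.index):
        diff = sorted(set(gwas_ranking.index) ^ set(netwas_ranking.index))
        raise ValueError(f"rankings cover different universes; difference: {diff}")
    gwas = bootstrap_ci(gwas_ranking, gold, n_boot, ci_level, seed, method="gwas")
    netwas = bootstrap_ci(netwas_ranking, gold, n_boot, ci_level, seed, method="netwas")
    mean_auc, lo, hi = permutation_band(
        permuted_rankings, gold, ci_level=ci_level, n_boot=n_boot, seed=seed
    )
    return MethodComparison(
        gwas=gwas,
        netwas=netwas,
        permuted_mean_auc=mean_auc,
        permuted_band=(lo, hi),
    )
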