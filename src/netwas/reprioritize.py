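"""Network-wide association study (NetWAS): SVM re-ranking of genes.

Phase II of the pipeline.  Genes with nominally significant gene-level
p-values (p < 0.01, uncorrected) are positive examples; scored,
non-significant genes are negatives; a gene's feature vector is its row of
the tissue network's weight matrix.  A linear soft-margin SVM is trained
under five-fold cross-validation: each labeled gene receives the decision
value of the one fold-model that did not train on it (so no gene is ranked
by a model that saw its own label), and unlabeled genes receive the mean
decision value over the five fold-models.  Genes are ranked by descending
decision value (rank 1 = most disease-like).

Single runs are repeated over many independently drawn cross-validation
partitions, and the repeats aggregated by summing each gene's ranks; the
ascending summed-rank order is the final prioritization (identical to the
mean-rank order, which is also reported).  A permutation null — re-running
on score sets whose gene-to-p-value assignment has been shuffled —
calibrates how much of the ranking's performance reflects the network
alone.

Class imbalance (positives are typically 1-5 % of genes) is handled by
inverse-frequency class weighting; network weights already live in [0, 1]
with a shared meaning across genes, so no feature scaling is applied.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .seeds import child_rng, child_seed

__all__ = [
    "TissueNetwork",
    "LabelSet",
    "NetwasRun",
    "AggregateRanking",
    "scores_to_series",
    "build_labels",
    "netwas_single",
    "netwas_iterate",
    "aggregate_ranks",
    "permute_labels",
]

logger = logging.getLogger(__name__)

NOMINAL_THRESHOLD = 0.01
N_FOLDS = 5


@dataclass
class TissueNetwork:
    """Weighted undirected gene-gene functional network.

    ``W`` is symmetric with zero diagonal and entries in [0, 1]; a gene's
    classifier feature vector is its row of ``W``.
    """

    gene_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene ids must be unique")
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} genes")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have zero diagonal (no self-loops)")
        if self.W.min() < 0 or self.W.max() > 1:
            raise ValueError("weights must be in [0, 1]")

    def index_of(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)


@dataclass
class LabelSet:
    """Training labels from gene scores: nominal significance as truth proxy."""

    threshold: float
    positives: list[str]
    negatives: list[str]
    unlabeled: list[str]


@dataclass
class NetwasRun:
    """One cross-validated SVM run: decision values and the induced ranking."""

    iteration: int
    folds: dict[str, int]  # labeled gene -> fold index
    decision_values: pd.Series  # gene -> decision value, all network genes
    ranks: pd.Series  # gene -> rank, 1 = most disease-like
    seed: int


@dataclass
class AggregateRanking:
    summed_rank: pd.Series  # gene -> sum of ranks across runs
    mean_rank: pd.Series
    order: list[str]  # final prioritization, best first
    n_iterations: int


def scores_to_series(gene_scores) -> pd.Series:
    """Normalize gene scores (mapping, Series, or GeneScore iterable) to a
    Series of p-values indexed by gene id."""
    if isinstance(gene_scores, pd.Series):
        return gene_scores.astype(float)
    if isinstance(gene_scores, Mapping):
        return pd.Series(dict(gene_scores), dtype=float)
    return pd.Series({s.gene_id: s.p for s in gene_scores}, dtype=float)


def build_labels(
    gene_scores,
    network: TissueNetwork,
    threshold: float = NOMINAL_THRESHOLD,
) -> LabelSet:
    """Partition network genes into positives (p < threshold, strict),
    negatives (scored, p >= threshold) and unlabeled (no gene score)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ps = scores_to_series(gene_scores)
    in_net = set(network.gene_ids)
    positives = sorted(g for g, p in ps.items() if p < threshold and g in in_net)
    negatives = sorted(g for g, p in ps.items() if p >= threshold and g in in_net)
    unlabeled = sorted(in_net - set(ps.index))
    if not positives:
        raise ValueError(
            "no nominally significant genes below the threshold: the GWAS "
            "lacks nominal signal, so there is nothing for the classifier "
            "to learn (check the gene p-value inflation first)"
        )
    logger.info(
        "labels: %d positives, %d negatives, %d unlabeled (threshold %g)",
        len(positives), len(negatives), len(unlabeled), threshold,
    )
    return LabelSet(threshold, positives, negatives, unlabeled)


def _fit_linear_svm(X: np.ndarray, y: np.ndarray, cost: float) -> SVC:
    """Linear soft-margin SVM with inverse-frequency class weighting."""
    # tol tightened from libsvm's 1e-3 default: decision values feed a
    # ranking, so they must be converged well past rank resolution
    model = SVC(kernel="linear", C=cost, class_weight="balanced", tol=1e-6)
    model.fit(X, y)
    return model


def _draw_folds(
    labeled: list[str], y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random 5-fold partition; re-draw (<= 10 times) until every training
    complement has both classes, then fall back to a stratified split."""
    n = len(labeled)
    for _ in range(10):
        folds = rng.permuted(np.arange(n) % N_FOLDS)
        ok = all(
            len(np.unique(y[folds != f])) == 2 for f in range(N_FOLDS)
        )
        if ok:
            return folds
    # stratified: deal each class round-robin into folds
    folds = np.empty(n, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % N_FOLDS
    return folds


def _rank_by_decision(decision: pd.Series) -> pd.Series:
    """Ranks 1..n by descending decision value, ties broken by gene id."""
    order = sorted(decision.index, key=lambda g: (-decision[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(decision.index)


def netwas_single(
    network: TissueNetwork,
    labels: LabelSet,
    child_seed_value: int,
    svm_cost: float = 1.0,
) -> NetwasRun:
    """One five-fold cross-validated SVM run on the network.

    Labeled genes are scored held-out (by the fold-model that did not see
    them); unlabeled genes by the mean over the five fold-models.
    """
    labeled = labels.positives + labels.negatives
    if len(labeled) < 10:
        raise ValueError(f"need >= 10 labeled genes, have {len(labeled)}")
    if not network.W.any():
        raise ValueError("degenerate network: all rows are zero (no edges)")
    isolated = int((~network.W.any(axis=1)).sum())
    if isolated:
        # isolated genes are legitimate in sparse networks; they are scored
        # by the bias term alone
        logger.debug("%d isolated genes (all-zero feature rows)", isolated)

    rng = np.random.default_rng(child_seed_value)
    pos_set = set(labels.positives)
    y = np.array([1 if g in pos_set else -1 for g in labeled])
    folds = _draw_folds(labeled, y, rng)

    X_all = network.W
    labeled_idx = network.index_of(labeled)
    decision = np.zeros(len(network.gene_ids))
    unlabeled_mask = np.ones(len(network.gene_ids), dtype=bool)
    unlabeled_mask[labeled_idx] = False

    unlabeled_sum = np.zeros(int(unlabeled_mask.sum()))
    for f in range(N_FOLDS):
        train = folds != f
        model = _fit_linear_svm(X_all[labeled_idx[train]], y[train], svm_cost)
        held_out = labeled_idx[~train]
        if held_out.size:
            decision[held_out] = model.decision_function(X_all[held_out])
        if unlabeled_sum.size:
            unlabeled_sum += model.decision_function(X_all[unlabeled_mask])
    if unlabeled_sum.size:
        decision[unlabeled_mask] = unlabeled_sum / N_FOLDS

    decision_series = pd.Series(decision, index=network.gene_ids)
    if not np.isfinite(decision_series).all():
        raise ValueError("non-finite decision values")
    return NetwasRun(
        iteration=0,
        folds={g: int(f) for g, f in zip(labeled, folds)},
        decision_values=decision_series,
        ranks=_rank_by_decision(decision_series),
        seed=child_seed_value,
    )


def netwas_iterate(
    network: TissueNetwork,
    labels: LabelSet,
    n_iterations: int,
    master_seed: int,
    svm_cost: float = 1.0,
) -> list[NetwasRun]:
    """Repeat :func:`netwas_single` over independently seeded CV partitions."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    runs = []
    for i in range(n_iterations):
        try:
            run = netwas_single(
                network, labels, child_seed(master_seed, "netwas_cv", i), svm_cost
            )
        except Exception as exc:  # annotate with the failing iteration
            raise RuntimeError(f"NetWAS iteration {i} failed: {exc}") from exc
        run.iteration = i
        runs.append(run)
        if (i + 1) % 50 == 0:
            logger.info("NetWAS iteration %d/%d", i + 1, n_iterations)
    return runs


def aggregate_ranks(runs: list[NetwasRun]) -> AggregateRanking:
    """Sum each gene's rank across runs; final order is ascending summed
    rank with lexicographic tie-break.  The mean-rank order is identical
    when every run covers the same genes; both are reported."""
    if not runs:
        raise ValueError("no runs to aggregate")
    universe = set(runs[0].ranks.index)
    for r in runs[1:]:
        other = set(r.ranks.index)
        if other != universe:
            diff = sorted(universe.symmetric_difference(other))
            raise ValueError(f"runs rank different gene sets; difference: {diff}")
    genes = sorted(universe)
    summed = sum(r.ranks.reindex(genes) for r in runs)
    order = sorted(genes, key=lambda g: (summed[g], g))
    return AggregateRanking(
        summed_rank=summed.astype(int),
        mean_rank=summed / len(runs),
        order=order,
        n_iterations=len(runs),
    )


def permute_labels(gene_scores, seed: int) -> pd.Series:
    """Shuffle the gene-to-p-value assignment, preserving the p multiset.

    The label set derived from the permuted scores has exactly as many
    positives as the original — the permutation null for NetWAS.
    """
    ps = scores_to_series(gene_scores)
    if len(ps) < 2:
        raise ValueError("need >= 2 genes to permute")
    rng = child_rng(seed, "permute_labels")
    return pd.Series(rng.permutation(ps.to_numpy()), index=ps.index)
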