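"""Gene scoring: window assignment, chi-square transform, LD estimation
with PSD repair, the Monte Carlo gene p-value, and the multi-mapping
diagnostic."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from netwas.assoc import SnpAssociation
from netwas.gene_scoring import (
    GeneAnnotation,
    GeneAssignment,
    LdMatrix,
    McConfig,
    assign_snps,
    chisq_from_p,
    gene_p,
    ld_from_genotypes,
    multi_mapping_diagnostic,
    repair_psd,
)
from netwas.simulate import SimConfig, generate_gene_models


def snp(snp_id, pos, p=0.5, chrom="1"):
    return SnpAssociation(snp_id=snp_id, chrom=chrom, pos=pos, p=p)


class TestAssignSnps:
    def test_window_boundaries_inclusive(self):
        gene = GeneAnnotation("G1", "1", 100_000, 120_000)
        inside = snp("a", 100_000 - 50_000)
        outside = snp("b", 100_000 - 50_001)
        (assignment,) = assign_snps([inside, outside], [gene], window_bp=50_000)
        assert assignment.snp_ids == ["a"]
        right_edge = snp("c", 120_000 + 50_000)
        beyond = snp("d", 120_000 + 50_001)
        (assignment,) = assign_snps([right_edge, beyond], [gene], window_bp=50_000)
        assert assignment.snp_ids == ["c"]

    def test_matches_brute_force_on_overlap_cluster(self):
        config = SimConfig(n_genes=20, n_disease_genes=0, overlap_cluster_size=15, seed=6)
        genes = generate_gene_models(config)
        rng = np.random.default_rng(2)
        lo = min(g.start for g in genes) - 60_000
        hi = max(g.end for g in genes) + 60_000
        snps = [
            snp(f"s{i}", int(pos))
            for i, pos in enumerate(sorted(rng.integers(max(lo, 1), hi, size=400)))
        ]
        assignments = {a.gene_id: set(a.snp_ids) for a in assign_snps(snps, genes, 50_000)}
        for g in genes:  # exhaustive O(genes x SNPs) oracle
            expected = {
                s.snp_id
                for s in snps
                if s.chrom == g.chrom and g.start - 50_000 <= s.pos <= g.end + 50_000
            }
            assert assignments[g.gene_id] == expected

    def test_snp_in_shared_core_maps_to_all_cluster_genes(self):
        config = SimConfig(n_genes=20, n_disease_genes=0, overlap_cluster_size=15, seed=6)
        genes = generate_gene_models(config)
        cluster = genes[-15:]
        core = (max(g.start for g in cluster) + min(g.end for g in cluster)) // 2
        assignments = assign_snps([snp("core", int(core))], genes, 50_000)
        hit = {a.gene_id for a in assignments if a.snp_ids}
        assert hit >= {g.gene_id for g in cluster}

    def test_duplicate_snp_ids_rejected(self):
        gene = GeneAnnotation("G1", "1", 1, 10)
        with pytest.raises(ValueError, match="duplicate"):
            assign_snps([snp("a", 1), snp("a", 2)], [gene])

    def test_unknown_chromosome_warned_and_skipped(self):
        gene = GeneAnnotation("G1", "1", 1, 10)
        with pytest.warns(UserWarning, match="chromosome"):
            (assignment,) = assign_snps([snp("a", 5, chrom="7")], [gene])
        assert assignment.snp_ids == []


class TestChisqFromP:
    def test_support_edge_and_monotonicity(self):
        assert chisq_from_p(1.0) == 0.0
        ps = [0.9, 0.5, 0.1, 0.01, 1e-6]
        vals = [chisq_from_p(p) for p in ps]
        assert vals == sorted(vals)

    def test_matches_independent_quantile_inversion(self):
        # invert the chi2_1 survival function numerically, no isf involved
        target = brentq(lambda x: stats.chi2.sf(x, 1) - 0.05, 1e-12, 100, xtol=1e-13)
        assert chisq_from_p(0.05) == pytest.approx(target, abs=1e-10)
        assert chisq_from_p(0.05) == pytest.approx(3.841458820694124, rel=1e-9)

    @pytest.mark.parametrize("p", [0.5, 0.01, 1e-6])
    def test_round_trip(self, p):
        assert stats.chi2.sf(chisq_from_p(p), 1) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            chisq_from_p(bad)

    def test_underflow_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            val = chisq_from_p(1e-320)
        assert np.isfinite(val)


class TestLd:
    def test_duplicate_columns_perfect_ld(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=200).astype(float)
        ld = ld_from_genotypes(np.column_stack([col, col]))
        assert ld.R[0, 1] == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(2000, 6)).astype(float)
        ld = ld_from_genotypes(g)
        off = ld.R[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_monomorphic_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        g = np.column_stack([np.full(50, 2.0), rng.integers(0, 3, 50), rng.integers(0, 3, 50)])
        with pytest.warns(UserWarning, match="monomorphic"):
            ld = ld_from_genotypes(g, snp_ids=["m", "a", "b"])
        assert ld.snp_ids == ["a", "b"]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            ld_from_genotypes(np.array([[1.0, 2.0]]))

    def test_indefinite_matrix_repaired(self):
        # valid-looking "correlation" matrix that is not PSD
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        fixed, magnitude = repair_psd(R)
        assert magnitude > 0
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        np.testing.assert_allclose(np.diag(fixed), 1.0)
        np.testing.assert_allclose(fixed, fixed.T)


def make_gene_inputs(ps, R, stages=(10_000,), seed=0):
    k = len(ps)
    ids = [f"s{i}" for i in range(k)]
    assignment = GeneAssignment(gene_id="G", snp_ids=ids, window_bp=50_000)
    ld = LdMatrix(snp_ids=ids, R=np.asarray(R, dtype=float), source="provided")
    return assignment, np.asarray(ps), ld, McConfig(stages=stages, seed=seed)


class TestGenePValue:
    def test_empty_assignment_returns_no_score(self):
        assignment = GeneAssignment("G", [], 50_000)
        ld = LdMatrix([], np.zeros((0, 0)))
        assert gene_p(assignment, np.array([]), ld, McConfig()) is None

    def test_reproducible_and_never_zero(self):
        args = make_gene_inputs([1e-10, 1e-9], np.eye(2), stages=(1_000,), seed=5)
        a = gene_p(*args)
        b = gene_p(*args)
        assert a.p == b.p
        assert a.p >= 1.0 / (1 + a.n_sims) > 0

    def test_invariant_to_snp_ordering(self):
        R = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        ps = [0.01, 0.3, 0.07]
        perm = [2, 0, 1]
        a = gene_p(*make_gene_inputs(ps, R, seed=9))
        R_perm = R[np.ix_(perm, perm)]
        b = gene_p(*make_gene_inputs([ps[i] for i in perm], R_perm, seed=9))
        # same statistic; p agrees within joint Monte Carlo error
        assert a.stat == pytest.approx(b.stat)
        se = 2 * np.sqrt(a.p * (1 - a.p) / a.n_sims)
        assert abs(a.p - b.p) < 3 * np.sqrt(2) * se

    def test_monotone_in_statistic(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        p_list = []
        for snp_p in (0.5, 0.1, 0.01, 0.001):
            score = gene_p(*make_gene_inputs([snp_p, snp_p], R, seed=3))
            p_list.append(score.p)
        assert p_list == sorted(p_list, reverse=True)

    def test_adaptive_escalation_on_small_p(self):
        args = make_gene_inputs(
            [1e-8, 1e-8], np.eye(2), stages=(1_000, 10_000, 100_000), seed=2
        )
        score = gene_p(*args)
        assert score.n_sims == 100_000  # tiny p forces the final stage
        mild = gene_p(*make_gene_inputs([0.5, 0.5], np.eye(2),
                                        stages=(1_000, 10_000, 100_000), seed=2))
        assert mild.n_sims == 1_000  # clearly null gene stops early


class TestMultiMappingDiagnostic:
    def test_no_significant_snps_empty(self):
        a = GeneAssignment("G1", ["s1"], 50_000)
        assert multi_mapping_diagnostic([a], {"s1": 0.5}, alpha_snp=1e-3) == []

    def test_disjoint_single_genes_not_reported(self):
        a = GeneAssignment("G1", ["s1"], 50_000)
        b = GeneAssignment("G2", ["s2"], 50_000)
        assert multi_mapping_diagnostic([a, b], {"s1": 1e-8, "s2": 1e-8}, 1e-3) == []

    def test_shared_significant_snp_links_genes(self):
        a = GeneAssignment("G1", ["s1", "s2"], 50_000)
        b = GeneAssignment("G2", ["s2", "s3"], 50_000)
        clusters = multi_mapping_diagnostic(
            [a, b], {"s1": 0.5, "s2": 1e-8, "s3": 0.9}, 1e-3
        )
        assert len(clusters) == 1
        assert clusters[0].gene_ids == ["G1", "G2"]
        assert clusters[0].snp_ids == ["s2"]

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            multi_mapping_diagnostic([], {}, alpha_snp=0.0)
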