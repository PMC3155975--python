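import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpcei.cohort_io import ExpressionCohort
from cpcei.cpc import (
    CPCError,
    cluster_pcs,
    compare_pcs_across_cohorts,
    cpc_gene_union,
    linkage_to_newick,
    pc_dissimilarity,
    pc_distance_matrix,
)
from cpcei.synthetic_cohorts import simulate_cohort_family
from cpcei.variance_pca import (
    RepresentedPC,
    cv_filter,
    distill_selected,
    fit_pca,
    select_k_bic,
)


def make_pc(cohort_id, idx, signs, weights=None):
    genes = sorted(signs)
    wv = pd.Series(
        weights if weights is not None else [float(signs[g]) for g in genes],
        index=genes,
    )
    return RepresentedPC(cohort_id, idx, wv, dict(signs))


class TestDissimilarity:
    def test_identity_is_zero(self):
        a = make_pc("A", 1, {"g1": 1, "g2": -1, "g3": 1})
        d, j, c = pc_dissimilarity(a, a)
        assert d == 0.0 and j == 1.0 and abs(c) == 1.0

    def test_disjoint_sets_distance_one(self):
        a = make_pc("A", 1, {"g1": 1, "g2": 1})
        b = make_pc("B", 1, {"g3": 1, "g4": 1})
        d, j, c = pc_dissimilarity(a, b)
        assert d == 1.0 and j == 0.0 and np.isnan(c)

    def test_hand_computed_half_overlap(self):
        # sets {g1,g2,g3} vs {g2,g3,g4}; common weights (1,1) vs (1,1)
        # J = 2/4, C = 1 -> d = 1 - 0.5 = 0.5
        a = make_pc("A", 1, {"g1": 1, "g2": 1, "g3": 1}, weights=[1.0, 1.0, 1.0])
        b = make_pc("B", 1, {"g2": 1, "g3": 1, "g4": 1}, weights=[1.0, 1.0, 1.0])
        d, j, c = pc_dissimilarity(a, b)
        assert j == pytest.approx(0.5)
        assert c == pytest.approx(1.0)
        assert d == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_and_sign_invariance(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(12)]
        sa = {g: int(s) for g, s in zip(rng.choice(genes, 7, replace=False),
                                        rng.choice([-1, 1], 7))}
        sb = {g: int(s) for g, s in zip(rng.choice(genes, 7, replace=False),
                                        rng.choice([-1, 1], 7))}
        a = make_pc("A", 1, sa, weights=list(rng.normal(size=len(sa))))
        b = make_pc("B", 1, sb, weights=list(rng.normal(size=len(sb))))
        d_ab, *_ = pc_dissimilarity(a, b)
        d_ba, *_ = pc_dissimilarity(b, a)
        assert d_ab == pytest.approx(d_ba)
        neg_b = RepresentedPC("B", 1, -b.weight_vector,
                              {g: -s for g, s in b.representative_signs.items()})
        d_neg, *_ = pc_dissimilarity(a, neg_b)
        assert d_neg == pytest.approx(d_ab)
        assert 0.0 <= d_ab <= 1.0


def brute_force_average_linkage(d):
    """O(n^3) agglomerative average linkage over a dense distance matrix.

    Returns merge heights in order, with cluster-pair distances defined
    as the mean of all cross-pair member distances.
    """
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if dist < best[0]:
                    best = (dist, (i, j))
        h, (i, j) = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return np.array(heights)


class TestClusterPCs:
    def test_two_identical_plus_disjoint(self):
        a = make_pc("A", 1, {"g1": 1, "g2": 1, "g3": -1})
        b = make_pc("B", 1, {"g1": 1, "g2": 1, "g3": -1})
        c = make_pc("C", 1, {"h1": 1, "h2": 1})
        clusters, _, _ = cluster_pcs([a, b, c], cut_height=0.5)
        assert len(clusters) == 1
        assert len(clusters[0].member_pcs) == 2
        assert clusters[0].cpc_genes == {"g1", "g2", "g3"}

    def test_cpc_genes_need_two_members(self):
        a = make_pc("A", 1, {"g1": 1, "g2": 1})
        b = make_pc("B", 1, {"g1": 1, "g3": 1})
        clusters, _, _ = cluster_pcs([a, b], cut_height=0.95)
        assert clusters[0].cpc_genes == {"g1"}

    def test_linkage_heights_match_brute_force(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        pcs = []
        for i in range(6):
            chosen = rng.choice(genes, 10, replace=False)
            signs = {g: int(s) for g, s in zip(chosen, rng.choice([-1, 1], 10))}
            pcs.append(make_pc(f"C{i % 3}", i, signs,
                               weights=list(rng.normal(size=10))))
        _, link, dm = cluster_pcs(pcs, cut_height=2.0)
        np.testing.assert_allclose(
            link[:, 2], brute_force_average_linkage(dm.d), atol=1e-12
        )

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(20)]
        pcs = []
        for i in range(8):
            chosen = rng.choice(genes, 8, replace=False)
            signs = {g: int(s) for g, s in zip(chosen, rng.choice([-1, 1], 8))}
            pcs.append(make_pc(f"C{i % 4}", i, signs,
                               weights=list(rng.normal(size=8))))
        clusters, _, _ = cluster_pcs(pcs, cut_height=0.95)
        perm = list(rng.permutation(len(pcs)))
        clusters_p, _, _ = cluster_pcs([pcs[i] for i in perm], cut_height=0.95)
        sets = {frozenset(pc.pc_id for pc in c.member_pcs) for c in clusters}
        sets_p = {frozenset(pc.pc_id for pc in c.member_pcs) for c in clusters_p}
        assert sets == sets_p

    def test_no_multimember_cluster_is_an_error(self):
        a = make_pc("A", 1, {"g1": 1})
        b = make_pc("B", 1, {"g2": 1})
        with pytest.raises(CPCError, match="cut"):
            cluster_pcs([a, b], cut_height=0.5)

    def test_single_cohort_pool_rejected(self):
        a = make_pc("A", 1, {"g1": 1})
        b = make_pc("A", 2, {"g1": 1})
        with pytest.raises(CPCError, match="2 cohorts"):
            cluster_pcs([a, b])


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_shared_factors_recovered_private_excluded(self, seed):
        cohorts, _, truth = simulate_cohort_family(seed=seed)
        pooled = []
        for cohort in cohorts:
            filtered = cv_filter(cohort)
            pca = fit_pca(filtered)
            select_k_bic(pca)
            pooled.extend(distill_selected(pca, filtered))
        clusters, _, _ = cluster_pcs(pooled, cut_height=0.9)
        assert len(clusters) == len(truth.shared_blocks)
        private = {g for gs in truth.private_blocks.values() for g in gs}
        for cl in clusters:
            best_j = max(
                len(cl.cpc_genes & set(b)) / len(cl.cpc_genes | set(b))
                for b in truth.shared_blocks
            )
            assert best_j >= 0.8
            assert len(cl.cpc_genes & private) / len(cl.cpc_genes) <= 0.10


class TestCompareAcrossCohorts:
    def test_resampled_cohorts_cluster_by_component(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(60)]
        u = np.linalg.qr(rng.standard_normal((60, 2)))[0]
        master = u @ np.diag([30.0, 12.0]) @ rng.standard_normal((2, 200))
        master += 0.5 * rng.standard_normal((60, 200))
        cohorts = []
        for c in range(4):
            cols = rng.choice(200, 60, replace=False)
            df = pd.DataFrame(
                master[:, cols], index=genes,
                columns=[f"c{c}s{i}" for i in range(60)],
            )
            cohorts.append(ExpressionCohort(f"R{c}", df))
        assignment, _, _ = compare_pcs_across_cohorts(
            cohorts, set(genes), cut_height=0.5
        )
        pc1 = {assignment[f"R{c}.PC1"] for c in range(4)}
        pc2 = {assignment[f"R{c}.PC2"] for c in range(4)}
        assert len(pc1) == 1 and len(pc2) == 1 and pc1 != pc2

    def test_noise_cohort_stays_apart(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(60)]
        u = np.linalg.qr(rng.standard_normal((60, 2)))[0]
        master = u @ np.diag([30.0, 12.0]) @ rng.standard_normal((2, 150))
        master += 0.5 * rng.standard_normal((60, 150))
        cohorts = []
        for c in range(3):
            cols = rng.choice(150, 50, replace=False)
            df = pd.DataFrame(master[:, cols], index=genes,
                              columns=[f"c{c}s{i}" for i in range(50)])
            cohorts.append(ExpressionCohort(f"R{c}", df))
        noise = pd.DataFrame(rng.standard_normal((60, 50)), index=genes,
                             columns=[f"ns{i}" for i in range(50)])
        cohorts.append(ExpressionCohort("NOISE", noise))
        assignment, _, _ = compare_pcs_across_cohorts(
            cohorts, set(genes), cut_height=0.5
        )
        consistent = {assignment[f"R{c}.PC1"] for c in range(3)}
        assert len(consistent) == 1
        assert assignment["NOISE.PC1"] not in consistent
        assert assignment["NOISE.PC2"] not in consistent

    def test_single_cohort_rejected(self, small_family):
        cohorts, _, _ = small_family
        with pytest.raises(CPCError, match="2 cohorts"):
            compare_pcs_across_cohorts([cohorts[0]], set(cohorts[0].features))

    def test_tiny_gene_set_rejected(self, small_family):
        cohorts, _, _ = small_family
        with pytest.raises(CPCError, match="too small"):
            compare_pcs_across_cohorts(cohorts, {"G0000", "G0001"})


def test_newick_export_has_all_leaves_and_parses():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(15)]
    pcs = []
    for i in range(5):
        chosen = rng.choice(genes, 6, replace=False)
        signs = {g: int(s) for g, s in zip(chosen, rng.choice([-1, 1], 6))}
        pcs.append(make_pc(f"C{i % 2}", i, signs, weights=list(rng.normal(size=6))))
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    dm = pc_distance_matrix(pcs)
    link = linkage(squareform(dm.d, checks=False), method="average")
    nwk = linkage_to_newick(link, dm.pc_ids)
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(dm.pc_ids)


def test_cpc_gene_union_merges_clusters():
    a = make_pc("A", 1, {"g1": 1, "g2": 1})
    b = make_pc("B", 1, {"g1": 1, "g2": 1})
    c = make_pc("A", 2, {"h1": -1, "h2": 1})
    d = make_pc("B", 2, {"h1": -1, "h2": 1})
    clusters, _, _ = cluster_pcs([a, b, c, d], cut_height=0.5)
    assert cpc_gene_union(clusters) == {"g1", "g2", "h1", "h2"}
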