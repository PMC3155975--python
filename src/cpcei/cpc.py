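"""Cross-cohort comparison and clustering of distilled principal components.

Distilled PCs from all cohorts are pooled and compared with a
Jaccard-cosine dissimilarity: d = 1 - J * |C|, where J is the Jaccard
index of the two representative feature sets and C the cosine of the
weight vectors restricted to the common features.  Average-linkage
hierarchical clustering of this matrix yields consistent principal
components (CPCs); the CPC gene set of a cluster collects every feature
representative in at least two of its member PCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_io import ExpressionCohort
from .variance_pca import RepresentedPC, distill_pc, fit_pca

logger = logging.getLogger(__name__)


class CPCError(ValueError):
    pass


@dataclass
class PCDistanceMatrix:
    pcs: list[RepresentedPC]
    d: np.ndarray = field(repr=False)
    jaccard: np.ndarray = field(repr=False)
    cosine: np.ndarray = field(repr=False)  # nan where no common features

    @property
    def pc_ids(self) -> list[str]:
        return [pc.pc_id for pc in self.pcs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.pc_ids, columns=self.pc_ids)


@dataclass
class CPCCluster:
    cluster_id: int
    member_pcs: list[RepresentedPC]
    cpc_genes: set[str]

    @property
    def cohorts(self) -> set[str]:
        return {pc.cohort_id for pc in self.member_pcs}


def pc_dissimilarity(a: RepresentedPC, b: RepresentedPC) -> tuple[float, float, float]:
    """Return (d, J, C) for two distilled PCs.

    J is the Jaccard index of the representative feature sets; C is the
    cosine correlation of the two weight vectors restricted to the
    common representative features (nan if the intersection is empty,
    in which case d = 1).  d = 1 - J * |C| is sign-invariant because PC
    orientations are arbitrary.
    """
    sa, sb = a.representative_features, b.representative_features
    if not sa or not sb:
        raise CPCError("representative sets must be non-empty")
    inter = sa & sb
    union = sa | sb
    j = len(inter) / len(union)
    if not inter:
        return 1.0, 0.0, float("nan")
    common = sorted(inter)
    wa = a.weight_vector.reindex(common).to_numpy(dtype=float)
    wb = b.weight_vector.reindex(common).to_numpy(dtype=float)
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na == 0 or nb == 0:
        return 1.0, j, float("nan")
    c = float(wa @ wb / (na * nb))
    c = max(-1.0, min(1.0, c))
    d = 1.0 - j * abs(c)
    return float(min(max(d, 0.0), 1.0)), j, c


def pc_distance_matrix(pcs: list[RepresentedPC]) -> PCDistanceMatrix:
    m = len(pcs)
    d = np.zeros((m, m))
    jac = np.eye(m)
    cos = np.full((m, m), np.nan)
    np.fill_diagonal(cos, 1.0)
    for i in range(m):
        for k in range(i + 1, m):
            dd, jj, cc = pc_dissimilarity(pcs[i], pcs[k])
            d[i, k] = d[k, i] = dd
            jac[i, k] = jac[k, i] = jj
            cos[i, k] = cos[k, i] = cc
    return PCDistanceMatrix(pcs=pcs, d=d, jaccard=jac, cosine=cos)


def _cpc_genes(members: list[RepresentedPC]) -> set[str]:
    counts = Counter(g for pc in members for g in pc.representative_features)
    return {g for g, c in counts.items() if c >= 2}


def cluster_pcs(
    pcs: list[RepresentedPC], cut_height: float = 0.9
) -> tuple[list[CPCCluster], np.ndarray, PCDistanceMatrix]:
    """Average-linkage clustering of pooled PCs; returns CPC clusters.

    The tree is cut at `cut_height`; only clusters with at least two
    members are kept, each carrying the genes representative in at
    least two of its members.  Returns (clusters, linkage matrix,
    distance matrix).
    """
    if len(pcs) < 2:
        raise CPCError("need at least 2 PCs to cluster")
    if len({pc.cohort_id for pc in pcs}) < 2:
        raise CPCError("need PCs from at least 2 cohorts")
    dm = pc_distance_matrix(pcs)
    link = linkage(squareform(dm.d, checks=False), method="average")
    labels = fcluster(link, t=cut_height, criterion="distance")
    clusters: list[CPCCluster] = []
    next_id = 1
    for lab in sorted(set(labels)):
        members = [pc for pc, l in zip(pcs, labels) if l == lab]
        if len(members) < 2:
            continue
        genes = _cpc_genes(members)
        span = {pc.cohort_id for pc in members}
        if len(span) < 2:
            logger.warning(
                "CPC cluster %d spans a single cohort (%s); kept but "
                "consistency is within-cohort only", next_id, span,
            )
        clusters.append(CPCCluster(next_id, members, genes))
        next_id += 1
    if not clusters:
        raise CPCError(
            f"no cluster with >= 2 members at cut height {cut_height}; "
            "try a higher cut"
        )
    return clusters, link, dm


def cpc_gene_union(clusters: list[CPCCluster]) -> set[str]:
    out: set[str] = set()
    for c in clusters:
        out |= c.cpc_genes
    return out


def compare_pcs_across_cohorts(
    cohorts: list[ExpressionCohort],
    gene_set: set[str],
    cut_height: float = 0.9,
    alpha: float = 0.01,
    n_components: int = 2,
) -> tuple[pd.Series, np.ndarray, PCDistanceMatrix]:
    """Consistency diagnostic: cluster each cohort's first PCs on a gene set.

    PCA is run per cohort restricted to `gene_set`, the first
    `n_components` PCs are distilled and pooled, and the pooled PCs are
    clustered with the Jaccard-cosine dissimilarity.  Returns (cluster
    assignment per PC id, linkage matrix, distance matrix).
    """
    if len(cohorts) < 2:
        raise CPCError("consistency check needs at least 2 cohorts")
    if len(gene_set) < 10:
        raise CPCError(f"gene set too small ({len(gene_set)} < 10)")
    pooled: list[RepresentedPC] = []
    for cohort in cohorts:
        present = gene_set & set(cohort.features)
        coverage = len(present) / len(gene_set)
        if coverage < 0.5:
            logger.warning(
                "cohort %s covers only %.0f%% of the gene set",
                cohort.cohort_id, 100 * coverage,
            )
        sub = cohort.subset_features(present)
        pca = fit_pca(sub)
        for j in range(1, min(n_components, len(pca.omega)) + 1):
            pooled.append(distill_pc(pca, sub, j, alpha=alpha))
    dm = pc_distance_matrix(pooled)
    link = linkage(squareform(dm.d, checks=False), method="average")
    labels = fcluster(link, t=cut_height, criterion="distance")
    assignment = pd.Series(labels, index=dm.pc_ids, name="cluster")
    return assignment, link, dm


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(link)

    def walk(node, parent_dist: float | None) -> str:
        if node.is_leaf():
            body = labels[node.id]
        else:
            body = f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
        if parent_dist is None:
            return body
        return f"{body}:{max(parent_dist - node.dist, 0.0):.6g}"

    return walk(tree, None) + ";"
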