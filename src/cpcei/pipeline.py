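"""End-to-end wiring: cohorts -> CPC clusters -> CEI definitions.

This is the programmatic counterpart of the ``derive`` CLI command and
the single place the full derivation chain lives:

    cv_filter -> fit_pca -> select_k_bic -> distill_pc   (per cohort)
    cluster_pcs -> merge_zscores -> derive_ceis          (across cohorts)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cei import CEIDefinition, derive_ceis, merge_zscores
from .cohort_io import ExpressionCohort
from .cpc import CPCCluster, cluster_pcs, cpc_gene_union
from .variance_pca import (
    CohortPCA,
    RepresentedPC,
    cv_filter,
    distill_selected,
    fit_pca,
    select_k_bic,
)

logger = logging.getLogger(__name__)


@dataclass
class DeriveResult:
    pcas: dict[str, CohortPCA]
    pooled_pcs: list[RepresentedPC]
    clusters: list[CPCCluster]
    cpc_genes: set[str]
    ceis: list[CEIDefinition]
    linkage: np.ndarray = field(repr=False)


def derive_from_cohorts(
    cohorts: list[ExpressionCohort],
    cv_low: float = 1.0,
    cv_high: float = 1000.0,
    alpha: float = 0.01,
    cut_height: float = 0.9,
    n_factors: int = 6,
    threshold: float = 0.1,
    k_max: int | None = None,
) -> DeriveResult:
    """Run the whole CPC/CEI derivation on reference cohorts.

    Per cohort: CV filter, PCA, BIC component selection, distillation
    of the selected PCs.  Across cohorts: Jaccard-cosine clustering of
    the pooled PCs, CPC gene extraction, z-score merge and varimax
    factor analysis into sign-weighted CEIs.
    """
    if len(cohorts) < 2:
        raise ValueError("derivation needs at least 2 cohorts")
    pcas: dict[str, CohortPCA] = {}
    pooled = []
    for cohort in cohorts:
        filtered = cv_filter(cohort, cv_low, cv_high)
        pca = fit_pca(filtered)
        k = select_k_bic(pca, k_max)
        logger.info(
            "cohort %s: n=%d p=%d k_selected=%d nu=%.3g",
            cohort.cohort_id, pca.n, pca.p, k, pca.nu,
        )
        pcas[cohort.cohort_id] = pca
        pooled.extend(distill_selected(pca, filtered, alpha=alpha))
    clusters, link, _ = cluster_pcs(pooled, cut_height=cut_height)
    genes = cpc_gene_union(clusters)
    logger.info(
        "%d CPC clusters, %d CPC genes", len(clusters), len(genes)
    )
    merged = merge_zscores(cohorts, genes)
    ceis = derive_ceis(merged, n_factors=n_factors, threshold=threshold)
    return DeriveResult(
        pcas=pcas, pooled_pcs=pooled, clusters=clusters, cpc_genes=genes,
        ceis=ceis, linkage=link,
    )
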