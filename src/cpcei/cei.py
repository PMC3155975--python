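"""Consistent expression indices: factor analysis of merged z-scores.

CPC-gene expression from each reference cohort is z-scored gene-wise
within the cohort and the cohorts are concatenated.  A maximum-
likelihood factor analysis with varimax rotation is fitted to the
merged matrix; per-factor gene coefficients are estimated by least
squares of each gene's z-scores on the factor scores, coefficients
below a magnitude threshold are zeroed, and the surviving signs become
the +/-1 gene weights of one consistent expression index (CEI).  Any
cohort can then be scored: a CEI score is the sum of signed
within-cohort z-scores over the CEI's genes present in that cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis
from sklearn.exceptions import ConvergenceWarning

from .cohort_io import ExpressionCohort

logger = logging.getLogger(__name__)


class CEIError(ValueError):
    pass


@dataclass
class CEIDefinition:
    """A sign-weighted metagene: gene -> weight in {-1, +1}."""

    cei_id: str
    gene_weights: dict[str, int]
    factor_index: int | None = None
    variance_share: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_weights:
            raise CEIError(f"{self.cei_id}: a CEI needs at least one nonzero weight")
        bad = {g: w for g, w in self.gene_weights.items() if w not in (-1, 1)}
        if bad:
            raise CEIError(f"{self.cei_id}: weights must be +/-1, got {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_weights)


def merge_zscores(
    cohorts: list[ExpressionCohort], genes: set[str]
) -> pd.DataFrame:
    """Z-score each gene within each cohort and concatenate column-wise.

    Only genes present in every cohort are used (dropped genes are
    logged); a gene with zero variance in any cohort is dropped with a
    warning.  Columns are prefixed "cohort_id:sample" so merged sample
    ids stay unique.
    """
    if not cohorts:
        raise CEIError("no cohorts to merge")
    common = set(genes)
    for c in cohorts:
        common &= set(c.features)
    dropped = set(genes) - common
    if dropped:
        logger.info("merge_zscores: %d genes absent from some cohort", len(dropped))
    if not common:
        raise CEIError("no requested gene is present in every cohort")
    order = [g for g in sorted(genes) if g in common]
    blocks = []
    degenerate: set[str] = set()
    for c in cohorts:
        block = c.values.loc[order]
        sd = block.std(axis=1, ddof=1)
        degenerate |= set(block.index[sd == 0])
    if degenerate:
        warnings.warn(
            f"dropping {len(degenerate)} zero-variance gene(s): "
            f"{sorted(degenerate)[:5]}...", stacklevel=2,
        )
        order = [g for g in order if g not in degenerate]
        if not order:
            raise CEIError("all genes are degenerate in some cohort")
    for c in cohorts:
        block = c.values.loc[order]
        z = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=1), axis=0)
        z.columns = [f"{c.cohort_id}:{s}" for s in block.columns]
        blocks.append(z)
    return pd.concat(blocks, axis=1)


def _varimax_fa(x: np.ndarray, n_factors: int, max_iter: int = 1000):
    """ML factor analysis + varimax; deterministic (LAPACK SVD, sign fixed)."""
    fa = FactorAnalysis(
        n_components=n_factors,
        rotation="varimax",
        svd_method="lapack",
        max_iter=max_iter,
        tol=1e-3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            scores = fa.fit_transform(x)
        except ConvergenceWarning as exc:
            raise CEIError(
                f"factor extraction did not converge in {max_iter} "
                f"iterations: {exc}"
            ) from exc
    load = fa.components_  # factors x genes, already rotated
    # deterministic orientation: largest-|loading| entry positive per factor
    flip = np.sign(load[np.arange(load.shape[0]), np.argmax(np.abs(load), axis=1)])
    flip[flip == 0] = 1.0
    load = load * flip[:, None]
    scores = scores * flip[None, :]
    return load, scores


def derive_ceis(
    merged: pd.DataFrame,
    n_factors: int = 6,
    threshold: float = 0.1,
    coefficient_method: str = "regression",
) -> list[CEIDefinition]:
    """Derive sign-weighted CEIs from a merged gene x sample z-score matrix.

    A varimax-rotated factor model is fit with samples as observations.
    Per-factor gene coefficients come either from an ordinary
    least-squares regression of each gene on the factor scores
    (``coefficient_method="regression"``, default) or directly from the
    rotated loadings (``"loadings"``).  Coefficients with magnitude
    below `threshold` are zeroed and the surviving signs become the
    gene weights.  Factors are ordered by variance explained after
    rotation, so CEI1 is always the dominant factor.
    """
    genes = list(merged.index)
    n_genes, n_samples = merged.shape
    if not n_factors < min(n_genes, n_samples):
        raise CEIError(
            f"n_factors={n_factors} must be < min(genes={n_genes}, "
            f"samples={n_samples})"
        )
    if threshold < 0:
        raise CEIError("threshold must be >= 0")
    x = merged.to_numpy(dtype=float).T  # samples x genes
    load, scores = _varimax_fa(x, n_factors)
    if coefficient_method == "regression":
        xc = x - x.mean(axis=0)
        sc = scores - scores.mean(axis=0)
        coef, *_ = np.linalg.lstsq(sc, xc, rcond=None)  # factors x genes
    elif coefficient_method == "loadings":
        coef = load
    else:
        raise CEIError(f"unknown coefficient_method {coefficient_method!r}")
    ssl = (load**2).sum(axis=1)  # variance explained per rotated factor
    total_var = x.var(axis=0, ddof=0).sum()
    order = np.argsort(-ssl, kind="stable")
    ceis: list[CEIDefinition] = []
    for rank, f in enumerate(order, start=1):
        w = coef[f].copy()
        w[np.abs(w) < threshold] = 0.0
        nz = {genes[i]: (1 if w[i] > 0 else -1) for i in np.flatnonzero(w)}
        if not nz:
            raise CEIError(
                f"factor {f + 1}: every coefficient below threshold "
                f"{threshold}; no CEI can be defined"
            )
        ceis.append(
            CEIDefinition(
                cei_id=f"CEI{rank}",
                gene_weights=nz,
                factor_index=int(f) + 1,
                variance_share=float(ssl[f] / total_var),
            )
        )
    logger.info(
        "derived %d CEIs explaining %.0f%% of merged variance",
        len(ceis), 100 * ssl.sum() / total_var,
    )
    return ceis


def score_cei(cohort: ExpressionCohort, cei: CEIDefinition) -> pd.DataFrame:
    """Score a cohort on one CEI: sum of signed within-cohort z-scores.

    Genes absent from the cohort are excluded (never imputed); the
    fraction present is reported as coverage.  Coverage below 0.5
    triggers a warning, zero coverage an error.
    """
    present = [g for g in cei.genes if g in cohort.values.index]
    coverage = len(present) / len(cei.genes)
    if not present:
        raise CEIError(
            f"{cei.cei_id}: none of its {len(cei.genes)} genes are present "
            f"in cohort {cohort.cohort_id!r}"
        )
    if coverage < 0.5:
        warnings.warn(
            f"{cei.cei_id}: coverage {coverage:.2f} < 0.5 in cohort "
            f"{cohort.cohort_id!r}", stacklevel=2,
        )
    block = cohort.values.loc[present]
    sd = block.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise CEIError(f"{cei.cei_id}: all scoring genes are constant")
    block = block.loc[usable]
    z = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=1), axis=0)
    w = np.array([cei.gene_weights[g] for g in block.index], dtype=float)
    scores = w @ z.to_numpy()
    return pd.DataFrame(
        {
            "sample_id": cohort.samples,
            "cei_id": cei.cei_id,
            "score": scores,
            "coverage": coverage,
        }
    )


def score_ceis(cohort: ExpressionCohort, ceis: list[CEIDefinition]) -> pd.DataFrame:
    """Score a cohort on several CEIs; rows stack per CEI."""
    return pd.concat(
        [score_cei(cohort, cei) for cei in ceis], ignore_index=True
    )


def write_ceis(ceis: list[CEIDefinition], path) -> None:
    """Write CEI definitions as TSV: cei_id <TAB> gene <TAB> weight."""
    rows = [
        {"cei_id": cei.cei_id, "gene": g, "weight": w}
        for cei in ceis
        for g, w in cei.gene_weights.items()
    ]
    pd.DataFrame(rows, columns=["cei_id", "gene", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_ceis(path) -> list[CEIDefinition]:
    df = pd.read_csv(path, sep="\t", dtype={"cei_id": str, "gene": str, "weight": int})
    ceis = []
    for cei_id, grp in df.groupby("cei_id", sort=False):
        ceis.append(
            CEIDefinition(cei_id=cei_id, gene_weights=dict(zip(grp["gene"], grp["weight"])))
        )
    return ceis
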