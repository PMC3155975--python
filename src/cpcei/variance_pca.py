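"""Per-cohort variance filtering, PCA and component distillation.

The workflow per cohort: keep probes whose coefficient of variation on
the anti-log (linear) scale lies in an interval, decompose the centered
log2 matrix by SVD, pick the number of informative components by the
minimum of a Gaussian-residual BIC, and distill each retained component
to the set of features significantly correlated with its score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionCohort

logger = logging.getLogger(__name__)


class PCAError(ValueError):
    pass


@dataclass
class CohortPCA:
    """PCA of one cohort's filtered, feature-centered log2 matrix.

    sigma : per-feature sample standard deviation (sd of probe i).
    omega : per-component explained standard deviation (sqrt eigenvalue
        of the sample covariance), non-increasing.
    scores : samples x components; weights : features x components.
    k_selected / nu are set by :func:`select_k_bic`; nu is the residual
    variance sum(sigma^2) - sum_{j<=k}(omega^2).
    """

    cohort_id: str
    feature_ids: list[str]
    sample_ids: list[str]
    sigma: np.ndarray
    omega: np.ndarray
    scores: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    n: int
    p: int
    k_selected: int | None = None
    nu: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.omega) > 1e-9):
            raise PCAError("explained standard deviations must be non-increasing")
        total = float(np.sum(self.sigma**2))
        explained = float(np.sum(self.omega**2))
        if explained > total * (1 + 1e-8) + 1e-8:
            raise PCAError("explained variance exceeds total variance")


@dataclass
class RepresentedPC:
    """One distilled principal component.

    representative_signs maps each representative feature to the sign
    (+1/-1) of its Pearson correlation with the component score.
    """

    cohort_id: str
    component_index: int  # 1-based
    weight_vector: pd.Series = field(repr=False)
    representative_signs: dict[str, int]

    @property
    def pc_id(self) -> str:
        # "." separator keeps ids safe for newick export
        return f"{self.cohort_id}.PC{self.component_index}"

    @property
    def representative_features(self) -> set[str]:
        return set(self.representative_signs)


def cv_filter(
    cohort: ExpressionCohort, low: float = 1.0, high: float = 1000.0
) -> ExpressionCohort:
    """Keep features whose anti-log coefficient of variation is in (low, high).

    Values are assumed log2; CV = sd(2^x) / mean(2^x) per feature, with
    the sample (n-1) standard deviation.  Feature order is preserved.
    """
    if not low < high:
        raise PCAError(f"cv_filter needs low < high, got {low} >= {high}")
    linear = np.exp2(cohort.values.to_numpy(dtype=float))
    cv = linear.std(axis=1, ddof=1) / linear.mean(axis=1)
    keep = (cv > low) & (cv < high)
    if not keep.any():
        raise PCAError(
            f"cohort {cohort.cohort_id!r}: no feature passes the CV filter "
            f"({low}, {high}); review the thresholds"
        )
    logger.info(
        "cohort %s: CV filter kept %d / %d features",
        cohort.cohort_id, int(keep.sum()), cohort.n_features,
    )
    return ExpressionCohort(cohort.cohort_id, cohort.values.loc[keep])


def fit_pca(cohort: ExpressionCohort) -> CohortPCA:
    """SVD-based PCA of the feature-centered matrix (no unit-variance scaling).

    Component signs follow a deterministic convention: each weight
    vector's largest-magnitude entry is made positive.
    """
    n = cohort.n_samples
    if n < 3:
        raise PCAError(f"PCA needs at least 3 samples, got {n}")
    x = cohort.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # fix signs so outputs are reproducible across LAPACK backends
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    u *= flip
    vt *= flip[:, None]
    omega = s / np.sqrt(n - 1)
    scores = vt.T * s  # samples x components
    sigma = x.std(axis=1, ddof=1)
    return CohortPCA(
        cohort_id=cohort.cohort_id,
        feature_ids=cohort.features,
        sample_ids=cohort.samples,
        sigma=sigma,
        omega=omega,
        scores=scores,
        weights=u,
        n=n,
        p=cohort.n_features,
    )


def bic_curve(pca: CohortPCA, k_max: int) -> np.ndarray:
    """Gaussian-residual BIC over k = 1..k_max.

    BIC(k) = n * ln(nu_k / n) + k * ln(n) with nu_k the residual
    variance sum(sigma_i^2) - sum_{j<=k} omega_j^2.  A non-positive
    residual (perfect fit) maps to -inf.
    """
    n = pca.n
    total = float(np.sum(pca.sigma**2))
    nu = total - np.cumsum(pca.omega[:k_max] ** 2)
    nu[nu <= total * 1e-12] = 0.0  # numerically perfect fit
    ks = np.arange(1, k_max + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bic = np.where(
            nu > 0, n * np.log(np.maximum(nu, 1e-300) / n) + ks * np.log(n), -np.inf
        )
    return bic


def select_k_bic(pca: CohortPCA, k_max: int | None = None) -> int:
    """Pick the number of components at the BIC minimum; stores k and nu.

    k_max defaults to min(n - 1, 20, #components).  If the residual hits
    zero (perfect reconstruction) the first such k is returned with a
    warning.
    """
    n_comp = len(pca.omega)
    if k_max is None:
        k_max = min(pca.n - 1, 20, n_comp)
    if k_max > n_comp:
        raise PCAError(f"k_max={k_max} exceeds {n_comp} computed components")
    bic = bic_curve(pca, k_max)
    if np.isneginf(bic).any():
        k = int(np.argmax(np.isneginf(bic))) + 1
        warnings.warn(
            f"cohort {pca.cohort_id!r}: perfect fit at k={k}; residual is zero",
            stacklevel=2,
        )
    else:
        k = int(np.argmin(bic)) + 1
    pca.k_selected = k
    pca.nu = float(np.sum(pca.sigma**2) - np.sum(pca.omega[:k] ** 2))
    return k


def distill_pc(
    pca: CohortPCA,
    cohort: ExpressionCohort,
    component_index: int,
    alpha: float = 0.01,
) -> RepresentedPC:
    """Distill a PC to its significantly correlated features.

    For every filtered feature, the Pearson correlation r between its
    expression and the component scores is tested with the Student
    t statistic t = r * sqrt(n-2) / sqrt(1-r^2) (two-sided, n-2 df);
    features with P < alpha form the representative set, tagged with
    sign(r).  component_index is 1-based.
    """
    n = pca.n
    if n < 4:
        raise PCAError("distillation needs n >= 4 (t-test with n-2 >= 2 df)")
    j = component_index - 1
    if not 0 <= j < pca.scores.shape[1]:
        raise PCAError(f"component_index {component_index} out of range")
    x = cohort.values.loc[pca.feature_ids].to_numpy(dtype=float)
    s = pca.scores[:, j]
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, xc @ sc / np.maximum(denom, 1e-300), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1 - r**2, 1e-300))
    pval = 2 * stats.t.sf(np.abs(t), df=n - 2)
    keep = pval < alpha
    if not keep.any():
        raise PCAError(
            f"{pca.cohort_id} PC{component_index}: empty representative set "
            f"at alpha={alpha}; consider relaxing alpha"
        )
    signs = {
        f: (1 if r[i] > 0 else -1)
        for i, f in enumerate(pca.feature_ids)
        if keep[i]
    }
    return RepresentedPC(
        cohort_id=pca.cohort_id,
        component_index=component_index,
        weight_vector=pd.Series(pca.weights[:, j], index=pca.feature_ids),
        representative_signs=signs,
    )


def distill_selected(
    pca: CohortPCA, cohort: ExpressionCohort, alpha: float = 0.01
) -> list[RepresentedPC]:
    """Distill all k_selected components of a fitted cohort PCA."""
    if pca.k_selected is None:
        raise PCAError("run select_k_bic before distilling")
    return [
        distill_pc(pca, cohort, j, alpha=alpha)
        for j in range(1, pca.k_selected + 1)
    ]


def save_pca(pca: CohortPCA, outdir) -> None:
    """Serialize a CohortPCA as TSVs (weights, scores, summary)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        pca.weights, index=pca.feature_ids,
        columns=[f"PC{j+1}" for j in range(pca.weights.shape[1])],
    ).to_csv(outdir / "weights.tsv", sep="\t")
    pd.DataFrame(
        pca.scores, index=pca.sample_ids,
        columns=[f"PC{j+1}" for j in range(pca.scores.shape[1])],
    ).to_csv(outdir / "scores.tsv", sep="\t")
    summary = pd.DataFrame(
        {
            "key": ["cohort_id", "n", "p", "k_selected", "nu", "omega"],
            "value": [
                pca.cohort_id, pca.n, pca.p, pca.k_selected, pca.nu,
                ",".join(f"{w:.10g}" for w in pca.omega),
            ],
        }
    )
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
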