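"""Cohort input/output and sample annotation.

Expression cohorts are tab-delimited text matrices (rows = probes or
genes, columns = samples) on a log2 RMA-like scale.  Clinical tables
carry a binary treatment-response flag and/or a (time, event) survival
pair per sample.  This module also collapses probe-level matrices to
gene level and assigns a receptor subtype by k-medoids (PAM) clustering
of two marker genes.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

DOUBLE_NEGATIVE = "double_negative"


class CohortError(ValueError):
    """Raised for malformed or invariant-violating cohort inputs."""


@dataclass
class ExpressionCohort:
    """One cohort's expression matrix, features x samples, log2 scale.

    Invariants: unique feature and sample ids, no missing values,
    at least 3 samples.
    """

    cohort_id: str
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise CohortError(
                f"cohort {self.cohort_id!r}: duplicated feature ids {dupes[:5]}"
            )
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise CohortError(
                f"cohort {self.cohort_id!r}: duplicated sample ids {dupes[:5]}"
            )
        if self.values.isna().any().any():
            raise CohortError(
                f"cohort {self.cohort_id!r}: missing values remain after load"
            )
        if self.values.shape[1] < 3:
            raise CohortError(
                f"cohort {self.cohort_id!r}: needs at least 3 samples, "
                f"got {self.values.shape[1]}"
            )

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features) -> "ExpressionCohort":
        keep = [f for f in self.features if f in set(features)]
        return ExpressionCohort(self.cohort_id, self.values.loc[keep])


def read_cohort(path, cohort_id: str) -> ExpressionCohort:
    """Read a tab-delimited expression matrix (optionally gzipped).

    First column holds feature ids, the header row sample ids, the body
    is numeric.  Rows containing any missing value are dropped with a
    logged count.  Malformed numeric cells and duplicate feature ids
    raise :class:`CohortError`.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad][0]
                cell = raw.loc[row, col]
                raise CohortError(
                    f"{path}: malformed numeric cell {cell!r} at "
                    f"feature {row!r}, sample {col!r}"
                ) from None
        values = raw.apply(pd.to_numeric, errors="coerce")
    n_missing = int(values.isna().any(axis=1).sum())
    if n_missing:
        logger.warning(
            "cohort %s: dropping %d feature rows with missing values",
            cohort_id, n_missing,
        )
        values = values.dropna(axis=0)
    return ExpressionCohort(cohort_id, values)


def write_cohort(cohort: ExpressionCohort, path) -> None:
    """Write the matrix in the same tab-delimited layout `read_cohort` reads."""
    out = cohort.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table (CSV or TSV, delimiter sniffed).

    Columns: sample_id, response (0/1/NA), time (years), event (0/1),
    treatment.  Every row must carry a response or a complete
    (time, event) pair; time and event must be jointly present.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "sample_id" not in df.columns:
        raise CohortError(f"{path}: clinical table lacks a sample_id column")
    for col in ("response", "time", "event", "treatment"):
        if col not in df.columns:
            df[col] = np.nan
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise CohortError(f"{path}: duplicated sample ids in clinical table")
    has_resp = df["response"].notna()
    has_time = df["time"].notna()
    has_event = df["event"].notna()
    if (has_time != has_event).any():
        raise CohortError(f"{path}: time and event must be present together")
    if (~has_resp & ~has_time).any():
        n = int((~has_resp & ~has_time).sum())
        raise CohortError(
            f"{path}: {n} rows carry neither a response nor a (time, event) pair"
        )
    if (df.loc[has_time, "time"] < 0).any():
        raise CohortError(f"{path}: negative survival times")
    return df.set_index("sample_id", drop=False)


def read_probe_map(path) -> pd.DataFrame:
    """Read a two-column probe_id <TAB> gene_symbol map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CohortError(f"{path}: probe map needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["probe_id", "gene_symbol"]
    if df["probe_id"].duplicated().any():
        raise CohortError(f"{path}: a probe maps to more than one gene")
    return df


def collapse_probes(cohort: ExpressionCohort, probe_map: pd.DataFrame) -> ExpressionCohort:
    """Collapse a probe-level matrix to gene level.

    For each gene the retained row is the probe with the largest sample
    standard deviation of its values; remaining probes and unmapped
    probes are dropped.  Ties in standard deviation are broken by file
    order (first probe wins) so the result is deterministic.  No
    arithmetic is performed on expression values.
    """
    gene_of = dict(zip(probe_map["probe_id"], probe_map["gene_symbol"]))
    mapped = [p for p in cohort.features if p in gene_of]
    if not mapped:
        raise CohortError(
            f"cohort {cohort.cohort_id!r}: no probe overlaps the probe map"
        )
    sd = cohort.values.std(axis=1, ddof=1)
    best: dict[str, str] = {}  # gene -> probe; first-in-file wins ties
    for probe in mapped:
        gene = gene_of[probe]
        if gene not in best or sd[probe] > sd[best[gene]]:
            best[gene] = probe
    genes = list(best)
    rows = cohort.values.loc[[best[g] for g in genes]]
    rows.index = pd.Index(genes, name="feature_id")
    return ExpressionCohort(cohort.cohort_id, rows)


def _pam(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PAM (k-medoids): greedy BUILD then best-improvement SWAP.

    Returns (medoid_indices, labels). Ties resolve to the lowest index.
    """
    n = points.shape[0]
    dist = squareform(pdist(points))
    if dist.max() == 0.0:
        raise CohortError("degenerate marker distribution: all samples identical")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        nearest = dist[:, medoids].min(axis=1)
        gains = np.full(n, -np.inf)
        for j in range(n):
            if j in medoids:
                continue
            gains[j] = np.maximum(nearest - dist[:, j], 0.0).sum()
        medoids.append(int(np.argmax(gains)))

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                cand = list(medoids)
                cand[mi] = h
                c = cost(cand)
                if c < best_cost - 1e-12:
                    best_cost, medoids, improved = c, cand, True
    order = np.argsort(medoids)  # stable identity regardless of build order
    meds = np.asarray(medoids)[order]
    labels = np.argmin(dist[:, meds], axis=1)
    return meds, labels


def assign_subtype(
    cohort: ExpressionCohort,
    marker_features: tuple[str, str] = ("ESR1", "ERBB2"),
    n_clusters: int = 4,
) -> pd.Series:
    """Assign a receptor subtype per sample by PAM on two marker genes.

    Samples are clustered on the 2-d profile of the two markers.  The
    double-negative cluster is the one whose medoid has the smallest sum
    of the two marker values; remaining clusters are labelled other_1,
    other_2, ... in increasing order of that sum.
    """
    missing = [m for m in marker_features if m not in cohort.values.index]
    if missing:
        hints = {
            m: difflib.get_close_matches(m, cohort.features, n=3)
            for m in missing
        }
        raise CohortError(
            f"cohort {cohort.cohort_id!r}: marker feature(s) {missing} absent; "
            f"near matches: {hints}"
        )
    n = cohort.n_samples
    if not 2 <= n_clusters <= n - 1:
        raise CohortError(
            f"n_clusters must be in [2, {n - 1}], got {n_clusters}"
        )
    points = cohort.values.loc[list(marker_features)].to_numpy().T  # samples x 2
    meds, labels = _pam(points, n_clusters)
    medoid_sums = points[meds].sum(axis=1)
    rank = np.argsort(medoid_sums, kind="stable")  # lowest sum first
    names = [DOUBLE_NEGATIVE] + [f"other_{i}" for i in range(1, n_clusters)]
    name_of = {int(cluster): names[pos] for pos, cluster in enumerate(rank)}
    return pd.Series(
        [name_of[int(l)] for l in labels], index=cohort.samples, name="subtype"
    )
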