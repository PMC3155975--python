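"""Synthetic families of analogous expression cohorts.

The generator embodies the working assumption behind cross-cohort
metagene extraction: analogous cohorts are draws from one "expression
space", so a handful of latent factors recur across cohorts (shared
factors, identical gene loadings everywhere) while each cohort also
carries private structure (a factor whose genes and loadings exist in
that cohort only) plus gene-level noise and per-cohort baseline offsets
(batch).  Outcomes are tied to the shared factors: a logistic link
yields the binary response, an exponential proportional-hazards link
the survival times, with independent uniform censoring.

Gene architecture (defaults sized to a post-filter microarray regime:
5 cohorts, 1000 genes, 40-80 samples each):

* shared-factor genes — blocks of `genes_per_factor` genes per shared
  factor, loading `loading` with random but cohort-invariant signs;
* private-factor genes — disjoint blocks, one per cohort;
* variable background — genes with high independent variance (they
  survive an anti-log CV filter but carry no structure);
* flat background — the remainder, low variance.

On the log2 scale each gene's centered profile is multiplied by a
dynamic-range scale (`signal_scale` for factor and variable-background
genes, `background_scale` for flat genes) so that structured genes show
the fold-change spread real RMA data shows for its variable probes;
scaling a gene by a constant changes neither its correlation structure
nor its z-scores, so the loading:noise ratio is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import ExpressionCohort


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_cohorts: int = 5
    n_genes: int = 1000
    n_samples: int | tuple[int, ...] = 80
    n_shared: int = 3
    n_private: int = 1
    genes_per_factor: int = 40
    loading: float = 0.8
    noise_sd: float = 0.6
    # relative strength (activity sd) per shared factor; None -> geometric
    # decay 1.6 * 0.707**f, giving factors distinct variance shares so the
    # per-cohort PCA eigenvalues are non-degenerate (as in real cohorts,
    # where biological programs differ in how much variance they explain)
    factor_strengths: tuple[float, ...] | None = None
    private_strength: float = 1.0
    # decorrelate factor activities in-sample so planted variance shares
    # are exact and PCA eigenvectors align with the planted factors
    orthogonal_activities: bool = True
    n_variable_background: int = 100
    signal_scale: float = 1.7
    background_scale: float = 0.45
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    batch_sd: float = 0.3
    # outcome links on shared-factor activity (length n_shared or scalar pad)
    response_coef: tuple[float, ...] = (1.5, 0.0, 0.0)
    response_intercept: float = -1.0
    hazard_coef: tuple[float, ...] = (0.7, 0.0, 0.0)
    baseline_hazard: float = 0.15  # events per year
    censor_max_years: float = 15.0

    def samples_for(self, c: int) -> int:
        if isinstance(self.n_samples, int):
            return self.n_samples
        return self.n_samples[c % len(self.n_samples)]

    def shared_strengths(self) -> np.ndarray:
        if self.factor_strengths is not None:
            if len(self.factor_strengths) != self.n_shared:
                raise SimulationError("factor_strengths length must equal n_shared")
            return np.asarray(self.factor_strengths, dtype=float)
        return 1.6 * 0.707 ** np.arange(self.n_shared)


def _draw_activities(
    rng: np.random.Generator, n: int, strengths: np.ndarray, orthogonal: bool
) -> np.ndarray:
    """Sample factor activities with per-factor sd = strength.

    With ``orthogonal=True`` the centered columns are orthogonalized
    (QR with positive diagonal) and rescaled, so factor activities are
    exactly uncorrelated in-sample and each factor's variance share is
    the planted one.
    """
    raw = rng.standard_normal((n, len(strengths)))
    if not orthogonal:
        return raw * strengths
    raw -= raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    sign = np.sign(np.diag(r))
    sign[sign == 0] = 1.0
    q = q * sign
    return q * strengths * np.sqrt(n - 1)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated family; bit-reproducible from (config, seed)."""

    config: SimulationConfig
    seed: int
    gene_ids: list[str]
    shared_loadings: np.ndarray = field(repr=False)  # genes x n_shared
    shared_blocks: list[list[str]]  # gene ids per shared factor
    private_blocks: dict[str, list[str]]  # cohort -> gene ids
    activities: dict[str, np.ndarray] = field(repr=False)  # cohort -> samples x factors


def _block_slices(cfg: SimulationConfig) -> tuple[list[slice], list[slice], slice]:
    g = cfg.genes_per_factor
    shared = [slice(i * g, (i + 1) * g) for i in range(cfg.n_shared)]
    start = cfg.n_shared * g
    private = [
        slice(start + c * cfg.n_private * g, start + (c + 1) * cfg.n_private * g)
        for c in range(cfg.n_cohorts)
    ]
    var_start = start + cfg.n_cohorts * cfg.n_private * g
    variable = slice(var_start, var_start + cfg.n_variable_background)
    if variable.stop > cfg.n_genes:
        raise SimulationError(
            f"gene budget exceeded: need {variable.stop} genes, have {cfg.n_genes}"
        )
    return shared, private, variable


def simulate_cohort_family(
    config: SimulationConfig | None = None, seed: int = 0
) -> tuple[list[ExpressionCohort], list[pd.DataFrame], SimulationTruth]:
    """Simulate analogous cohorts with shared/private factors and outcomes.

    Returns (cohorts, clinical tables, truth).  All randomness flows
    from a single ``numpy.random.default_rng(seed)``, so a fixed
    (config, seed) pair reproduces the family bit-exactly.
    """
    cfg = config or SimulationConfig()
    min_n = min(cfg.samples_for(c) for c in range(cfg.n_cohorts))
    total_factors = cfg.n_shared + cfg.n_private
    if total_factors >= min(cfg.n_genes, min_n):
        raise SimulationError(
            f"{total_factors} factors infeasible for {cfg.n_genes} genes x "
            f"{min_n} samples"
        )
    if cfg.n_cohorts < 2:
        raise SimulationError("need at least 2 cohorts")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    shared_sl, private_sl, variable_sl = _block_slices(cfg)

    # shared loadings: identical across cohorts, random +/- signs
    shared_load = np.zeros((cfg.n_genes, cfg.n_shared))
    shared_blocks = []
    for f, sl in enumerate(shared_sl):
        signs = rng.choice([-1.0, 1.0], size=sl.stop - sl.start)
        shared_load[sl, f] = cfg.loading * signs
        shared_blocks.append(genes[sl])

    resp_coef = np.resize(np.asarray(cfg.response_coef, dtype=float), cfg.n_shared)
    haz_coef = np.resize(np.asarray(cfg.hazard_coef, dtype=float), cfg.n_shared)

    # per-gene dynamic-range scale on the log2 axis
    scale = np.full(cfg.n_genes, cfg.background_scale)
    for sl in shared_sl:
        scale[sl] = cfg.signal_scale
    for sl in private_sl:
        scale[sl] = cfg.signal_scale
    scale[variable_sl] = cfg.signal_scale
    baseline = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(cfg.n_genes)

    cohorts: list[ExpressionCohort] = []
    clinicals: list[pd.DataFrame] = []
    activities: dict[str, np.ndarray] = {}
    private_blocks: dict[str, list[str]] = {}
    for c in range(cfg.n_cohorts):
        cid = f"SIM{c + 1}"
        n = cfg.samples_for(c)
        strengths = np.concatenate(
            [cfg.shared_strengths(), np.full(cfg.n_private, cfg.private_strength)]
        )
        act = _draw_activities(rng, n, strengths, cfg.orthogonal_activities)
        load = np.zeros((cfg.n_genes, total_factors))
        load[:, : cfg.n_shared] = shared_load
        sl = private_sl[c]
        priv_signs = rng.choice([-1.0, 1.0], size=(sl.stop - sl.start, cfg.n_private))
        load[sl, cfg.n_shared :] = cfg.loading * priv_signs
        private_blocks[cid] = genes[sl]

        structured = load @ act.T + cfg.noise_sd * rng.standard_normal((cfg.n_genes, n))
        # unstructured genes get unit-sd noise so scale alone sets their spread
        unstructured = np.abs(load).sum(axis=1) == 0
        structured[unstructured] = rng.standard_normal((int(unstructured.sum()), n))
        batch = cfg.batch_sd * rng.standard_normal(cfg.n_genes)
        log2 = baseline[:, None] + batch[:, None] + scale[:, None] * structured
        # anti-log / re-log round trip keeps the log2 RMA convention explicit
        log2 = np.log2(np.exp2(log2))
        samples = [f"{cid}_S{i:03d}" for i in range(n)]
        cohorts.append(
            ExpressionCohort(cid, pd.DataFrame(log2, index=genes, columns=samples))
        )
        activities[cid] = act

        shared_act = act[:, : cfg.n_shared]
        logit = cfg.response_intercept + shared_act @ resp_coef
        response = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
        rate = cfg.baseline_hazard * np.exp(shared_act @ haz_coef)
        t_event = rng.exponential(1.0 / rate)
        t_censor = rng.uniform(0.0, cfg.censor_max_years, size=n)
        event = (t_event <= t_censor).astype(int)
        time = np.minimum(t_event, t_censor)
        clinicals.append(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "response": response,
                    "time": time,
                    "event": event,
                    "treatment": "simulated",
                }
            ).set_index("sample_id", drop=False)
        )

    truth = SimulationTruth(
        config=cfg,
        seed=seed,
        gene_ids=genes,
        shared_loadings=shared_load,
        shared_blocks=shared_blocks,
        private_blocks=private_blocks,
        activities=activities,
    )
    return cohorts, clinicals, truth


def simulate_holdout_cohort(
    truth: SimulationTruth, n_samples: int, seed: int
) -> tuple[ExpressionCohort, pd.DataFrame, np.ndarray]:
    """Draw an extra cohort from the same shared factors (no private factor).

    Returns (cohort, clinical table, shared-factor activity).  Used to
    validate CEI scoring on data never seen during derivation.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    cid = "HOLDOUT"
    act = _draw_activities(
        rng, n_samples, cfg.shared_strengths(), cfg.orthogonal_activities
    )
    structured = truth.shared_loadings @ act.T
    structured += cfg.noise_sd * rng.standard_normal((cfg.n_genes, n_samples))
    unstructured = np.abs(truth.shared_loadings).sum(axis=1) == 0
    structured[unstructured] = rng.standard_normal((int(unstructured.sum()), n_samples))
    scale = np.full(cfg.n_genes, cfg.background_scale)
    shared_sl, private_sl, variable_sl = _block_slices(cfg)
    for sl in shared_sl:
        scale[sl] = cfg.signal_scale
    scale[variable_sl] = cfg.signal_scale
    baseline = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(cfg.n_genes)
    batch = cfg.batch_sd * rng.standard_normal(cfg.n_genes)
    log2 = baseline[:, None] + batch[:, None] + scale[:, None] * structured
    samples = [f"{cid}_S{i:03d}" for i in range(n_samples)]
    cohort = ExpressionCohort(
        cid, pd.DataFrame(log2, index=truth.gene_ids, columns=samples)
    )
    resp_coef = np.resize(np.asarray(cfg.response_coef, dtype=float), cfg.n_shared)
    haz_coef = np.resize(np.asarray(cfg.hazard_coef, dtype=float), cfg.n_shared)
    logit = cfg.response_intercept + act @ resp_coef
    response = (rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    rate = cfg.baseline_hazard * np.exp(act @ haz_coef)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, cfg.censor_max_years, size=n_samples)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "response": response,
            "time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
            "treatment": "simulated",
        }
    ).set_index("sample_id", drop=False)
    return cohort, clinical, act


def write_family(
    cohorts: list[ExpressionCohort],
    clinicals: list[pd.DataFrame],
    truth: SimulationTruth,
    outdir,
) -> None:
    """Write the family in the TSV layouts the IO module reads; truth under truth/."""
    from .cohort_io import write_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort, clin in zip(cohorts, clinicals):
        write_cohort(cohort, outdir / f"{cohort.cohort_id}_expression.tsv")
        clin.to_csv(outdir / f"{cohort.cohort_id}_clinical.tsv", sep="\t", index=False)
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(
        truth.shared_loadings,
        index=truth.gene_ids,
        columns=[f"factor{f + 1}" for f in range(truth.config.n_shared)],
    ).to_csv(tdir / "shared_loadings.tsv", sep="\t")
    rows = [
        {"cohort": cid, "gene": g} for cid, gs in truth.private_blocks.items() for g in gs
    ]
    pd.DataFrame(rows).to_csv(tdir / "private_genes.tsv", sep="\t", index=False)
    for cid, act in truth.activities.items():
        pd.DataFrame(
            act,
            columns=[f"factor{f + 1}" for f in range(act.shape[1])],
        ).to_csv(tdir / f"{cid}_activity.tsv", sep="\t", index=False)


def noise_sweep_config(base: SimulationConfig, noise_sd: float) -> SimulationConfig:
    """Convenience: same family, different gene-level noise."""
    return replace(base, noise_sd=noise_sd)
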