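"""Clinical association of CEI scores.

Treatment response is evaluated by the empirical ROC curve with
trapezoidal AUC and a two-sided Wilcoxon rank-sum test.  Survival is
evaluated by a median split of the score: follow-up is administratively
censored at a horizon (5 or 10 years by default), patients are split
at the score median into two near-equal groups, and the high/low hazard
ratio comes from a univariate Cox model with the log-rank test for
significance.  Kaplan-Meier curves per group accompany the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_curve


class EvalError(ValueError):
    pass


@dataclass
class ROCResult:
    auc: float
    p_value: float
    direction: str  # "positive": high score enriched in positives
    n_pos: int
    n_neg: int
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)


@dataclass
class SurvivalResult:
    hazard_ratio: float  # high-score group vs low-score group
    p_value: float  # log-rank
    cox_p_value: float
    horizon: float
    n_low: int
    n_high: int
    events_low: int
    events_high: int
    km_curves: dict[str, pd.DataFrame] = field(repr=False)


def roc_auc(scores, labels) -> ROCResult:
    """Trapezoidal AUC of the empirical ROC plus Wilcoxon rank-sum P.

    Ties are handled by simultaneous threshold crossing, which makes the
    trapezoidal area equal to the Mann-Whitney U statistic (1/2 credit
    per tied pair) divided by n_pos * n_neg.  The P value uses the
    normal approximation with tie correction, two-sided.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.isnan(scores).any():
        raise EvalError("missing scores are not allowed")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise EvalError(f"need exactly two classes, got {list(classes)}")
    pos = labels == classes.max()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    fpr, tpr, _ = roc_curve(pos, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    stat = stats.mannwhitneyu(
        scores[pos], scores[~pos], alternative="two-sided", method="asymptotic"
    )
    return ROCResult(
        auc=auc,
        p_value=float(stat.pvalue),
        direction="positive" if auc >= 0.5 else "negative",
        n_pos=n_pos,
        n_neg=n_neg,
        fpr=fpr,
        tpr=tpr,
    )


def km_cox_median_split(
    scores, time, event, horizon: float = 10.0
) -> SurvivalResult:
    """Median-split survival analysis at a follow-up horizon.

    Follow-up beyond the horizon is censored at the horizon.  Samples
    with score <= median form the low group (so an odd cohort puts the
    median sample low, keeping group sizes within one).  The hazard
    ratio of high vs low comes from a univariate Cox model (Efron ties);
    the P value is the two-group log-rank test.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if horizon <= 0:
        raise EvalError("horizon must be positive")
    if len(scores) != len(time) or len(time) != len(event):
        raise EvalError("scores, time and event must align")
    over = time > horizon
    time = np.where(over, horizon, time)
    event = np.where(over, 0, event)
    high = scores > np.median(scores)
    groups = {"low": ~high, "high": high}
    for name, mask in groups.items():
        if mask.sum() == 0:
            raise EvalError(f"median split left group {name!r} empty")
        if event[mask].sum() == 0:
            raise EvalError(f"no events in group {name!r} within the horizon")
    df = pd.DataFrame({"time": time, "event": event, "high": high.astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    cox_p = float(cph.summary.loc["high", "p"])
    lr = logrank_test(
        time[high], time[~high], event_observed_A=event[high],
        event_observed_B=event[~high],
    )
    km = {}
    for name, mask in groups.items():
        fitter = KaplanMeierFitter()
        fitter.fit(time[mask], event[mask], label=name)
        km[name] = fitter.survival_function_
    return SurvivalResult(
        hazard_ratio=hr,
        p_value=float(lr.p_value),
        cox_p_value=cox_p,
        horizon=horizon,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        events_low=int(event[~high].sum()),
        events_high=int(event[high].sum()),
        km_curves=km,
    )


def evaluate_ceis(
    score_table: pd.DataFrame,
    clinical: pd.DataFrame,
    mode: str,
    horizon: float = 10.0,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-CEI association report in response or survival mode.

    Sample ids are inner-joined between the score table and the
    clinical table (dropped ids are counted in the report is empty ->
    error).  In response mode each CEI gets a trapezoidal AUC with
    Wilcoxon P; in survival mode a median-split hazard ratio with
    log-rank P.  With ``adjust=True`` a Benjamini-Hochberg column is
    appended across the CEIs of this call.
    """
    if mode not in ("response", "survival"):
        raise EvalError(f"mode must be 'response' or 'survival', got {mode!r}")
    clin = clinical.copy()
    if "sample_id" in clin.columns:
        clin = clin.set_index(clin["sample_id"].astype(str))
    rows = []
    for cei_id, grp in score_table.groupby("cei_id", sort=False):
        grp = grp.copy()
        grp["sample_id"] = grp["sample_id"].astype(str)
        joined = grp.join(
            clin[["response", "time", "event"]], on="sample_id", how="inner"
        )
        if mode == "response":
            joined = joined.dropna(subset=["response"])
            if joined.empty:
                raise EvalError(f"{cei_id}: no samples join a response label")
            if joined["response"].nunique() < 2:
                raise EvalError(f"{cei_id}: only one response class after join")
            res = roc_auc(joined["score"], joined["response"].astype(int))
            rows.append(
                {
                    "cei_id": cei_id,
                    "mode": mode,
                    "n": len(joined),
                    "n_events": int(joined["response"].sum()),
                    "statistic": res.auc,
                    "p_value": res.p_value,
                    "direction": res.direction,
                }
            )
        else:
            joined = joined.dropna(subset=["time", "event"])
            if joined.empty:
                raise EvalError(f"{cei_id}: no samples join a survival record")
            res = km_cox_median_split(
                joined["score"], joined["time"], joined["event"], horizon=horizon
            )
            rows.append(
                {
                    "cei_id": cei_id,
                    "mode": mode,
                    "n": res.n_low + res.n_high,
                    "n_events": res.events_low + res.events_high,
                    "statistic": res.hazard_ratio,
                    "p_value": res.p_value,
                    "direction": "adverse" if res.hazard_ratio > 1 else "protective",
                }
            )
    report = pd.DataFrame(rows)
    if adjust and not report.empty:
        from statsmodels.stats.multitest import multipletests

        report["p_adjusted"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report
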