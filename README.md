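# cpcei — consistent principal components and expression indices across cohorts

`cpcei` extracts **metagenes that replicate across independent expression
cohorts**.  Given several analogous gene/probe expression matrices (log2,
RMA-like), it finds, per cohort, the principal components that carry the
dominant variation; matches components *between* cohorts; and distills the
recurring ones into compact sign-weighted gene signatures that can score any
new cohort and be tested against treatment response and survival.  It is
aimed at transcriptomics analysts who want unsupervised, cross-study-robust
signatures — the motivating use case is double-negative (ESR1−/HER2−) breast
cancer, where supervised predictors trained on one cohort often fail to
transfer.

## Method

Per reference cohort with expression matrix *X* (p probes × n samples):

1. **Variance filter** — keep probes whose coefficient of variation on the
   anti-log scale, CV = sd(2^x)/mean(2^x), lies in (1, 1000).
2. **PCA** — SVD of the feature-centered matrix; ω_j = explained standard
   deviation of PC j (√eigenvalue), σ_i = probe standard deviation.
3. **Model order by BIC** — residual variance ν_k = Σσ_i² − Σ_{j≤k} ω_j²;
   choose k minimising BIC(k) = n·ln(ν_k/n) + k·ln(n).
4. **Distillation** — for each kept PC, keep probes whose Pearson
   correlation r with the PC score is significant by Student's t
   (t = r√(n−2)/√(1−r²), two-sided P < 0.01), each tagged with sign(r).

Across cohorts:

5. **Consistency clustering** — pooled PCs are compared with
   d_ij = 1 − J_ij·|C_ij|, where J is the Jaccard index of the two
   representative probe sets and C the cosine of the weight vectors on the
   common probes; average-linkage clustering cut at 0.9 yields consistent
   principal components (CPCs).  **CPC genes** are the genes representative
   in ≥ 2 members of a cluster.
6. **Consistent expression indices (CEIs)** — CPC-gene profiles are
   z-scored within each cohort and merged; a varimax-rotated factor model
   is fitted; per-factor least-squares gene coefficients below 0.1 in
   magnitude are zeroed, and the surviving signs become ±1 gene weights.
7. **Scoring & evaluation** — a cohort's CEI score is the sum of signed
   within-cohort z-scores; association with response uses the trapezoidal
   ROC AUC with a Wilcoxon rank-sum P, and with survival uses a
   median-split Cox model (hazard ratio at a 5/10-year horizon) with the
   log-rank test.

A synthetic-cohort generator (`cpcei.synthetic_cohorts`) plants shared and
cohort-private latent factors plus outcome links, and is the test harness
for the whole chain.

## Worked example

```python
from cpcei import (simulate_cohort_family, simulate_holdout_cohort,
                   derive_from_cohorts, score_ceis, evaluate_ceis)

cohorts, clinicals, truth = simulate_cohort_family(seed=1)   # 5 cohorts x 80
result = derive_from_cohorts(cohorts, n_factors=3)
print({cid: p.k_selected for cid, p in result.pcas.items()})
print([(c.cluster_id, len(c.member_pcs), len(c.cpc_genes))
       for c in result.clusters])

holdout, clinical, activity = simulate_holdout_cohort(truth, 240, seed=2)
scores = score_ceis(holdout, result.ceis)
print(evaluate_ceis(scores, clinical, mode="response").to_string(index=False))
```

prints

```
{'SIM1': 4, 'SIM2': 4, 'SIM3': 4, 'SIM4': 4, 'SIM5': 4}
[(1, 5, 40), (2, 5, 40), (3, 5, 40)]
cei_id     mode   n  n_events  statistic      p_value direction
  CEI1 response 240        86   0.909770 6.851107e-26  positive
  CEI2 response 240        86   0.497055 9.404927e-01  negative
  CEI3 response 240        86   0.574524 5.577364e-02  positive
```

Each cohort's BIC picked 4 components (3 shared factors + its private one).
The three CPC clusters each contain one PC from every cohort and recover a
planted 40-gene factor.  On the held-out cohort, CEI1 — the index matching
the outcome-linked factor — separates responders from non-responders with
AUC 0.91, while the unlinked CEI2 sits at chance (AUC ≈ 0.50).

The same pipeline is available from the shell:

```sh
cpcei simulate --out fam --seed 1
cpcei derive --cohort fam/SIM1_expression.tsv --cohort fam/SIM2_expression.tsv \
      --cohort fam/SIM3_expression.tsv --cohort fam/SIM4_expression.tsv \
      --cohort fam/SIM5_expression.tsv --n-factors 3 --out derived
cpcei score --cohort fam/SIM1_expression.tsv --ceis derived/ceis.tsv --out scores.tsv
cpcei evaluate --scores scores.tsv --clinical fam/SIM1_clinical.tsv \
      --mode survival --horizon 10 --out report.tsv
```

`cpcei subtype` assigns receptor subtypes (the double-negative group is the
PAM cluster whose medoid has the lowest combined ESR1+ERBB2 expression).

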