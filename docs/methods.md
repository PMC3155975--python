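# Methods

## Model and assumptions

The package assumes that a set of analogous cohorts (same disease entity,
comparable platform, log2-scale normalized expression) are samples from a
common "expression space": a handful of latent transcriptional programs
recur in every cohort, while additional structure (batch composition,
cohort-specific biology, platform artifacts) is private to single cohorts.
Under this model the recurring programs appear as principal components that
match across cohorts in both *gene membership* and *weight direction*, and
the private structure appears as components that match nothing elsewhere.
The pipeline makes the matching explicit and keeps only what recurs.

Nothing in the chain uses outcome labels until the final evaluation step,
so the derived indices are unsupervised and can be validated on cohorts
with entirely different endpoints.

## Pipeline stages and numerical choices

**CV filter.** CV is computed on the anti-log (2^x) scale with the sample
(n−1) standard deviation, bounds (1, 1000) exclusive.  On log2 data this
admits features whose log2 sd exceeds ≈ 1.2, i.e. genes with genuine
fold-change spread; the upper bound excludes pathological dynamic ranges.
Adding a constant on the log2 scale (a pure fold-change rescaling) leaves
the anti-log CV unchanged.

**PCA.** SVD of the feature-centered matrix, no per-feature rescaling: the
CV filter has already equalized dynamic range, and rescaling would let
near-constant features contribute as much as variable ones.  Component
signs follow a fixed convention (largest-magnitude weight entry positive)
so results are identical across linear-algebra backends.

**BIC model order.** With ν_k = Σσ_i² − Σ_{j≤k}ω_j² (the residual sum of
squared variation after k components), BIC(k) = n·ln(ν_k/n) + k·ln(n), the
Gaussian-residual form: it uses exactly the quantities the decomposition
provides and, on realistic cohort sizes, selects small component counts
(3–6) for structured data and 1 for isotropic noise.  Any scale factor on
ν shifts BIC by a constant and cannot change the argmin; a numerically
zero residual (ν ≤ 10⁻¹² of total variance) is treated as a perfect fit
and returns the first such k with a warning.  k_max defaults to
min(n−1, 20).

**Distillation.** Two-sided t-test on the Pearson correlation between each
feature and the PC score, α = 0.01 by default.  Two-sided is the
conservative choice when the direction is not pre-specified; the sign of r
is retained separately and carries the directional information.

**PC dissimilarity.** d = 1 − J·|C|: 0 iff the representative sets
coincide and weights are collinear, 1 for disjoint sets, bounded in [0,1],
and invariant to the (arbitrary) orientation of either component.  The
cosine is computed on the PC weight entries restricted to the common
representative features.  An alternative combination (e.g. 1 − (J+|C|)/2)
can be swapped in via `pc_dissimilarity`, which is the single place the
formula lives.

**Clustering and cut.** Average-linkage agglomeration on the pooled
distilled PCs (SciPy linkage on the condensed matrix), tree cut at 0.9 by
default.  Because cross-factor distances sit near 1 and same-factor
distances well below it, the result is insensitive to cuts in roughly
[0.6, 0.95]; clusters must have ≥ 2 members, and a cluster whose members
all come from one cohort is kept but logged, since within-cohort
duplication is not evidence of cross-study consistency.  CPC genes require
representativeness in ≥ 2 members, which is what suppresses
private-factor and false-positive genes.

**Factor analysis.** Maximum-likelihood factor analysis with varimax
rotation (scikit-learn `FactorAnalysis`, LAPACK SVD, fixed sign
convention) on the merged within-cohort z-scores; non-convergence raises
with iteration diagnostics rather than returning a partial fit.  Gene
coefficients default to the ordinary least-squares regression of each
gene's z-scores on the factor scores (`coefficient_method="regression"`);
the rotated loadings are available behind the same switch
(`"loadings"`) because the two interpretations of "least-squares
coefficients" differ only by the factor-score covariance, and on clean
data they give the same thresholded signs.  Coefficients with |coef| <
0.1 are zeroed; an all-zero factor is an error, not an empty index.
Factors are renumbered by post-rotation variance explained so CEI1 is
always the dominant index.

**Scoring.** Sum (not mean) of signed within-cohort z-scores.  Every
downstream statistic (AUC, median split) is invariant to positive scaling,
so the choice is cosmetic; the sum is the most literal reading of
"sign-weighted index".  Genes missing from the scored cohort are dropped,
never imputed, and the coverage fraction is reported; coverage < 0.5
warns, 0 errors.

**Clinical evaluation.** Trapezoidal AUC over the empirical ROC with
simultaneous threshold crossing at ties — algebraically identical to the
tie-corrected Mann–Whitney U divided by n₊·n₋, which the test suite
asserts exactly.  The Wilcoxon rank-sum P uses the normal approximation
with tie correction, two-sided, with direction reported separately.
Survival: follow-up is administratively censored at the horizon (default
10 years); the score median splits samples with ties-to-low so group
sizes differ by at most one; the hazard ratio comes from a univariate Cox
fit (lifelines, Efron ties) and the P value from the two-group log-rank
test.  Multiple testing across CEIs is reported raw, with an optional
Benjamini–Hochberg column.

**PAM subtyping.** Deterministic k-medoids (greedy BUILD then
best-improvement SWAP, ties to the lowest index) on the 2-d profile of two
marker genes, default ESR1/ERBB2 and k = 4 (double-negative, ER+, HER2+,
double-positive geometry).  The double-negative group is the cluster whose
medoid has the smallest marker sum — a rule, not a threshold, so it needs
no platform-specific calibration.  All-identical marker profiles are
rejected as degenerate.

## The synthetic generator: what it emulates and what it does not

`simulate_cohort_family` produces cohort families with: shared factors
whose gene blocks and loading signs are identical in every cohort;
one private factor per cohort on disjoint gene blocks; high-variance
unstructured background genes (they pass the CV filter but carry no
signal); low-variance background; per-gene baselines; per-cohort gene
offsets (batch); and outcomes tied to the shared factors (logistic link
for binary response, exponential proportional-hazards link with uniform
censoring for survival).

Defaults are sized to a post-normalization microarray regime: 5 cohorts,
1000 genes, 80 samples per cohort, 3 shared + 1 private factor with
40-gene blocks, loading 0.8 against gene noise sd 0.6 (communality 0.64),
100 variable-background genes, batch sd 0.3, ≈ 30% censoring over a
15-year follow-up window.  Two deliberate design choices:

* **Distinct factor strengths.** Shared factors get activity sds in a
  geometric decay (1.60, 1.13, 0.80 by default; private 1.0 on disjoint
  genes).  Equal strengths would make the covariance eigenvalues
  degenerate, and the per-cohort PCs would be arbitrary rotations within
  the shared subspace — individually unmatched across cohorts even though
  the subspace is identical.  Real transcriptional programs differ in the
  variance they explain, and the CPC idea presumes exactly that
  identifiability.
* **In-sample orthogonal activities.** Factor activity columns are
  decorrelated within each cohort (QR with positive diagonal, then
  rescaled), so the planted variance shares are exact and cross-factor
  leakage reflects only gene noise.  With raw Gaussian activities the
  finite-sample correlations (≈ ±1/√n) would leak between factors; that
  leakage is a property of sampling, not of the method under test.
* **Dynamic-range scale.** The structured z-profile of each gene is
  multiplied on the log2 axis by 1.7 (signal genes) or 0.45 (flat
  background).  Scaling a gene by a constant changes neither its
  correlations nor its z-scores, but it places signal genes in the
  fold-change range that survives an anti-log CV filter with the default
  (1, 1000) bounds — as real variable probes do — and flat genes below it.

The generator does *not* emulate probe-level measurement physics,
normalization artifacts, correlated (non-isotropic) gene noise, overlapping
factor gene sets, nonlinear factor effects, or informative censoring.
Passing tests therefore demonstrate that the chain recovers what its model
class assumes — linear factors with distinct variance shares, recurring
across cohorts — not that any particular biological dataset satisfies those
assumptions.

## Problem sizes used in the test suite

Unit and property tests run on 200–400-gene, 30–80-sample simulations; the
end-to-end recovery checks use the full default family (5 × 1000 × 80) over
10 seeds; survival calibration uses 100 replicates of 236-sample cohorts.
These sizes put every Monte-Carlo assertion several standard errors away
from its threshold while keeping the whole suite around half a minute.

## Known limitations

* The BIC functional form and the d = 1 − J·|C| combination are the
  package's own concrete instantiations of the selection-by-BIC and
  Jaccard-cosine-dissimilarity ideas; both are isolated behind single
  functions so alternatives can be swapped in.
* Median-split hazard ratios inherit the usual dichotomization loss of
  power and depend on the score distribution only through its median.
* `merge_zscores` requires each gene to vary within every cohort; genes
  constant in any cohort are dropped rather than imputed.
* PAM subtyping interprets "consistently low in both markers" as
  minimal medoid sum; with k clusters on strongly non-convex marker
  distributions the geometric labels (other_1, ...) are positional, not
  biological.
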