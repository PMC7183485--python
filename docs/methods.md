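# Methods

## Model and procedure

The analysis asks, for every pair of metabolites, whether their Pearson
correlation differs between two phenotype groups — non-responders ("case")
and responders ("control") to total joint replacement. Each group's
correlation r is mapped to Fisher's z = arctanh(r), whose sampling variance
is approximately 1/(n − 3) and essentially free of the underlying
correlation. The test statistic standardises the difference:

r_diff = (z_case − z_control) / √(1/(n_case − 3) + 1/(n_control − 3)).

The denominator makes the statistic valid for strongly unbalanced groups
(the motivating design is ≈ 67 vs ≈ 378). Under the null of equal
population correlations and approximately Gaussian (after log transform)
data, r_diff ~ N(0, 1); the package verifies this by simulation but never
relies on it for inference — edge selection uses permutation p-values.
Pearson correlation is used throughout: the 1/(n − 3) variance is the
Pearson form, and the pipeline's log/Z-score normalisation is designed to
make it appropriate.

### Permutation test

Phenotype labels are shuffled uniformly at random; one shuffle per replicate
defines a single permuted dataset shared by all pairs (shuffling per pair
would break the joint null and cost three orders of magnitude more). Group
sizes are preserved by construction. The two-sided p-value uses the add-one
estimator p = (b + 1)/(B + 1) with b the count of permuted |r_diff| ≥
observed |r_diff|; it is a valid finite-sample p-value, never zero, with
floor 1/(B + 1). Ties and non-finite permuted statistics count as
exceedances (conservative). Defaults: B = 1000, threshold p < 0.01
(primary) and p < 0.05 (exploratory), both strict inequalities. No
multiple-testing correction is applied beyond these fixed thresholds; the
output states this prominently, and the analytic normal approximation is
exposed only as a diagnostic column (`p_normal`), never used for selection.

### Responder classification

WOMAC pain (0–20) and function (0–68) subscales, 0 = no symptoms. Change
score = baseline − follow-up, so improvement is positive; a change strictly
below the MCID (pain 7, function 22) marks a non-responder, a change at the
MCID a responder. Exclusions apply in order: (1) WOMAC missing — no
complete subscale at all; (2) non-primary osteoarthritis; (3) baseline
below both MCIDs simultaneously (the conjunction reading: such patients
cannot reach either MCID; a per-outcome reading was the open alternative).
A patient with exactly one complete subscale remains analyzable for that
outcome, which is how the per-outcome denominators can differ from the
overall analyzable count. Percentages are reported to one decimal, rounding
half away from zero.

### Quality control

Fixed order: LOD filter → mean imputation → ln + Z-score → outlier mask.

* **LOD filter.** A metabolite is dropped when *more than* the threshold
  fraction (default 10%) of its values is below the limit of detection —
  strictly more; exactly 10% is retained.
* **Imputation** replaces missing and below-LOD values with the metabolite's
  mean over observed values, on the raw scale (imputation precedes the log
  transform in the procedure's ordering). Below-LOD values receive the same
  mean imputation as other missing values; an LOD/√2-style substitute was
  the open alternative.
* **Normalisation**: natural log, then per-metabolite Z-score with the
  sample SD (n − 1 denominator).
* **Outlier mask**: cells with |z| strictly beyond k = 3 are re-masked as
  missing — individual cells, not whole samples (the open alternative;
  cell-masking keeps the sample's other metabolites in play). Masked cells
  are *not* re-imputed; downstream correlations use pairwise-complete
  observations and feed each pair's complete-observation count, not the
  global group size, into the r_diff denominator. The masking rule operates
  on the already-standardised values, which makes it idempotent.

### Network construction

Edges with p < α form an undirected graph; sign(r_diff) is stored as
positive/negative and rendered red/blue. The *central network* is the
connected component with the most nodes (ties broken by edge count, then by
lexicographically smallest node); *hubs* are ranked by degree with
lexicographic tie-breaks. Metabolite classes (glycerophospholipid, lysoPC,
sphingolipid, acylcarnitine, amino acid, biogenic amine, monosaccharide)
are inferred from Biocrates-style identifier prefixes; unknown names map to
"other". Networks export to GraphML (node class/degree, edge
r/r_diff/p/sign/color attributes) and delimited edge lists; lowering α can
only shrink the network (monotone nesting).

## Synthetic cohorts

No public dataset exists for this design, so the generator is a first-class
module. Per group, log-scale values are multivariate normal with correlation
matrix = uniform background (default 0.2) plus planted per-group entries
(positive-definiteness is checked and a violation reported with the
offending edges), scaled by per-metabolite location/spread and
exponentiated. Raw concentrations are therefore log-normal — an assumption
of convenience, chosen so the pipeline's log transform recovers exactly the
scale on which correlations were planted; real panels need not be
log-normal, and heavy non-log-normality is one thing passing tests do not
speak to.

Defaults mirror the motivating study's conditions: 67 cases vs 378 controls,
a 186-metabolite panel of which 55 designated metabolites are censored below
their empirical 15% quantile (so the >10% LOD rule removes exactly those 55,
retaining 131), 2% sporadic missingness, 0.5% injected outliers at |z| ∈
[4, 6] on the log scale (past the ±3 SD rule by a margin that survives the
variance inflation the outliers themselves cause). The three manipulation
masks are kept disjoint so ground truth is unambiguous. WOMAC scores are
drawn as integers clipped to subscale ranges, with change scores
constructed strictly below the MCID for cases and at/above it for controls
on both subscales, so classification recovers the generating labels
exactly. What the generator does *not* emulate: instrument batch/plate
effects, correlated missingness, non-Gaussian tails, and any real
epidemiological structure in the outcomes — conclusions about those require
real data.

Calibration runs (the type-I error study) use the same generator with all
censoring/missingness/outlier fractions at zero: the purpose there is to
test the permutation machinery itself under a clean exchangeable null,
not the QC chain, which has its own recovery tests against generator truth.

## Numerical choices

* |r| is clamped at 1 − 1e−12 before arctanh so numerically collinear pairs
  stay finite; the bias is negligible and continuity is preserved.
* A pair needs ≥ 4 complete observations per group (n − 3 ≥ 1); pairs below
  that, or with zero variance in a group, are dropped from the edge table
  and logged rather than propagated as NaN.
* Pairwise-complete correlations are computed with indicator-matrix algebra
  (sums, cross-products and counts via matrix products), with a fast
  centred-matmul path when no cells are masked — this keeps the ~1000-fold
  permutation loop at study scale in seconds.
* Edge tables are written at six significant digits; re-running with the
  same configuration and seed is byte-identical. Every artifact records the
  seed and a configuration hash. All randomness flows through
  `numpy.random.default_rng`; derived seeds are drawn below 2³¹.

## Problem sizes used in validation

The statistical checks run at the following scales, chosen to make the
Monte-Carlo error small relative to the tolerances being asserted: type-I
calibration on 50 null cohorts of 67 + 378 samples × 30 metabolites at
B = 1000 (≈ 21 750 pairs) against binomial 99% bounds; exhaustive-oracle
agreement at 4 + 4 samples × 3 metabolites against all C(8,4) = 70 label
assignments, sampled at B = 5000, tolerance ±0.03; planted-edge recovery
with 5 planted pairs of effect ≳ 5 on the r_diff scale among 30 metabolites
over 20 cohorts (power ≥ 80% asserted, observed ≈ 100%; false-positive rate
among null pairs ≤ 2%). The acceptance script reports the same quantities
at 10 replicates/seeds, which keeps its full runtime around ten seconds.

## Known limitations

* Mean imputation shrinks variances and can attenuate correlations when
  missingness is substantial; the default missingness is small (≲ 2%).
* The permutation test assumes exchangeability of samples under the null;
  structured confounding (batch, kinship of repeated visits) would violate
  it and is not modelled.
* With B = 1000 the smallest attainable p is ≈ 0.001; ranking edges much
  below the threshold is not meaningful.
* The baseline-floor exclusion uses the conjunction reading (both baselines
  below their MCIDs); cohorts where the per-outcome reading was intended
  will classify a handful of patients differently.
* Component and hub summaries depend only on topology; edge weights play no
  role in centrality.
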