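# Methods

## Data

The packaged dataset holds the per-cell mean of every response for the 12
variety × drying-method cells, exactly as printed in the study's tables
(`sweetdry/resources/study_means.csv`), with sample ids 1–12 following the
published numbering (variety blocks white → pink → orange → purple;
methods lyophilization → convective → osmotic within each block). The
printed ± uncertainties are carried in a side table
(`study_sd.csv`) and are used only as default noise levels by the
simulator; the modelling pipeline operates on means. Total carbohydrates
are stored as printed and not recomputed from the other proximate columns,
and the anomalously large potassium uncertainty of the osmotic purple cell
is stored as-is. Antioxidant values keep a unit tag of "TE/100 g DW"
without conversion, since the source mixes μM and μg prefixes across
tables.

## Network model

The regression is a single-hidden-layer perceptron with 7 inputs (one-hot
variety and method indicators), 9 tanh hidden neurons and 22 logistic
outputs. Outputs are min-max scaled per response onto [0.05, 0.95]: the
margin keeps targets away from the logistic asymptotes so the output layer
never needs saturated weights. Inputs are already in {0, 1} and are not
scaled. With 292 free parameters against 264 target values the network is
mildly over-parameterized, yet exact interpolation is impossible — the
hidden layer plus bias spans at most rank 10 of the 12 samples — so the
attainable SOS floor is positive and optimization quality matters.

Training minimizes the sum-of-squares error with BFGS using analytic
backpropagated gradients. The default schedule is 30 seeded restarts
(weights initialized uniform(−0.5, 0.5), a standard symmetric range for
tanh layers) of 600 exploratory iterations each, after which the five
lowest-SOS candidates are polished to convergence (≤5000 iterations,
gradient tolerance 1e−12) and the best final SOS wins. The landscape is
rugged: fully polished local minima on the packaged data range over
roughly SOS 0.043–0.14 in normalized space, and the two-phase schedule
reaches the good basins (SOS ≈ 0.05) far more cheaply than uniformly long
runs. A default fit takes about two minutes on one CPU. Restarts that
diverge to non-finite loss are discarded with a warning.

Fitting is by resubstitution: with one observation per design cell, any
true hold-out would leave entire factor levels unseen. The report's
"testing" and "validation" r² are computed on seeded random subsets of the
fitted samples (an 8/2/2-style partition), which mirrors the near-identical
per-cycle performance the study reports but should be read as in-sample
quantities.

Two r² conventions appear in the report and are both exposed: the
per-cycle (overall) r² is the squared Pearson correlation between observed
and predicted over all sample × output pairs in normalized space — the
"performance" measure reported by the Statistica-style SANN tooling the
study used — while per-output r² is 1 − SS_res/SS_tot. On the packaged
data the defaults give overall training r² ≈ 0.998 with every per-output
r² above 0.98.

## Sensitivity

Yoon relative importance uses the signed convention: RI_ij =
Σ_k W1[k,i]·W2[j,k], normalized by the signed sum over inputs per output,
×100. Columns therefore sum to exactly 100% while individual entries may
be negative or exceed 100 — matching the signed percentages the study
plots. Biases are excluded. When the signed denominator of an output
nearly cancels (|Σ| < 1e−12) the computation refuses and points to the
absolute-value (Garson-style) variant behind `signed=False`. With zero
hidden biases the input gradient of the network at the origin is
proportional, output by output, to the Yoon numerator, which provides the
independent finite-difference oracle used in the tests. The exact RI
magnitudes of the study depend on its unreported trained weights, so only
structural identities (column sums, permutation and scaling invariances)
are asserted.

## Goodness of fit

Per output: χ² = SSE/(N−n), RMSE = √(SSE/N), MBE = mean(pred−obs),
MPE = 100·mean((pred−obs)/obs), SSE, AARD = 100·mean(|pred−obs|/|obs|),
r², and the residual moments. AARD is defined as the mean absolute
relative deviation ×100 (the standard reading of the name; the study does
not define it). Kurtosis is excess kurtosis — the study's "remarkably
close to zero … normal distribution" reading implies that convention.
n defaults to 0 constants per output, since the per-output share of a
shared network's 292 parameters is not well defined. Relative metrics
refuse zero observations, listing the offending indices.

## Multivariate analysis

PCA is an eigendecomposition of the correlation matrix (standardized
variables); the responses mix % DW, mg/kg and dimensionless scales, so
covariance PCA would be meaningless. Components are deterministically
oriented so each one's largest-magnitude eigenvector entry is positive.
Variable contributions are squared unit-norm eigenvector entries ×100
(summing to 100 per component); loadings (eigenvector × √eigenvalue) are
exported as well, because the study's printed "contribution to total
variance" percentages are ambiguous between the two conventions.
Correlation p-values use the exact t-transform with n−2 degrees of
freedom and no multiplicity correction, as in the source analysis.

Hierarchical clustering defaults to Ward linkage on unstandardized
Euclidean distances. The linkage method is not stated in the study; Ward
is the default here because it exactly reproduces the published
bioactivity + color partition {1,3,5,8}, {2,4,7}, {6,9}, {10,11,12} where
complete, average and single linkage do not, and it matches them on the
other variable sets. The printed linkage-distance magnitudes (~40 for %
variables, ~25,000 for mg/kg minerals) confirm unstandardized distances;
heights are exported but not asserted numerically.

### Known irreproducibilities of the printed tables

Three published statistics cannot be reproduced from the printed data
under any standard convention, and the corresponding acceptance-test cases
fail by design:

* **carbs–moisture correlation.** Printed r = −0.957; the printed
  carbohydrate column gives −0.922. Recomputing carbohydrates by
  difference (100 − moisture − proteins − fats − ash) gives −0.953, inside
  the rounding band — the correlation analysis evidently used
  carbs-by-difference while the table prints a different column. The
  package stores and uses the printed column.
* **Chemical-set PCA.** Printed PC1+PC2 = 72.33%; the printed columns give
  71.93% (no 4–7 variable subset or carbs variant reproduces 72.33 within
  0.3 points).
* **Chemical and mineral cluster partitions.** The published chemical
  partition {1,4,7}, {2,5,8}, {3,6,9}, {10,11,12} and mineral partition
  {1,2,5}, {4,7,8}, {3,6,9}, {10,11,12} are not produced by any linkage ×
  metric × standardization combination on the printed tables. Notably, a
  single plausible typo (sample 2 sugars 35.14 instead of the printed
  45.14) makes every linkage reproduce the chemical partition, suggesting
  the in-software data differed from the printed tables.

## Multi-objective optimization

Eight objectives are read off the model's predictions: maximize phenolics,
DPPH, ABTS, RP, SoA, AIA and AHgA; minimize moisture. The feasible space
has 12 cells, so exhaustive enumeration of the non-dominated set is exact
and is the authoritative result. The genetic algorithm (generational,
non-dominated sorting with crowding, uniform crossover, Gaussian mutation,
default 593 generations × population 100) operates on the relaxed cube
[0,1]^7 and repairs every genome to a feasible one-hot cell by per-block
argmax before evaluation; its front is validated against the enumeration
in the tests. The published front size of 79 points is only meaningful in
relaxed coordinates and is not asserted.

Compromise selection takes the front member with the smallest Euclidean
distance to the ideal point (per-objective best over the front). By
default the distance is computed on the raw objective scales, which
selects the lyophilized purple sample — the study's reported optimum —
because the large-magnitude antioxidant assays dominate; min-max
normalized selection (`normalize=True`) weighs all objectives equally and
would instead select the convective purple sample, trading most
antioxidant values for slightly lower moisture and higher AIA. The study
does not state its normalization; the raw-scale default reproduces its
outcome and the normalized variant carries the scale-invariance property
tests. Reported optimum values are the measured responses of the selected
cell whenever it is one of the 12 study cells, matching how the study
quotes its optimum.

## Synthetic data

`simulate_factorial` draws response = cell mean + Gaussian(0, sd) with the
reported uncertainties as default sd (5% of the mean where none was
printed, i.e. total carbohydrates), clipped so percentage responses stay
in [0, 100] and non-negative responses at 0; clipping is negligible at the
default noise levels, which sit far from the bounds. It emulates the
measurement layer only — between-response correlation beyond the cell
means is not modelled, so passing recovery tests demonstrate estimator
correctness, not robustness to correlated measurement error.
`plant_mlp_dataset` draws a random 7-9-22 network (weights uniform ±0.5),
evaluates it on all 12 encodings and denormalizes with a known scaler;
refitting with that scaler recovers the planted function essentially
exactly (SOS ≈ 1e−20), which is the recovery oracle for the trainer and
the sensitivity analysis. Refitting with a scaler re-fitted to the planted
data instead composes an extra per-output affine map that the logistic
output cannot absorb exactly; the recovery contract therefore uses the
planted scaler.

## Numerical choices and limitations

* Seeds: every stochastic stage takes an explicit integer seed; the CLI
  derives per-stage seeds from a single global seed via spawned
  `SeedSequence` keys. Identical seeds give bit-identical results.
* Scaler inversion is exact to floating-point round-off (asserted at
  1e−12 relative).
* Ties in compromise selection and influence ranking break toward the
  earliest candidate/input index (stable ordering).
* The trained network interpolates 12 design cells; it cannot generalize
  to unseen varieties or drying methods, and "testing"/"validation"
  figures are in-sample. The value of the model lies in compressing the
  factorial response surface for sensitivity and optimization, not in
  out-of-sample prediction.
* With an unlucky restart stream the default 30-restart schedule can land
  ~1e−4 short of overall r² 0.998; more restarts or a different seed
  recover it. The acceptance script reports whatever the seeded run
  produces.
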