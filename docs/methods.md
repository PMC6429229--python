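# Methods

## Problem setting

The package models a membrane transporter's ligand activity from tabular
molecular descriptors. The endpoint is the inhibition constant of
bilitranslocase (BTL) transport, expressed as pKi = −log₁₀ Ki with Ki in
mmol/L; a compound is *active* iff pKi > 1.3 (strict inequality — a
compound at exactly 1.3 is inactive). The modelling workflow is two-staged:
classification models separate active from inactive compounds over the full
modeling set, and regression models — trained on the active compounds only —
estimate pKi for compounds called active.

## Synthetic data generator

Real BTL descriptor tables come from commercial software and are not
redistributable, so the package carries a generator that emulates the
*statistical* structure of that data, not molecules:

* descriptor marginals are standard normal (matching the autoscaled
  representation used downstream, and keeping Euclidean distances
  well-behaved for map training);
* a planted signal: pKi is a linear combination of `n_informative` columns
  (coefficients of magnitude 0.5–1.5, random sign) plus
  `nonlinearity_weight` times the product of the first two informative
  columns, plus Gaussian noise of SD `noise_sd`;
* the remaining columns are noise, partly organized in
  `correlation_block_size`-sized blocks of near-duplicates (shared base
  vector plus N(0, 0.15) perturbation, re-standardized; pairwise r ≈ 0.98),
  so the intercorrelation filter always has work to do;
* the intercept is calibrated by a quantile shift — the cut is placed
  midway between the k-th and (k+1)-th order statistic of the raw response —
  so the realized class split matches `active_fraction` to within one
  compound without touching the descriptor distribution.

Defaults mirror the modelling-set composition: 120 compounds, 78-column
pool, active fraction 50/120 at threshold 1.3, noise 0.3 pKi units,
nonlinearity weight 0.3. The planted truth (support, coefficients,
intercept) is kept on the dataset object and written to a JSON sidecar, so
tests can score recovery against ground truth. `generate_screening_set`
redraws from the same column structure (default library size 300).

What the generator does **not** emulate: discrete/fat-tailed descriptor
distributions, descriptor semantics, activity cliffs, scaffold clustering,
and class-dependent descriptor covariance. A test passing on this data
shows the machinery is correct and recovers planted structure at realistic
noise; it does not certify performance on real chemistry.

## Descriptor treatment

Fixed order: (1) drop zero-variance columns (population variance ≤ 1e−12);
(2) greedy intercorrelation filter — scanning columns left to right, a
column is dropped when its |Pearson r| with an already-kept column exceeds
0.9, so the earlier column of an offending pair survives (deterministic
tie-break); (3) optional Kohonen similarity reduction — the *transposed*
matrix is mapped (descriptors as objects), and from each occupied neuron
only the descriptor closest to the neuron's weight vector is retained; the
grid is the smallest near-square with at least the requested pool size,
since pool sizes, not grids, are the specified quantity; (4) autoscaling to
zero mean and unit **population** SD (ddof = 0, the common chemometrics
convention), fitted on the training partition and applied as-is to test and
screening compounds. The convention is recorded on `ScalingParams`.
Re-running the filters on their own output is the identity.

The similarity-reduction step is computed on the whole modeling set (not
training only): it is an unsupervised pool-shaping step performed before
any split, and is exposed as a config option (`kohonen_pool`, off by
default in the pipeline because the synthetic pools are already small after
the intercorrelation filter).

## Splitting

75/25 (train/validation) or 60/25/15 (train/test/validation); for n = 120
these give 90/30 and 72/30/18. Method `random` stratifies by class with
largest-remainder apportionment; method `som` maps compounds onto a
self-organizing map and draws held-out compounds per occupied neuron
(largest neurons first, farthest-from-centroid compound first), which keeps
every occupied map region represented in training. Splits are disjoint and
exhaustive for all seeds and both methods; a split that would leave a class
absent from training is an error.

## CP-ANN

Rectangular `rows × cols` Kohonen grid. Weights initialize from seeded
uniform noise in (−0.1, 0.1). Per epoch, training vectors are visited in a
seeded shuffled order; the winner is the neuron with minimal Euclidean
distance (ties to the lowest row-major index), and the update is
w_j ← w_j + η(t)·a_j·(x − w_j) with the counter-propagated output update
u_j ← u_j + η(t)·a_j·(y − u_j). The learning rate decays linearly from
η_max to η_min over the epochs. The triangular neighbourhood factor is
a_j = max(0, 1 − d_grid(j, winner)/(r(t)+1)) with Chebyshev grid distance;
the radius starts at the full grid radius and reaches zero at 2/3 of the
run, leaving the final third winner-only. That schedule choice is
deliberate: with a radius that only reaches zero on the last epoch the map
under-spreads (many unoccupied neurons, mixed-class winners); collapsing at
2/3 nearly doubles occupancy on the synthetic data and visibly improves
both resubstitution accuracy and map smoothness.

Defaults: 10×10 grid (neuron count near compound count for ~100-compound
training sets), 100 epochs, η 0.5 → 0.01, non-toroidal. Per-epoch training
RMSE of the output layer is recorded on the model.

Prediction is the winning neuron's output weight; classification cuts at
0.5 with the boundary assigned active. The applicability domain is gated by
ED_crt, the maximal distance of any *training* compound to its winning
neuron on the final map — every training compound is in-domain by
construction, and the in-domain fraction of a screening set decreases
monotonically if ED_crt is lowered.

Two tensions are worth knowing. A sharply trained map (high η, long
winner-only phase) memorizes training compounds, which shrinks training
distances and hence ED_crt, making the AD very strict in high-dimensional
pools; the pipeline therefore keeps classification maps a bit coarser (7×7,
η 0.5 → 0.01) and uses the sharp schedule (η 0.8 → 0.05) only for the
regression lookups, where tight memorization of the small active subset is
what the consensus needs. Second, a CP-ANN is a piecewise-constant lookup:
on a narrow-range external subset its R² can be poor even when the fitted
surface is good — the regression quality claims are therefore evaluated
against the generator's planted truth over all in-domain actives, where the
inverse-leverage consensus reaches R² ≈ 0.9 while individual models sit at
0.6–0.8.

## MLR

OLS on the intercept-augmented autoscaled design, requiring n > p+1 and a
full-rank design (a QR-based check names the collinear columns). The model
stores (XᵀX)⁻¹ so the leverage of any query, h = x̃ᵀ(XᵀX)⁻¹x̃, is available
at prediction time; training leverages lie in [1/n, 1] and sum to p+1. The
warning threshold is h\* = 3(p+1)/n; the multiplier 3 reproduces the
classical 0.4 for p = 11, n = 90. Classification is thresholded regression
on a 0/1 target at cut 0.5 — the minimal reading that lets an MLR appear in
a classifier battery. The strict gate flags h > h\* as out-of-domain.

`LeverageMap` exposes the same leverage structure for an arbitrary training
design independent of any response, so counter-propagation regression
models report the identical h statistic that the inverse-leverage consensus
weighting needs; a model's reliability weight is then architecture-agnostic.

## GA descriptor selection

Binary masks over the descriptor pool; seeded initialization with popcounts
uniform in [subset_min, subset_max]; tournament selection of size 2;
uniform crossover (rate 0.9); per-bit mutation (rate 0.02); random
add/remove repair back to the size bounds; elitism (2), which makes the
best-ever fitness monotone non-decreasing. Fitness is k-fold
cross-validated (default 5; the pipeline uses 3–4 for speed): stratified
folds and held-out standard accuracy for classification, plain folds and
held-out squared Pearson correlation for regression. Stratified folding
retries with a seed offset if a training fold misses a class and errors
after five attempts. A mask whose model cannot be fitted (rank-deficient
fold) scores 0. Fitness evaluations are cached by mask.

In the pipeline, the NN-D mask is searched with CP-ANN fitness (small 6×6,
30-epoch maps inside CV) and the Q-D mask with MLR fitness. The four
regression masks are searched with **MLR** fitness as a fast, low-variance
proxy — on the small active subset (~38 training compounds) CP-ANN
cross-validation scores are too noisy to rank masks reliably, while the
response is close enough to linear that MLR CV ranks the informative
subsets correctly; the final models trained on the winning masks are
CP-ANNs. Distinct GA seeds per model keep the masks diverse (pairwise
Hamming distances ≥ 1 on the synthetic study).

## Consensus

Classification: all participating models must have predicted (an
out-of-domain abstention voids the consensus); `strict` then demands
unanimity (type A), `A+B` accepts the majority with at most one
disagreement among three (types A and B), `pairwise` demands agreement of
both models. Strict predictions are a subset of A+B predictions, hence
PR(A) ≤ PR(A+B) always.

Regression: ȳ_w = (Σ_k y_k/h_k)/(Σ_k 1/h_k) over in-domain models only — a
convex combination in which low-leverage (central, reliable) responses
weigh more; the simple mean is reported alongside. A compound with no
in-domain regression model gets no estimate. The weighting direction
(dividing by h rather than multiplying) follows from leverage being an
unreliability measure; the alternative reading is not a mean of the
responses and is rejected.

## Pipeline and screening

`run_modeling_pipeline` trains the full battery on one descriptor/activity
table: filters → splits (three-way for the full-pool network, a shared
75/25 split for the two GA-reduced models, a further 75/25 split of the
actives for regression) → GA selection → model training → reports. The
quality table is computed over the whole modeling set with single models
predicting everything (their in-domain fraction reported separately) and
consensus columns built from AD-gated votes, so consensus coverage (Σ)
shrinks with strictness. A battery-level external check reports consensus
accuracy and coverage over the shared validation compounds. All stage seeds
derive from the single pipeline seed; two runs with the same seed produce
byte-identical serialized batteries and screening profiles.

`run_screening` applies a battery to an untested library and emits
per-compound profiles (per-model call + AD flag, consensus calls, and a
consensus pKi only for compounds called active by at least one
classification model) plus summary counts.

Problem sizes in the default study (120 compounds, 40-descriptor pool, 5
informative, noise 0.2; GA populations 12–20 over 6–10 generations; 300
screening compounds) are chosen to keep a full pipeline run under half a
minute while leaving all qualitative behaviors — descriptor recovery,
accuracy/coverage trade-off, consensus gains — clearly measurable.

## Numerical conventions and edge cases

* Population (ddof = 0) variance/SD throughout scaling and the regression
  metrics' internal moments.
* Quality indicators with a zero denominator are reported as 0 and listed
  in an `undefined` field (the usual MCC = 0 convention, extended so
  reports stay total). Both accuracy conventions are always computed —
  balanced (SE+SP)/2 and standard (TP+TN)/N — with the standard form as the
  headline value; report rounding is half-even at two decimals.
* rm² clips the R² − R0² difference at zero before the square root (the
  through-origin fit can numerically exceed the ordinary one); the plain
  rm² variant is implemented, not the averaged form.
* Q²F3 references the mean squared external error to the *training*
  population variance.
* ROC/AUC delegates to scikit-learn's staircase construction; one-class
  input is an error.
* Winner ties break to the lowest row-major neuron index; intercorrelation
  ties keep the earlier column; GA masks that mutate to empty are repaired
  by a random single-bit set.

## Known limitations

* CP-ANN predictions are piecewise constant; external R² on narrow-range
  subsets understates fit quality (see above).
* ED_crt as a hard max is sensitive to the most peripheral training
  compound and to how sharply the map was trained.
* The GA optimizes a CV estimate; with small active subsets the selected
  masks can include a few noise descriptors (the consensus is the intended
  mitigation).
* No regularized MLR variants, no probabilistic ensembling, no
  vote-weighted classification consensus.
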