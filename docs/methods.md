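# Methods

`connpred` implements a predictive-modelling chain for relating resting-state
functional connectomes to a continuous behavioural outcome — the setting is a
stroke cohort whose tactile discrimination is scored on a 0–100
area-under-curve scale — together with a synthetic-cohort generator that
provides ground truth for validating every stage.

## Connectome construction

Region-wise time series (T time points × R regions; the reference
configuration is T=140, R=90 on the cerebrum-only AAL parcellation) are
correlated pairwise (Pearson) to give the **low-order functional
connectivity** (LOFC) matrix. The **high-order functional connectivity**
(HOFC) matrix is the "correlation of the correlation": entry (i, j) is the
Pearson correlation between the LOFC rows of regions i and j. Two profile
conventions are implemented; the default removes the entries at positions i
and j from both rows before correlating (profile length R−2), so neither the
unit diagonal nor the pair's own edge inflates the similarity. The
alternative (`full-row-with-diagonal`) correlates the complete rows. The
source literature on topographical-profile connectivity does not restate its
convention, so the choice is exposed in configuration.

Correlations are used raw: no Fisher z-transform (a `fisher_z` utility is
provided, default off), no thresholding, no absolute values. Features are
the upper-triangle entries in row-major order — R(R−1)/2 = 4005 per pool at
R=90, 8010 for the combined LOFC+HOFC pool (LOFC block first). The ordering
is frozen so feature indices are stable across runs.

## Feature engineering: randomized-LASSO stability selection

With p ≈ 8000 edge features and n ≈ 40 subjects, sparse selection is done by
stability selection over the randomized LASSO: B resamples (default 200)
each draw ⌊f·n⌋ subjects without replacement (default f = 0.75, the
randomized-LASSO sample fraction popularised by its scikit-learn
implementation; at n = 40 a 50% subsample leaves too few observations for
any edge to enter the path reliably), z-score features and centre the
response *within the resample* (no statistics leak into cross-validation),
multiply each column by an independent weight drawn uniformly from
[α, 1] (weakness α = 0.5), and fit the ℓ1 path over a 30-point geometric
grid from λ_max = max_j |Xᵀy|/n down to 10⁻³ λ_max. A feature is *selected
in a resample* if its coefficient is nonzero at any grid point; its
selection frequency is the fraction of resamples selecting it, and the
sparse set keeps frequencies ≥ π (default 0.6, inclusive).

The path is computed by an in-house least-angle-regression solver with drop
handling, specialised for n ≪ p (each step is one (n×p) BLAS product plus a
small dense solve); it is verified against `sklearn.linear_model.lars_path`
to 10⁻⁸ in the test suite. The number of features a resample may admit is
capped at q = max(3, ⌈√((2π−1)p)⌉), the scale at which the
Meinshausen–Bühlmann expected-false-selection bound E[V] ≤ q²/((2π−1)p)
stays near one; without the cap the deep λ grid admits ~n features per
resample and background frequencies become uninformative. Note what this
bound does and does not control: the expected *number* of null features
above π is ≈ 1, but the *identity* of the best-aligned noise feature is
fixed given a response vector, so under a permuted-score null the single
luckiest feature can still recur in most resamples. Calibration claims
should therefore be phrased in counts, not maxima.

## Models

Two deliberately simple regressors, both on features z-scored by training
statistics stored in the model, with the target centred (not scaled) so
predictions return on the 0–100 scale:

* **LR** — least squares via `lstsq`; for p ≥ n this is the minimum-norm
  interpolator (pseudoinverse solution).
* **SVR** — linear-kernel ε-insensitive support vector regression,
  ½‖w‖² + C·Σ max(0, |yᵢ − w·xᵢ − b| − ε), solved by libsvm through
  scikit-learn and checked against a direct scipy minimisation of the primal
  in the tests. ε is specified in units of the training-score SD so the
  grid is scale-free. The conventional RBF parameter γ is accepted in
  configuration for fidelity with common SVR parameter files but has no
  effect with a linear kernel; it is logged and ignored.

The tuning grid is C ∈ {2⁻⁵, 2⁻³, …, 2⁵}, ε ∈ {0.01, 0.1, 1}.

## Nested leave-one-out cross-validation

For N subjects: each outer fold holds one subject out, runs stability
selection on the remaining N−1 (strict blind test — the held-out subject
never influences its fold's features), and tunes (C, ε) by an inner LOOCV
over those N−1 subjects, scoring each grid point by the Pearson r between
inner predictions and truths (constant predictions score −1, so a fully
regularised model never wins; ties break toward smaller C, then smaller ε).
A majority vote across the N inner winners fixes one hyperparameter pair,
and a second pass refits every fold with its own features and the voted pair
to produce the N held-out predictions. The vote shares a little information
across folds (documented; a strictly nested `per-fold` mode is available).
Performance is the Pearson r between predicted and observed scores with
one- and two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df. Both sidedness
variants are reported because published tables of this design are usually
consistent only with the one-sided convention.

A fold whose selection is empty predicts its training mean. One consequence
deserves emphasis: the leave-one-out training mean is (S − yᵢ)/(N−1), which
is *exactly anti-correlated* with the observed scores, so a run in which
every fold is empty reports r = −1. This is a well-known LOOCV artifact,
not a bug; it dominates permutation-null runs at high dimension, where
selection (correctly) finds nothing. Null-calibration experiments are
therefore run in a regime where selection stays active (small R with the
cap q raised to 10), which is the only regime in which "null r ≈ 0,
p ≈ uniform" is even the right expectation.

## Consensus final model

Features selected in at least ⌈half the folds⌉ (inclusive) form the
consensus set; a second stability-selection pass over all subjects,
restricted to the consensus columns (seed derived from the base seed with a
fixed tag), gives the final features; the majority-voted hyperparameters are
refit on the full cohort. Final features are reported as named atlas edges
(the 90-region AAL label table ships with the package), each region pair
categorised LOFC-only / HOFC-only / both depending on which pool(s)
contributed it.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

* **Base correlation**: a 5-factor loading model ΛΛᵀ + ψI normalised to unit
  diagonal — positive definite by construction, with the block structure of
  resting-state connectomes.
* **Between-subject variability**: i.i.d. symmetric background noise on all
  edges (SD 0.1, a typical between-subject edge-FC spread) plus uniform
  deviations δ_s ∈ [−0.3, 0.3] at the planted edges. Without the background
  term every feature would be a deterministic function of the few planted
  deltas and the selection problem would be degenerate. Matrices are
  re-projected to valid correlations (eigenvalue clipping at 10⁻⁶, unit
  diagonal re-normalisation).
* **HOFC-planted edges**: a fixed random loading pattern over ~10 partner
  regions is added, scaled by δ_s, to *both* endpoint rows, so the pair's
  profile similarity (its HOFC value) varies across subjects while its own
  LOFC entry does not carry the signal. Because the HOFC value is
  approximately even in δ_s while the perturbed LOFC entries are linear in
  it, a linear model on LOFC features cannot capture this component — the
  mechanism behind the combined-pool advantage.
* **Scores**: exactly linear in the realized edge values (LOFC edges read
  off the subject's matrix, HOFC edges off the HOFC derived from it), plus
  Gaussian noise calibrated on an internal 300-subject cohort so the oracle
  linear model attains a requested R², then affinely mapped to mean ≈ 55,
  SD ≈ 15 on the 0–100 scale and clipped. Planted weights are scaled so
  each edge contributes equal variance. Time-series mode draws T×R
  zero-mean Gaussian series with the subject's target correlation, so the
  empirical LOFC converges to the target as T grows; connectome-level mode
  skips sampling and returns the targets (same subjects, same scores).
* **Reproducibility**: subject s uses the stream
  `SeedSequence(master_seed, spawn_key=(s,))`; regeneration is
  bit-identical. All randomness in selection/CV flows from integer seeds,
  with per-fold streams spawned the same way.

What the generator does **not** emulate: scanner artifacts, head motion,
haemodynamic filtering, lesioned-tissue signal dropout, non-Gaussian BOLD
marginals, and autocorrelated time courses. Passing recovery tests on these
cohorts demonstrates the statistical machinery, not robustness to fMRI
nuisance structure.

## Experiment scales and numerical choices

Validation experiments use the following sizes, chosen to exercise each
property at the smallest scale where it is meaningful: oracle-equivalence
checks at R = 5–10; selection recovery at the study's full feature count
(n = 200 cohorts, 10 planted edges, 4005 features; B = 100); end-to-end
nested CV at the full n = 40 × 8010 scale with one LOFC- and one
HOFC-planted edge and B = 25 inside CV (B trades Monte-Carlo resolution
against the 40-fold outer loop; frequencies near the 0.6 threshold move by
at most 0.04); the pool-comparison trend at R = 30 over five cohorts with
ε fixed at 0.1 in the tuning grid; and permutation-null calibration at
R = 10 with q = 10 (see the LOOCV-artifact note above). Degenerate inputs
(constant time courses, zero-variance profiles or columns, empty feature
sets, empty consensus) raise by default with named offenders; flag-guarded
zero-fill variants exist where a pipeline run should survive an isolated
bad region.

## Known limitations

* The two-pass majority-vote protocol lets hyperparameter choice see all
  folds' inner winners; the strictly nested mode avoids this at the cost of
  per-fold hyperparameters.
* At n ≈ 40 with thousands of features, edges whose marginal correlation
  with the outcome is below ≈ 0.6 are statistically invisible to any
  selector; recovery experiments therefore concentrate the planted signal
  in few edges. This is a property of the regime, not of the
  implementation.
* Stability selection controls the expected count of false high-frequency
  features, not the maximum frequency of the luckiest null feature (see
  above).
* The impairment cutoff (60.25 on the behavioural scale) is carried as an
  annotation in reports only; modelling treats the score as continuous.
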