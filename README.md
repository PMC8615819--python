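# connpred

Predicting a continuous behavioural outcome from resting-state functional
connectomes, for researchers studying brain–behaviour relationships in
clinical cohorts — the motivating setting is predicting residual
somatosensory function (a 0–100 tactile-discrimination score) in chronic
stroke survivors from 90-region resting-state fMRI connectivity.

The pipeline:

1. **Connectomes** — per subject, the low-order functional connectivity
   (LOFC) matrix is the Pearson correlation of region time courses,
   `LOFC[i,j] = corr(x_i, x_j)`; the high-order matrix (HOFC) is the
   correlation of connectivity profiles,
   `HOFC[i,j] = corr(LOFC[i,·], LOFC[j,·])` (entries i, j excluded from
   both profiles), the "correlation of the correlation".
2. **Features** — upper-triangle edges: 4005 per pool at R=90, 8010 for
   the combined LOFC+HOFC pool.
3. **Selection** — randomized-LASSO stability selection: B subsample-and-
   fit repetitions with per-feature penalty weights drawn from [α, 1];
   features kept when their selection frequency ≥ π.
4. **Models** — linear regression and linear-kernel ε-SVR, evaluated by
   nested leave-one-out cross-validation with per-fold blind feature
   selection, inner-loop hyperparameter tuning, and a majority vote;
   performance is the Pearson r between held-out predictions and observed
   scores with a t-based p-value (t = r·√((n−2)/(1−r²))).
5. **Final model** — features selected in at least half the folds are
   re-selected on all subjects and refit, reported as named AAL atlas
   edges (LOFC-only / HOFC-only / both).

A synthetic-cohort generator with planted edge→score signal (known ground
truth, calibrated oracle R²) stands in for clinical data and backs the test
suite. See `docs/methods.md` for the model details and design choices.

## Worked example

```sh
connpred simulate   --out-dir cohort --n-subjects 40 --n-regions 90 \
                    --n-timepoints 140 --lofc-edges 1 --hofc-edges 0 --seed 7
connpred connectome --manifest cohort/manifest.csv --out-dir conn
connpred cv         --features conn/features.tsv --manifest cohort/manifest.csv \
                    --model SVR --n-resamples 50 --seed 7 --out cv_svr.json
connpred report     --cv-result cv_svr.json --manifest cohort/manifest.csv
```

prints (abridged):

```
r=0.8697 p_one_sided=1.63e-13

pool        model  r     p_one_sided  p_two_sided  n   seed
LOFC+HOFC   SVR    0.87  1.6e-13      3.3e-13      40  7

# impairment annotation: 24/40 subjects at or below the 60.25 cutoff
```

Here `r` is the correlation between each subject's held-out CV prediction
and their observed score — 0.87 means the planted edge was recovered from
the 8010-feature pool in essentially every fold and carries most of the
score variance (the cohort was simulated at oracle R² = 0.9, i.e. r ≈ 0.95
for a perfect model; the gap is T = 140 sampling noise in the empirical
connectomes plus selection noise at n = 40). The demo plants its signal in
a single edge because estimating connectivity from 140 time points roughly
halves detectable effect sizes — at n = 40 an edge must correlate ≳ 0.65
with the outcome to be found among 8010 candidates; `docs/methods.md`
discusses this detection ceiling. The impairment line counts subjects at
or below the 60.25 abnormality cutoff; it annotates reports only and never
enters the models.

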