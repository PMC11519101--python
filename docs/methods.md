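# Methods

## Outcomes and data model

The package models two daily recovery outcomes per athlete: the morning
Perceived Recovery Status (AM PRS, 0–100, centered around each athlete's
own mean so that a unit is "one point relative to my usual morning") and
the day-over-day change in Ln rMSSD (HRV change).  Raw inputs are two
long-format CSV tables: one row per workout (modality, minutes, CR100 RPE,
pre-exercise carbohydrate grams) and one row per athlete-day (diet totals,
sleep duration and 1–7 quality, 1–10 soreness, 1–7 life stress, AM PRS,
Ln rMSSD, resting HR, body mass).

## Feature engineering conventions

* Session training load is `RPE × duration_min / 10`; the division by 10
  rescales the 100-point RPE so load values are comparable to the familiar
  10-point session-RPE convention.  Multi-session days are summed for
  duration and load, and use the duration-weighted mean for daily session
  RPE and pre-exercise carbohydrate; a day is flagged fasted if any session
  was preceded by < 5 g of carbohydrate in the pre-exercise window.
* Rolling windows are trailing, include the current day, and are emitted
  only once the full window exists — warm-up days are missing, never
  zero-filled.  Rest days contribute zero load to the windows (monotony is
  only meaningful if easy days count as low-load days).
* SDs are sample (n−1) SDs throughout.  Monotony (`7-day mean / 7-day SD`)
  with a zero-SD window is missing rather than infinite, and is later
  imputed like any other gap; this avoids infinite-leverage rows while
  keeping the day in the dataset.
* The 7-day EWMA uses the span convention `alpha = 2/(7+1)`, seeded at the
  first observation (`ewm(span=7, adjust=False)`), applied to training
  load, Ln rMSSD and resting HR.
* Day of week is encoded as 7 indicator columns.  Planned interaction
  columns are literal products of their named parents (7-day TL × 3-day
  CHO and monotony × 3-day CHO for AM PRS; prior-day TL × sleep and
  prior-day TL × prior-day PRS for HRV change) and are only admitted by
  the interaction-aware LASSO learner.
* A "training feeling" column is accepted as an optional pass-through; no
  collection instrument is assumed.

## Preprocessing

Inclusion requires ≥ 6 h/week average training, ≥ 85% of predictor cells
logged, and ≥ 42 tracked days; days without any energy-intake record are
dropped before anything else.  Missing raw values are imputed within
athlete: diet columns by k-nearest-neighbour (k = 5) on the standardized
within-athlete block (mean fallback when no neighbour is defined, medians
for anything left), everything else by the athlete's median.  Dropped days
are re-inserted as missing rows first so calendars stay gap-free for the
rolling windows.  Residual derived-feature gaps (warm-up windows, zero-SD
monotony) are median-filled per athlete after feature construction.

Predictors with pairwise |Pearson r| > 0.85 are pruned iteratively: find
the most correlated pair, drop the member with the larger mean absolute
correlation against everything else, recompute, repeat.  Pruning runs once
on the full unfolded design matrix before cross-validation; this mirrors a
prior-to-modeling pruning order and is accepted as mild leakage (feature
identity, not coefficients, crosses folds).

### Lag unfolding

Each athlete's series is converted to independent-observation rows by
stacking lagged copies (lags 1..7) of every dynamic column and discarding
the athlete's first 7 rows; static subject characteristics pass through
unlagged.  Seven lags cover a weekly behavioural cycle, and 7-day rolling
features at lag 7 let a model see two weeks of history.  Unfolding is
strictly within athlete — shifting across athletes would be incoherent.

Lag-0 admission is governed by morning availability: variables known at
the morning observation (sleep, wellness scores, HRV, resting HR) may
enter at lag 0; variables accrued later that day (training, diet and their
rolling summaries) enter only at lags 1..7, so a morning score is never
predicted from that afternoon's workout.  A config switch
(`same_day_policy='all_lag0'`) relaxes this for exploratory use.  Columns
concurrent with the outcome are never admitted at lag 0: the outcome's own
family for AM PRS, and both the HRV and resting-HR families for HRV change
(the day's resting HR comes from the same morning reading that defines the
day's HRV change, and would otherwise predict it almost exactly).

## Models

Group models are validated by leave-one-subject-out CV: each athlete is
held out in turn, hyperparameters are tuned by inner CV on the remaining
athletes (LASSO/ridge pick their penalty by internal cross-validation at
the minimum mean CV RMSE, not the one-SE rule), and reported RMSE/R² are
across-fold means with a 95% t-interval from the fold distribution.
Predictors are standardized on training folds inside each pipeline.  R² is
the squared Pearson correlation of observed and predicted, defined 0 for a
constant predictor, so the intercept baseline has R² 0 and RMSE close to
the outcome SD by construction.

The learner registry holds regularized linear models (ridge, LASSO, LASSO
plus the planned interaction columns), k-NN, an RBF SVM, two gradient-
boosted tree adapters and a single-hidden-layer network; adapters that
cannot be built in the running environment are skipped with a warning.  No
multivariate-adaptive-regression-splines backend is provided.  Regularized
linear learners are the load-bearing path — in this problem family the
LASSO is typically the best performer, and the registry exists to
demonstrate that more complex learners are not needed.

The top-5 comparison model is a random-intercept linear mixed model on the
five highest-importance features, evaluated under the same LOSO scheme
with the held-out athlete's random effect set to 0.  REML fitting retries
across optimizers because a zero random-effect variance sits on the
parameter boundary.

Individual models run per athlete (≥ 30 usable rows): 10×10-fold CV over
the requested learners, lowest mean RMSE wins, ties break toward the
simpler learner class (regularized linear first).  Accuracy metrics are
means ± SD of out-of-bag RMSE/R² over 500 bootstrap resamples (resamples
with no out-of-bag rows are redrawn).

## Interpretation

Permutation importance is the increase in pooled held-out RMSE after
permuting one feature within each LOSO test block, averaged over repeats
(default 10; the repeat distribution is retained for box plots).  Using
held-out rather than resubstitution error keeps the ranking an
out-of-sample statement.  Lagged copies of a variable are distinct
features.  Individual-model importance uses |standardized coefficient| for
linear learners (permutation fallback otherwise), scaled to sum to 1 so
rankings are comparable across athletes whose best learners differ; the
across-athlete aggregate is the mean scaled importance with absent
features counted as 0.  Partial dependence sweeps a feature over its
5th–95th percentile grid with all other columns at observed values.

## Model-family comparison

Per-athlete RMSEs (one per model type) enter a random-intercept mixed
model with model type as fixed effect; estimated marginal means are
recovered by contrast vectors from intercept + treatment coding.  Pairwise
contrasts use the Sidak adjustment `p_adj = 1 − (1 − p)^m` by default;
the Tukey studentized-range test is selectable, since both conventions are
common for this comparison and they rarely disagree qualitatively.
α = 0.05.  The compact letter display uses insert-and-absorb, so two model
types share a letter iff their adjusted p exceeds α.

## The synthetic cohort

The generator emulates a 12-week observational monitoring study at its
published scale and descriptive statistics, used as fixed defaults: 43
athletes × 84 days, sleep 7.5 ± 0.7 h, intake 39.6 kcal/kg with
4.1/1.9/1.7 g/kg CHO/protein/fat, ~11.8 training hours/week with a weekly
cycle (weekday rest probability ~0.15, long weekend sessions), centered
AM PRS SD ≈ 14.3, HRV-change SD ≈ 0.31, and 2.4% MCAR missingness in
predictor cells (current-day outcomes are never blanked; a rate is all
that is known about the real mechanism, so MCAR is assumed).

Generative structure:

* **HRV**: `x_t = mu_i + phi_i (x_{t-1} - mu_i) + gamma * load_{t-1} +
  delta * sleep_t + eps_t` with athlete-specific baseline `mu_i` in
  [3.1, 4.9] Ln rMSSD units and persistence `phi_i ~ U(0.45, 0.75)`.  The
  load term uses athlete-centered load (a raw-load term would only shift
  the personal baseline).  Residual SD 0.28 makes sd(HRV change) ≈ 0.31.
  The pure AR(1) core implies lag-1 autocorrelation `(phi − 1)/2` for the
  change series — the mean-reversion signature the models must find.
* **AM PRS**: personal mean plus an AR(1) carry-over (coefficient 0.35) of
  the centered previous score plus linear effects of standardized drivers
  — soreness (−4.5 points/SD), life stress (−3.5), sleep quality (+3.5) —
  plus N(0, 11) noise, clipped to [0, 100].  These defaults make total
  centered SD ≈ 14.3 with roughly a third of the variance predictable,
  matching the scale of group-model gains observed in practice.
* **Wellness**: integer scores are binned latent Gaussians — soreness
  loads on yesterday's and smoothed training load, sleep quality on sleep
  duration, stress is AR(1) noise — matching the 1–10/1–7 integer
  instruments.  RPE is drawn per session around CR100 ~45 ± 13, clipped to
  [10, 95]; no empirical RPE distribution is assumed.
* **Heterogeneity switch**: with `heterogeneity_sd > 0`, each athlete's
  PRS driver coefficients get independent N(0, sd) deviations over a wider
  candidate pool (soreness, stress, sleep quality, sleep duration,
  prior-day protein, 3-day CHO, prior-day load).  Athletes then differ in
  *which* variables matter, which is what makes individually selected
  top-5 models beat group-selected top-5 models — the central
  individual-vs-group contrast becomes a testable scenario.

What the generator does **not** emulate: menstrual-cycle, alcohol and
illness effects; device-specific measurement noise; informative
missingness; non-linear or interaction effects in the outcome models; drift
in fitness over the block.  Passing tests therefore show that the pipeline
recovers linear, stationary, within-athlete structure at realistic noise
levels — not that real athlete data satisfies those assumptions.

## Problem sizes and numerical choices

Tests exercise the study-scale cohort (43 × 84) where the property under
test concerns cohort-level behaviour (signal detection, driver recovery:
20 seeded replicates each; the null-cohort leakage guard uses 5), and
smaller cohorts (6–8 athletes, 6–8 weeks) for structural and end-to-end
checks.  The acceptance script runs single full-scale cohorts per
scenario.  LASSO penalties search a fixed 15-point log grid with 3-fold
inner CV; bootstrap B = 500 for reported individual metrics (200 in the
top-5 comparison loop); permutation importance uses 10 repeats by default
and 3–5 inside replicate loops.  All stochastic steps fan out from one
seed via `SeedSequence`, so any artifact is bit-reproducible from
(config, seed).

## Known limitations

* Individual-model selection over large learner grids is the slowest path;
  the default configuration restricts it to regularized linear and k-NN
  learners.
* The correlation-pruning order (before cross-validation) is a documented
  mild leakage accepted for parity with common practice.
* The mixed model assumes exchangeable per-athlete RMSEs across model
  types; no variance heterogeneity across types is modelled.
* Imputation of derived features by athlete medians is crude for long
  missing runs; with ≤ 20% missingness per athlete this is immaterial.
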