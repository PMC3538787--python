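# Methods

## The prediction problem

The input is a sparse long-format table of neurodevelopmental event
timings: rows (species, event, PC day) with PC day > 0 the
post-conceptional day of the event, plus a primate flag per species and
a coarse anatomical class (cortical / limbic / other) per event. With s
species and e events, p ≤ s·e cells are observed; the task is to predict
the remaining cells. Raw PC days are strongly right-skewed — late
events, mostly in primates, form a thin long tail — so both models work
on a natural-log response, chosen to compress the dynamic range rather
than to enforce normality.

Before any modelling the table is restricted to events documented in at
least two species and species with at least two documented events. The
two criteria interact (removing an event can push a species below its
threshold and vice versa), so the filter iterates to a fixed point where
both hold simultaneously; a single pass is not sufficient in general.
The fixed point also guarantees that every leave-one-out training fold
still contains each held-out observation's species and event.

## Offset-log dummy regression

ln(PC − k) = Xβ is fit by least squares via QR factorization. The design
X contains species indicators (base species dropped), event indicators
(base event dropped), primate×cortical and primate×limbic interaction
columns, and an intercept: (s−1) + (e−1) + 2 + 1 = s + e + 1 columns
(106 at the 10 × 95 scale). The auto-selected base levels are the
lexicographically first species and event; in-sample predictions are
invariant to this choice (tested to 1e-8), so it only affects coefficient
readout, not predictions.

The offset k is shared across species and must satisfy
0 < k < min(observed PC) for the log to exist. It is estimated by
maximizing the Pearson correlation between observed PC days and
back-transformed in-sample predictions exp(X β̂(k)) + k:

* a uniform 200-point grid spans [0.01, min(PC) − 0.01] days (the 0.01-day
  guard bands keep the response finite); the grid keeps the search
  global because the correlation profile need not be unimodal;
* the grid maximizer is then polished by a bounded Brent search between
  its two neighboring grid points (xatol 1e-10). On noiseless
  generative data this recovers the true offset to ~1e-7 days, which is
  what makes exact leave-one-out recovery checks possible;
* ties on the grid break toward smaller k.

Correlation is computed on the original day scale by default — the
quantity being matched is the event timing itself — with a log-scale
option. Since the design matrix does not depend on k, X is factorized
once per table and reused for every k on the grid and in the polish.

Two estimability edge cases arise in small tables and LOO folds: an
interaction column can be identically zero (no primate observation of
that class) or exactly collinear with a primate's species indicator
(every observed event of that primate is cortical or limbic). In both
cases the interaction coefficient is inestimable and is pinned to 0; the
remaining coefficients are estimated as usual. Rank deficiency among
species/event/intercept columns (e.g. a disconnected species–event
observation graph) is a hard error naming the collinear columns.

A fixed-k mode (e.g. k = 7 days) reproduces the original
peak-neurogenesis model family. No standard errors are computed for β;
the model's use here is purely predictive.

## Feed-forward network

A single hidden layer of h logistic units, linear output, optional skip
layer, inputs the s + e binary indicators (full coding — the network has
its own biases and weight decay absorbs the redundancy; every input row
sums to exactly 2). The response is ln(PC day); predictions
back-transform with exp alone, no offset. Parameter count is
h·(s+e+1) + (h+1), plus s+e skip weights if present: 108 for h = 1, no
skip, at the 10 × 95 scale.

Training minimizes SSE + λ‖θ‖² over all parameters — biases included in
the penalty, keeping the regularizer a single scalar contract — by
full-batch L-BFGS-B with the analytic gradient (verified against finite
differences to 1e-5 relative). Initial weights are uniform in
[−0.5, 0.5] from a caller-supplied seed; training is deterministic given
(data, architecture, seed). Non-convergence within `max_iter` (default
2000) produces a warning and returns the best point found. Per-parameter
bounds can clamp individual weights; clamping the hidden→output weight
to 0 with a skip layer reduces the model to ordinary linear regression,
which is used as a structural test. No stochastic gradient is used — the
data sets are hundreds of rows.

## Leave-one-out assessment and hyperparameter choice

Each of the p observations is held out in turn; the model is refit on
the remaining p − 1 rows and the held-out day predicted. For the
regression, k is re-estimated inside every training fold — holding it
fixed would leak the held-out value. For the network, every fold is
trained from `restarts` (default 10) random initializations and the
per-restart predictions retained.

The prediction error is the mean squared difference between observed and
predicted values on the original day scale. The (h, λ) grid search
computes, for every cell, the per-restart day-scale MSE and averages the
errors across restarts (averaging predictions first is exposed as
`mode="error_of_mean"`); the chosen cell minimizes the averaged error,
ties breaking toward smaller h then smaller λ. The default λ grid is 21
log-spaced points on [1e-3, 1] plus 0, resolving the region where the
error typically drops sharply before rising again under heavy decay.

Per-fold training seeds are derived as CRC32(master seed | species |
event | restart index), making every prediction independent of row order
and reproducible; derived seeds stay below 2³¹.

## Error-threshold profiles

For a set of LOO predictions, N(θ) counts observations with
|observed − predicted| strictly greater than θ days (restart-mean
predictions for the network), split into primate and non-primate
contributions — the partition is exact and N(θ) is non-increasing in θ
by construction, both asserted over the grid. The default θ grid is the
integers 1–30 days. Exceedance sets from two models over the same
observations can be intersected to count events both models mispredict,
|A∩B| ≤ min(|A|, |B|).

## Synthetic data

The generator draws pc(i,j) = k_true + exp(α_i + β_j + ε_ij) with
ε ~ N(0, noise_sd²) — exactly the regression's generative form, so the
regression recovers the truth in the noiseless limit. Defaults emulate
the empirical compilation's conditions: 10 species (2 primates), 95
events, k_true = 5 days, noise_sd = 0.1 on the log scale, 60 % of cells
missing. Species effects are N(0, 0.6²); event effects are uniform on
[1, 5] sorted ascending, so later indices are later events and raw days
span roughly one to two hundred days with the characteristic positive
skew. Event classes are drawn 40/30/30 cortical/limbic/other.

Missingness is elevated by a factor of 2 for primate rows and 2 for the
last third of events (the late tail), with per-cell rates calibrated so
the expected overall missing fraction hits the target (clipped at 0.95,
which leaves the realized rate slightly under the target when the
multipliers saturate). Masked cells are then re-added greedily — always
the cell whose counterpart axis has the fewest observations — until
every event spans ≥ 2 species and every species has ≥ 2 events, so the
generated tables always pass the coverage filter.

A `nonlinear` knob adds a saturating term c·tanh(α_i β_j) on the log
scale, producing data the additive regression cannot represent exactly —
the regime where the network's nonlinearity can pay off.

What the generator does **not** emulate: phylogenetic covariance between
species, heteroscedastic noise (e.g. noisier primate literature),
genuine interaction structure matching the primate×class columns, and
the idiosyncratic missingness of real literature compilations. Passing
recovery tests therefore demonstrate correctness of the estimators under
the assumed model, not predictive validity on empirical tables.

## Problem sizes used in tests and the acceptance script

Unit and property tests run at 4–6 species × 5–15 events. Recovery
checks use 10 species × 30 events at 50 % missingness (≈ 140–150
observations); the grid-search demonstration uses 6 species × 15 events
with h ∈ {1, 2}, 8 λ values and 3 restarts; the FD-vs-FFNN LOO
comparison uses 10 species × 40 events (≈ 215 observations) with 3
restarts at the network's typical optimum (h = 1, λ = 0.05). These sizes
keep a full run to a few minutes on one CPU while leaving every
qualitative behaviour (noiseless exactness, noise monotonicity,
underfitting at large λ) visible.

## Known limitations

* Offset estimation assumes a single shared k; real compilations suggest
  k drifts as data accumulate.
* The interaction-pinning rule silently zeroes inestimable interaction
  coefficients; predictions for the affected primate×class cells fall
  back to the additive part.
* Network training at λ = 0 can stall near flat regions of the loss;
  all selection paths use λ > 0 cells unless the data are exactly
  realizable.
* No inferential output (standard errors, intervals) is provided for
  either model; restart spread is the only uncertainty indication for
  the network.
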