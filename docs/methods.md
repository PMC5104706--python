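# Methods

This note documents the models, conventions and design choices behind
`sedlm`, in the order the pipeline runs them.

## The three-state mortality process

Mortality displacement requires at least three states.  `sedlm.simulator`
implements the minimal such model: an effectively infinite healthy pool,
a small dynamic frail pool `m_t`, and an absorbing dead state.

    m_{t+1} = m_t + u_t − y_t
    u_t ~ Poisson(μ_t),        log μ_t   = α_entry + β_entry X_t + offset_t
    y_t ~ Binomial(m_t, φ_t),  logit φ_t = α_exit  + β_exit  X_t

Daily deaths equal daily entries in equilibrium, so seasonality lives in
the entry rate (`offset_t`); low-frequency structure in the exit
probability would only modulate the pool size, not observed seasonality,
and is omitted.

**Lifetime convention.**  The mean lifetime in the frail state (MLT) maps
to the base exit probability as `φ = 1/(1+MLT)`: under daily geometric
death the expected number of *additional* days survived after entry is
`(1−φ)/φ`, and `MLT = 0` gives `φ = 1` — immediate death, collapsing the
model to a plain Poisson (two-state) process.  The alternative `φ = 1/MLT`
is inconsistent with that degenerate case; both are available via
`alpha_exit` if a caller wants full control.

**Within-day ordering.**  The pool update is taken literally: day-t
entrants join `m_{t+1}` and are first at risk the next day.  The
alternative (entrants immediately at risk) is the
`entrants_at_risk_same_day` flag.  For lifetimes of a few days or more
the difference is far below sampling noise, but the degenerate case
differs qualitatively: with MLT = 0 the default ordering makes deaths
echo the previous day's entries (`y_t = u_{t−1}`), while the same-day
flag yields the exact two-state reduction `y_t ~ Poisson(μ_t)` in which
deaths respond to concurrent exposure — the regime in which a lag-0
regression recovers the entry effect exactly.  Tests of the two-state
limit therefore use the flag.

**Initial pool and burn-in.**  `m₀ = round(MLT × mean daily deaths)` is
the standard equilibrium substitute; the exact equilibrium under this φ
convention is `(1+MLT) × mean deaths`, so the simulator prepends
`ceil(5×MLT)` burn-in days (recycling the first year of
offset/exposure) and discards them, removing the transient.  The
burn-in default is configurable.

**Overflow guard.**  |linear predictor| > 30 aborts with the offending
day named; this catches mis-scaled exposure before Poisson draws
overflow.

## Step 0 — seasonal baseline and real-data DLM

`sedlm.baseline` fits the conventional seasonal Poisson GLM:

    log E[deaths_t] = intercept + s1(t) + DOW(t) + s2(Td_t) + s3(T_t) + s4(T_{t−1})

with natural cubic regression splines (patsy `cr`, centering constraint
so multiple smooths coexist with one intercept): 7 df per observed year
for `s1` (total df = round(7 × span in years)), 3 df for dew point, 6 for
temperature and 6 for lag-1 temperature, with interior knots at the
basis's quantile defaults and boundary knots at the data range.  The
first row is dropped for the lag-1 term.  Fitting is the package's own
Poisson IRLS (below); statsmodels' GLM is used as an independent
cross-check in the tests.

From the fit the simulator gets `α_entry = log(mean observed deaths)` and
`offset_t = η̂_t − α_entry`, so `exp(α_entry + offset_t)` is exactly the
fitted daily mean and the simulated long-run death rate matches the
observed one.  By default the offset carries the full linear predictor
(time, DOW and weather smooths); `offset_terms="time_dow"` restricts it
to the time/DOW components for sensitivity analyses.  All campaign
simulations share this one fixed offset — the seasonal-smoothness choice
is made once, in the Monte-Carlo stage, not refitted per simulation.

## The distributed-lag model

`sedlm.dlm` fits

    log E[y_t] = α + Σ_{i=0}^{L} β_i X_{t−i} + seasonal block

with the lag vector optionally restricted through an (L+1)×(J+1) matrix
C (`β = C β*`):

* `("none",)` — C = I, the unconstrained DLM;
* `("poly", p)` — Almon restriction, columns `i^j`, j = 0..p;
* `("bspline", df)` — cubic B-spline basis over the lag axis 0..L with
  `df` columns, interior knots equally spaced, boundary knots repeated at
  0 and L.  The basis is a partition of unity (spans constants), so no
  intercept-style column is removed.

The summary the posterior step consumes is `β̂*` itself (for the
unconstrained model, all L+1 lag coefficients); the conventional
total-effect estimate is `Σ β̂_i = colsums(C)·β̂*`.

Cleaned series may contain calendar gaps where outlier/missing days were
removed.  By default lags count *rows* — the cleaned series is treated
as contiguous, mirroring how the death series itself was truncated; the
`lag_respects_calendar` flag instead drops rows whose lag window spans a
gap.

**Fitting.**  Poisson log-link IRLS, deviance-change convergence
`1e-8·(|dev|+0.1)`, max 100 iterations, linear predictor clipped at
±30.  A campaign fits thousands of models whose design matrix is
*identical* (only the simulated deaths change), so `DLMDesignCache`
builds the design once, checks rank once, and warm-starts every IRLS at
a single fixed solution (fitted to the observed series) — fixed, so
results are independent of fit order and worker scheduling.

## Step 1 — the simulation campaign

The envelope S is a rectangle of (β_entry, β_exit) values split into
`n_cells_x × n_cells_y` cells.  Defaults follow the reference settings:
a square with corners (−0.02, −0.02) and (0.02, 0.02) — 0.02 per unit is
a 22% mortality increase per 10 µg/m³, comfortably above current
ambient-pollution estimates — gridded 32×32 with 80 triplets per cell
(81,920 simulations) at full scale; a rectangle with entry ∈ (−0.04,
0.04) at the same cell size is provided for edge-sensitivity work.
Within each cell, (entry, exit) are uniform and the MLT is drawn from a
prior: U(1, 28) days by default (a zero lifetime is degenerate, several
months would no longer be "displacement"), with 1 + Poisson(14) as the
sensitivity alternative.

Records are assigned to k folds balanced within each cell (80 per cell,
k = 5 → train 64 / test 16), enabling cross-validated evaluation.  Each
record's RNG stream derives from (campaign seed, record index) via
numpy's SeedSequence, so campaigns are reproducible and embarrassingly
parallel: worker count cannot change the results.  Failed refits are
flagged, never dropped; more than 1% failures aborts as evidence of
misconfiguration.

## Step 2 — response surfaces

For each restricted coefficient j, `E[β̂*_j | β_entry, β_exit]` is a
smooth surface estimated by an Epanechnikov running mean with span h
equal to the cell side:

    w(a|p) = (3/4)(1 − ‖(p−a)/h‖²)₊
    f̂(p)  = Σ_a w(a|p) β̂*(a) / Σ_b w(b|p)

Only records in the test point's cell or its ≤8 neighbours can carry
non-zero weight; for cell-center test points this equals the naive
all-records computation exactly (tested), it is purely a locality
speed-up.  The local covariance is the weighted residual covariance
`Σ w r rᵀ / Σ w` (no small-sample correction — the reference formulation
states none) plus a relative ridge `1e-10 · trace/(J+1) · I` against
near-singularity.  Test points default to the centers of the inner
(n−2)×(n−2) cells; the outermost ring is excluded because a boundary
kernel is one-sided and attenuated.

## Step 3 — approximate posterior

Assuming the fitted vectors scatter around the surface as multivariate
normal, the likelihood of a lattice point a given the observed fit β̂ is

    d²(a) = (β̂ − f̂(a))ᵀ Σ̂(a)⁻¹ (β̂ − f̂(a))
    L̃(a) ∝ exp(−d²/2) / |Σ̂(a)|^{1/2},     L̃ ≡ 0 outside S

MVN dimension constants are the same at every lattice point and cancel
under normalization, so they are omitted (the (J+1)-dimensional constant
would anyway differ from a literal 2π).  Normalization is a Riemann sum
over the lattice — equivalently, a uniform prior on S; any bounded prior
could multiply in before normalizing.  Marginals sum over the other
axis.  The reported point estimate is the **posterior mean** (the
reference work never names its point estimator; the mode is also
reported and flagged in the results object).  HPD intervals are greedy
density-ranked accumulations of lattice cells at the lattice's
resolution; a non-contiguous HPD set is reported as multiple intervals
with a warning.

## Evaluation conventions

* RMSE is displayed ×500 (effects are of order 10⁻²); internal values
  stay per-unit.
* The combined score is `sqrt(entry² + exit²)` — the Euclidean
  combination, verified to reproduce published combined cells from their
  entry/exit components to printed precision.
* Only inner-region records are scored, and only converged fits.
* `variance_explained` smooths the estimate on the true-entry axis alone
  and on the (entry, exit) plane with the same Epanechnikov kernel
  (span h) and reports both R²; the O(n²) kernel mean subsamples to
  4,000 records.

## Synthetic data

`sedlm.synthetic` generates a structurally Chicago-like series so the
whole pipeline is testable without any external data: Poisson daily
deaths around 100/day (a realistic large-city 65+ count) with a
winter-peaked log-scale seasonal amplitude of 0.15 and small day-of-week
effects; exposure with mean 35, sd 18 µg/m³, lag-1 autocorrelation 0.7,
a summer-peaked seasonal component of 8 µg/m³ and rare exponential
spikes (p = 0.004, scale 70) so that a handful of days per decade exceed
the 150 µg/m³ outlier threshold; temperature and dew point as correlated
(ρ = 0.85) annual sinusoids with dew point capped at temperature.  The
generator has **no built-in exposure–mortality effect**: β_entry and
β_exit enter only through the simulator.  What it does not emulate:
measurement error and missingness patterns of real monitors, long-term
mortality trends, heat waves/influenza epidemics, or any true
exposure–mortality association — so passing tests demonstrate correct
recovery of effects *the three-state model generated*, not
epidemiological validity on real data.

## Problem sizes used in tests and the acceptance script

The packaged replication runs the pipeline on an 8-year synthetic
series with a 16×16-cell square envelope, 20 triplets per cell
(5,120 simulations), reference DLM L=20 with a df-5 B-spline, five
folds; the edge study adds a 32×16 rectangular campaign (entry ±0.04,
same cell size) with 8 per cell.  These sizes give stable orderings
(SEDLM entry RMSE well below DLM; exit below entry; clear edge
attenuation) with per-cell sampling noise larger than a full 32×32×80
campaign would have; the full-scale settings are one constructor
argument away.

## Degenerate inputs and numerical tie-breaks

* Cleaning applies the outlier rule on the natural (uncentered) scale,
  so cleaning is idempotent; centering happens after removal, and the
  constants are stored with the series.
* An all-removed series, a constant exposure column, a rank-deficient
  design, an empty kernel neighbourhood, an all-zero likelihood and a
  singular local covariance each raise a typed error naming the culprit.
* `mlt = 0` is fully supported (φ = 1, logit(φ) = +∞ is special-cased).
* Ties in the HPD greedy accumulation follow numpy's stable argsort.

## Known limitations

* Single frail state, linear effects, concurrent exposure only in the
  simulator — richer processes (multiple frail states, frail-state
  bypass, non-linear or lagged entry/exit) are out of scope, and a
  mis-specified three-state model propagates into the posterior.
* The posterior is 2-D; the MLT is integrated over by its prior, not
  estimated (a 3-D grid scales poorly).
* Estimates for truths outside — or near the edge of — the envelope are
  attenuated; use a larger envelope.
* The MVN approximation of coefficient scatter is unchecked beyond the
  simulation evidence; heavy-tailed refit noise would distort the
  posterior tails.
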