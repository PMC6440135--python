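# Methods

## Census construction

Events (one arrival and one departure timestamp per visit, naive local time)
are binned onto a half-open 30-minute grid: an event at exactly a half-hour
boundary belongs to the later interval, so nothing is double counted. A
365-day grid therefore has exactly 48 × 365 = 17,520 intervals. Timestamps
are treated as civil time with no timezone or daylight-saving arithmetic,
which is what a fixed 48-intervals-per-day grid presumes.

The queue recursion Q(t+1) = Q(t) + A(t) − D(t) starts from Q(0) = 0. Two
start-up artefacts follow from that arbitrary choice and are handled
explicitly:

* intervals in which more patients depart than the recursion says are
  present (possible when patients who arrived before the grid depart inside
  it) are flagged invalid, excluded from fitting, and the queue is floored
  at zero afterwards;
* all intervals starting before the end of the third work shift after the
  grid start are excluded from the design table. Shift boundaries are 07:00,
  15:00 and 23:00, so a grid starting at midnight loses 46 intervals (a
  partial 14-interval night, then a full day and evening shift) and a grid
  starting at 07:00 loses exactly three full shifts.

Shifts are day [07, 15), evening [15, 23), night otherwise; each civil day
contributes 16 interval starts to each shift. The weekend window is
[Friday 23:00, Sunday 23:00), so the Friday and Saturday night shifts belong
to the weekend and the Sunday night shift does not. How Sunday night should
be classified is genuinely open; this literal two-night reading is the
package's choice and is isolated in `census.label`.

## Design table and index convention

For response interval s the covariates are the concurrent arrivals A(s), the
previous queue Q(s−1), the queue change Q(s)−Q(s−1), the departure counts of
the three preceding intervals, and shift/weekend indicators with the
shift × weekend interaction (weekday day shift is the reference cell). The
trial count is n(s) = Q(s) + A(s); rows with n = 0 are dropped, since a
binomial observation with zero trials carries no likelihood information.
Whether the arrival covariate should be concurrent or lagged is ambiguous in
the field's usage; concurrent is the default because it is the reading under
which a "one new arrival" waiting-time scenario makes sense, and
`build_design(..., arrival_lag=True)` fits the other reading. The algebraic
identity Q(s)−Q(s−1) = A(s−1) − D(s−1) ties the queue-change covariate to
the lagged flow and is asserted by tests.

## Fitting

The binomial logit model is fitted by iteratively reweighted least squares
(Newton scoring; for the canonical logit link expected and observed
information coincide). Convergence is declared when the deviance changes by
less than 1e−10 relative between iterations, capped at 100 iterations; the
IRLS start is the pooled departure probability on the intercept. The
covariance is the inverse information at the optimum; CIs and p-values are
Wald on the log-odds scale with z = 1.96 (the conventional choice where the
interval type is not otherwise fixed). Rank-deficient designs are rejected
up front, naming the collinear columns found by rank-revealing QR.
Coefficients drifting past ±30 on the logit scale trigger a
complete-separation warning rather than an error. Degenerate IRLS weights
are floored at 1e−12 purely to keep the linear solve well posed.

The shift × weekend interaction is tested by the likelihood-ratio χ²:
the deviance drop from the no-interaction fit to the full fit on identical
rows, referred to χ² with 2 degrees of freedom.

## Waiting time

With the queue in steady state, the number of half-hour steps until a given
patient departs is geometric with success probability p, so
WT = 0.5 × (1−p)/p hours; the 0.5 is the interval length and is exposed as a
parameter for other grids. For two scenarios, WT₀/WT₁ equals the odds ratio
of scenario 1 vs 0, so 1/OR is the waiting-time multiplier per unit
covariate. The incremental calculator defaults to the *linear* reading —
k arrivals add k copies of the single-step increment wt₀(1/OR − 1) — because
that is the additive per-arrival narrative the model's users quote (a
two-hour baseline gains ≈7.4 min per arrival, 142 min for three); the
compound mode wt₀(1/OR)^k is provided and agrees to first order.

## Diagnostics and validation

One-step-ahead expected departures are E(t+1) = n(t+1)·p(t+1|t), using only
covariates that encode past state, never the interval's own outcome.
"Standardised residuals" are Pearson residuals (D−E)/√(n p (1−p)) — the
standard residual for binomial regression; rows with degenerate variance are
dropped from residual tables with a count. QQ tables use plotting positions
(i−0.5)/m. Diagnostics are emitted as plot-ready tables (fitted vs residual,
theoretical vs sample quantiles), not rendered figures. Goodness of fit is
the null and residual deviance, 2×(saturated − model) log-likelihood with
p̂_sat = D/n and 0·log 0 := 0. Validation scores a new design table under
coefficients fixed from training and reports the deviance and the residual
mean/SD; validating on the training data reproduces the training residual
deviance exactly, which the tests assert.

## Synthetic ED

The simulator draws arrivals as a nonhomogeneous Poisson process constant
within each 30-minute cell, with rates by (shift, weekend). The default
profile is busiest in the day shift, quietest at night and slightly busier
on weekends (relative weights 1.60/1.25/0.55 weekday, 1.70/1.35/0.70
weekend per interval), scaled so a year carries 41,693 arrivals in
expectation — the annual volume of the Danish university-hospital ED whose
published estimates also supply the default truth coefficients
(α = −1.397 and the natural logs of the reported ORs). The relative shape
is a package convention: the model conditions on arrivals, so only the
level, not the exact curve, matters for realism. Departures are then drawn
generatively from the transition model itself, D(t) ~ Bin(Q(t)+A(t), p),
with the logit evaluated on exactly the covariates the design table defines;
simulated series therefore satisfy queue conservation and D ≤ n by
construction. `emit_events` synthesises per-patient timestamps (arrivals
uniform within their interval, departures assigned FIFO), chosen because any
pairing consistent with the counts is valid and FIFO is deterministic and
auditable; re-aggregating emitted events reproduces the census counts
exactly. One integer seed drives named generator streams per stage
(arrivals, departures, event emission), so stages are independently
reproducible.

What the simulator does *not* emulate: patient-level heterogeneity (triage
acuity, age), boarding, seasonality, staffing changes, or misrecorded
timestamps. Passing tests therefore demonstrate correctness of the
estimator and calculus under the model's own assumptions, not that the
model describes any particular real ED.

## Experiment sizes and numerical checks

Parameter recovery runs 50 replicate 365-day simulations under the
reference truth and checks ≥86% per-coefficient Wald CI coverage; the
null-size check of the interaction test uses 1,000 replicates of 14-day
simulations (about 620 design rows each, enough for the χ²₂ asymptotics);
residual calibration uses a single simulated year (≈17,500 rows, mean in
±0.05, variance in [0.8, 1.2]); the root-n spread check compares 40
replicates at 30 vs 60 days and tests the median SD ratio across
coefficients, the median being stable where any single coefficient's ratio
is noisy at that replicate count. The fitter is cross-checked against an
independent grid-refinement likelihood search (to 1e−4) and against
statsmodels GLM (to 1e−6).

## Known limitations

* The waiting-time formula is a steady-state geometric argument; it is a
  scenario summary, not a queueing-network waiting-time distribution.
* Wald inference can misbehave near separation (tiny departments, extreme
  covariates); no profile-likelihood fallback is provided.
* The weekend window and the concurrent-arrival convention are documented
  choices where the field's usage is ambiguous (switches are exposed for
  the latter).
* No overdispersion correction: heterogeneous per-patient departure
  probabilities within an interval would make the binomial variance an
  undercount.
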