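# edtransit

Transition regression modelling of emergency-department (ED) departures and
waiting time from 30-minute census data.

ED crowding arises when demand outstrips beds and staff, and a first sign is
rising waiting time. `edtransit` is for ED researchers and operations analysts
who have only *system-level* administrative data — one arrival and one
departure timestamp per visit — and want a dynamic, interpretable model of
patient flow: which factors speed up or slow down departures, what waiting
time to expect under a given scenario, and how well the model predicts a
held-out period.

## The model

Events are binned onto a 30-minute grid. With A(t) arrivals and D(t)
departures in interval t, the queue (patients present at the start of the
interval) follows

    Q(t+1) = Q(t) + A(t) − D(t),   Q(0) = 0.

Departures are modelled as a binomial *transition* regression — a regression
for the current count conditional on past counts, which absorbs the serial
correlation of departures:

    D(t) ~ Bin(n(t), p(t|t−1)),      n(t) = Q(t) + A(t),
    logit p(t|t−1) = α + Σⱼ δⱼ D(t−j) + Σᵢ βᵢ xᵢ(t),

with three departure lags δ₁..δ₃ and pre-specified predictors x: concurrent
arrivals A(t), previous queue Q(t−1), queue change Q(t)−Q(t−1), work shift
(day 07–15, evening 15–23, night 23–07), weekend (Friday 23:00 – Sunday
23:00) and the shift × weekend interaction. exp(β) is the odds ratio (OR) of
a departure per unit covariate.

Assuming the queue is in steady state, the time to departure is geometric in
30-minute steps, so the expected waiting time in hours is

    WT = 0.5 × (1 − p) / p,

and the reciprocal OR of a covariate is the multiplicative change in expected
waiting time it causes (OR 0.942 per extra arrival ⇒ waits stretch by
1/0.942 ≈ 1.06, i.e. 106%).

The package fits the model by iteratively reweighted least squares, reports
ORs with Wald 95% CIs and the relative waiting-time column, tests the
shift × weekend interaction by a likelihood-ratio χ² test, produces
one-step-ahead expected departures E(t+1) = n(t+1)·p(t+1|t) with Pearson
residual diagnostics, validates fixed coefficients on held-out data, and
ships a synthetic ED simulator (nonhomogeneous Poisson arrivals, departures
drawn generatively from the transition model) so every stage is testable
without real patient data.

## Worked example

Simulate two months of a ~40,000-visits/year ED, rebuild the census from the
raw events, fit the model and ask for a waiting time:

```sh
edtransit simulate --days 60 --seed 7 --events-out events.csv
edtransit aggregate --events events.csv --start 2013-01-01T00:00 \
    --end 2013-03-02T00:00 --census-out census.csv --design-out design.csv
edtransit fit --design design.csv --out fit.json --interaction-test
edtransit wt --coefs fit.json --arrivals 1
```

prints (abridged):

```
design table with 2828 rows (52 intervals excluded) written to design.csv
Binomial logit transition model of ED departures
rows: 2828   converged: True (4 IRLS iterations)
term                   coef      se      OR         p   WT%
arrivals            -0.0454  0.0081   0.956   2.3e-08  105%
queue_prev          -0.0087  0.0031   0.991    0.0058  101%
dqueue              -0.0187  0.0078   0.981     0.017  102%
...
shift x weekend interaction: chi2=7.63, df=2, p=0.02207
logit=-1.499  p=0.1826  WT=2.24 h (2:14)
```

Each extra arrival in a half hour multiplies the odds of any patient leaving
by 0.956 (so waits stretch by ~5%); one arrival into an otherwise empty
weekday day shift implies a departure probability of 0.18 per half hour and
an expected stay of 2.24 hours. The 52 excluded intervals are the first
three work shifts (start-up of the queue recursion) plus the lag window and
empty intervals with n = 0.

The same pipeline is available as a library:

```python
import edtransit as e

census = e.simulate_census(e.ArrivalProfile.reference(),
                           e.TruthParams.reference(), days=60, seed=7)
fit = e.DepartureModel(e.build_design(census)).fit()
print(fit.summary())
print(fit.odds_ratio_table())
print(e.wt_from_scenario(fit.params, {"arrivals": 1}))
```

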