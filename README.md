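# sedlm — simulation-enhanced distributed lag models for mortality displacement

`sedlm` estimates how an environmental exposure (a PM10-like pollutant,
µg/m³) affects daily mortality in a way that separates two very different
mechanisms:

* the **entry effect** β_entry — exposure pushes healthy people into a
  small "frail" pool of near-death individuals.  This is the
  population-level effect that matters for life expectancy.
* the **exit effect** β_exit — exposure raises a frail individual's daily
  probability of dying.  This only *displaces* deaths by days to weeks
  ("harvesting"): an excess-mortality peak followed by a compensating
  deficit.

The conventional tool, a distributed-lag Poisson model (DLM)

    y_t ~ Poisson(ν_t),
    log ν_t = α + β₀X_t + β₁X_{t−1} + ⋯ + β_L X_{t−L} + s₁(t) + s₂(covariates_t),

summarises the total impact by the sum of the lag coefficients, Σᵢ β̂ᵢ.
When the data actually come from a three-state process

    m_{t+1} = m_t + u_t − y_t,
    u_t ~ Poisson(μ_t),                log μ_t   = α_entry + β_entry X_t + s(t),
    y_t ~ Binomial(m_t, φ_t),          logit φ_t = α_exit  + β_exit  X_t,

that summary is biased in a way that depends non-trivially on L, the
effect sizes and the mean lifetime in the frail state (MLT = (1−φ)/φ).
`sedlm` corrects the bias by **simulation-based inference**: it simulates
the three-state process over a grid ("envelope") of known
(β_entry, β_exit) values using the real exposure/covariate series, refits
the identical DLM to every simulated series, smooths the fitted
coefficients into response surfaces f_j(β_entry, β_exit) with an
Epanechnikov kernel, and inverts the surfaces through a multivariate-
normal approximate likelihood into a grid posterior for
(β_entry, β_exit) — with marginals, posterior means and HPD intervals.

## Worked example

```python
from sedlm import SEDLM, SynthConfig, generate_daily_series, clean_series
from sedlm.dlm import DLMSpec
from sedlm.campaign import Envelope

series = clean_series(generate_daily_series(SynthConfig(n_years=8, seed=11)))
model = SEDLM(series,
              dlm_spec=DLMSpec(20, ("bspline", 5)),
              envelope=Envelope(n_cells_x=16, n_cells_y=16),
              per_cell=20)
res = model.fit(seed=3)
print(res.summary())
```

```
Simulation-enhanced distributed lag model
=========================================================
series length: 2919 days   reference DLM: L=20 bs5
envelope: entry [-0.02, +0.02], exit [-0.02, +0.02] (16x16 cells)
simulations: 5120   seed: 3
---------------------------------------------------------
effect        post. mean  post. mode              95% HPD
entry           -0.00024    -0.00125 [-0.00250, +0.00250]
exit            -0.00037    -0.00125 [-0.00250, +0.00250]
---------------------------------------------------------
DLM sum of lags (conventional estimate): -0.00017 (SE 0.00031)
entry RR per 10 ug/m3 (posterior mean): 0.9976
```

The synthetic series has no built-in exposure effect, and both HPD
intervals indeed cover zero: no evidence of either a net effect on the
general population or a displacement effect.  On campaigns where the
truth is known, the cross-validated RMSE of the posterior-mean entry
estimate is well under half the sum-of-lags RMSE, and the exit effect
is recovered more accurately still (run `sedlm evaluate`, or see the
acceptance results below).

The same pipeline is available from the shell:

```bash
sedlm synth --years 8 --seed 11 --out series.csv
sedlm run-all --preset demo --series series.csv --seed 3 --out run/
```

## Layout

| module | role |
|---|---|
| `sedlm.data_io` | read/validate/clean daily series (outlier rule >150 µg/m³, joint removal, centering) |
| `sedlm.synthetic` | Chicago-like synthetic daily series generator |
| `sedlm.baseline` | seasonal Poisson GLM (natural cubic splines, 7 df/year + DOW + weather smooths) |
| `sedlm.simulator` | three-state healthy→frail→dead process |
| `sedlm.dlm` | distributed-lag Poisson regression (unconstrained, polynomial, B-spline) |
| `sedlm.campaign` | gridded simulate-and-refit campaign with folds |
| `sedlm.surface` | Epanechnikov response-surface smoother + local covariances |
| `sedlm.posterior` | Mahalanobis/MVN approximate likelihood, grid posterior, HPD |
| `sedlm.evaluation` | RMSE tables, variance decomposition, binned quantile bands |
| `sedlm.model` | `SEDLM` / `SEDLMResults` facade |
| `sedlm.cli` | `sedlm` command-line tool |

See `docs/methods.md` for the model details, parameter conventions and
known limitations.
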