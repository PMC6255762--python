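# feverseek

Distance decay in public-sector fever treatment-seeking for children under
five, modelled end-to-end: georeferenced household-survey data (synthetic or
ingested), least-cost travel time to the nearest public health facility, a
Bayesian three-parameter logistic (3PL) item-response model of the latent
ability to seek treatment, and back-calculated probability-of-treatment
curves with credible intervals.

The package is aimed at epidemiologists and health-geography researchers who
want to quantify how the probability that a febrile child is taken to a
public facility declines with travel time, and to test every stage of such
an analysis against known ground truth without restricted survey microdata.

## The model

A carer's reported action for a child's two-week fever episode is a binary
response `Y_ij` (sought treatment at a public facility or not). The response
probability follows a unidimensional 3PL item-response model,

```
P(Y_ij = 1 | θ_j, a_i, b_i, c_i) = c_i + (1 − c_i) · exp(a_i θ_j − b_i) / (1 + exp(a_i θ_j − b_i))
θ_j = α + β_time · t_j + β_urban · urban_j
```

where `θ_j` is the latent ability of person `j` to seek treatment, driven by
travel time `t_j` (minutes, from a least-cost surface over land class, roads
and elevation) and urban/rural residence; `a_i > 0` is the item
discrimination, `b_i` the difficulty, and `c_i ∈ (0, 1]` the **threshold
(minimum) probability** — the floor the curve decays to at large travel
time. The posterior `f(θ, a, b, c | y) ∝ L(y | θ, a, b, c) f(a) f(b) f(c)`
(truncated-normal prior on `a`, beta on `c`, normal on `b`, `α`, `β`) is
sampled with a Metropolis-within-Gibbs scheme with burn-in adaptation,
monitored by Gelman–Rubin and Raftery–Lewis diagnostics.

## Worked example

Simulate 5,000 fever cases from known truth (α = 0.5, β_time = −0.01/min,
c = 0.2) and refit them:

```python
import numpy as np, pandas as pd
from feverseek import FeverTreatmentModel, McmcConfig, TrueParameters

truth = TrueParameters(alpha=0.5, beta_time=-0.01, c=0.2, beta_urban=0.0,
                       fever_prevalence=1.0, missing_rate=0.0)
rng = np.random.default_rng(1)
t = rng.uniform(0, 240, 5000)
y = (rng.random(5000) < truth.response_probability(t, 0)).astype(float)
data = pd.DataFrame({"y": y, "travel_time_min": t, "urban": 0})

model = FeverTreatmentModel(data, fix={"beta_urban": 0.0})
results = model.fit(McmcConfig(n_iterations=8000, burn_in=1500, thinning=5,
                               n_chains=2, seed=1))
print(results.summary().round(4))
print(results.summarize_at_thresholds([10, 30, 60, 120]).to_string(index=False))
```

prints

```
             mean      sd  median    2.5%   97.5%    psrf
parameter
alpha      0.5950  0.0909  0.5941  0.4250  0.7714  1.0042
beta_time -0.0137  0.0022 -0.0139 -0.0178 -0.0094  0.9997
c          0.2363  0.0498  0.2490  0.1115  0.3026  1.0011

 t_min   median     lo95     hi95        formatted
  10.0 0.704449 0.673039 0.735922 0.70 (0.67–0.74)
  30.0 0.653925 0.629860 0.678519 0.65 (0.63–0.68)
  60.0 0.576956 0.557793 0.595869 0.58 (0.56–0.60)
 120.0 0.439036 0.418194 0.461388 0.44 (0.42–0.46)
```

All three 95% credible intervals cover the generative truth, chains mix
(PSRF ≈ 1), and the back-calculated curve shows the distance decay: the
median probability of seeking treatment falls from 0.70 at 10 minutes to
0.44 at 2 hours, approaching the threshold floor `c` from above.

The full pipeline — synthetic landscape, PPS cluster sampling with
DHS-style coordinate displacement, travel-time surface, fit, curves,
holdout validation (misclassification error + ROC) and admin-level treated
rates per 1,000 under-5 children — runs from one command:

```
feverseek run-all --seed 3 --out run/
```

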