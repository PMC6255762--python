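# Methods

This note documents the models, numerical choices and limitations of
`feverseek`, stage by stage.

## The response model

Treatment-seeking for a child's fever episode is a single dichotomous survey
item analysed under a unidimensional three-parameter logistic (3PL)
item-response model:

    P(Y = 1 | θ, a, b, c) = c + (1 − c) · logistic(aθ − b),
    θ_j = α + β_time t_j + β_urban u_j,

with travel time `t_j` in minutes and `u_j` the urban-residence indicator.
The threshold `c` is the scientifically interesting lower asymptote: the
minimum probability of seeking public-sector treatment, reached by
households far from any facility. `θ_j` is deterministic given the
covariates — the model deliberately carries no child-level residual, since
one binary response per child cannot identify one; an optional noise term is
out of scope.

**Identifiability.** With a single item, `(a, b)` are confounded with the
scale and location of `θ` and have only a marginal influence on the overall
probability; the default configuration therefore fixes `a = 1, b = 0` and
estimates `(α, β_time, β_urban, c)`. With responses attributed to multiple
facility-tier items (hospital / health centre / dispensary), per-item
`(a_i, b_i, c_i)` are estimated with the first item anchored at
`(a = 1, b = 0)`.

**Missing responses** (carer answered "don't know" for a fever case) are
dropped from the likelihood. Under missing-at-random this yields the same
parameter posterior as explicitly imputing the unobserved Bernoulli
outcomes within the sampler; the predictive machinery can impute them from
the fitted model where reports need them.

## Priors

Defaults, all configurable through `PriorSpec`:

| parameter | prior | default | rationale |
|---|---|---|---|
| `a` | N(μ_a, σ_a²) truncated to a > 0 | μ_a = 0, σ_a = 2.5 | weakly informative half-normal scale |
| `c` | Beta(2, 5) on (0, 1) | — | weak preference for small floors |
| `b`, `α` | Normal | N(0, 5²) | diffuse location |
| `β_urban` | Normal | N(0, 1²) | unit-scale covariate |
| `β_time` | Normal | N(0, (1/60)²) per minute | equals N(0, 1) on the per-hour coefficient, keeping coefficient scales comparable |

## Sampler

Metropolis-within-Gibbs with Gaussian random-walk proposals on
unconstrained scales (`log a`, `logit c`; Jacobian terms included). Blocks:
all free ability coefficients jointly, then each item's free `(a, b, c)`.
Proposal scales adapt only during burn-in (every 50 proposals the log-scale
moves by `1.2 · (acceptance − 0.3)`), targeting 20–50% acceptance; after
burn-in the scales freeze so the chain is a valid time-homogeneous
Metropolis sampler. Chains start from independent prior-scale draws
(over-dispersed relative to the posterior). Draws are retained after each
complete thinning window, giving exactly
`floor((n_iterations − burn_in)/thinning)` draws per chain — the long
reference schedule (550,000 iterations, 50,000 burn-in, thinning 500)
retains exactly 1,000.

The desk-scale default is 22,000 iterations, 2,000 burn-in, thinning 10,
three chains. Tests and the acceptance script use shorter schedules
(6,000–14,000 iterations, 2 chains) chosen as the smallest runs at which
the Gelman–Rubin PSRF of every parameter is comfortably below 1.1 on the
synthetic data sizes used; these are the package's own default study sizes,
not a statement about the model.

**Correctness checks.** On a reduced model with only `α` free, the sampler's
posterior mean and sd are tested against deterministic trapezoid quadrature
of the exact 1-D posterior, with tolerance set by the Monte-Carlo standard
error from the effective sample size. Full parameter recovery is tested on
20 replicate surveys of 5,000 fever cases (α = 0.5, β_time = −0.01/min,
c = 0.2): 95% credible intervals must cover each truth in ≥ 18/20
replicates and the median β_time bias must stay below 25% of its magnitude.

## Diagnostics

* **Gelman–Rubin PSRF**: the classic non-split ratio
  `sqrt(((n−1)/n · W + B/n)/W)`; two identical chains give exactly
  `sqrt((n−1)/n)`, a degenerate all-constant ensemble returns 1.
* **Raftery–Lewis**: binarise the chain at its q-quantile, find the smallest
  thinning at which a first-order Markov chain is preferred over a
  second-order one by BIC on the triple counts, estimate the transition
  probabilities (with a half-count guard against empty cells), and report
  the burn-in `M`, required length `N`, the closed-form independent-chain
  minimum `N_min = ceil(z²_{(1+s)/2} q(1−q)/r²)` (3,746 at the conventional
  q = 0.025, r = 0.005, s = 0.95) and the dependence factor `(M + N)/N_min`.

## Travel time

The friction surface assigns each cell a scalar speed (km/h): road cells
take the motorised `road_speed` (default 50 km/h) independent of slope;
walking land classes take their land-class speed scaled by Tobler's hiking
factor `exp(−3.5 |s + 0.05|)/exp(−0.175)` normalised to 1 on flat ground,
with `s` the steepest local slope magnitude (rise/run over the 8
neighbours); classes with non-positive speed (water) are impassable.
Default walking speeds: built-up 5, agriculture 4, savanna 4, forest
2 km/h — a conventional desk-scale table, fully configurable.

Travel time is exact multi-source Dijkstra over the 8-connected cell graph
(scipy's sparse-graph engine with `min_only` multi-source mode). Edge cost
in minutes is centre-to-centre distance (diagonals √2 longer) divided by
the **harmonic mean** of the two cell speeds — the time-additive choice for
crossing a shared boundary. The isotropic scalar slope correction keeps
edge weights symmetric, so a single shortest-path pass is exact; this is an
approximation to fully anisotropic (direction-dependent) slope costing,
which would require an asymmetric graph. Facilities snap to their
containing cell centre; co-located facilities collapse to one source.
Correctness is tested against two independent oracles (exhaustive
simple-path enumeration on 3×3; Bellman–Ford-style fixpoint relaxation up
to 5×5) plus the scaling and source-monotonicity invariants.

## Synthetic study generator

The generator emulates the study design of national household surveys
(DHS/MIS/MICS-style) on a synthetic 100 × 100 km landscape at 1-km
resolution:

* **Landscape**: spatially coherent land-class patches from a thresholded
  smooth Gaussian field; smooth elevation scaled to the configured relief
  (default 800 m); straight-segment road network to a target coverage
  (default 5% of cells); log-Gaussian under-5 population surface boosted on
  built-up cells and zeroed on water (default 200,000 children);
  facilities placed probability-proportional-to-population (defaults: 2
  hospitals, 8 health centres, 25 dispensaries); a regular K-block admin
  partition (default 4 units).
* **Clusters**: probability-proportional-to-size selection of cells without
  replacement (distinct locations guaranteed), urban iff cell population ≥
  the urban threshold, 15–30 households per cluster, uniform.
* **Displacement**: published coordinates jittered uniformly in angle and
  distance — urban ≤ 2 km, rural ≤ 5 km with 1% of rural up to 10 km (the
  standard survey-confidentiality convention; magnitudes configurable).
  Displacements leaving the study region or landing on impassable cells are
  redrawn. True coordinates are retained internally for oracle tests only.
* **Responses**: one under-5 child per household (configurable); fever is
  Bernoulli(prevalence, default 0.25); fever cases draw their response from
  the 3PL probability at the cluster's travel time and residence; a
  missing-at-random share (default 2%) of fever-case responses is blanked;
  non-fever children carry no response.

What the generator does **not** emulate: real sampling frames and admin
boundaries, survey design weights and non-sampling error, multiple
treatment sources per episode, private-sector competition, seasonality.
Passing recovery tests therefore demonstrates the estimator is correct
under its own assumptions, not that those assumptions hold in any real
survey.

## Back-calculated surfaces

Curves, threshold tables and probability maps are **draw-wise**: the 3PL
probability is evaluated at every retained draw and summarised per grid
point / cell by the median and central 95% interval
(linear-interpolation quantiles). This yields valid credible bands, unlike
plugging in parameter medians; a plug-in mode exists behind a flag for
comparison. Because every draw's curve is bounded below by its own `c`, the
median curve is bounded below by the posterior median of `c` — the floor
interpretation of the threshold parameter.

## Validation and aggregation

A 10% holdout (uniform without replacement among children with observed
responses, stratified by survey where present) is excluded from fitting.
Holdout predictions are posterior-median probabilities, binarised at 0.5
(configurable; the cutoff is a reporting convention, not part of the
model). Scoring: misclassification error and a full ROC sweep whose
trapezoid AUC equals the Mann–Whitney pair-count statistic (tested on
random instances and against scikit-learn).

Admin-level descriptive rates are the observed treated fraction among
sampled fever cases per unit, expressed per 1,000 under-5 children, with
optional per-child design weights (default 1 for synthetic data). National
summaries weight units by their under-5 population (the population at
risk); the exact weighting is a package convention, stated here because
"population-weighted" admits several readings.

## Pipeline and reproducibility

All randomness flows from one master seed through a fixed-order
`SeedSequence.spawn` fan-out (landscape, clusters, displacement, responses,
holdout, MCMC), so toggling one stage never perturbs another's stream and
derived seeds stay below 2³¹. Re-running with the same config and seed
reproduces every artefact; ingest mode pointed at a simulate-mode run
directory reproduces the downstream results exactly. Rasters are stored in
a small documented ASCII grid format (header + rows, NaN nodata,
north-west origin, cell-centre coordinates).

## Known limitations

* Isotropic slope correction (see above) and raster-only routing — no
  vector road network, no travel-mode choice.
* Single-country runs; multi-country looping is left to the shell.
* The single-item configuration cannot separate discrimination/difficulty
  from the ability scale; conclusions about `a` and `b` require multi-item
  data.
* Metropolis-within-Gibbs mixes slowly when `β_time` and `c` are strongly
  correlated (weak decay signal); the Gelman–Rubin / Raftery–Lewis report
  should be consulted before trusting any fit.
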