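# Methods

## The joint model

`mrdsim` simulates longitudinal minimal-residual-disease (MRD)
measurements together with survival outcomes that depend on the MRD
process — the data structure collected in modern ctDNA- and
flow-cytometry-monitored trials.

### Trajectory process

Each subject's true MRD level follows a three-phase piecewise curve

```
            ⎧ β0 · exp(−ln(β0/β1)/te · t)   0 ≤ t < te      (decay)
    μ(t) =  ⎨ β1                            te ≤ t ≤ tr     (plateau)
            ⎩ β1 · exp(β2 (t − tr))         t > tr          (relapse)
```

with baseline level `β0`, plateau level `β1` reached exactly at the
end-of-treatment time `te`, and relapse regrowth at rate `β2` from onset
`tr` (`tr = ∞` for subjects who never relapse). The decay rate
`k = ln(β0/β1)/te` is fully determined by the endpoints, so each
subject's rate is individualized through their `(β0, β1, te)` draw. The
curve is continuous, strictly positive, and has closed-form derivative
and running integral, which the implementation uses throughout (no
numerical differentiation or quadrature on the trajectory itself).

Observed values add Gaussian measurement error `ε ~ N(0, σ²)` to the
true curve. Additive draws on a positive biomarker can go negative; the
reported value is floored at zero and the raw draw kept in a
`raw_value` field, so the error model is preserved while the observable
stays physically meaningful. A multiplicative (log-scale) noise mode,
`μ(t)·exp(ε)`, is available as a config switch for assays whose error is
proportional.

Degenerate case `β0 = β1`: the decay-rate expression has the limit 0 and
the decay phase degrades gracefully to a constant — continuity in the
parameters, so population sampling never hits a singularity.

At the kinks `te` and `tr` the derivative is taken one-sided from the
right, so the hazard at a phase boundary reflects the phase about to
begin. This is a documented convention; any fixed choice works, but it
must be fixed for reproducibility.

### Hazard process

Event times follow a Cox model whose log relative hazard combines
baseline covariates and three features of the trajectory:

```
    h(t) = h0(t) · exp( γᵀx + α1·g(μ(t)) + α2·g'(t) + α3·G(t) )
```

`g` is the identity (`link_scale: raw`) or `log10 μ` (`link_scale:
log10`), with the slope `g'` and cumulative burden `G` transformed
consistently as the derivative and running integral of `g(μ)`. The
log10 link is provided because raw MRD fractions span many orders of
magnitude, which makes raw-scale `α`'s awkward to choose; on the log10
scale every trajectory feature is piecewise linear and the burden
integral is piecewise quadratic, all closed-form. The two links are
never mixed within one dataset.

The baseline hazard `h0` is exponential by default (constant rate —
every null has a closed form, which anchors the test suite), with
Weibull and piecewise-constant alternatives.

### Event-time sampling

The production sampler inverts the cumulative hazard: `H(T) = −ln U`
with `U ~ Uniform(0,1)`, solved by Brent root finding on `[0, t_max]`.
`H` is computed by adaptive quadrature with the trajectory phase
boundaries and baseline cut points supplied as breakpoints (relative
tolerance 1e-8; root residual below 1e-8 in `H` units — both far below
Monte-Carlo noise at any realistic cohort size). When all three
association parameters are zero the hazard's time dependence reduces to
the baseline, `H(t) = exp(γᵀx)·H0(t)`, and the sampler uses the
closed-form inverse of `H0` directly — identical to the root-finding
result within its tolerance, at a fraction of the cost.

If the exponent overflows inside follow-up (raw-scale relapse growth
with a large `t_max`), the event is certain to occur before the
overflow point, and the root finder treats unevaluable points as lying
far past the root; a spec whose exponent overflows at `t = 0` is a
configuration error and raises with the offending exponent.

An independent Lewis–Shedler thinning sampler (propose from a
homogeneous Poisson process at a majorizing rate, accept with
probability `h(t)/h_sup`) serves as the cross-validation oracle. The
majorizer exploits that every trajectory feature is monotone within a
phase; on the log10 link the burden integrand can change sign inside a
phase and its zero-crossings are added to the candidate set. Weibull
baselines with shape < 1 are unbounded at 0 and are rejected by the
thinning sampler (the inversion sampler handles them fine).

Censoring — which the joint model itself does not define — is
administrative at `t_max` plus optional independent exponential dropout;
status is 1 for events, 0 for censoring, with the reason recorded.
Observations past a subject's follow-up end are not generated.

## Population and cohort model

Subgroups (e.g. the response categories CR/PR/SD/PD) each carry their
own cohort size, lognormal distributions for `β0` and `β1`, a fixed
`te`, a relapse probability, and a normal relapse-time distribution
truncated below at `te` by rejection (1000 attempts, then an error —
which signals a relapse mean far below the end of treatment). Relapse
occurrence is Bernoulli per subject; `β2` and `σ` are subgroup
constants.

Assessment schedules are an explicit visit list or a regular grid, with
optional Gaussian visit-time jitter (redrawn until order is preserved;
the baseline visit is pinned at its nominal time) and per-visit
Bernoulli missingness. Missing visits are retained as records with
`missing: true` so missingness patterns remain analyzable.

Baseline covariates are binary, categorical or continuous; the hazard's
`γ` has one entry per declared baseline covariate, with binary encoded
0/1, continuous as-is, and categorical as the integer level index.
Time-variant covariates are piecewise-constant tracks re-drawn at
configured change times; they appear in the output for visualization
but do not enter the hazard, which uses baseline covariates only.

The limit of detection flags measurements with `value < lod` (strict
inequality — boundary equality counts as detectable) as MRD-negative;
values are not altered unless `censor_at_lod` replaces them with the
LoD for left-censored reporting.

### Reproducibility

One master seed per dataset. Per-subject generators are spawned from
`numpy.random.SeedSequence(seed)` in subject order, and within a subject
the draw order is fixed: trajectory parameters, relapse occurrence,
relapse time, covariates (declared order), event uniform, dropout,
visit jitter, missingness, then measurement noise per visit. The same
(config, seed) therefore reproduces a dataset bit for bit, any subject
can be regenerated in isolation, and the fully-resolved config echoed
into dataset metadata suffices to replay the whole simulation
(`mrdsim.io.replay_dataset`).

## Analytics

Kaplan–Meier estimation and the log-rank test are computed by
`lifelines` behind thin wrappers that expose the product-limit curve
(distinct event times, survival, risk sets, event counts; ties resolved
events-before-censorings) and the k-sample chi-square statistic. The
MRD-negativity rate at a landmark uses each subject's nearest
non-missing visit within half the median inter-visit gap; subjects with
no qualifying visit are tallied separately rather than silently
dropped.

The power driver simulates paired two-arm trials from two configs with
per-replicate seeds derived from one master seed, applies the log-rank
test (or any supplied per-replicate analysis returning `(statistic,
p)`) and reports the rejection fraction with its binomial Monte-Carlo
standard error and mean event counts per arm.

## What the generator does and does not emulate

The generator reproduces the features that drive joint-model behaviour:
subject-level heterogeneity in baseline and plateau levels, subgroup
structure, relapse kinetics, irregular and missing sampling,
measurement noise, LoD censoring of the negativity call, and a hazard
genuinely coupled to the biomarker path. It does not emulate assay
batch effects, informative missingness linked to disease state,
treatment switching, competing risks, or clonal-evolution dynamics —
so passing tests demonstrate correctness of the simulator and of
analyses under its assumptions, not robustness of any method to those
real-data complications.

## Test and validation design

Closed-form claims are checked against independent numerics (adaptive
quadrature for integrals, central differences for slopes). Samplers are
validated two ways: exactly, against analytic nulls (an all-zero
association with exponential baseline must give Exponential event
times), and distributionally, inversion versus thinning on non-null
specs via two-sample Kolmogorov–Smirnov. The log-rank wrapper is
calibrated by direct type-I-error simulation. Parameter recovery —
simulate with a known `α1` on the log10 link, expand to
counting-process form on the assessment grid with the true `g(μ(t))`,
and refit with a time-varying Cox model — closes the loop from
generator to estimand: across replicates the 95% CI covers the truth at
its nominal rate. Problem sizes in the test suite (cohorts of a few
hundred to a few thousand, tens of replicates) were chosen so each
check's Monte-Carlo error is well below the tolerance it asserts.

## Parameter reference

| Parameter | Meaning | Units | Default |
|---|---|---|---|
| `beta0`, `beta1` | baseline / plateau MRD level | user-declared (fraction, copies/mL, ...) | per subgroup, lognormal |
| `beta2` | relapse growth rate | 1/time | 0 (no growth) |
| `te` | end-of-treatment time | time | per subgroup |
| `tr` | relapse onset | time | `∞` (no relapse) |
| `sigma` | measurement-error SD | same as `mu` (additive) or log units (multiplicative) | 0 |
| `rate` / `shape`,`scale` / `cuts`,`rates` | baseline hazard | events/time | exponential, 0.1 |
| `gamma` | baseline-covariate log-hazard ratios | per covariate unit | `()` |
| `alpha1..3` | association with level / slope / burden | per `g`-unit | 0 |
| `link_scale` | `raw` or `log10` transform of `mu` in the hazard | — | `raw` |
| `t_max` | administrative censoring | time | 100 |
| `dropout_rate` | exponential dropout | events/time | 0 |
| `lod` | limit of detection | same as `mu` | none |

All times are in one dataset-wide unit (declared in metadata); `t = 0`
is treatment start.
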