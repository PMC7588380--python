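# Methods

## Attribution model

The package implements comparative risk assessment for ambient PM2.5:
the proportional reduction in mortality that would occur if exposure
were lowered to a counterfactual level, holding everything else fixed.
Its three inputs are (1) a gridded annual-mean PM2.5 surface with
population per cell, keyed by country; (2) baseline deaths by country,
cause, sex and age group for the five modelled causes — ischaemic
heart disease (IHD), stroke, COPD, lung cancer (ages > 25 years each)
and acute lower respiratory infection (LRI, all ages); (3) parameter
draws for an exposure–response curve family.

Because mortality is national, stratum deaths are apportioned to grid
cells proportionally to cell population (no sub-national mortality
variation is modelled). Each cell then contributes its population
attributable fraction PAF = (RR − 1)/RR at the cell's concentration.
Attributable deaths are therefore strictly below baseline deaths, are
linear in baseline deaths, and are invariant under a uniform rescaling
of all populations (only population *shares* enter).

## Risk curves

**IER.** RR(z) = 1 + α·(1 − exp(−γ·(z − z_cf)^δ)) for z > z_cf, else
exactly 1. α ≥ 0 is the asymptotic excess risk (ceiling 1 + α), γ ≥ 0
a rate, δ > 0 a power. Risk below the counterfactual is clamped to 1 —
no extrapolated benefit — matching standard practice. IHD and stroke
accept per-age-band parameter sets; a single band is accepted for any
cause (a stratum falls back to its cause's unique band when no exact
band match exists).

**GEMM.** HR(z) = exp(θ·log(1 + Δ/α_k)·ω(Δ)), Δ = max(z − z_cf, 0),
with logistic weight ω(Δ) = 1/(1 + exp(−(Δ − μ)/ν)). Parameters are
user-supplied; the published model's counterfactual is fixed at
2.4 μg/m³ (the lowest concentration observed in its fitting cohorts),
so z_cf is *not* sampled for GEMM. Parameter uncertainty enters
through θ ~ N(θ̂, se_θ) per draw, truncated at 0 so the hazard ratio
stays ≥ 1. ν = 0 (a degenerate weight) is rejected.

**Counterfactual (TMREL).** For IER runs z_cf is drawn uniformly from
[2.4, 5.9] μg/m³ by default, one draw shared by all causes within a
Monte-Carlo iteration. Setting low = high yields a fixed-counterfactual
run; both modes exist because point estimates can legitimately be
computed either way.

## Scenarios

A scenario is a cap applied cell-wise: z → min(z, cap), populations
untouched. The built-in ladder is current (no cap), IT1 = 35, IT2 = 25,
IT3 = 15, AQG = 10 μg/m³. Capping is idempotent and monotone in the
cap, which forces percent reductions to be non-decreasing along the
ladder for every stratum, per draw. Caps act on grid cells, not on
country means; note that when reading results against summary-level
(population-weighted-mean) descriptions of scenarios, the cell-level
rule is the stricter interpretation and both coincide only for
uniform-exposure countries. Zero-population cells are retained so
files round-trip unchanged.

## Monte-Carlo procedure

Per draw d: sample z_cf, take curve-parameter draw d mod n_curves per
cause/age stratum (draw_id order), evaluate attributable deaths for
every stratum. The point estimate is the mean over draws (median
available); the 95% UI is the 2.5th/97.5th percentile. Draws are
matched across scenarios by re-running the engine with the same seed
on capped grids, so within a draw the current and capped runs share
every sampled input; percent reduction is summarised per draw,
100·(D_cur,d − D_scen,d)/D_cur,d, which differs in general from the
ratio of summarised points. If any current draw is exactly zero the
reduction is reported as undefined (NaN), never as 0. Default
n_draws = 1000 — a config value chosen so the Monte-Carlo standard
error of the point is well under the interval width at the bundled
problem sizes.

Aggregation sums per-draw vectors (never summarised intervals)
hierarchically in sorted key order — strata → country → WHO region →
world — so world = Σ regions = Σ countries holds bitwise per draw.

All randomness flows through `numpy.random.default_rng`; a run is a
pure function of (inputs, seed, n_draws).

## Synthetic worlds

`synthetic.generate_world` emulates the three inputs so the pipeline
runs and is tested without external data. Cell exposures are
log-normal around a per-country median (the simplest positive,
right-skewed model consistent with published exposure surfaces;
dispersion 0 pins every cell to the median exactly). Cell populations
are a symmetric-Dirichlet split of national population. Deaths are
deterministic rate × population products split 55/45 male/female and
across age bands (30/70 for the two-band cardiovascular causes),
rounded half-even, so closed-form oracle tests are exact; a Poisson
mode adds count noise for robustness checks. Curve draws jitter
per-cause central parameters multiplicatively (log-normal, log-sd 0.1)
and carry a TMREL sample each. Central parameters are plausible
IER-shaped values (e.g. α = 0.9, γ = 0.05, δ = 0.8 for IHD; α = 1.2
for LRI), steeper at low concentrations for cardiovascular causes and
LRI — chosen once as order-of-magnitude-realistic, not fitted.

The bundled `high-low` preset has five high-exposure countries
(medians 44–61 μg/m³, dispersion 0.25; regions AFR/EMR/SEAR/WPR ×2)
where all four caps bind, and six low-exposure countries (7–16 μg/m³)
including a zero-dispersion country at 7 μg/m³ where no cap binds —
giving both the large-reduction regime and the exact-null regime.
Populations are round realistic values (0.06–1.4 billion); death rates
per 100,000 are IHD 120, stroke 85, COPD 45, lung cancer 25, LRI 40.
200 cells per country keep the default runs fast while leaving
population-weighted summaries within a few percent of their targets.

What the generator does **not** emulate: spatial autocorrelation,
exposure-model calibration error, sub-national mortality gradients,
cause-specific age pyramids beyond the fixed band shares, or
correlation between exposure and baseline rates. Passing tests
therefore certify the attribution arithmetic, the scenario logic and
the uncertainty bookkeeping — not the realism of any particular
exposure surface.

## Numerical choices

* `1 − exp(−x)` is computed as `-expm1(−x)` for accuracy at small
  excess risks; the IER is continuous at z_cf by construction
  (Δ^δ → 0).
* PAF rejects RR < 1 outright — curves cannot produce it, so a
  sub-unity input signals an upstream bug rather than something to
  clamp silently.
* Percentiles use numpy's default (linear-interpolation) definition.
* The engine evaluates risk on a (cells × draws) broadcast grid per
  country and curve set, cached per scenario; the bundled preset
  (11 countries × 200 cells × 7 curve sets × 1000 draws × 5 scenarios)
  runs in about two seconds on one core.
* CSV round-trips parse floats with `float_precision="round_trip"`, so
  write → read → re-render is byte-identical.

## Interfaces

Canonical CSV schemas (UTF-8, header row required):
`exposure.csv` (country_code, cell_id, pm25, population [, lon, lat]),
`mortality.csv` (country_code, cause, sex, age_group, deaths),
`population.csv` (country_code, population), `regions.csv`
(country_code, who_region ∈ AFR/AMR/EMR/EUR/SEAR/WPR),
`ier_curves.csv` (cause, age_group, draw_id, alpha, gamma, delta,
z_cf) or a GEMM file (cause_group, draw_id, theta, se_theta,
knot_alpha, mu, nu, z_cf). Age-band labels are "all", "a-b" or "a+";
adult-cause bands must start at ≥ 25 years. A thin shim reads
WHO-style per-country XLSX summaries (country, population-weighted
mean) for comparison only — the engine needs cell-level grids.
Validation happens at load with file and line context; countries
straddling data sets (deaths without a grid, grid without a region)
are rejected before any computation.

## Limitations

Beyond the generator caveats above: no DALY/YLL or life-table
analysis (an instantaneous exposure drop is assumed, not a phased
reduction); no NO2/O3 or household-air-pollution burden; no
double-counting correction between ambient and household PM2.5; no
diabetes endpoint; exposure modelling itself (data fusion,
downscaling) is out of scope — grids are consumed as given, with
cells pre-assigned to countries.
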