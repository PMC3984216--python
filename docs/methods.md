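# Methods

This note records the modelling assumptions, numerical choices and
calibration decisions behind `velodyn`, and what the shipped tests do
and do not establish.

## Dynamic structure

The model is a deterministic stock-flow system. Stocks are the smoothed
(delayed) mode perceptions and the lagged cyclist count behind the
physical-activity lead time; everything else is computed algebraically
from the stocks each step. Integration is fixed-step Euler with
dt = 0.25 yr, the convention of system-dynamics engines; the solver and
step of the original modelling environment are not published, so
fidelity is established instead by a refinement property: halving dt
changes every 2051 output by well under 1% (the shipped check observes
≈0.1%).

Feedback loops represented:

* **Injury balance (dominant).** Bicycle share → cyclist numbers →
  collisions → fatal/serious injuries → perceived safety → bicycle
  attractiveness → share. This loop holds the baseline share in a
  damped band around 1–2% and pulls it slowly downward as traffic
  grows.
* **Safety in numbers (reinforcing, thresholded).** Above a 2.5% mode
  share, per-cyclist collision risk falls as `(share/0.025)^(−0.3)` —
  half the exponent of the classic ecological power law, reflecting
  the evidence that much of the ecological effect is
  "numbers-in-safety". A configuration switch (`pure_jacobsen`)
  substitutes the no-threshold `(share/ref)^(−0.6)` law for structure
  testing; another (`half_risk_reduction_variant`) reads "half the
  effect" as halving the risk reduction instead of the exponent.
* **Mode shift reduces collisions.** Averted light-vehicle kilometres
  lower the vehicle volumes entering the collision model.

## Mode-share model

Shares are proportional to baseline-share-weighted attractiveness
indices (a logit-equivalent with alternative-specific constants), with
hard distance caps (bicycle ≤ 0.50, walk ≤ 0.27 of commuters) and
renormalization of the excess over uncapped modes. Two structural
choices deserve note:

* **Perception → utility elasticity.** Survey perception indices do not
  enter utilities linearly; the mapping between a stated perception
  change and a revealed share change is a calibrated, nonlinear
  relationship. It is carried here as a mode-specific power transform
  (default exponents: bicycle 4, light vehicle 2, walking and public
  transport 1). With unit elasticities a 30% drop in car convenience
  could only move the car share by ~3 points from a 0.85 base, which is
  inconsistent with the share separations the policy analyses require;
  the defaults were calibrated once against the documented scenario
  behaviours (see *Calibration*).
* **Composition.** Perception boosts from distinct infrastructure
  components multiply; additive points would exceed 1 under combined
  policies. The combined scenario's effects are exactly the composition
  of its parts at every rollout fraction.

The 1-year preference delay is a first-order exponential smoothing —
the simplest delay consistent with "1 year on average".

## Injury model

Five steps per road class (local/arterial): baseline allocation of
cyclists and vehicles (50/50), baseline collision rates calibrated to
1991 counts, collision scaling, severity split, and a rate per 1,000
cyclists.

* **Vehicle-volume nonlinearity.** Collisions scale with
  `(volume/baseline)^e` with e = 0.5 on local roads and 1.0 on
  arterials (crash-prediction models put vehicle-flow exponents in
  the 0.5–1 range; arterial exposure is taken at the upper end).
  Vehicle volumes combine commuter VKT with an exogenous background
  traffic growth of 0.7%/yr — injury exposure comes from all traffic,
  not only commuters, and this term is what drives the baseline
  injury-rate growth.
* **Speed effects.** The published local-street result — a 10 km/h
  mean-speed reduction cuts collisions by 60% — is an *empirical
  composite* of fewer collisions and milder outcomes. It is therefore
  applied as a single multiplier `0.4^(Δv/10)` at the collision stage,
  and the severity curves are evaluated at the configured class speeds,
  not the policy-reduced ones; applying both would double-count the
  effect. The severity lookups (logistic-shaped in speed, scaled at
  calibration to reproduce the 1991 fatal and adjusted-serious counts
  exactly) still govern differences between configured class speeds and
  are clamped outside their knot range.
* **Underreporting.** Serious injuries carry a reporting multiplier
  (default 2.0); the model works on the adjusted scale, synthetic
  histories emit the reported scale.
* **Perceived safety.** A monotone lookup from annual (media-reported)
  cyclist deaths to the fraction of the public considering cycling
  "always or mostly" safe, anchored at 0.19 for baseline-era counts and
  flattening at high counts (public response saturates); only the
  anchors are evidence-based, the shape is a calibration input.
* **Car-occupant fatalities.** A constant 17 fatalities per 10⁹
  light-vehicle km, derived from the internal consistency of the
  published cumulative outcomes; no time trend is applied.

## Environment and physical activity

Emission factors decline exponentially (half-lives: CO₂-class gases
40 yr, CO 20 yr, particulate index 15 yr), standing in for external
fleet-model tables that are not published; the CO₂eq factors are
rescaled at model build so the baseline run reproduces the 3.1 t per
regional capita commuting emissions anchor in 2007. That anchor implies
an *effective* ~2.5–3 kg CO₂eq per commuter-VKT — several times a
light vehicle's tailpipe CO₂ — and the package deliberately preserves
it rather than a bottom-up tailpipe factor, because the published
cumulative GHG savings are consistent with it (≈1.4 kg/km averaged over
the policy window). CO carries an indirect 100-yr GWP of 1.9 (config);
CH₄ 25 and N₂O 298. Air-pollution burden scales the 1991
commuting-attributable baseline counts linearly in VKT, particulate
emission index and regional population. Fuel spend combines a slowly
improving fleet (80-yr half-life) with rising real pump prices, so
savings per averted km grow over the run.

Physical activity: regular commuter cyclists carry RR 0.72 for
all-cause mortality, with a linear dose assumption (scaling 1.0 for
≤6 km commutes). The 2-year lead time is a first-order delay on the
cyclist count, symmetric for uptake and abandonment. Background
mortality is a share-weighted mix of three working-age strata
(defaults representative of a high-income population, 1991 weighted
rate ≈ 4.6/1000) declining 0.8%/yr.

## Cost–benefit accounting

Cumulative 2012–2051 scenario-minus-baseline outcomes (trapezoid rule
on the simulation grid; negative = saving) are monetized at fixed unit
values with no discounting and no cost inflation (a discount-rate
option exists, defaults to 0, and is off everywhere). Physical-activity
deaths are valued at the fatality unit value ($3.1 m), as are
car-occupant fatalities. The benefit–cost ratio divides the summed net
benefit by the scenario's infrastructure cost (45/250/380/630 $NZ m).

## Sensitivity analysis

Best/worst-case runs set every *policy-effect* parameter simultaneously
to its favorable/unfavorable study bound (collision RRs spanning
protective-to-null/harmful findings; ±25% on perception increments;
10–15 km/h speed reduction; 0.30–0.55 composite speed base). The Monte
Carlo set adds the structurally uncertain inputs — PA relative risk
(0.60–0.88), lead time (1–5 yr), safety-in-numbers threshold
(0.015–0.040) and exponent (−0.60 to −0.15) — as triangular draws with
mode at the point estimate (the sampling distributions of the original
analysis are not published; triangular is the least-committal choice
with those supports). Default n = 1000 with a mandatory seed.

Effects are classified on a hierarchy: `shape_change` if the
least-squares trend over the terminal 10-year window (flatness band
±1%/yr relative) or the overall direction of change differs from the
reference run; else `order_of_magnitude` for a ≥10× difference in 2051
levels; else `within_order`.

## Synthetic calibration histories

The generator emulates the 1991–2012 calibration data: the latent
bicycle share is the deterministic baseline path times a multiplicative
AR(1) oscillation (φ = 0.8, innovation σ = 0.15, clipped to
(0.004, 0.0295)); census-year observations (5-yearly) add 10% relative
Gaussian noise; fatal, serious (reported-scale) and all-severity
reported crash counts are Poisson around the generative per-cyclist
rates; fuel-price and emission series are the smooth configured trends.
A zero-noise configuration collapses exactly to the deterministic run,
which is what makes the calibration-recovery check exact.

What the synthetic histories do *not* emulate: real census measurement
structure (multi-leg trips collapsed to a "main mode"), spatial
heterogeneity, weather/topography shocks, and any correlation between
share fluctuations and injury reporting. Passing validation against
them shows the pipeline is self-consistent and statistically powered,
not that the model is calibrated to any real city.

The safety-in-numbers structure comparison conditions each variant's
predicted per-cyclist crash rate on the *observed* share series, fits a
free level (the baseline-rate calibration), and compares MAPE on the
all-severity crash series. That series, rather than fatal+serious
counts, carries the evidence: the safety-in-numbers term acts at the
collision stage, and the downstream severity split only adds Poisson
noise (~20/yr fatal+serious vs ~110/yr reported crashes). With 22
observation years the generating structure is preferred in ≥95% of
replicates in both directions.

## Calibration

Constants the source evidence pins directly (demographics, baseline
shares, distance caps, delays, unit values, policy effect sizes,
rollout windows, RR 0.72, the safety-in-numbers threshold/exponent, the
0.19 perceived-safety and 3.1 t/capita anchors) are used as published.
The remaining free constants — baseline collision/severity levels,
perception-curve knots, utility elasticities, background traffic
growth, fleet half-lives, mortality strata — are calibration inputs
whose originals live in unpublished supplementary material. They were
set once, during model construction, so that the baseline run
reproduces the documented historical pattern (share oscillating in the
1–2% band, counts near baseline-era levels, rising injury rate) and the
policy runs reproduce the documented qualitative behaviour modes
(scenario orderings of mode share, mortality savings and emission
savings; rate reversal under traffic calming but not under the partial
network; plateauing counts after the threshold crossing; positive
benefit–cost ratios with physical activity dominant). This mirrors how
the original analysis calibrated to regional data; the package's tests
then verify those behaviours mechanically.

## Numerical details and degenerate inputs

* Lookups clamp at their endpoints; out-of-range severity speeds warn.
* The logistic rollout passes through 1%/99% of its range at the window
  endpoints and is clipped to [floor, ceiling].
* Mode-share renormalization iterates cap enforcement (bicycle, walk)
  until no cap is newly violated; an all-zero attractiveness vector is
  rejected as degenerate.
* An injury rate with zero cyclists returns NaN (undefined), not a
  division error. Non-finite state during integration raises an error
  naming the variable and step.
* All stochastic components take explicit seeds; runs are bit-identical
  given config + seed, and written outputs omit wall-clock timestamps
  by default so output sets are byte-identical.
* Problem sizes in the shipped checks (240 Euler steps per run, 100
  replicates per comparison study, Monte Carlo n = 200 in the CLI
  default) were chosen as the smallest sizes at which the assessed
  properties are stable.

## Known limitations

* Only cyclist injuries from light-vehicle collisions are modelled;
  heavy-vehicle, cyclist-only and cyclist–pedestrian injuries are out
  of scope, as are walking/public-transport co-benefits beyond share
  bookkeeping, equity stratification, and discounting.
* The perception→share elasticities and the perceived-safety curve are
  calibration constructs; different defensible choices rescale scenario
  magnitudes (though the orderings proved robust across the shipped
  uncertainty set).
* Commuter growth, strata shares and trip parameters are stationary;
  no cohort ageing or land-use response.
* The GHG anchor bundles congestion/upstream effects into an effective
  per-km factor; absolute emission levels should be read as
  anchor-consistent indices, not fleet inventories.
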