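# velodyn

System-dynamics simulation of commuter-bicycling policy in a
car-dominated city.

`velodyn` is for transport and public-health modellers who want to ask:
*if a region invests in particular kinds of cycling infrastructure over
the next forty years, what happens to mode share, cyclist injuries, air
pollution, greenhouse-gas emissions, fuel costs and physical-activity
mortality — and do the benefits outweigh the costs?* Unlike comparative
risk assessments that *assume* a future mode share, the model simulates
it, with the feedback loops that make cycling uptake hard: more cyclists
mean more collisions, collisions depress perceived safety, and perceived
safety drives uptake.

## The model

A deterministic stock-flow system integrated by fixed-step Euler
(dt = 0.25 yr) over 1991–2051:

- **Demand.** Commuters grow exponentially (+40% over the 60-year
  horizon from 400,000). Mode share follows a relative-utility form
  over four modes (light vehicle, bicycle, walking, public transport):

  `share_m = b_m A_m / Σ_k b_k A_k`

  with baseline shares `b = (0.85, 0.02, 0.055, 0.075)` as
  alternative-specific constants and attractiveness indices `A_m`
  built from policy perception effects and the perceived safety of
  cycling, behind a first-order preference delay (τ = 1 yr). The
  bicycle share is capped by the fraction of trips within cycling range
  (≤ 6 km, 50%), walking by the ≤ 2 km fraction (27%).

- **Injury.** Annual cyclist–car collisions per road class (local /
  arterial) scale with cyclist exposure, a power of vehicle volume, any
  infrastructure collision relative risk, a composite speed-reduction
  multiplier (0.4 per 10 km/h), and a *thresholded* safety-in-numbers
  term: per-cyclist risk is flat below a 2.5% mode share and follows
  `(share/0.025)^(−0.3)` above it — half the classic `volume^(−0.6)`
  power law, which is also available as a no-threshold variant for
  structure testing. Collisions split into fatal and serious injuries
  through speed-dependent severity curves calibrated to baseline-era
  counts; annual deaths feed a lookup for the fraction of the public
  considering cycling "always or mostly" safe (0.19 at baseline-era
  counts), closing the dominant balancing loop.

- **Co-benefits.** Averted light-vehicle kilometres scale an
  air-pollution burden-of-disease baseline (with declining fleet
  emission factors), CO₂-equivalent emissions (GWP-weighted, anchored
  to 3.1 t per capita from commuting in 2007), fuel costs, and
  car-occupant fatalities. Regular cycling carries an all-cause
  mortality relative risk of 0.72, accruing behind a 2-year first-order
  lead time over declining background mortality.

- **Policy.** Five scenarios roll out along S-shaped curves from 2012:
  business-as-usual **baseline**; **rcn**, a partial network of painted
  lanes and shared paths (complete 2040); **asbl**, segregated arterial
  lanes with intersection treatments (collision RR 0.72 midblock / 0.80
  at intersections, complete 2050); **ser**, "self-explaining"
  low-speed local streets (−15 km/h, −25% local traffic, light-vehicle
  convenience −30%); and the combination **asbl_ser**.

- **Accounting.** Cumulative 2012–2051 scenario-minus-baseline outcomes
  are monetized ($NZ3.1 m per fatality, $0.325 m per serious injury,
  $40/t CO₂eq, …; undiscounted) into net benefit and a benefit–cost
  ratio against infrastructure cost.

Best/worst-case runs move every policy-effect parameter to the bounds of
the underlying studies; a seeded Monte Carlo samples triangular
distributions over the most uncertain inputs. A synthetic-history
generator reproduces the statistical structure of the 1991–2012
calibration data (census-style share observations, Poisson casualty
counts) for validation, calibration-recovery and model-structure tests.

## Worked example

```python
from velodyn import preset, CommuteModel
from velodyn.cba import accumulate, monetize, benefit_cost_ratio

base = CommuteModel(preset("baseline")).run()
for name in ("rcn", "asbl", "ser", "asbl_ser"):
    cfg = preset(name)
    traj = CommuteModel(cfg).run()
    cost = cfg.policy.infrastructure_cost_m[name]
    out = accumulate(traj, base, start_year=2012.0, infrastructure_cost_m=cost)
    bcr = benefit_cost_ratio(monetize(out, cfg.costs), cost)
    print(name, f"{traj['share_bicycle'].iloc[-1]:.1%}",
          round(out.pa_deaths_averted), round(bcr["bcr"], 1))
```

prints (2051 bicycle share, cumulative deaths averted, BCR):

```
scenario   bike 2051  LV 2051 deaths averted GHG saved (Mt)  net $NZm   BCR
rcn             4.0%    83.3%            266            1.6       263   5.9
asbl           12.9%    75.6%            783            4.8      1670   6.7
ser             4.5%    72.9%            220            6.3      1700   4.5
asbl_ser       41.0%    45.1%           2298           17.8      9183  14.6
```

Reading: the planned partial network (`rcn`) and local-street calming
(`ser`) each lift cycling only a few points; segregated arterial lanes
(`asbl`) several-fold more; the combined programme reaches a
bicycle-friendly-city share (~40%) and returns roughly $15 per dollar of
infrastructure. Every active scenario pays for itself several times
over, with physical-activity mortality savings the largest single
benefit. The same run also shows the injury trade-off: the baseline and
`rcn` injury *rate* per 1,000 cyclists keeps rising with traffic growth,
while `ser` and the combined scenario reverse it, and the combined
scenario's total injury counts plateau once the safety-in-numbers
threshold is crossed.

The same analyses are available from the shell:

```bash
velodyn compare --outdir out/            # all five scenarios + summary table
velodyn run --scenario asbl_ser --outdir out/
velodyn sensitivity --scenario rcn --n 200 --seed 1 --outdir out/
velodyn gen-history --seed 1 --out out/history.csv
velodyn validate --seed 1
```

## Layout

- `src/velodyn/engine.py` — grids, lookups, delays, S-curves, Euler driver
- `src/velodyn/demand.py`, `injury.py`, `env_health.py`, `phys_activity.py` — sector models
- `src/velodyn/policy.py` — scenario definitions and effect translation
- `src/velodyn/model.py` — the coupled simulation
- `src/velodyn/cba.py` — cumulative accounting and monetization
- `src/velodyn/sensitivity.py` — best/worst case, Monte Carlo, classification
- `src/velodyn/synthetic.py` — synthetic history, validation, calibration
- `src/velodyn/cli.py`, `io.py`, `config.py`, `presets/` — interface and configuration
- `docs/methods.md` — modelling assumptions, calibration and limitations
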