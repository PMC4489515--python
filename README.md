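# otternet

A spatially explicit, hourly individual-based model (IBM) of coastal river
otters (*Lontra canadensis*) foraging on a linear landscape network, built
for ecologists studying how the availability of schooling pelagic fish
shapes otter sociality and the transport of marine-derived nutrients (MDN)
to the terrestrial landscape.

Coastal river otters show unusual, sex-structured sociality: males forage
cooperatively on schooling pelagic fish (herring, sand lance, salmonids),
while females and some males feed solitarily on intertidal-demersal prey.
Both communicate through feces deposited at shoreline latrine sites, which
concentrates nitrogen into deposition "hotspots" that alter plant
productivity. Because schooling fish are cold-water specialists expected to
withdraw from shallow coastal waters as sea-surface temperature rises, the
model exposes six availability scenarios and asks what happens to group
formation, defecation rates, nutrient transport and the spatial pattern of
deposition as schools decline.

## The model

* **Landscape.** All movement happens on a 1-D network of 10-m
  point-locations: digitized coastline plus "virtual line" corridors
  between islands and across bays. Each point carries a habitat quality
  MEP ∈ [0, 1] (probability of being a latrine site; points with
  MEP > 0.464 are latrine-grade), a spawning-habitat flag (depth ≤ 3 m
  proxy) and an in-study-area flag. A synthetic generator reproduces the
  study system's dimensions (245.3 km of coastline, 80.3 km of corridors,
  58% study-area share) with a Gaussian-smoothed autocorrelated MEP field.
* **Agents.** 55–78 otters are drawn for the study area
  (total = study + round(0.585 × study) for the outside coast), 69% male.
  Each otter tracks activity state, hours-in-state, hours-since-defecation
  and a satiation flag. Females hold exclusive 50% core ranges
  (truncated-Normal(4, 2) km of shoreline) centred on latrine-grade points.
* **Hourly rules.** State switching and defecation use normal-CDF hazards
  q = Φ((h − μ)/σ) with the field means/SDs (active 1.433 (1.393) h,
  inactive 11.692 (8.286) h, defecation gap 4.865 (1.825) h; forced
  defecation at 9 h). Movement is a biased correlated random walk: hourly
  search distance ~ Normal(941, 1731) m clamped at zero, walked in 10-m
  steps with directional persistence; bias targets are (in priority) a
  female's home centre when beyond her core edge, the nearest
  highest-quality latrine within the 1-km memory-perception distance when
  satiated, or a latrine whose scent is detected by olfaction with
  probability exp(−0.003 d) · exp(−0.1 a) (distance d m, scat age a h).
  Movement stops within 50 m (visual range) of a fish school; a successful
  encounter sets satiation, which doubles the stop-foraging and defecation
  hazards and halves the wake-up hazard until the meal is voided. Deposits
  land on the nearest highest-quality latrine in memory range.
* **Fish field.** A season maximum of U{40, …, 98} schools is scaled by the
  scenario availability multiplier (1, 1-random-placement, 0.75, 0.5,
  0.25, 0) and a seasonal weight, and re-placed uniformly on (by default)
  spawning-habitat points every hour.
* **Emergent outputs.** No attraction or repulsion between otters is ever
  coded: groups are detected after the fact as connected components of
  active otters within 100 m. The package computes defecation rates,
  encounter counts, group statistics, 1-D network core-range lengths, 50-m
  deposition windows with hotspot classes (>150 deposits; 50–150
  intermediate), annual nitrogen transport (5.15 g N per deposit), a
  detrended correspondence analysis (DCA) comparing deposition patterns
  across scenarios, and a one-at-a-time sensitivity tornado.

The compiled (numba) engine runs a full paper-scale replicate
(~105–120 otters × 2,232 h on 32,560 points) in a couple of seconds; a
pure-Python reference engine implements the identical per-hour rules and
the test suite asserts the two produce bit-identical logs.

## Worked example

```python
import otternet as ot

net = ot.generate_synthetic_landscape(
    total_coast_km=40.0, corridor_km=8.0, study_fraction=0.58,
    spawn_fraction=0.2, mep_autocorrelation_range=2.0, seed=7)
init = ot.InitParams(density_min=8, density_max=12)   # scaled to 40 km
logs = ot.run_scenario(net, ot.get_scenario("School_100%"), init,
                       ot.BehaviorParams(), n_replicates=5, base_seed=11)
print(ot.scenario_summary(logs).round(3).to_string(index=False))
```

prints

```
                   metric    mean   ci_lo   ci_hi
                abundance  14.800  13.360  16.240
          defecation_rate   0.099   0.098   0.099
        school_encounters 254.504 245.709 263.299
             active_hours 535.649 529.144 542.153
   defecation_rate_female   0.098   0.097   0.098
 school_encounters_female 277.930 253.724 302.136
      active_hours_female 520.547 509.633 531.461
     defecation_rate_male   0.099   0.099   0.100
   school_encounters_male 244.798 229.822 259.774
        active_hours_male 541.892 531.759 552.025
       mean_feces_per_day  35.062  31.813  38.311
        pct_pelagic_feces  70.787  69.516  72.057
                 n_groups   0.151   0.118   0.184
          mean_group_size   2.061   2.043   2.079
           max_group_size   3.600   3.120   4.080
           min_group_size   2.000   2.000   2.000
 pct_time_in_group_female   4.289   2.725   5.852
   pct_time_in_group_male  10.285   8.663  11.906
         pct_mixed_female  99.126  98.029 100.223
           pct_mixed_male  15.909  10.171  21.647
     prop_windows_hotspot   0.002   0.002   0.003
prop_windows_intermediate   0.007   0.003   0.011
  prop_windows_background   0.990   0.986   0.994
              annual_N_kg  65.908  59.801  72.016
```

Each row is a cross-replicate mean with a normal-approximation 95% CI.
On this 40-km world with ~15 otters, roughly 35 deposits/day reach the
shoreline (≈66 kg N per year at 5.15 g per deposit), about 10% of male
active hours are spent in (emergent) groups versus 4% for females, and
nearly all female grouped time is in mixed-sex groups — the sexual
asymmetry in sociality arises with no interaction rule coded.

A command-line interface wraps the same library:

```bash
otternet fixtures --name paper_scale --seed 1 --out net.geojson
otternet simulate --scenario School_100% --landscape net.geojson \
    --replicates 20 --seed 42 --out runs/
otternet metrics --landscape net.geojson --scenario School_None --out summary.csv
otternet sensitivity --landscape net.geojson --replicates 20 --seed 7 --out tornado.csv
```

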