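# Methods

## Model overview

`otternet` simulates individual coastal river otters on a one-dimensional
landscape network at an hourly time step over a single 93-day season
(May 15 00:00 – Aug 16 00:00, 2,232 steps). The network is the sole
movement space: 10-m point-locations along the coastline plus "virtual
line" corridor chains connecting stretches of coast. Every behavioural
quantity — perception, movement, home ranges, group membership,
deposition windows — is defined in network (shortest-path) distance;
planar coordinates exist only to resolve turn angles at junctions.

Each otter carries five state variables: sex, activity state
(active/inactive), integer hours in the current state, integer hours since
the last defecation, and a satiation flag marking an un-voided meal of
schooling pelagic fish. Each hour an otter (1) evaluates a state switch;
(2) if active, chooses a movement bias, draws a search distance, walks the
network until the budget is spent, a bias target is reached, or a fish
school comes within visual range; (3) evaluates defecation and, on
success, deposits a scat at the nearest highest-quality latrine within
memory range (falling back to its own position); (4) advances its clocks.
Deposits become visible to other otters' olfaction only from the next hour
on, which makes trajectories independent of the within-hour update order.
No rule of attraction or repulsion between otters exists anywhere in the
model; social groups, sex-specific home-range sizes and deposition
hotspots are read off the logs afterwards.

## Behavioural rules and their reconstruction

The supplementary equations of the original study (its ODD protocol) are
not publicly available, so three functional forms are reconstructions
chosen to consume exactly the published parameter means and SDs. They are
deliberately isolated in `behavior.py` so they can be swapped if the
supplement is consulted:

* **Duration hazards.** The probability of leaving the current activity
  state after `h` whole hours, and of defecating `h` hours after the last
  event, is `q = Φ((h − μ)/σ)` with the published (μ, σ): active bouts
  1.433 (1.393) h, inactive bouts 11.692 (8.286) h, defecation gaps
  4.865 (1.825) h. `q` is ½ at the published mean. Note that an hourly
  Bernoulli evaluation of this form does *not* reproduce μ as the realized
  mean bout length: because the hazard is already ≈8% at h = 0 for the
  inactive state, realized inactive bouts average ≈5.8 h and active bouts
  ≈2.6 h. The consequences for absolute deposition rates are documented
  under "Known limitations".
* **Satiation scalers.** A satiated otter's stop-foraging hazard and
  defecation hazard are multiplied by 2 (capped at 1), and its wake-up
  hazard divided by 2. Satiation is set on a school encounter and cleared
  when a deposit is laid while satiated (that deposit is flagged
  "pelagic"). Defecation is forced (q = 1) at 9 h regardless of satiation.
* **Scent kernel.** The probability of detecting a scat at network
  distance `d` (m) and age `a` (h) is `exp(−0.003 d) · exp(−0.1 a)`,
  hard-zeroed beyond the 1,000-m memory-perception distance. The distance
  and age terms are treated as a separable product.

Movement is a biased correlated random walk walked in 10-m steps. The
hourly budget is Normal(941, 1731) m with negative draws clamped to zero —
clamping rather than rejection keeps the published parameters intact
instead of inflating the mean. Without a bias target the otter keeps its
heading, at junctions taking the edge that minimises the turn angle and
reversing only at dead ends. Bias targets are resolved once per hour,
before moving, in strict priority: (1) a female farther than half her core
length from her home centre turns home; (2) a satiated otter targets the
nearest highest-quality latrine in memory range; (3) otherwise one
Bernoulli scent trial is run per latrine point in memory range that holds
a committed deposit (using its freshest deposit's age), and the nearest
success is the target. A biased walk follows the shortest path and stops
on arrival (no overshoot). Tie-breaks are uniform everywhere: habitat
quality first, then proximity, then lower point id; the olfaction choice
among detected latrines is proximity first, then quality, then lower id.

## Fish schools

Each replicate draws a season maximum M ~ U{40, …, 98}. The hourly count
is `round(M × availability × w(day))` where the availability multiplier
defines the scenario (1.0 baseline, 0.75, 0.5, 0.25, 0, and a
random-placement variant at 1.0). The within-season weight `w` is a
symmetric triangular ramp from 0.5 at the season edges to 1.0 at
mid-season; the true spawning phenology curve is unpublished, so the shape
is a declared placeholder (a constant weight is selectable) — every
reported metric aggregates over the whole season and is insensitive to
mild shape changes. Schools are re-placed uniformly at random each hour
(1-h residence) on spawning-habitat coastline points, or on any coastline
point in the random-placement scenario; they are never depleted by
feeding, which is what allows several otters to converge on one school —
the group-formation mechanism.

## Initialization

Study-area abundance ~ U{55, …, 78}; total abundance adds
`round(0.585 × study)` otters for the coast outside the study area,
following the source text literally even though 0.585 is arithmetically
inconsistent with the stated 58% study-area coastline share (the factor is
a config field). Sex is Bernoulli(0.69 male). The initial activity state
is Bernoulli(0.122) — the ratio of mean active to inactive hours — with
hours-in-state ~ round(U(0, 1.88)) or round(U(0, 15.32)) and
hours-since-defecation ~ round(U(0, 5)). All otters start on latrine-grade
points (MEP > 0.464) in their region. Female core lengths are
Normal(4, 2) km truncated to positive values by rejection sampling, scaled
by the radial-extent factor at the chosen centre; centres are drawn among
latrine-grade points under the constraint that no two female core
intervals overlap (centre distance ≥ sum of half-lengths), in random
female order. On crowded coastlines a single large core draw may fit
nowhere, so within the 10,000-attempt budget the core length is redrawn
every 50 failed attempts; a capacity error naming the female is raised if
the budget is exhausted.

## Synthetic landscape

The generator emulates the study system's dimensions — 245.3 km of
coastline (24,530 points), 80.3 km of corridors (8,030 virtual points,
distributed over ~40 corridors short-cutting 3–8 km of coast), 58%
in-study-area share — with: a MEP field built from uniform noise smoothed
by a Gaussian kernel (default range 2 km) and min-max rescaled to [0, 1];
spawning habitat in contiguous ~1-km patches covering 20% of the coastline
(both the fraction and patchiness are free calibration knobs, unreported
for the real system); and a radial-extent factor fixed at 1. It does
*not* reproduce the real archipelago geometry, the MaxEnt-fitted latrine
probabilities, bathymetry, or the Thiessen-polygon corridor topology.
Tests that pass on this landscape therefore demonstrate the behavioural
mechanisms and their qualitative contrasts, not site-specific predictions;
absolute spatial statistics (e.g. hotspot proportions) depend on the MEP
field's patch structure. Corridors are discretized so that every edge is
exactly 10 m (a corridor of nominal length L carries round(L/10) points),
which also lets the engine use hop-counting breadth-first search.

## Emergent metrics

* Defecation rate: defecation events / 2,232 h per otter, averaged overall
  and by sex. Mean feces/day: total deposits / 93.
* Groups: connected components of active otters within 100 m network
  distance (the source never states a radius; 100 m = 10 point-locations
  is the default and is exposed as a parameter); a group needs ≥ 2
  members, so 2 is the definitional minimum group size. Percent time in
  group divides grouped active-hours by active-hours, per sex; the
  mixed-sex share is the fraction of grouped time spent in components
  containing both sexes.
* Core range: a 1-D network utilization distribution — hourly occupancy
  mass per point, Gaussian-smoothed along the network (default bandwidth
  300 m), reporting the shoreline length of the smallest point set holding
  50% of the mass. This deliberately replaces the Brownian-bridge
  estimator of the original study, which is undefined on a 1-D network;
  it is the package's single intentional methodological substitution.
* Deposition windows: non-overlapping runs of 5 consecutive coastline
  points (50 m), tiled rather than sliding so window totals partition the
  deposits exactly; deposits on corridor points are windowed separately so
  conservation holds, and hotspot proportions are computed over coastline
  windows only. Classes: > 150 deposits per season = hotspot, 50–150
  intermediate, < 50 background.
* Nitrogen: annual kg N = feces/day × 365 × 5.15 / 1000.
* Cross-replicate intervals are normal-approximation mean ± 1.96·SE.

## Ordination

Correspondence analysis is computed from the SVD of the standardized
residual matrix (observed minus expected under independence, scaled by
square-root margins); eigenvalues are squared singular values, and the
test suite pins the first axis against an independent reciprocal-averaging
iteration to 1e-8. Detrending by segments cuts the axis-1 range into 26
equal-width segments (the de facto standard; configurable) and centres
axis-2 within each, optionally rescaling by the pooled within-segment SD.
For cross-replicate comparison one DCA is run per replicate on the
scenario × window matrix. Axis signs are arbitrary in CA; each axis is
oriented so the first row scores at least as high as the last row
(fallback: first non-zero score positive). An orient-the-largest-score
convention was tried first and rejected: with near-balanced row masses the
identity of the most extreme row flips between replicates, flipping the
sign and destroying cross-replicate averaging.

## Sensitivity design

Ten parameters are perturbed one at a time. Empirical (mean, SD) rows
move the mean ±10% and rescale the SD to preserve the coefficient of
variation; the published table's values for the active-bout row
(1.418/1.379 and 1.734/1.685) are used verbatim even though they are not
±10% of the 1.433 default — an inconsistency inherited from the source.
Expert rows use the published lower/upper settings (scent-distance rate
−0.002/−0.004, desiccation 0.001/0.2, visual 25/75 m, memory 500/1,500 m,
both satiation scalers 1.5/2.5). The response is mean feces/day under the
full-availability scenario. By default all 21 configurations share
replicate seeds (common random numbers), which sharpens contrasts at small
replicate counts; an independent-seed mode is available.

## Randomness and determinism

Every replicate seed expands (via `numpy.SeedSequence`) into three
streams: initialization, the school schedule, and the behavioural kernel.
The kernel uses a counter-based splitmix64 generator keyed by (replicate
seed, otter id, hour), so each otter-hour has a private substream and
trajectories are invariant to update order; movement normals are
Box–Muller pairs from that stream. Breadth-first searches explore
neighbours in ascending-id order from a FIFO queue, making shortest-path
trees (and hence every bias path) deterministic. The compiled kernel and
the pure-Python reference engine implement these choices identically and
are asserted bit-equal in the tests. Replicate r of a scenario run is
seeded by `SeedSequence([base_seed, r])` reduced to 31 bits.

## Problem sizes used by the tests and the acceptance script

Unit tests run on 100–2,000-point line worlds with 5-otter populations.
The emergent checks run the six scenarios on the full paper-scale
synthetic world with 20 paired-seed replicates each (the acceptance script
uses 40, for a tighter estimate of the replicate mean); the sensitivity
tornado uses 5 paired replicates per configuration. One paper-scale
replicate takes roughly two seconds in the compiled engine.

## Known limitations

* The reconstructed hourly hazards realize shorter bouts than the
  published means (see above). Season-aggregated *contrasts* between
  scenarios keep their direction — defecation rate and feces/day rise, and
  pelagic share, group counts and grouped time fall, as school
  availability declines — but two magnitudes fall short of the published
  ones: the absolute deposition ceiling (the no-school scenario reaches
  ≈273 feces/day here versus ≈391 reported) and the relative rise in
  defecation rate without schools (≈4% here versus ≈25%). Under the
  voiding rule the satiation flag is usually cleared within the encounter
  hour (the doubled defecation hazard at typical 5–8-h gaps is ≈1), so
  fish meals rarely lengthen the following rest — the pathway that the
  original description implies drives the large rate contrast.
* For the same reason the sensitivity ranking only partially matches: the
  satiation-activity scaler is the widest tornado bar here as in the
  source, but the memory distance — which in these rules relocates
  deposits without changing their number — has almost no leverage on mean
  feces/day.
* A single season, closed population: no recruitment, mortality,
  immigration, prey depletion, or multi-year dynamics.
* Benthic (intertidal-demersal) prey is implicitly uniform; only schooling
  fish are modelled explicitly.
* The engine requires the uniform 10-m discretization; networks read from
  user files with other edge lengths can be queried geometrically but not
  simulated.
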