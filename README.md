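# niche-shift

Presence-background maximum-entropy niche modelling and habitat range-shift
accounting for species distribution studies on latitude/longitude climate
grids.

Given presence-only occurrence records and stacks of bioclimatic raster
layers (bio1–bio19, one stack per climate scenario), the package answers the
standard questions of a climate-suitability study:

* Which cells are suitable for the species, and how suitable? — a
  from-scratch maximum-entropy (Gibbs) model over background cells,
  q(x) = exp(λ·f(x))/Z, fitted by L1-regularized coordinate descent and
  reported through cloglog/logistic suitability p ∈ [0, 1], with AUC,
  variable contributions, permutation importance, jackknife gains and
  response curves.
* Which predictors matter? — two-stage screening: zero-contribution
  variables are dropped after a preliminary fit, then Pearson-correlated
  pairs (|r| > 0.8) are broken in favour of the more important member.
* How much habitat, and where is it going? — four suitability classes
  (p ≤ 0.2 non, 0.2–0.4 low, 0.4–0.6 medium, > 0.6 high), spherical
  per-class areas in 10⁴ km², reserved/lost/new change matrices between
  scenarios with loss/increase/retention rates, and centroid-migration
  tracks with WGS84 geodesic distances and compass directions.

Because real occurrence/climate archives are large and access-controlled,
the package ships a first-class **virtual species simulator**: correlated
bioclim-like raster stacks built from smooth latent fields with a
controllable correlation structure, a known truth suitability surface,
presence samples drawn from it, and shifted "future scenario" stacks — so
the entire pipeline is testable offline and parameter recovery is
measurable against ground truth.

## Worked example

```python
import niche_shift as ns
from niche_shift.geo import extract_values

cfg = ns.default_config(seed=1)                    # 200x200 world, 19 layers
stack, truth = ns.generate_stack(cfg)
occ = ns.sample_presences(stack, truth, cfg.n_presence, seed=2)
thinned = ns.thin(occ, min_km=10.0, seed=42)       # enforce 10 km spacing
train, test = ns.split(thinned, ns.SplitConfig(seed=42))

model = ns.MaxEnt.from_occurrences(train, stack, background_size=5000, seed=42)
res = model.fit()
print(res.summary())
```

```
Maximum-entropy presence-background model
=============================================
presences:          236
background samples: 5236 (presences included)
variables:          19
feature classes:    linear, quadratic, product, hinge, threshold
features:           1349 (88 nonzero weights)
beta multiplier:    1.0
converged:          True (40 sweeps)
final objective:    6.872870
training gain:      1.7815 nats
entropy H:          6.8727
training AUC:       0.9349
```

The training gain (1.78 nats) is the mean log-probability improvement of
presence cells over a uniform landscape; the entropy H feeds the cloglog
link.  Held-out evaluation and variable importance recover the simulated
species' biology — the world's single causal layer is bio1:

```python
tv = extract_values(stack, test.points())
print(res.evaluate(tv[tv["valid"]][stack.names]).auc_test)  # 0.9251
print(res.importance(seed=42).sort_values("permutation_pct").tail(1))
#       contribution_pct  permutation_pct
# bio1              88.6             91.6
```

Suitability maps, class areas and a warming scenario:

```python
suit = res.predict(stack)                           # cloglog p in [0, 1]
report = ns.class_areas(ns.classify(suit))
# LSDA 10.79  MSDA 9.55  HSDA 17.22  TSDA 37.57     (10^4 km^2)

from niche_shift.simulate import (DEFAULT_SCENARIO_DELTAS,
                                  DEFAULT_MULTIPLICATIVE, shift_scenario)
future = res.predict(shift_scenario(stack,
                     DEFAULT_SCENARIO_DELTAS["2050s_SSP1-2.6"],
                     DEFAULT_MULTIPLICATIVE))
change = ns.change_matrix(suit, future)
# reserved 37.57  lost 0.0  new 20.37 (10^4 km^2)
# loss 0.0%  increase 54.23%  retention 100.0%
track = ns.migration_track({"current": suit, "2050s": future}, "current")
# 2050s centroid 4.94 km NE of the current centroid
```

For this virtual species the optimum sits in the warm tail of the region,
so a +1 °C scenario only adds habitat (retention 100%); stronger warming
shifts and eventually erodes it.

The same chain runs from the shell:

```sh
niche-shift simulate --out-dir world --seed 1
niche-shift run --config pipeline.yaml      # thin -> select -> fit -> predict
                                            # -> classify -> change -> centroid
```

writing `selection.json`, `model.json`, per-scenario `suit_*.asc`,
`classes_*.asc`, `areas_*.json`, `change_*.json`, `track.csv` and a
`manifest.json` with seeds and artifact hashes (identical config + seeds
reproduce byte-identical outputs).

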