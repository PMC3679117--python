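# seedscape

Spatially explicit, event-driven simulation of frugivorous birds foraging on
a gridded landscape and dispersing the seeds of fleshy-fruited trees — plus
the likelihood machinery to fit the movement model to observed bird tracks,
and the spatial statistics to characterize the resulting seed rain.

The package is aimed at movement ecologists and seed-dispersal modellers who
want a mechanistic alternative to phenomenological dispersal kernels: seed
rain here *emerges* from behaviour (gut passage, perching, frugivory,
landscape-biased movement) interacting with landscape structure (forest
cover, clumped multi-species fruit crops, depletion).

## The model in brief

On a plot of square cells (default 22 × 20 cells of 20 m), each bird
repeats: perch for a Gamma-distributed residence time; eat a zero-inflated
Poisson number of fruits, truncated at what the cell holds, with fruit
species drawn by availability (no built-in preference) and counts depleted
immediately; then either leave the plot with logistic probability

```
p_leave(B) = 1 / (1 + exp(-(a_o - b_o·B)))        B = distance to nearest edge
```

or fly straight at 6 m/s to a destination cell drawn from a discrete
distribution **k** over all cells, built from saturating tanh factors

```
d_i = 1 - tanh((dist_i/ε_d)^η_d)      distance (always)
c_i = tanh((cover_i/ε_c)^η_c)         forest cover        (combos DC, DCF)
f_i = tanh((log1p(fruits_i)/ε_f)^η_f) fruit abundance     (combos DF, DCF)
k ∝ d·c·f  (normalized)
```

Every ingested fruit's seeds carry a Gamma gut-passage-time draw (mean
scaling linearly with body mass) and are deposited wherever the bird is when
the clock runs out — in a perch cell, along a flight path, or beyond the
boundary (EXPORTED) on the exit flight. Factor combinations {D, DC, DF, DCF}
are fitted to observed trajectories by maximum likelihood and compared with
AICc per species. A distance-only baseline resamples observed step lengths
with random bearings, ignoring cover and fruit. SADIE-style aggregation (Ia)
and association (Xp) indices, solved as transportation problems, quantify
seed-rain patchiness and the match between two seed rains.

No field data ship with the package: a synthetic-data module generates
landscapes (autocorrelated cover, Thomas-clustered fruit trees with
order-of-magnitude FAI crop classes), a six-thrush/three-tree default
assemblage, and short field-like observation tracks with known ground truth.
See `docs/methods.md` for assumptions, parameters and design decisions.

## Worked example

```python
import numpy as np
from seedscape import SimulationConfig, fit_movement, run_experiment
from seedscape.defaults import default_assemblage, default_landscape_spec
from seedscape.synth import generate_landscape, generate_observations

rng = np.random.default_rng(42)
landscape, crops = generate_landscape(default_landscape_spec(), rng)
assemblage = default_assemblage()

# simulate field-like follow-observations and fit the movement model
tracks = generate_observations(landscape, assemblage, 656, rng)
merula = [t for t in tracks if t.bird_species == "Turdus_merula"]
fit = fit_movement(merula, landscape, combo="DCF")
print(f"T. merula: {len(merula)} tracks, {fit.n_events} decision events")
print(f"  eps_d = {fit.params.eps_d:.1f} m   AICc = {fit.aicc:.1f}")

# paired experiment: full model vs distance-only baseline
cfg = SimulationConfig(n_birds=150, n_replicates=30, seed=42)
exp = run_experiment(landscape, assemblage, cfg, observations=tracks)
print(exp.comparison.groupby("mode")[
    ["p_origin_cell", "p_zero_cover", "mean_displacement_m"]].mean().round(3))
```

prints

```
T. merula: 104 tracks, 204 decision events
  eps_d = 46.1 m   AICc = 1157.9
               p_origin_cell  p_zero_cover  mean_displacement_m
mode
distance_only          0.053         0.123               90.961
full                   0.084         0.005               71.582
```

The fitted distance scale (46 m from 104 short tracks, true value 45 m for
this species) shows the closed loop working at realistic sample sizes. The
comparison table is the package's central result: relative to the
distance-only baseline, the full behavioural model drops more seeds in the
cell of the mother plant (8.4% vs 5.3%), almost none into cells with no
forest cover (0.5% vs 12.3%), and produces shorter mean dispersal distances
— landscape-responsive movement concentrates seed rain where cover and
fruit already are.

The same pipeline is scriptable from the shell:

```
seedscape synth --seed 1 --out data/           # landscape, crops, tracks, truth
seedscape fit --landscape data/landscape.csv \
              --trajectories data/trajectories.csv --out fits.json
seedscape experiment --seed 1 --out results/   # paired full vs distance-only
seedscape analyze --seed-rain results/seed_rain_full.csv \
                  --landscape data/landscape.csv --out analysis/
```

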