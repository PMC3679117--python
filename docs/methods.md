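# Methods

`seedscape` is an event-driven, spatially explicit simulator of frugivorous
birds foraging on a gridded landscape and dispersing the seeds of
fleshy-fruited trees, together with the likelihood machinery to fit its
movement model to observed trajectories and the spatial statistics to
characterize the resulting seed rain. This note records the model, its
assumptions, the tunable parameters, and the design decisions taken where the
design was genuinely open.

## Landscape

The plot is a rectangle of `rows x cols` square cells of side `cell_size`
(default 22 x 20 cells of 20 m — a 400 x 440 m plot of 440 cells). Each cell
carries a forest-cover amount in m² (0 to the 400 m² cell area) and an
integer fruit count per plant species. Coordinates originate at the
lower-left corner; cell ids are 0-based row-major; the centroid of cell
(r, c) is ((c + 0.5)s, (r + 0.5)s). All between-relocation distances are
centroid-to-centroid, so a within-cell move has distance zero; fine-scale
positions inside a cell are deliberately not modelled.

Fruit crops per tree are encoded by an ordinal Fruiting Abundance Index
(FAI): class 0 is zero fruits, 1 is 1–10, 2 is 11–100, 3 is 101–1000,
4 is 1001–10⁴, 5 is >10⁴. Realizing an integer crop from a class is
under-determined by the interval; we draw uniformly for class 1 and
log-uniformly within classes 2–5 (class 5 capped at a configurable 10⁵),
preserving the order-of-magnitude semantics without favouring the top of an
interval. Depletion is exact bookkeeping: eating n fruits decrements the
cell's count by n, immediately; driving a count below zero is treated as a
simulator bug, not an input error.

## Behavioural submodels

Each bird species has:

* **Gut passage time (GPT)** — Gamma with a shape parameter common to the
  assemblage and a species-specific scale, in minutes. Species scales derive
  from a linear regression of mean GPT on body mass,
  `scale = (intercept + slope * mass) / shape`, so the Gamma mean equals the
  regression prediction. Defaults (shape 2, mean = 8 + 0.18·mass min) are
  plausible for 60–120 g thrushes and are config-overridable; no quantitative
  GPT table ships with the emulated system.
* **Perch (residence) time** — Gamma per species, minutes. Defaults use
  shapes below 1 (frequent brief perches, occasional long ones) with means of
  2–4 min increasing with body size.
* **Fruit consumption** — zero-inflated Poisson per feeding bout:
  with probability `pi_zero` the bird eats nothing, otherwise a Poisson(λ)
  count. The realized intake is the minimum of the draw and the fruits
  present in the cell (truncation by min, not pmf renormalization). Defaults
  pi ≈ 0.5, λ ≈ 6 (feeding on roughly half of perches, 4–8 fruits per bout).
  Consumption and perch duration share no state, so they are independent by
  construction.
* **Fruit-species assignment** — the eaten fruits are assigned to plant
  species proportionally to their current availability in the cell, without
  replacement (multivariate hypergeometric). There is no built-in diet
  preference; diet differences between species are emergent.
* **Seeds per fruit** — a per-plant integer (holly 4, hawthorn and yew 1 by
  default). All seeds of one fruit share that fruit's GPT draw; different
  fruits get independent draws. The finer per-fruit grain was chosen over a
  single draw per bout to avoid artefactual clumping of deposition times.

`fit_gamma` (scipy MLE with location fixed at 0) and `fit_zip` (direct
two-parameter MLE on logit/log scales, robust at the pi → 0 boundary) fit
these submodels to observed data; both report log-likelihoods.

## Movement model

At the end of each perch the bird first evaluates a plot-leaving probability
that decays logistically with the distance B (m) from the current cell to
the nearest plot edge:

    p_leave = 1 / (1 + exp(-(a_o - b_o * B)))

If it stays, a destination cell (including the current one — the stay option
has distance 0 and hence maximal distance weight) is drawn from a discrete
distribution k over all cells. Candidate cell i is weighted by the product of
up to three saturating sigmoid factors built from tanh:

    d_i = 1 - tanh((dist_i / eps_d) ** eta_d)          (distance, always)
    c_i = tanh((cover_frac_i / eps_c) ** eta_c)        (cover, combos DC, DCF)
    f_i = tanh((log1p(fruits_i) / eps_f) ** eta_f)     (fruit, combos DF, DCF)

and k ∝ d·c·f normalized. The scale eps sets where each response saturates
(metres for distance, cover fraction in [0, 1] for cover, log1p fruit count
for fruit); the shape eta sets how sharply. The fruit covariate is
log-compressed because crop sizes span five orders of magnitude; cover
enters as a fraction of cell area. Both transformations are switchable.

Three numerical choices matter:

* the three equal-length factor vectors are combined elementwise — the only
  composition that returns one weight per cell;
* every factor weight receives an additive floor of 1e-6 before
  multiplication, so an observed move never has exactly zero likelihood and
  the MLE stays finite under an imperfect model;
* `(x/eps)**eta` is evaluated in log space with exponent clipping, so
  extreme shape parameters saturate instead of overflowing, and the weight
  at x = 0 is exactly 0 (increasing) or 1 (decreasing).

A consequence of this parameterization worth noting: as eps_c → 0 the cover
factor saturates to a constant over all covered cells and the destination
distribution converges to the distance-only one (zero-cover cells remain
suppressed); as eps_c grows the normalized factor converges to a cov^eta
profile rather than to a constant. The "weak response" limit therefore sits
at small eps, and the property tests check that direction.

### Likelihood, fitting and selection

A within-plot move from cell j to i contributes
`log(1 − p_leave(B_j)) + log k_i`; an observed plot exit contributes
`log p_leave(B_j)`; a track that ends with the bird lost to observation is
right-censored and contributes no terminal term.

The likelihood factorizes over parameter blocks: (a_o, b_o) appear only in
the exit/stay terms and are fitted by logistic regression (statsmodels) of
exit indicators on edge distance; the destination parameters appear only in
the choice terms and are fitted by L-BFGS-B in log-parameter space from
several data-driven starts (move-distance quantiles for eps_d, spread
cover/fruit starts for the richer combos). Decision events are grouped by
origin cell into a count matrix, so one likelihood evaluation costs a single
weight-matrix pass over unique origins. Standard errors come from the logit
fit and from a central-difference Hessian of the destination likelihood,
delta-transformed to the natural scale.

The four factor combinations D, DC, DF, DCF are compared with
`AICc = −2ℓ + 2p + 2p(p+1)/(n − p − 1)`, where p counts the two leave
parameters plus two per factor and n counts decision events (moves and
exits; lost terminals excluded). Ties break toward fewer parameters, then
lexicographic combo order. Single-cell landscapes are rejected as
zero-information rather than returning a flat likelihood.

## Simulation

Each bird runs on its own continuous clock in minutes. Per visit: draw a
perch time; draw consumption against availability; assign species; deplete
the cell; enqueue each ingested fruit's seeds with due time = ingestion time
+ GPT draw. Seeds coming due while perched deposit in the perch cell; seeds
coming due mid-flight deposit at the linearly interpolated along-path point,
mapped to its cell. Flights are straight lines at 6 m/s between cell
centroids. When the bird decides to leave it flies to the nearest boundary
point; seeds due en route drop inside, and everything still in the gut is
carried out and recorded as EXPORTED at the boundary crossing. The dispersal
distance convention is centroid-to-centroid within the plot, and distance
from the origin centroid to the crossing point plus 1 m ("just outside the
edge") for exported seeds. Exit gut handling preserves seed conservation
exactly: ingested = deposited in-plot + exported, always.

A cohort run introduces birds sequentially, with species sampled from the
configured relative abundances. Fruit depletion carries across birds within
a replicate; the landscape resets between replicates (the alternative —
carrying depletion across replicates — would make replicates exchangeable
in name only). Replicate and bird RNG streams are spawned deterministically
from one master seed, so runs are bitwise reproducible. Seeds ingested
during a bird's first `burn_in_moves` visits (default 5) are flagged and
excluded from analyses, damping the arbitrary initial placement; they still
participate in the conservation ledgers. A hard cap of 10⁵ moves per bird
is a safety valve only — leave probabilities are positive everywhere for
finite parameters, so termination is almost sure.

The **distance-only baseline** replaces the landscape-responsive choice by
resampling an observed step length (from a supplied pool, typically the
fitted tracks) with a uniform random bearing; the displaced point is mapped
to its cell, and the bird exits when the point falls outside the plot. Cover
and fruit play no role in baseline movement, which the tests verify by
permuting the cover map under a fixed seed.

Default protocol: 5000 bird sequences per replicate, 30 replicates, 6 m/s
flight, 5-move burn-in. Tests and the acceptance script run the same
machinery at smaller cohort sizes (tens to hundreds of birds per replicate,
12 x 12 fitting landscapes) chosen so the full suite completes at a desk
scale while keeping every protocol constant that defines the design —
replicate counts, burn-in, flight speed, and the paired-mode structure.

## Synthetic data

The generators emulate the study system rather than any measured dataset:
spatially autocorrelated cover (smoothed Gaussian noise, re-standardized and
clipped to [0, 1], so large cover SDs produce both closed-canopy and
zero-cover cells), fruiting trees placed by a Thomas cluster process
(clustering = mean trees per parent; 0 gives complete spatial randomness)
with FAI classes drawn per species and realized to crops, and a six-thrush /
three-tree default assemblage. Observation tracks are simulated from the
full model itself with an independent per-step "lost" probability (default
0.35), reproducing the short tracks of field follow-observations (a few
moves on average); fruit state is reset between tracks so the generating
process matches the static-landscape likelihood that is fitted to it.
What the generators do *not* emulate: observer detection bias beyond random
censoring, seasonal phenology, within-cell tree positions, regurgitation,
and flocking. Passing closed-loop tests therefore demonstrate internal
consistency of estimator and simulator, not fidelity to any particular
field system.

## Seed-rain analytics

Distance summaries per bird x plant species report the mean displacement
with empirical 2.5/97.5 percentile intervals, tail probabilities beyond 100
and 200 m, the proportion deposited in the cell of origin, the proportion
exported, and — among in-plot seeds — the proportion landing in zero-cover
cells. Seed-rain grids and focal-cell seed shadows are per-cell counts and
renormalized proportions. Diet composition is the per-bird-species share of
fruits eaten by plant.

**SADIE.** The distance to regularity D is the minimal count-weighted
distance required to rearrange the observed per-cell counts into the uniform
arrangement (total/n per cell), solved as a balanced transportation linear
program (HiGHS; the transportation polytope has integral optima for integer
marginals, which the brute-force enumeration oracle in the tests exploits).
The aggregation index is Ia = D / mean(D) over random permutations of counts
across cells (999 by default, 99 minimum), with a rank-based p-value; a
perfectly uniform grid has D = 0 and Ia = 0 by convention. Local clustering
indices are the signed per-cell transport costs — positive for donor (patch)
cells, negative for receiver (gap) cells — and the association index Xp
between two grids is the Pearson correlation of their local indices, with
significance from permutations of one grid's indices. This is a
reconstruction of the SADIE family of statistics in its canonical
transportation form, not a port of any particular SADIE implementation;
variants differ in the local-index normalization.

The SAR export table applies the transformations a spatial regression
expects — arcsin-sqrt seed proportions and cover fractions, log1p seed and
fruit counts — and leaves the autoregressive model fitting to external
software.

## Known limitations

* The tanh/logistic functional forms are declared substitutes chosen for
  their monotone, saturating, inflection behaviour; alternatives live behind
  `factor_weight` and `leave_probability`.
* Movement likelihoods treat the fruit field as static within a fitting
  dataset; the simulator depletes it. Closed-loop fitting experiments use
  combo-D generators or depletion-free choice sequences where exactness
  matters.
* Exported seeds get a single conventional distance (+1 m past the
  crossing); nothing beyond the boundary is modelled.
* ZIP truncation by min slightly deflates realized consumption in nearly
  empty cells relative to a renormalized truncated distribution; the
  stated min convention was kept deliberately.
* eta parameters are weakly identified when a factor's covariate range sits
  deep in the saturated part of its sigmoid; the recovery experiments use
  scales chosen to keep responses on their informative range.
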