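# cartrend

Spatially explicit estimation of population trends from route-level survey
count data, in the style of the North American Breeding Bird Survey (BBS).

Large-scale count surveys report trends for big reporting regions (Bird
Conservation Regions, states), but routes are allocated within 1°×1°
longitude/latitude degree blocks, and sampling density can differ several-fold
across a region. `cartrend` models counts at the degree-block scale, borrows
strength between neighboring blocks through a spatial prior, and aggregates
block-level trends to *any* region with explicit area-based weights — so
regional estimates are no longer dragged toward the densely sampled corners
of a stratum.

## Model

Counts `Y_it` on route *i* in year *t* are Poisson with

```
log λ_it = α_t + ω_K(i,t) + b_c(i),t
```

- `α_t` — year intercepts, diffuse normal priors N(0, 10⁶);
- `ω_k` — observer(-route) effects, iid N(0, σ²) — observers differ in
  detection skill, and ignoring this aliases observer turnover into trend;
- `b_c,t` — one intrinsic CAR (Besag) spatial field per year on the lattice
  of occupied degree blocks: `b_c | rest ~ N(mean of neighbors, τ²/n_c)`,
  with `n_c` the rook-neighbor count. Each year's field satisfies a
  sum-to-zero constraint (the intrinsic model is rank-deficient by one);
- σ², τ² — inverse-gamma(0.001, 0.001) hyperpriors (half-normal SD priors
  available).

Fitting is Metropolis-within-Gibbs MCMC (3 chains by default) with
vectorized adaptive random-walk updates and conjugate variance draws;
convergence is monitored with the Gelman–Rubin statistic.

The abundance index for cell *c* is the expected count of a *theoretical
route*, `n_c,t = exp(α_t + b_c,t + σ²/2)`, and the trend from year *a* to
*b* is the geometric mean annual change as a percentage,
`100·((n_c,b/n_c,a)^{1/(b−a)} − 1)`, computed per posterior draw. A region's
trend is the weighted average of member-cell trends with weights
`w″ = w′ · A_c / Ā` — overlap proportion times relative spherical cell area
`A = R²·Δλ·(sin φ₁ − sin φ₂)` — again per draw, so credible intervals
propagate coherently.

The package also ships the published 1999–2009 BCR trend comparison table
for three focal species (Carolina wren, cerulean warbler, red-bellied
woodpecker) and recomputes its spatial-vs-nonspatial precision statistics.

## Worked example

```python
import numpy as np
from shapely.geometry import box
import cartrend as ct

# a synthetic survey with known truth: 5x5 degree blocks, 10 years,
# sigma^2 = 0.1, tau^2 = 0.5, 3:1 route-density gradient
data, truth = ct.simulate(shape=(5, 5), n_years=10, sig2=0.1, tau2=0.5, seed=42)
print(data.summary())

model = ct.CARTrendModel(n_chains=3, n_keep=6000, n_burn=1000, random_state=42)
model.fit(data)                      # sklearn-style estimator
print("worst Rhat:", round(max(model.rhat_.values()), 3))

est = model.cell_trend((-100, 35), 2000, 2009)
print(f"cell (-100, 35) trend 2000-2009: {est.estimate:.2f}%/yr "
      f"[{est.lo:.2f}; {est.hi:.2f}]  (truth {truth.cell_trend((-100,35),2000,2009):.2f})")

r = model.region_trend(box(-100, 35, -97.5, 40), 2000, 2009, region_id="west-half")
print(f"region 'west-half' trend: {r.estimate:.2f}%/yr [{r.lo:.2f}; {r.hi:.2f}]")

s2 = model.draws_.stacked("sig2"); t2 = model.draws_.stacked("tau2")
print(f"sigma2: {np.median(s2):.3f} [{np.percentile(s2,2.5):.3f}; "
      f"{np.percentile(s2,97.5):.3f}] (truth 0.1)")
print(f"tau2:   {np.median(t2):.3f} [{np.percentile(t2,2.5):.3f}; "
      f"{np.percentile(t2,97.5):.3f}] (truth 0.5)")
```

which prints

```
{'records': 570, 'routes': 57, 'cells': 25, 'detections': 6293,
 'years': [2000, 2009], 'observers': 131, 'observer_effects': 131}
worst Rhat: 1.008
cell (-100, 35) trend 2000-2009: -19.34%/yr [-25.38; -13.45]  (truth -22.63)
region 'west-half' trend: -5.69%/yr [-7.99; -3.42]
sigma2: 0.110 [0.075; 0.159] (truth 0.1)
tau2:   0.467 [0.357; 0.613] (truth 0.5)
```

The cell in the grid's southwest corner is declining steeply (the posterior
interval covers the known simulated truth), the aggregated western half
declines more mildly, and both variance parameters are recovered within
their 95% credible intervals. `Rhat ≈ 1` says the three chains agree.

The same workflow is available from the shell:

```bash
cartrend simulate --seed 1 --out run/
cartrend fit --counts run/counts.csv --seed 1 --out run/fit/
cartrend trend --counts run/counts.csv --seed 1 --interval 2000 2009 --out run/trends.csv
cartrend region-trend --counts run/counts.csv --seed 1 --regions regions.geojson \
    --interval 2000 2009 --out run/region_trends.csv
cartrend table1-summary
cartrend run --config run.toml     # full pipeline from a TOML config
```

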