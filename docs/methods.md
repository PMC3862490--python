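# Methods

## Model

Route-level survey counts `Y_it` are modeled as Poisson with a log-linear
mean combining a year intercept, an observer effect and a per-year spatial
effect at the degree-block scale:

```
Y_it ~ Poisson(λ_it),   log λ_it = α_t + ω_K(i,t) + b_c(i),t
```

A route belongs to the half-open 1°×1° block containing its start point
(the survey's sample-allocation unit); the grid resolution is configurable.
The spatial effect is an intrinsic conditional autoregressive (ICAR /
Besag) Gaussian Markov random field on the graph of occupied blocks:

```
b_c,t | B_−c,t ~ N( (Σ_k w_ck b_k,t) / n_c ,  τ² / n_c )
```

with binary rook adjacency `w_ck` (cells sharing an edge), `n_c = Σ_k w_ck`
and the conditional-variance scaling `M_c = 1/n_c`. The joint density is
the improper pairwise form `exp(−(1/2τ²) Σ_{c<k} w_ck (b_c − b_k)²)` of
rank C−1; identifiability comes from a per-year sum-to-zero constraint,
with the field's level absorbed by `α_t`. One field is drawn per year,
independently across years given a shared τ², so the spatial pattern of
abundance — and hence of trend — can change over time.

### Priors

- `α_t ~ N(0, 10⁶)` (diffuse normal; variance configurable);
- `ω_k ~ N(0, σ²)`, one effect per observer-route pair by default (an
  observer's detection behavior is route-specific: traffic, habitat and
  familiarity all differ by route); a pure per-observer indexing is a
  config switch;
- `σ², τ² ~ inverse-gamma(0.001, 0.001)` by default — the conventional
  conjugate "non-informative" choice for Gibbs samplers of this model
  family. Because it can misbehave when a variance is truly near zero, a
  half-normal prior on the SD (scale 10, configurable) is available; it
  replaces the conjugate Gibbs draw with a random-walk step on log SD.
- No overdispersion or first-year ("start-up") observer term by default:
  the spatial model stands on year + observer + space. A record-level
  normal overdispersion effect can be switched on (`overdispersion=True`)
  for data with extra-Poisson noise.

## Sampler

Metropolis-within-Gibbs, self-contained (no external MCMC engine):

- **α, ω blocks** — all components are conditionally independent given the
  rest (years partition the records; observer-route pairs partition the
  records), so each block is updated in one vectorized random-walk step
  with per-parameter scales.
- **b block** — the lattice graph is colored greedily; cells within a
  color class are mutually non-adjacent, so their full conditionals (Poisson
  likelihood terms + ICAR conditional prior) do not interact and each class
  is updated in one vectorized step. A 2-coloring suffices on rook grids.
- **Centering** — after each sweep every year's field is recentered to mean
  zero and the subtracted mean added to `α_t`, leaving the likelihood
  untouched. With the diffuse α prior this projection onto the identified
  parameterization is the standard treatment of the ICAR's flat direction.
- **Variances** — conjugate inverse-gamma Gibbs draws: `σ²` from the ω
  sum of squares with shape increment K/2; `τ²` from the ICAR pairwise
  quadratic form `Σ_t b_t'(D−W)b_t` with shape increment (C−1)/2 per year
  (the rank deficiency of each yearly field).
- **Adaptation** — proposal scales adapt in batches of 50 sweeps toward a
  0.44 acceptance rate (the scalar random-walk optimum), with a decaying
  step; adaptation is frozen at the end of burn-in so the retained chain is
  a fixed-kernel Markov chain with the correct invariant distribution.
- **Initialization** — `α_t` at log(mean count + 0.5) plus chain-specific
  jitter, effects at small jitter, variances at 1. Chains get independent
  streams from a `SeedSequence` spawn of the seed, making runs
  bit-reproducible (`random_state`).
- **Diagnostics** — Gelman–Rubin PSRF per year intercept and per variance
  (between/within-chain variance ratio, floored at 1.0), plus per-block
  acceptance rates, all stored in the run manifest.

Defaults (3 chains, 20,000 retained draws pooled across chains after 5,000
burn-in sweeps each) suit production runs; the tests and acceptance study
use smaller, faster settings stated below.

## Trend and post-stratification

The abundance index is the expected count of a *theoretical route*,
`n_c,t = exp(α_t + b_c,t + σ²/2)`: the σ²/2 term is the lognormal mean of
the observer-effect distribution, i.e. the index describes a route visited
by a randomly drawn observer rather than one with ω = 0. Which variance
components enter this retransformation is genuinely a modeling choice; a
`retransform="none"` switch drops the term. Since σ² is shared across years
within a draw, the term cancels in the trend ratio — the switch affects
reported abundance levels only, a fact the tests assert.

Trend between years a < b is the geometric mean annual change
`100·((n_c,b/n_c,a)^{1/(b−a)} − 1)` computed per retained draw and
summarized by the posterior median (mean optional) and central 95%
interval (type-7 percentiles).

Regions are reduced to per-cell weights: the overlap proportion `w′`
(spherical area of polygon ∩ cell over cell area — computed exactly via a
Green's-theorem line integral of the spherical area element over the
lon/lat intersection geometry) times the relative cell area `A_c/Ā`, which
corrects for degree blocks shrinking poleward, `A = R²·Δλ·(sin φ₁ −
sin φ₂)` with R = 6371 km (mean Earth radius, configurable). The region
trend is the weighted mean of member-cell trends *per draw* (default),
which propagates posterior dependence between cells into the interval; a
`point-estimate` mode averaging cell medians exists for comparison.
Polygons crossing ±180° are wrapped into [−180, 180] before intersection.

## Lattice construction

Occupied blocks (≥ 1 route record) form the lattice; an optional buffer
ring of empty neighbors can be added (the block set beyond occupied cells
is a genuinely open choice — both options are exposed). Adjacency is rook
by default ("common boundary" taken literally); queen is available. The
ICAR is undefined on a disconnected graph, so three policies exist:
`strict` (error naming components), `largest-component` (default: drop
smaller components with a warning — matching common CAR-software
behavior), and `bridge` (connect each stray component to its nearest cell
by centroid great-circle distance).

## Synthetic data

`cartrend.simulate` draws from exactly the model above: routes placed
uniformly within their block, per-year ICAR fields sampled by
eigendecomposition of the graph Laplacian on the sum-zero subspace,
observer-route effects iid N(0, σ²), geometric observer turnover, Poisson
counts. Defaults define the desk-scale study conditions: 6×6 blocks at a
mid-latitude window, 10 years, 1–4 routes per cell with a 3:1 west-east
expected-density gradient (emulating the real survey's regional imbalance),
σ² = 0.1 (≈ ±37% between-observer detection spread), τ² = 0.5 (clearly
visible spatial correlation), baseline mean count 10 with a −2%/yr drift,
15%/yr observer turnover (mean tenure ≈ 6–7 years, BBS-like).

What the generator does **not** emulate: overdispersion beyond the observer
term, first-year observer learning effects, route paths (only start points),
missing-year patterns, detection covariates (weather), and temporal
dependence between the yearly spatial fields. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to the misspecifications real
surveys exhibit.

## Verification

- ICAR conditionals and the pairwise log density are checked against dense
  Gaussian conditioning of the joint precision `(1/τ²)(D−W)` on *every*
  connected sub-lattice of a 3×3 grid; field sampling is checked against
  the pseudo-inverse covariance on small graphs.
- Conjugate variance draws are KS/QQ-tested against the analytic
  inverse-gamma posteriors.
- Spherical areas are checked against 2-D numerical integration, analytic
  latitude bands, and the full-globe 4πR² closure.
- Trend algebra (chaining across intervals, scale invariance,
  monotonicity, closed forms such as a decade-long doubling ⇒ 7.177%/yr)
  is exact to 1e−12 per draw.
- The end-to-end recovery study (20 seeds in the test suite, 8 in the
  acceptance script): 6×6 grid, 10 years, σ² = 0.1, τ² = 0.5, 3 chains ×
  3,000 sweeps (1,000 burn-in, ~3 s per fit) — requires Rhat < 1.1 for all
  year intercepts and variances, ≥ 90% of replicates covering each true
  variance, and ≥ 90% pooled coverage of true cell trends by 95% intervals.
  These run sizes are chosen so the whole suite stays interactive; the
  sampler's per-sweep cost is linear in records + cells.

## Known limitations

- Large lattices (thousands of cells) would benefit from sparse-aware
  color updates and thinning of stored fields; the current dense per-draw
  storage of `b` is the memory bottleneck.
- The Gelman–Rubin implementation is the classic non-split form; very slow
  mixing within a chain can evade it.
- The printed comparison table is transcribed at the published precision;
  statistics derived from it (CI-length SDs, gains) inherit that rounding.
  The row-wise count of which method's interval is shorter is not robust
  to rounding and is exposed but not treated as a reference value (only
  the tie count, verifiable row by row, is).
- Region overlap treats polygon edges as straight in lon/lat
  (equirectangular) coordinates, consistent with the cell geometry; for
  continental-scale polygons with very long edges this differs from
  great-circle edges.
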