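# Methods

This note documents the model implemented by `ecoevometa`, the default
parameterization and why each value was chosen, the numerical strategy,
and the package's known limitations.

## Model

### State variables and landscape

The landscape is a one-dimensional chain of `L` patches (default 50),
each 200 km long, spanning pole (patch 1) to equator (patch `L`). The
state of species `i` in patch `k` is its density `N_i^k` (dimensionless
abundance) and the local mean of its heritable temperature optimum
`μ_i^k` (°C). Within-species optima are normal, `z ~ N(μ_i^k, σ²)`, with
fixed phenotypic variance `σ² = σ_G² + σ_E²` (genetic plus environmental);
under the infinitesimal model only the mean evolves.

### Climate forcing

Patch temperature is a linear gradient plus a warming ramp:

    T^k(t) = T_min + (T_max − T_min)·k/L + ΔT^k · Q(t / t_E),

where `Q` is the quintic smoothstep `10τ³ − 15τ⁴ + 6τ⁵` clamped to
[0, 1], `t_E = 300 yr` is the ramp duration, and the warming amplitude
interpolates from `C_max` at the pole to `C_min` at the equator (polar
amplification). Defaults: `T_min = −10`, `T_max = 30`, `C_max = 8`,
`C_min = 2` °C. Simulations run from `t₀ = −4000` (assembly under the
stationary pre-warming climate) to `t_end = 2500`.

### Local dynamics

The per-phenotype intrinsic growth rate is a Gaussian thermal performance
curve with a width–height tradeoff:

    r(z) = (ϱ / w) · exp(−(T^k − z)² / 2w²) − κ,    w = b_w − a_w·μ_i^k.

Warm-adapted species (large μ) have narrower, taller curves. Competition
is Lotka–Volterra; in the temperature-dependent mode the coefficient
between two phenotypes is the Gaussian kernel `exp(−(z − z′)² / η²)`
(note: no factor 2 in the denominator), so niche overlap in trait space
sets competitive intensity. Consumers (optional second trophic level) feed
on five resource species each with a Holling type II functional response
`F_ij = q_i W_ij ω_ij N_j / (1 + q_i H_i Σ_s W_is ω_is N_s)`, with
conversion efficiency ε; consumer intrinsic growth is negative for every
admissible phenotype, making consumption obligatory. Consumers do not
compete directly; they interact through shared prey. Trophic interactions
are phenotype-independent and therefore exert no direct selection on the
temperature optimum.

All phenotype integrals are Gaussian–Gaussian products with closed forms
(module `closures`): the density equation uses the mean growth
`ϱ/√(w²+σ²) · exp(−Δ²/2(w²+σ²)) − κ` with `Δ = T − μ`, and the effective
competition coefficient
`η/√(η² + 2(σ_i²+σ_j²)) · exp(−(μ_i−μ_j)²/(η² + 2(σ_i²+σ_j²)))`; the
trait equation uses the corresponding selection differentials, scaled by
heritability `h² = σ_G²/(σ_G² + σ_E²)`. An adaptive-quadrature oracle
(`quadrature_oracle`, `quadrature_oracle_2d`) provides an independent
check of every closed form.

### Dispersal

Nearest-neighbour migration at rate `m_i = d_i / Δx` (dispersal distance
per year over patch length) with a reflecting pole and a mirroring
equator boundary, so pure dispersal conserves each species' total
abundance. Immigration also mixes trait means, mass-weighted by the
immigrant stream: `dμ_i^k/dt ⊃ h² Σ_l m (N^l/N^k)(μ^l − μ^k)`.

### Genetic variance regulation and extinction

To keep near-extinct populations from evolving implausibly fast, the
effective genetic variance is ramped down at low density:
`σ_G,eff² = σ_G² · N²/(N² + N_c²)` with `N_c` ten times the extinction
threshold. At every snapshot (default cadence 100 yr) local densities
below the extinction threshold (default 1e−6) are set to zero; a species
with no occupied patch is globally extinct, irreversibly.

## The scenario grid and replicate draws

A numerical experiment crosses high/low mean dispersal (100 vs 0.01 m/yr)
× high/low mean genetic variance (0.1 vs 0.001 °C²) × one/two trophic
levels × constant/temperature-dependent competition = 16 scenarios. The
random stream of a replicate is keyed by (seed, dispersal level, variance
level) only, and all parameter groups are drawn in a fixed order, so the
four model setups within a (seed, dispersal, variance) triple share
identical underlying draws — paired comparisons isolate the effect of
trophic structure and competition mode.

### Parameter defaults

Per-species parameters are log-normal with 20% coefficient of variation
around the means below (drawn once per replicate); choices marked (c) are
package calibrations where no published value exists, fixed once so that
the default community exhibits the regime the model is built to study —
multispecies coexistence in banded thermal ranges, with persistent
consumers in two-trophic runs — and not revisited.

| parameter | symbol | default | units | rationale |
|---|---|---|---|---|
| resource growth scale | ϱ | 1.0 | yr⁻¹·°C | sets the time unit (c) |
| resource mortality | κ | 0.1 | yr⁻¹ | 10% of peak growth scale (c) |
| tolerance width intercept | b_w | 7.0 | °C | gives banded ranges ≈25% of the gradient (c) |
| tolerance width slope | a_w | 0.08 | — | w spans ≈7.8–4.2 °C across the trait range (c) |
| competition kernel width | η | 2.5 | °C | comparable to tolerance width (c) |
| interspecific a_ij | — | U(0.15, 0.6) | — | below a_ii = 1: stable coexistence (c) |
| genetic variance | σ_G² | 0.1 / 0.001 | °C² | scenario axis |
| environmental variance | σ_E² | 0.01 | °C² | small relative to high σ_G² (c) |
| dispersal distance | d | 100 / 0.01 | m/yr | scenario axis |
| patch length | Δx | 200 | km | 10,000 km pole→equator over 50 patches |
| attack rate | q | 5.0 | yr⁻¹ | consumers persist through assembly (c) |
| handling time | H | 2.0 | yr | saturating response in the observed density range (c) |
| conversion efficiency | ε | 0.3 | — | standard trophic efficiency order (c) |
| consumer mortality | κ_C | 0.05 | yr⁻¹ | balances Holling-II gain ε·F (c) |
| consumer growth peak | — | 0.5·κ_C·w_min | — | intrinsic growth negative everywhere: obligate consumer |
| links per consumer | — | 5 | — | each consumer eats its temperature-matched resource + 4 random others |

Initial conditions: trait means equally spaced over [T_min, T_max]
(`μ_i = T_min + (T_max−T_min)·i/S`), patch-independent; densities
`N_i^k(t₀) = exp(−(μ_i − T^k(0))²/8)`, so each species starts centred on
the latitude it is adapted to.

## Numerical choices

- Integration: `scipy.integrate.solve_ivp` RK45, `rtol 1e-6`,
  `atol 1e-9`, chunked between 100-yr snapshots; the extinction threshold
  is applied at snapshots and the integrator restarts from the thresholded
  state. Halving the tolerances changes snapshot densities by well under
  0.1% (asserted in the test suite). Densities that undershoot below
  −threshold abort the run; small negative round-off is clipped to zero.
- Closed forms vs quadrature: production dynamics always use the closed
  forms; the oracle is test-only. Oracle convergence failures raise rather
  than returning an unreliable value.
- Degenerate inputs: zero-density patches contribute no trait flux;
  empty communities yield NaN metrics and are excluded from averages; a
  tolerance width `w ≤ 0` (trait outside the admissible range) raises.
- Tie-break: a consumer's temperature-matched resource is the one with
  the smallest |Δμ|, lowest index on ties.
- Regions: polar/temperate/tropical are the patch-index thirds, cut
  points rounded to the nearest patch (17/16/17 at L = 50).
- Trait lag is reported signed (warming ⇒ positive); an absolute-value
  variant is available (`absolute_lag=True`). Turnover defaults to
  abundance-weighted Bray–Curtis on region-summed densities, with Jaccard
  on presence/absence as an alternative.
- Presence threshold for richness/range/occupancy metrics: 1e−3, well
  above the 1e−6 extinction threshold; all reported richness metrics use
  it unless overridden.

## Scope of the simulated conditions

The replicate generator emulates the study design it implements: a smooth
deterministic warming signal on a regular 1-D gradient, log-normal
interspecific parameter heterogeneity, and a fixed bipartite food-web
topology. It does not emulate weather-scale climate variability or
extremes, 2-D geometry or heterogeneous patch sizes, correlated parameter
draws across species, within-species genetic architecture beyond the
infinitesimal model, or adaptive foraging. Passing tests therefore show
that the model mechanisms behave as specified under these idealized
conditions, not that any particular natural community will match them.

## Test problem sizes

The test suite exercises the closed forms against quadrature on 1,000
random draws, structural invariants exactly, and the directional
ensemble properties on a reduced grid — all 16 scenarios at 10 species
per trophic level × 30 patches × 5 replicates — plus a 16-replicate
baseline ensemble at the full 50 × 50 size for the turnover and
trait-lag-regression checks. These sizes are the package's default
verification configuration; larger ensembles sharpen the stochastic
comparisons but do not change their direction.

## Known limitations

- The trait equation assumes a fixed phenotypic variance; variance
  evolution and plasticity are out of scope.
- Consumers experience no direct selection from feeding (interactions are
  phenotype-independent by construction), so consumer evolution is driven
  by the abiotic environment and immigration only.
- With temperature-dependent competition the right-hand side densifies
  (per-patch S×S kernel evaluations); two-trophic kernel runs at full
  size are roughly an order of magnitude slower than constant-competition
  runs.
- The solver is non-stiff (RK45); parameterizations far from the defaults
  (e.g., very fast attack rates) may need `method="LSODA"`/`"BDF"`, which
  `run_replicate` accepts but which are untested at scale.
- Single-CPU execution; the experiment command runs realizations
  serially. Per-run RNG streams are keyed by (scenario, seed), so a
  parallel driver would produce identical aggregates.
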