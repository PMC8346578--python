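# ecoevometa

Spatially explicit eco-evolutionary simulations of multispecies communities
responding to climate change along a latitudinal gradient.

`ecoevometa` is for ecologists and evolutionary biologists who want to ask
how dispersal, rapid trait evolution, trophic structure, and the
temperature dependence of competition jointly shape community reassembly
under warming: which species shift their ranges poleward, which adapt in
place, which go extinct — and how long losses continue after the climate
has stabilized.

## The model

The landscape is a chain of `L` patches from pole (patch 1) to equator
(patch `L`), coupled by nearest-neighbour dispersal with a reflecting
boundary at the pole and a mirroring boundary at the equator. Each species
`i` in patch `k` is described by two state variables: its population
density `N_i^k` and the local mean of its temperature optimum `μ_i^k` (the
evolving trait). Within a species, optima are normally distributed with
fixed phenotypic variance (infinitesimal-model quantitative genetics); only
the mean evolves, at a rate proportional to heritability times the
selection differential.

The local per-capita growth of a phenotype `z` at temperature `T` is a
Gaussian thermal performance curve with a width–height tradeoff

    r(z) = (ϱ / w) · exp(−(T − z)² / 2w²) − κ,    w = b_w − a_w·μ,

so warm-adapted species grow faster over a narrower thermal band. Species
interact through Lotka–Volterra competition — either constant coefficients
or a Gaussian kernel `exp(−(z − z′)²/η²)` in trait space, under which
similar temperature optima compete harder and selection drives character
displacement — and, optionally, through a second trophic level of
consumers feeding on resources with a Holling type II functional response.
All phenotype integrals (mean growth, selection differentials, effective
competition coefficients) are evaluated in closed form; an adaptive
quadrature oracle cross-checks every closed form in the test suite.

The climate is a linear temperature gradient that warms over 300 years
following a smooth (quintic smoothstep) ramp, with polar amplification:
the pole warms by several degrees more than the equator. A simulation runs
from 4000 years before the onset of warming (community assembly under a
stationary climate) through the ramp and a further 2200 post-warming
years, tracking range shifts, local and global extinctions, compositional
turnover, and the community-wide trait lag behind the moving temperature.

The full numerical experiment is a factorial of 16 scenarios — high/low
mean dispersal × high/low mean genetic variance × one/two trophic levels ×
constant/temperature-dependent competition — with replicate parameter
draws keyed so that scenarios differing only in trophic structure or
competition mode share identical underlying draws (matched comparisons).

## Worked example

Run one replicate of the baseline model (one trophic level, constant
competition, high dispersal, high genetic variance) at the default size of
50 species on 50 patches:

```bash
$ ecoevometa run --seed 0 --out demo_out
running scenario one-constant-dhigh-vhigh seed 0 (50 species x 50 patches)
  t=      0 (establishment end): 28 species extant
  t=    300 (warming end): 24 species extant
  t=   2500 (final): 16 species extant
  global extinction events: 34
wrote demo_out/trajectory_seed0.csv
```

Of the 50 species seeded along the gradient, 28 coexist after the 4000-yr
assembly phase; warming then drives losses that continue long after the
climate stabilizes at t = 300 — an extinction debt (24 species at the end
of warming, 16 at t = 2500). Diversity and trait metrics can be recomputed
from the saved trajectory:

```bash
$ ecoevometa metrics --trajectory demo_out/trajectory_seed0.csv --seed 0 --out demo_metrics
integrated trait lag: 1.2616 degC, dispersion: 1.1199 degC^2, polar turnover: 0.482
wrote 4 tables to demo_metrics
```

The integrated trait lag (1.26 °C) is the time- and landscape-averaged gap
between the local temperature and the community's density-weighted mean
temperature optimum over the warming period — a community tracking the
climate perfectly would score 0. The polar turnover (0.482) is the
abundance-weighted Bray–Curtis dissimilarity of the polar third of the
landscape between the onset of warming and the end of the run: roughly
half of the polar community, weighted by abundance, was replaced.

The same computation from Python:

```python
from ecoevometa import Scenario, draw_replicate, run_replicate
from ecoevometa.metrics import turnover, integrated_lag_and_dispersion

config = draw_replicate(Scenario("high", "high", "one", "constant"), seed=0)
traj = run_replicate(config)
lag, dispersion = integrated_lag_and_dispersion(traj)
print(f"integrated trait lag:        {lag:.3f} degC")
print(f"integrated trait dispersion: {dispersion:.3f} degC^2")
print(f"polar turnover (t=0 vs 2500): {turnover(traj, 'polar'):.3f}")
```

prints

```
integrated trait lag:        1.262 degC
integrated trait dispersion: 1.120 degC^2
polar turnover (t=0 vs 2500): 0.482
```

The full 16-scenario factorial with replicates:

```bash
ecoevometa experiment --replicates 5 --out results/
```

writes `experiment_summary.csv` with one row per realization (integrated
lag and dispersion, final relative richness, polar turnover) plus a
reproducibility manifest. See `docs/methods.md` for the model equations,
parameter defaults, and numerical choices.

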