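# sessile

Demography and spatial patterning of sessile organisms — trees, termite
mounds, ant nests, fairy circles — from a single quantitative framework:
allometric growth and mortality of individuals, competition for fluctuating
resources through overlapping capture areas, and the order metrics that
distinguish random, liquid-like, and regularly spaced communities.

## Who this is for

Theoretical ecologists and quantitative biologists who want to simulate
size-structured populations of immobile organisms, explore how growth,
death, and competitive attrition shape both the size distribution and the
spatial arrangement of a community, or score field point patterns (plain
x,y tables) against a complete-spatial-randomness null.

## The model

**Individuals.** Metabolic scaling sets the radial growth rate and natural
mortality of an organism of basal radius r:

    rdot(r) = (3/8) c_m^(1-b) a_bar r^b,        mu(r) = A_bar r^(b-1),

with growth exponent b = 1/3 and mass–radius relation r = c_m m^(3/8), so
that r(t) ~ t^(3/2) at late times. At demographic equilibrium the
population number density n(r) ~ r^(-alpha) with

    alpha = b + 8 A_bar / (3 a_bar c_m^(1-b)),

which equals 2 (space filling) when the mortality-to-growth ratio is 5/3.

**Competition.** Each organism captures resources over an area
a(r) = c_r r^(2 alpha_r) against a basal need Q0(r) = beta1 r^eta1, under a
plot-wide scarcity xi drawn from a Pareto tail h(xi) ∝ xi^(-nu). An
organism whose net balance

    dQ = eps rho(t) (a_i - f Σ_j Δ_i a_j) - Q0(r_i),    rho(t) = rho_bar / xi(t)

turns negative dies at rate s; the mean-field probability of such a fatal
fluctuation is (r/r_max)^kappa with kappa = (nu-1)(eta1 - 2 alpha_r). The
generalized size-class model then has the closed-form steady state

    n(r) = n0 (r/r0)^(-alpha) exp(-F r^(kappa+1-b)/(kappa+1-b)),

a power law truncated at a cutoff that moves to smaller radii as the
competitive cost F grows. Asymmetric (canopy) competition — larger
individuals shade all sufficiently smaller ones through a Heaviside kernel
— instead fixes alpha = 4 alpha_can + 2 - b and excites transient
population shock waves that travel up the size axis.

The package implements this as composable layers: `sessile.allometry`
(scaling laws and exponent relations), `sessile.meanfield` (discrete
size-class chain, upwind finite-volume PDE, closed-form steady state,
oscillation and dip diagnostics), `sessile.automaton` (individual-based 2D
simulation on a periodic plot), `sessile.spatial_stats` (nearest-neighbor
distributions, boundary-corrected CSR null, bias-corrected KL order metric
in bits, neighbor-density profile), `sessile.fixtures` (synthetic patterns
and brute-force oracles), and a `sessile` command line.

## Worked example

```python
from sessile import (AllometryParams, CompetitionParams, growth_rate,
                     alpha_symmetric, kappa, fatal_fluctuation_prob)

p = AllometryParams()          # a_bar=0.8, A_bar=0.5, b=1/3, c_m=1
c = CompetitionParams()        # nu=5/2, eta1=2.5, alpha_r=1, r_max=10
print("growth rate at r=1:", growth_rate(1.0, p))
print("population exponent alpha:", alpha_symmetric(p))
print("competition exponent kappa:", kappa(c))
print("fatal-fluctuation prob at r=5:", round(fatal_fluctuation_prob(5.0, c), 4))
```

prints

```
growth rate at r=1: 0.30000000000000004
population exponent alpha: 1.9999999999999998
competition exponent kappa: 0.75
fatal-fluctuation prob at r=5: 0.5946
```

— the default demography grows a unit-radius stem by 0.3 radius units per
unit time and sits exactly at space filling (alpha = 2); with the default
resource scalings, a mid-sized organism is five times more exposed to fatal
scarcity than its size alone would suggest (0.59 vs (5/10)^0.75 of the
largest organism's certain exposure).

The same prediction emerges dynamically. With a minimal config

```toml
[run]
seed = 1
mode = "meanfield"
t_max = 120.0
snapshot_every = 10.0

[competition]
s = 0.0
```

```
$ sessile meanfield --config config.toml --mode pde --out demo
wrote demo_snapshots.csv, demo_diag.json
```

`demo_diag.json` reports `alpha_symmetric: 2.0` and a fitted stationary
log-log slope of `-1.966 ± 0.0005` over the window [2, 5] — the solver
recovers the predicted exponent to within its discretization error.

Other entry points: `sessile automaton` (individual-based runs with CSV
snapshots), `sessile stats --pattern FILE` (order metrics for a point
pattern), `sessile fixtures` (synthetic patterns), `sessile sweep` (phase
tables over growth/death/attrition grids).

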