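# herbigame

Evolutionarily stable root–shoot allocation under herbivory: a
game-theoretic model of plant tolerance, with the numerical machinery to
solve it, sweep resource and damage gradients, and analyse (or simulate)
the block-design clipping experiments used to test it.

## The problem

Plants lose substantial fractions of their tissues to herbivores, yet many
species *tolerate* attack: they regrow, and a damaged plant can end a
season with nearly the fitness of an undamaged one. Is such compensatory
growth an evolutionarily stable strategy (ESS), or must it be assumed?
This package implements a two-player foraging game in which compensation is
*not* built in, but can emerge as the equilibrium:

* the **plant** chooses season-total root and shoot production
  $(u_r, u_s)$, balancing carbon gain above ground against nitrogen gain
  below ground;
* the **herbivore** chooses a scalar foraging time $u_h$ and consumes a
  saturating fraction $\phi = 1 - e^{-a u_h}$ of the attacked tissue
  (shoot *or* root).

Plant fitness is a stoichiometrically weighted product of net resource
harvests,

$$G = E\,\pi_C^{\alpha}\,\pi_N^{\beta}, \qquad \beta = 1-\alpha,$$

$$\pi_C = C\,(1-e^{-V_c u_s}) - c_{cr}u_r - c_{cs}u_s - \alpha\,u_i\,\phi,$$

$$\pi_N = N\,(1-e^{-V_n u_r}) - c_{nr}u_r - c_{ns}u_s - \beta\,u_i\,\phi,$$

where $u_i$ is the attacked tissue. Herbivore fitness is
$u_i(1-e^{-a u_h}) - c_h u_h$, giving the closed-form best response
$u_h^* = \max\{0, \tfrac1a \ln(a u_i^*/c_h)\}$. The plant's best response
has no closed form; the package solves its first-order conditions
numerically (multi-start root solve in log-strategy space, second-order
conditions verified), and finds the coupled Nash equilibrium by damped
best-response iteration verified against the full stationarity system.

Compensation is quantified as a log response ratio,
$\mathrm{lnRR} = \ln(u_{i,\text{damaged}}/u_{i,\text{undamaged}})$, against
the no-compensation floor $\ln(1-D)$ for damage fraction
$D = 1-e^{-a u_h^*}$. The same metric applies to randomized-complete-block
clipping experiments (block-paired lnRR of spike, total shoot = standing +
clippings, and root mass), for which the package provides trend fitting
with block fixed effects, an observed-versus-expected slope comparison,
per-treatment compensation verdicts, and a ground-truth synthetic-data
generator.

## Worked example

```python
from herbigame import *

plant, env = PlantParams(), Environment(C=5000, N=50)

# herbivore-free ESS
eq = PlantHerbivoreGame(plant, env=env).fit()
print(eq.u_r_star, eq.u_s_star, eq.payoffs.G_plant)
# 5.351271138 7.367090795 394.5700618

# coupled Nash equilibrium with a shoot-feeding herbivore
dyn = PlantHerbivoreGame(plant, HerbivoreParams(location="shoot"), env,
                         DamageSpec(mode="dynamic", location="shoot"),
                         partials_mode="table2").fit()
print(dyn.summary())
```

```
Plant-herbivore game equilibrium
==================================
mode                   dynamic
attack location        shoot
...
root production u_r*   5.355608045
shoot production u_s*  7.151239694
herbivore time u_h*    2.300872545
damage fraction D      0.8002344363
plant fitness G        394.0396623
converged              True
```

Undamaged, this plant builds 5.35 g of root and 7.37 g of shoot for a
reproductive output of 394.6. Against an optimally foraging shoot
herbivore it concedes an 80% consumed fraction yet rebuilds to within 3%
of its undamaged shoot mass and 0.1% of its undamaged fitness — tolerance
through regrowth, emerging purely from the equilibrium.

The experiment side, from the command line:

```bash
herbigame simulate-experiment --seed 7 --out sim/
herbigame analyze-experiment --input sim/experiment.csv --out results/
```

```
observed lnRR_shoot ~ d: slope -1.0497 (SE 0.0642, 95% CI [-1.1777, -0.9218]), ...
expected lnRR_shoot ~ d: slope -1.5119 (SE 0.1181, ...), intercept 0.0469 ...
slope difference (obs - exp) = 0.4622 (SE 0.0754), chi2 = 37.55, p = 8.9e-10
```

The simulated plants were generated with a true shoot lnRR slope of −1.0;
the analysis recovers it (−1.05 ± 0.06) and flags it as significantly
shallower than the no-compensation floor slope −1.51 — the compensatory
growth signature.

Other subcommands: `herbigame solve`, `sweep-fixed`, `sweep-dynamic`
(CSV tables of equilibria and lnRR across nitrogen × damage grids; add
`--plot` for figures).

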