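# Methods

## Model

Two players interact once per season. The plant's strategy is the pair
$(u_r, u_s)$ of season-total root and shoot production; the herbivore's is
a foraging time $u_h$. Net harvests are saturating-benefit/linear-cost:

$$\pi_C = C(1-e^{-V_c u_s}) - c_{cr}u_r - c_{cs}u_s - \alpha u_i \phi,
\qquad
\pi_N = N(1-e^{-V_n u_r}) - c_{nr}u_r - c_{ns}u_s - \beta u_i \phi,$$

with $\phi = 1-e^{-a u_h}$ the consumed fraction of the attacked tissue
$u_i$ ($u_s$ for a shoot herbivore, $u_r$ for a root herbivore). The
consumed-tissue deduction books the carbon content $\alpha u_i\phi$
against $\pi_C$ and the nitrogen content $\beta u_i\phi$ against $\pi_N$,
so consumed mass is conserved between the players. Plant fitness is
$G = E \pi_C^{\alpha}\pi_N^{\beta}$ with $\beta = 1-\alpha$ (constant
returns to scale); herbivore fitness is $u_i\phi - c_h u_h$. The ESS is a
point where each player's first derivative vanishes and second derivatives
are negative, i.e. a Nash equilibrium in simultaneous best responses —
*not* a Stackelberg solution: each first-order condition holds with the
other player's strategy fixed.

**Dead-plant convention.** $G$ is undefined for non-positive harvests; the
package defines $G = 0$ whenever $\pi_C \le 0$ or $\pi_N \le 0$ and flags
such points. This makes the fitness function total (a herbivore can kill
the plant) and keeps the solvers well behaved.

**Damage modes.** `none` (herbivore-free), `fixed` (the consumed fraction
held exogenously at $D$, the clipping-experiment analogue; the implied
foraging time $-\ln(1-D)/a$ is reported), and `dynamic` ($\phi$
co-determined with growth by the herbivore's optimal foraging).

**Gradient variants.** Differentiating the harvest equations exactly
("derived", the default) puts the consumed-fraction term in *both*
partials of the attacked tissue: a shoot herbivore contributes
$-\alpha\phi$ to $\partial\pi_C/\partial u_s$ *and* $-\beta\phi$ to
$\partial\pi_N/\partial u_s$. The tabulated variant ("table2") keeps the
herbivore term only in the attacked tissue's own-resource partial. Both
are implemented and selectable because published tabulations of this model
use the second form; the two coincide at $\phi = 0$ and differ most for
root attack (where the dropped term carries the large coefficient
$\alpha$). The published root-damage ratio band is reproduced by "table2"
only (see *Known discrepancies*), so that variant is used where results
are compared against published summaries.

## Numerics

* **Plant best response.** The first-order conditions are solved per unit
  fitness (gradient of $\log G$ — better conditioned than the raw
  gradient, identical zeros) in log-strategy space, which enforces
  positivity. Multi-start: the argmax of a coarse 30×30 fitness grid plus
  8 points drawn log-uniformly over $[10^{-2}, 10^3]^2$ from a seeded
  generator, each polished by MINPACK's Powell hybrid method. Roots are
  accepted when every scaled-FOC component is below $10^{-10}$, both net
  harvests are positive, and numerical second differences (relative step
  $10^{-5}$) are negative on both axes; among accepted roots the
  highest-$G$ one is kept. Roots are judged by their residual rather than
  the solver's status flag, which reports failure when started at an exact
  root. No live root ⇒ a non-converged result (strategies NaN), never an
  exception.
* **Nash equilibrium.** Damped fixed-point iteration on $\phi$ (damping
  0.5, tolerance $10^{-12}$, cap 500): plant best response, then the
  closed-form herbivore response $u_h^* = \max\{0, \ln(a u_i/c_h)/a\}$
  (clamped — a herbivore never forages at a loss; the interior solution is
  negative when $a u_i < c_h$). The iterate is verified against the full
  three-component stationarity system at $10^{-8}$; on failure a 3-D
  Newton polish runs from the iterate. Damping and caps affect speed only
  — any returned equilibrium passed the direct verification.
* **Grid oracle.** An independent check used by the tests: exhaustive
  vectorised fitness evaluation on a 400×400 log-spaced grid over
  $[10^{-3}, 10^4]^2$ with one refinement pass around the argmax.
* **Sweeps.** 50 evenly spaced nitrogen levels on $[5, 100]$ (the
  documented gradient; even spacing assumed, overridable), damage grid
  $[0, 0.95]$. Consecutive solves warm-start from the previous cell.
  Non-converged cells are recorded per row and excluded from summary
  statistics with a logged count.

## Experiment analysis

lnRR is computed within blocks against the $d=0$ control, with total shoot
= standing + clippings, so the metric reflects season production exactly
as the sweeps' $u^*$ values do. Trend fits treat damage as continuous.
Block structure is handled by fixed block intercepts: in this balanced
design the treatment-effect point estimates coincide with those of a
random-intercept mixed model, and the only deterministic quantity
(the expected-floor fit, slope $-1.5119$, intercept $0.0469$ on levels
$\{0,.15,.3,.45,.6\}$) is unaffected; REML machinery is deliberately out
of scope. The within-block $d=0$ anchor rows (lnRR $\equiv 0$) are
included by default: the control's residual then enters each block as a
constant, which the block intercept absorbs exactly, leaving i.i.d.
errors — confidence intervals are exact under the generator's noise
model. The slope comparison stacks observed and expected series with a
scope indicator and Wald-tests the scope×damage interaction (χ², 1 df).
Per-treatment compensation verdicts use one-sample t-tests of mean block
lnRR against zero with Holm adjustment by default (`adjust="none"` gives
per-comparison error rates; the choice of post-hoc adjustment is
underdetermined by the design).

## Synthetic data

The generator emulates the randomized complete block design: 18 blocks ×
clipping levels $\{0, 0.15, 0.30, 0.45, 0.60\}$, one plant per cell.
Expected masses are baseline × $e^{\mathrm{truth\,lnRR}(d)}$ × a
log-normal block intercept × a log-normal residual, so generated lnRR is
exactly truth + Gaussian noise and every recovery test has transparent
algebra. Truth curves are either parametric per-tissue slopes or the
model's own fixed-damage ESS solutions at a chosen nitrogen level
(default $N = 20$, mimicking a nutrient-limited pot experiment). Clipping
accounting: clippings $= d\,\times$ total shoot production, standing
$= (1-d)\times$ total — clipping removes the same fraction of every leaf,
treated as a single season-total fraction. Defaults (chosen once; no
empirical values exist for them): baselines 2 g spike / 10 g total shoot
/ 5 g root, block SD 0.25 and residual CV 0.15 on the log scale — block
variation somewhat larger than plant-level noise, as is typical of
greenhouse bench layouts. What the generator does *not* emulate: leaf
phenology and clipping timing, any mean–variance relationship beyond the
log-normal, block×treatment interactions, and measurement error in the
clipped fraction itself; passing recovery tests therefore certify the
statistical pipeline, not those aspects of real data.

## Known discrepancies

The implemented equations reproduce the model's undamaged optimum (e.g.
$(u_r^*, u_s^*) = (5.351, 7.367)$ at $N=50$, confirmed by the independent
grid oracle) and, under the "table2" variant, the published root-damage
ratio band (88–99% of undamaged root mass at 50% root damage). Two
published summary numbers are *not* reproducible from these equations
under any gradient variant, a conclusion reached by exhaustive root
enumeration of the stationarity system and a scan over the loss-term
bookkeeping:

* the dynamic-equilibrium mean damage (published ≈ 43.8% shoot / 40.2%
  root): every stationary point of the coupled system at the default
  parameters has mean $D \approx 0.80$ (shoot) / $0.72$ (root). A mean
  damage of 0.438 would require equilibrium shoot mass ≈ 2.5 g, which the
  published fixed-damage ratios themselves rule out;
* the shoot-damage ratio band (published 70–94% at 50% shoot damage):
  this model yields 95–98%; no bookkeeping of the consumed-tissue terms
  reaches both published endpoints simultaneously.

The acceptance script reports what the equations actually produce.

## Limitations

One plant, one herbivore: no plant–plant competition (hence no stem
strategy), no multi-herbivore games, no additional nutrients, no
within-season dynamics. Equilibrium uniqueness is not proven; the solver
guards against multiple roots by multi-start and best-$G$ selection, and
the tests verify global optimality only against the grid oracle's
resolution.
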