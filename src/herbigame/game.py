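"""Best responses and equilibria of the allocation game.

The herbivore's best response is closed form; the plant's is found
numerically by solving the first-order conditions in log-strategy space
(which enforces positivity) with a deterministic multi-start Powell-hybrid
root solve, keeping the highest-fitness root that passes the second-order
check.  The coupled plant--herbivore (Nash) equilibrium is found by damped
best-response iteration and verified against the full three-component
stationarity system.

The model-object entry point is :class:`PlantHerbivoreGame`; its ``fit()``
returns an :class:`Equilibrium` results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from . import fitness as fit_mod
from .fitness import PartialsMode, consumed_fraction, herbivore_fitness
from .params import (
    DamageSpec,
    Environment,
    HerbivoreParams,
    Location,
    ParameterError,
    Payoffs,
    PlantParams,
    PlantStrategy,
)


@dataclass(frozen=True)
class SolverOptions:
    """Numerical knobs for the plant best-response and Nash solves.

    ``tol`` applies to each component of the per-unit-fitness first-order
    conditions (the gradient of ``log G``); strategies are solved in log
    space from ``n_starts`` points spread log-uniformly over
    ``[start_lo, start_hi]^2`` plus a coarse-grid warm start.  Any fixed
    point of the Nash iteration is verified directly against the full
    stationarity system, so ``damping`` and the iteration caps affect speed
    only, not correctness.
    """

    tol: float = 1e-10
    n_starts: int = 8
    start_lo: float = 1e-2
    start_hi: float = 1e3
    soc_step: float = 1e-5
    damping: float = 0.5
    max_iter: int = 500
    nash_tol: float = 1e-12
    seed: int = 0


@dataclass(frozen=True)
class Equilibrium:
    """Results object for a solved game.

    Carries the equilibrium strategies, realised payoffs, the damage
    fraction ``D`` of the attacked tissue, and solver diagnostics.
    ``converged`` implies the first-order residual is below tolerance and
    the second-order (local maximum) check passed.
    """

    u_r_star: float
    u_s_star: float
    u_h_star: float
    phi_star: float
    D: float
    payoffs: Payoffs
    converged: bool
    soc_ok: bool
    mode: str
    location: Location
    partials_mode: PartialsMode
    foc_residual: float = math.nan
    n_iter: int = 0
    plant_dead: bool = False

    @property
    def strategy(self) -> PlantStrategy:
        return PlantStrategy(self.u_r_star, self.u_s_star)

    def summary(self) -> str:
        rows = [
            ("mode", self.mode),
            ("attack location", self.location),
            ("partials mode", self.partials_mode),
            ("root production u_r*", f"{self.u_r_star:.10g}"),
            ("shoot production u_s*", f"{self.u_s_star:.10g}"),
            ("herbivore time u_h*", f"{self.u_h_star:.10g}"),
            ("consumed fraction phi", f"{self.phi_star:.10g}"),
            ("damage fraction D", f"{self.D:.10g}"),
            ("net C harvest pi_C", f"{self.payoffs.pi_C:.10g}"),
            ("net N harvest pi_N", f"{self.payoffs.pi_N:.10g}"),
            ("plant fitness G", f"{self.payoffs.G_plant:.10g}"),
            ("herbivore fitness", f"{self.payoffs.G_herb:.10g}"),
            ("converged", str(self.converged)),
            ("second-order check", str(self.soc_ok)),
            ("FOC residual", f"{self.foc_residual:.3g}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Plant-herbivore game equilibrium", "=" * 34]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)


def herbivore_best_response(u_i: float, herb: HerbivoreParams) -> float:
    """Closed-form optimal foraging time ``max(0, ln(a u_i / c_h) / a)``.

    The clamp at zero encodes that a herbivore never forages at a loss
    (the interior solution is negative when ``a * u_i < c_h``).
    """
    if u_i < 0:
        raise ParameterError(f"attacked tissue mass must be non-negative, got {u_i}")
    if u_i == 0.0:
        return 0.0
    return max(0.0, math.log(herb.a * u_i / herb.c_h) / herb.a)


def _scaled_foc(
    x: np.ndarray,
    env: Environment,
    plant: PlantParams,
    phi: float,
    location: Location,
    partials_mode: PartialsMode,
) -> np.ndarray:
    """First-order conditions per unit fitness (gradient of log G) at
    log-strategies ``x``; large sentinel values on the dead branch keep the
    root solver inside the live region."""
    u_r, u_s = np.exp(x)
    s = PlantStrategy(u_r, u_s)
    pi_C = fit_mod.net_carbon(s, env, plant, phi, location)
    pi_N = fit_mod.net_nitrogen(s, env, plant, phi, location)
    if pi_C <= 0.0 or pi_N <= 0.0:
        return np.array([1e6, 1e6])
    p = fit_mod.resource_partials(s, env, plant, phi, location, partials_mode)
    return np.array(
        [
            plant.alpha * p["dpiC_dur"] / pi_C + plant.beta * p["dpiN_dur"] / pi_N,
            plant.alpha * p["dpiC_dus"] / pi_C + plant.beta * p["dpiN_dus"] / pi_N,
        ]
    )


def _soc_ok(
    s: PlantStrategy,
    env: Environment,
    plant: PlantParams,
    phi: float,
    location: Location,
    step: float,
) -> bool:
    """Second-order conditions by central second differences of G: both
    pure second derivatives negative at the candidate optimum."""
    G0 = fit_mod.plant_fitness(s, env, plant, phi, location)
    for axis in ("u_r", "u_s"):
        u = getattr(s, axis)
        h = step * max(1.0, abs(u))
        up = replace(s, **{axis: u + h})
        dn = replace(s, **{axis: max(u - h, 0.0)})
        Gp = fit_mod.plant_fitness(up, env, plant, phi, location)
        Gm = fit_mod.plant_fitness(dn, env, plant, phi, location)
        if Gp + Gm - 2.0 * G0 >= 0.0:
            return False
    return True


def _start_points(options: SolverOptions, env: Environment, plant: PlantParams,
                  phi: float, location: Location) -> list[np.ndarray]:
    """Deterministic multi-start list: low-discrepancy points over the
    log-box plus the argmax of a coarse fitness grid."""
    lo, hi = math.log(options.start_lo), math.log(options.start_hi)
    rng = np.random.default_rng(options.seed)
    pts = [rng.uniform(lo, hi, size=2) for _ in range(options.n_starts)]
    # coarse-grid warm start (vectorised evaluation of G)
    g = np.linspace(lo, hi, 30)
    UR, US = np.meshgrid(np.exp(g), np.exp(g), indexing="ij")
    G = _fitness_grid(UR, US, env, plant, phi, location)
    i, j = np.unravel_index(int(np.argmax(G)), G.shape)
    if G[i, j] > 0:
        pts.insert(0, np.array([g[i], g[j]]))
    return pts


def _fitness_grid(UR, US, env, plant, phi, location):
    """Vectorised plant fitness over strategy arrays (dead points -> 0)."""
    ui = US if location == "shoot" else (UR if location == "root" else 0.0)
    piC = env.C * -np.expm1(-plant.Vc * US) - plant.c_cr * UR - plant.c_cs * US \
        - plant.alpha * ui * phi
    piN = env.N * -np.expm1(-plant.Vn * UR) - plant.c_nr * UR - plant.c_ns * US \
        - plant.beta * ui * phi
    live = (piC > 0) & (piN > 0)
    G = np.zeros(np.broadcast(UR, US).shape)
    G[live] = plant.E * piC[live] ** plant.alpha * piN[live] ** plant.beta
    return G


def _failed(mode: str, location: Location, partials_mode: PartialsMode,
            phi: float, u_h: float, dead: bool = False) -> Equilibrium:
    return Equilibrium(
        u_r_star=math.nan, u_s_star=math.nan, u_h_star=u_h, phi_star=phi,
        D=phi, payoffs=Payoffs(math.nan, math.nan, 0.0, math.nan, phi),
        converged=False, soc_ok=False, mode=mode, location=location,
        partials_mode=partials_mode, plant_dead=dead,
    )


def plant_best_response(
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
    partials_mode: PartialsMode = "derived",
    options: SolverOptions | None = None,
    x0: np.ndarray | None = None,
    herb: HerbivoreParams | None = None,
    u_h: float | None = None,
    mode: str = "fixed",
) -> Equilibrium:
    """ESS root/shoot production against a fixed consumed fraction.

    Solves the first-order conditions from multiple starts, discards roots
    on the dead branch or failing the second-order check, and keeps the
    root with the highest fitness.  Returns a non-converged
    :class:`Equilibrium` (strategies NaN) if no live root is found; the
    caller decides how to treat it.

    ``x0`` (log-strategies) warm-starts the solve, used by sweeps and the
    Nash iteration.
    """
    if not 0.0 <= phi < 1.0:
        raise ParameterError(f"phi must lie in [0, 1), got {phi}")
    options = options or SolverOptions()
    args = (env, plant, phi, location, partials_mode)
    starts = _start_points(options, env, plant, phi, location)
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    best = None
    for start in starts:
        with np.errstate(all="ignore"):
            sol = optimize.root(_scaled_foc, start, args=args, method="hybr", tol=1e-14)
        # judge by the residual, not sol.success: MINPACK reports failure
        # when started at (or next to) an exact root
        if not np.all(np.isfinite(sol.x)):
            continue
        resid = float(np.max(np.abs(_scaled_foc(sol.x, *args))))
        if not math.isfinite(resid) or resid > options.tol:
            continue
        u_r, u_s = np.exp(sol.x)
        s = PlantStrategy(u_r, u_s)
        pi_C = fit_mod.net_carbon(s, env, plant, phi, location)
        pi_N = fit_mod.net_nitrogen(s, env, plant, phi, location)
        if pi_C <= 0.0 or pi_N <= 0.0:
            continue
        G = plant.E * pi_C**plant.alpha * pi_N**plant.beta
        if best is None or G > best[0]:
            best = (G, s, resid)
    if best is None:
        return _failed(mode, location, partials_mode, phi,
                       u_h if u_h is not None else math.nan)
    G, s, resid = best
    soc = _soc_ok(s, env, plant, phi, location, options.soc_step)
    if u_h is None:
        # implied foraging time that would produce this consumed fraction
        a = herb.a if herb is not None else HerbivoreParams().a
        u_h = -math.log1p(-phi) / a if phi > 0 else 0.0
    pay = fit_mod.payoffs(s, env, plant, phi, location, u_h=u_h, herb=herb)
    return Equilibrium(
        u_r_star=s.u_r, u_s_star=s.u_s, u_h_star=u_h, phi_star=phi, D=phi,
        payoffs=pay, converged=bool(soc), soc_ok=soc, mode=mode,
        location=location, partials_mode=partials_mode, foc_residual=resid,
    )


def solve_undamaged(
    env: Environment,
    plant: PlantParams,
    partials_mode: PartialsMode = "derived",
    options: SolverOptions | None = None,
    x0: np.ndarray | None = None,
) -> Equilibrium:
    """Growth strategy in the herbivore-free game (``u_h = 0``)."""
    return plant_best_response(
        env, plant, phi=0.0, location="none", partials_mode=partials_mode,
        options=options, x0=x0, u_h=0.0, mode="none",
    )


def solve_fixed_damage(
    env: Environment,
    plant: PlantParams,
    D: float,
    location: Location,
    partials_mode: PartialsMode = "derived",
    options: SolverOptions | None = None,
    herb: HerbivoreParams | None = None,
    x0: np.ndarray | None = None,
) -> Equilibrium:
    """Plant ESS with the consumed fraction held exogenously at ``D``."""
    if not 0.0 <= D < 1.0:
        raise ParameterError(f"fixed damage must lie in [0, 1), got {D}")
    if D == 0.0:
        eq = solve_undamaged(env, plant, partials_mode, options, x0=x0)
        return replace(eq, mode="fixed", location=location)
    return plant_best_response(
        env, plant, phi=D, location=location, partials_mode=partials_mode,
        options=options, x0=x0, herb=herb, mode="fixed",
    )


def nash_residual(
    eq: Equilibrium,
    env: Environment,
    plant: PlantParams,
    herb: HerbivoreParams,
    partials_mode: PartialsMode = "derived",
) -> float:
    """Max-norm of the full three-component stationarity system at ``eq``:
    the two plant FOCs (per unit fitness) plus the herbivore FOC
    ``a u_i e^{-a u_h} - c_h`` (or the clamp condition at ``u_h = 0``)."""
    x = np.log([eq.u_r_star, eq.u_s_star])
    plant_res = np.max(np.abs(_scaled_foc(x, env, plant, eq.phi_star,
                                          herb.location, partials_mode)))
    u_i = eq.strategy.attacked_mass(herb.location)
    herb_marg = herb.a * u_i * math.exp(-herb.a * eq.u_h_star) - herb.c_h
    herb_res = abs(herb_marg) if eq.u_h_star > 0 else max(0.0, herb_marg)
    return float(max(plant_res, herb_res))


def solve_dynamic(
    env: Environment,
    plant: PlantParams,
    herb: HerbivoreParams,
    partials_mode: PartialsMode = "derived",
    options: SolverOptions | None = None,
    x0: np.ndarray | None = None,
) -> Equilibrium:
    """Simultaneous (Nash) equilibrium of plant growth and herbivore
    foraging: the plant strategy is a best response to the herbivore's
    consumed fraction, and the foraging time is the closed-form best
    response to the attacked tissue mass.

    Damped best-response iteration on the consumed fraction; the returned
    point is verified against the full stationarity system.  If the
    herbivore drives the plant to death (no live fixed point) the
    plant-dead outcome is returned, flagged, with zero plant fitness.
    """
    if herb.location not in ("shoot", "root"):
        raise ParameterError("dynamic damage requires herb.location shoot|root")
    options = options or SolverOptions()
    phi = 0.0
    warm = x0
    eq = None
    for it in range(1, options.max_iter + 1):
        eq = plant_best_response(
            env, plant, phi=phi, location=herb.location,
            partials_mode=partials_mode, options=options, x0=warm,
            herb=herb, mode="dynamic",
        )
        if not eq.converged:
            return replace(_failed("dynamic", herb.location, partials_mode,
                                   phi, math.nan, dead=True), n_iter=it)
        warm = np.log([eq.u_r_star, eq.u_s_star])
        u_i = eq.strategy.attacked_mass(herb.location)
        u_h = herbivore_best_response(u_i, herb)
        phi_new = consumed_fraction(u_h, herb)
        if abs(phi_new - phi) < options.nash_tol:
            phi = phi_new
            break
        phi = (1.0 - options.damping) * phi + options.damping * phi_new
    u_i = eq.strategy.attacked_mass(herb.location)
    u_h = herbivore_best_response(u_i, herb)
    eq = replace(
        eq,
        u_h_star=u_h,
        phi_star=phi,
        D=phi,
        n_iter=it,
        payoffs=fit_mod.payoffs(eq.strategy, env, plant, phi, herb.location,
                                u_h=u_h, herb=herb),
    )
    resid = nash_residual(eq, env, plant, herb, partials_mode)
    if resid > 1e-8:
        # fall back: polish the full 3-d system from the iterate
        def system(z):
            u_r, u_s = np.exp(z[:2])
            ph = 1.0 - math.exp(-herb.a * max(z[2], 0.0))
            r = _scaled_foc(z[:2], env, plant, ph, herb.location, partials_mode)
            ui = u_s if herb.location == "shoot" else u_r
            return np.array([r[0], r[1],
                             herb.a * ui * math.exp(-herb.a * z[2]) - herb.c_h])

        with np.errstate(all="ignore"):
            sol = optimize.root(system, np.array([*np.log([eq.u_r_star, eq.u_s_star]),
                                                  max(u_h, 1e-6)]), tol=1e-14)
        if sol.success:
            u_r, u_s = np.exp(sol.x[:2])
            u_h = max(sol.x[2], 0.0)
            phi = consumed_fraction(u_h, herb)
            s = PlantStrategy(u_r, u_s)
            eq = replace(
                eq, u_r_star=u_r, u_s_star=u_s, u_h_star=u_h, phi_star=phi, D=phi,
                payoffs=fit_mod.payoffs(s, env, plant, phi, herb.location,
                                        u_h=u_h, herb=herb),
            )
            resid = nash_residual(eq, env, plant, herb, partials_mode)
    soc = _soc_ok(eq.strategy, env, plant, phi, herb.location, options.soc_step)
    return replace(eq, foc_residual=resid, soc_ok=soc,
                   converged=bool(resid <= 1e-8 and soc))


def grid_oracle(
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
    n_grid: int = 400,
    bounds: tuple[float, float] = (1e-3, 1e4),
    refine: bool = True,
) -> tuple[float, float, float]:
    """Exhaustive log-spaced grid search for the plant optimum, with one
    local refinement pass around the coarse argmax.  A validation oracle:
    slow, independent of the root solver, used in tests."""
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    gr = gs = np.linspace(lo, hi, n_grid)
    for _ in range(2 if refine else 1):
        UR, US = np.meshgrid(np.exp(gr), np.exp(gs), indexing="ij")
        G = _fitness_grid(UR, US, env, plant, phi, location)
        i, j = np.unravel_index(int(np.argmax(G)), G.shape)
        dr = gr[1] - gr[0]
        ds = gs[1] - gs[0]
        best = (float(UR[i, j]), float(US[i, j]), float(G[i, j]))
        gr = np.linspace(gr[i] - dr, gr[i] + dr, n_grid)
        gs = np.linspace(gs[j] - ds, gs[j] + ds, n_grid)
    return best


class PlantHerbivoreGame:
    """Model object for one plant--herbivore game instance.

    Parameters
    ----------
    plant, env : the plant physiology and resource environment.
    herbivore : required for dynamic damage; supplies ``a``/``c_h`` for the
        implied foraging time otherwise.
    damage : a :class:`~herbigame.params.DamageSpec` choosing between the
        herbivore-free game, exogenously fixed damage, and damage
        co-determined by herbivore foraging.
    partials_mode : "derived" (exact differentiation of the harvest
        equations) or "table2" (the tabulated variant).
    options : solver tolerances and start points.

    ``fit()`` returns an :class:`Equilibrium` results object.
    """

    def __init__(
        self,
        plant: PlantParams | None = None,
        herbivore: HerbivoreParams | None = None,
        env: Environment | None = None,
        damage: DamageSpec | None = None,
        partials_mode: PartialsMode = "derived",
        options: SolverOptions | None = None,
    ) -> None:
        self.plant = plant or PlantParams()
        self.env = env or Environment()
        self.damage = damage or DamageSpec()
        self.herbivore = herbivore
        if self.damage.mode == "dynamic":
            if self.herbivore is None:
                self.herbivore = HerbivoreParams(location=self.damage.location)
            elif self.herbivore.location != self.damage.location:
                raise ParameterError("damage.location and herbivore.location disagree")
        self.partials_mode = partials_mode
        self.options = options or SolverOptions()

    def fit(self, x0: np.ndarray | None = None) -> Equilibrium:
        d = self.damage
        if d.mode == "none":
            return solve_undamaged(self.env, self.plant, self.partials_mode,
                                   self.options, x0=x0)
        if d.mode == "fixed":
            return solve_fixed_damage(self.env, self.plant, d.D_fixed, d.location,
                                      self.partials_mode, self.options,
                                      herb=self.herbivore, x0=x0)
        return solve_dynamic(self.env, self.plant, self.herbivore,
                             self.partials_mode, self.options, x0=x0)
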