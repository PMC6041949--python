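"""Numerical experiments over nitrogen and damage gradients.

Each sweep pairs every damaged equilibrium with the undamaged equilibrium
at the same nitrogen level and attaches log response ratios
``lnRR = ln(damaged / undamaged)`` for fruit (fitness), shoot and root
production, plus the no-compensation floor ``ln(1 - D)``.  lnRR uses the
strategy values ``u*`` (season-total production), matching the experiment's
"standing + clipped" accounting.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .game import (
    Equilibrium,
    SolverOptions,
    solve_dynamic,
    solve_fixed_damage,
    solve_undamaged,
)
from .fitness import PartialsMode
from .params import Environment, HerbivoreParams, Location, ParameterError, PlantParams

logger = logging.getLogger(__name__)

#: Columns of a sweep table, in stable output order.
SWEEP_COLUMNS = [
    "N", "damage_mode", "location", "D", "partials_mode",
    "u_r", "u_s", "u_h", "pi_C", "pi_N", "G",
    "lnRR_fruit", "lnRR_shoot", "lnRR_root", "null_floor", "converged",
]


def default_nitrogen_grid(n: int = 50, lo: float = 5.0, hi: float = 100.0) -> np.ndarray:
    """Evenly spaced nitrogen availabilities, 50 points on [5, 100] by
    default (the model's standard gradient)."""
    return np.linspace(lo, hi, n)


def default_damage_grid(n: int = 20, hi: float = 0.95) -> np.ndarray:
    """Evenly spaced damage fractions on [0, 0.95]."""
    return np.linspace(0.0, hi, n)


def ln_rr(value_damaged: float, value_undamaged: float) -> float:
    """Log response ratio ``ln(damaged / undamaged)``.

    Positive values indicate overcompensation, zero perfect compensation,
    negative undercompensation.
    """
    if value_damaged <= 0 or value_undamaged <= 0:
        raise ParameterError(
            "lnRR requires positive inputs, got "
            f"({value_damaged}, {value_undamaged})"
        )
    return math.log(value_damaged / value_undamaged)


def null_floor(D: float) -> float:
    """Expected lnRR of the attacked tissue with no compensatory response:
    a plant that loses fraction ``D`` and does not regrow sits at
    ``ln(1 - D)``."""
    if not 0.0 <= D < 1.0:
        raise ParameterError(f"damage fraction must lie in [0, 1), got {D}")
    return math.log1p(-D)


def damage_fraction(eq: Equilibrium, herb: HerbivoreParams) -> float:
    """Proportion of the attacked tissue consumed, ``1 - e^{-a u_h*}``.

    At an interior herbivore optimum this equals ``1 - c_h / (a u_i*)``.
    """
    return -math.expm1(-herb.a * eq.u_h_star)


def _row(eq: Equilibrium, N: float, base: Equilibrium | None) -> dict:
    row = {
        "N": N, "damage_mode": eq.mode, "location": eq.location,
        "D": eq.D, "partials_mode": eq.partials_mode,
        "u_r": eq.u_r_star, "u_s": eq.u_s_star, "u_h": eq.u_h_star,
        "pi_C": eq.payoffs.pi_C, "pi_N": eq.payoffs.pi_N,
        "G": eq.payoffs.G_plant,
        "lnRR_fruit": math.nan, "lnRR_shoot": math.nan, "lnRR_root": math.nan,
        "null_floor": math.nan, "converged": eq.converged,
    }
    if eq.converged and base is not None and base.converged:
        row["lnRR_fruit"] = ln_rr(eq.payoffs.G_plant, base.payoffs.G_plant)
        row["lnRR_shoot"] = ln_rr(eq.u_s_star, base.u_s_star)
        row["lnRR_root"] = ln_rr(eq.u_r_star, base.u_r_star)
        row["null_floor"] = null_floor(eq.D)
    return row


def sweep_fixed(
    env_grid: np.ndarray | None = None,
    damage_grid: np.ndarray | None = None,
    location: Location = "shoot",
    plant: PlantParams | None = None,
    partials_mode: PartialsMode = "derived",
    C: float = 5000.0,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Fixed-damage experiment: for each nitrogen level solve the
    undamaged game once, then the plant best response at every damage
    fraction, pairing each damaged cell with its same-N baseline.

    Per-cell non-convergence is recorded in the table, not raised.
    Deterministic given inputs.
    """
    env_grid = default_nitrogen_grid() if env_grid is None else np.asarray(env_grid, float)
    damage_grid = default_damage_grid() if damage_grid is None else np.asarray(damage_grid, float)
    if env_grid.size == 0 or damage_grid.size == 0:
        raise ParameterError("sweep grids must be non-empty")
    plant = plant or PlantParams()
    rows = []
    warm_base = None
    warm_dmg: dict[float, np.ndarray] = {}
    for N in env_grid:
        env = Environment(C=C, N=float(N))
        base = solve_undamaged(env, plant, partials_mode, options, x0=warm_base)
        if base.converged:
            warm_base = np.log([base.u_r_star, base.u_s_star])
        rows.append(_row(base, float(N), None) | {"damage_mode": "fixed",
                                                  "location": location,
                                                  "lnRR_fruit": 0.0 if base.converged else math.nan,
                                                  "lnRR_shoot": 0.0 if base.converged else math.nan,
                                                  "lnRR_root": 0.0 if base.converged else math.nan,
                                                  "null_floor": 0.0})
        for D in damage_grid:
            if D == 0.0:
                continue
            eq = solve_fixed_damage(env, plant, float(D), location, partials_mode,
                                    options, x0=warm_dmg.get(float(D), warm_base))
            if eq.converged:
                warm_dmg[float(D)] = np.log([eq.u_r_star, eq.u_s_star])
            rows.append(_row(eq, float(N), base))
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    n_bad = int((~table["converged"]).sum())
    if n_bad:
        logger.warning("sweep_fixed: %d non-converged cells excluded from lnRR", n_bad)
    table.attrs["n_nonconverged"] = n_bad
    return table


def sweep_dynamic(
    env_grid: np.ndarray | None = None,
    location: Location = "shoot",
    plant: PlantParams | None = None,
    herb: HerbivoreParams | None = None,
    partials_mode: PartialsMode = "derived",
    C: float = 5000.0,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Dynamic-damage experiment: at each nitrogen level solve the coupled
    plant--herbivore equilibrium and pair it with the undamaged game.

    The unweighted mean damage fraction over converged cells is stored in
    ``table.attrs['mean_D']``.
    """
    env_grid = default_nitrogen_grid() if env_grid is None else np.asarray(env_grid, float)
    if env_grid.size == 0:
        raise ParameterError("nitrogen grid must be non-empty")
    plant = plant or PlantParams()
    herb = herb or HerbivoreParams(location=location)
    if herb.location != location:
        raise ParameterError("herb.location and sweep location disagree")
    rows = []
    warm_base = warm_dyn = None
    for N in env_grid:
        env = Environment(C=C, N=float(N))
        base = solve_undamaged(env, plant, partials_mode, options, x0=warm_base)
        if base.converged:
            warm_base = np.log([base.u_r_star, base.u_s_star])
        eq = solve_dynamic(env, plant, herb, partials_mode, options,
                           x0=warm_dyn if warm_dyn is not None else warm_base)
        if eq.converged:
            warm_dyn = np.log([eq.u_r_star, eq.u_s_star])
        rows.append(_row(eq, float(N), base))
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    ok = table["converged"]
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("sweep_dynamic: %d non-converged cells excluded", n_bad)
    table.attrs["n_nonconverged"] = n_bad
    table.attrs["mean_D"] = float(table.loc[ok, "D"].mean()) if ok.any() else math.nan
    return table


def mean_damage(table: pd.DataFrame) -> float:
    """Unweighted arithmetic mean damage fraction over converged cells."""
    ok = table["converged"].astype(bool)
    return float(table.loc[ok, "D"].mean())


def write_sweep(table: pd.DataFrame, path) -> None:
    """Write a sweep table as CSV with 10 significant digits."""
    table.to_csv(path, index=False, float_format="%.10g")
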