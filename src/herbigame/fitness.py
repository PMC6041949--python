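"""Fitness and payoff equations of the plant--herbivore game.

Net harvests are saturating-benefit / linear-cost:

.. math::

    \\pi_C = C\\,(1 - e^{-V_c u_s}) - c_{cr} u_r - c_{cs} u_s
             - \\alpha\\, u_i\\, \\phi,

    \\pi_N = N\\,(1 - e^{-V_n u_r}) - c_{nr} u_r - c_{ns} u_s
             - \\beta\\, u_i\\, \\phi,

where :math:`u_i` is the attacked tissue (shoot or root) and
:math:`\\phi = 1 - e^{-a u_h}` the consumed fraction.  Plant fitness is
:math:`G = E\\, \\pi_C^{\\alpha} \\pi_N^{\\beta}` on the live domain
(:math:`\\pi_C, \\pi_N > 0`) and zero otherwise.  Herbivore fitness is
:math:`u_i \\phi - c_h u_h`.

Two variants of the analytic partial derivatives are provided (see
``partials_mode``): ``"derived"`` differentiates the harvest equations
exactly as written, so the consumed-fraction term appears in *both* partial
derivatives of the attacked tissue; ``"table2"`` keeps the herbivore term
only in the attacked tissue's own-resource partial (the variant the source
model tabulates).  The two coincide whenever ``phi == 0``.
"""

from __future__ import annotations

import math
from typing import Literal

from .params import (
    DeadPlantError,
    Environment,
    HerbivoreParams,
    Location,
    ParameterError,
    Payoffs,
    PlantParams,
    PlantStrategy,
)

PartialsMode = Literal["derived", "table2"]


def _check_phi(phi: float) -> None:
    if not 0.0 <= phi < 1.0:
        raise ParameterError(f"consumed fraction phi must lie in [0, 1), got {phi}")


def consumed_fraction(u_h: float, herb: HerbivoreParams) -> float:
    """Fraction of attacked tissue consumed after foraging time ``u_h``."""
    if u_h < 0:
        raise ParameterError(f"foraging time must be non-negative, got {u_h}")
    if herb.location == "none":
        return 0.0
    return -math.expm1(-herb.a * u_h)


def net_carbon(
    strategy: PlantStrategy,
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
) -> float:
    """Net carbon harvest: saturating photosynthesis minus construction
    costs minus the carbon content of consumed tissue.  May be negative."""
    _check_phi(phi)
    u_i = strategy.attacked_mass(location)
    return (
        env.C * -math.expm1(-plant.Vc * strategy.u_s)
        - plant.c_cr * strategy.u_r
        - plant.c_cs * strategy.u_s
        - plant.alpha * u_i * phi
    )


def net_nitrogen(
    strategy: PlantStrategy,
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
) -> float:
    """Net nitrogen harvest, mirror of :func:`net_carbon`."""
    _check_phi(phi)
    u_i = strategy.attacked_mass(location)
    return (
        env.N * -math.expm1(-plant.Vn * strategy.u_r)
        - plant.c_nr * strategy.u_r
        - plant.c_ns * strategy.u_s
        - plant.beta * u_i * phi
    )


def plant_fitness(
    strategy: PlantStrategy,
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
) -> float:
    """Reproductive output ``E * pi_C^alpha * pi_N^beta``.

    Returns 0 whenever either net harvest is non-positive (dead-plant
    convention): the Cobb-Douglas form is undefined there and a plant that
    cannot cover the cost of its own tissues sets no seed.
    """
    pi_C = net_carbon(strategy, env, plant, phi, location)
    pi_N = net_nitrogen(strategy, env, plant, phi, location)
    if pi_C <= 0.0 or pi_N <= 0.0:
        return 0.0
    return plant.E * pi_C**plant.alpha * pi_N**plant.beta


def herbivore_fitness(u_h: float, u_i: float, herb: HerbivoreParams) -> float:
    """Herbivore net harvest ``u_i (1 - e^{-a u_h}) - c_h u_h``."""
    if u_h < 0:
        raise ParameterError(f"foraging time must be non-negative, got {u_h}")
    return u_i * -math.expm1(-herb.a * u_h) - herb.c_h * u_h


def payoffs(
    strategy: PlantStrategy,
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
    u_h: float = 0.0,
    herb: HerbivoreParams | None = None,
) -> Payoffs:
    """Bundle both players' payoffs at a strategy profile."""
    pi_C = net_carbon(strategy, env, plant, phi, location)
    pi_N = net_nitrogen(strategy, env, plant, phi, location)
    G = 0.0
    if pi_C > 0.0 and pi_N > 0.0:
        G = plant.E * pi_C**plant.alpha * pi_N**plant.beta
    G_h = 0.0
    if herb is not None and location != "none":
        G_h = herbivore_fitness(u_h, strategy.attacked_mass(location), herb)
    return Payoffs(pi_C=pi_C, pi_N=pi_N, G_plant=G, G_herb=G_h, phi=phi)


def resource_partials(
    strategy: PlantStrategy,
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
    partials_mode: PartialsMode = "derived",
) -> dict[str, float]:
    """The four partial derivatives of the net harvests.

    Keys: ``dpiC_dur``, ``dpiC_dus``, ``dpiN_dur``, ``dpiN_dus``.
    """
    _check_phi(phi)
    if partials_mode not in ("derived", "table2"):
        raise ParameterError(f"unknown partials_mode {partials_mode!r}")
    d = {
        "dpiC_dur": -plant.c_cr,
        "dpiC_dus": env.C * plant.Vc * math.exp(-plant.Vc * strategy.u_s) - plant.c_cs,
        "dpiN_dur": env.N * plant.Vn * math.exp(-plant.Vn * strategy.u_r) - plant.c_nr,
        "dpiN_dus": -plant.c_ns,
    }
    if location == "shoot":
        d["dpiC_dus"] -= plant.alpha * phi
        if partials_mode == "derived":
            d["dpiN_dus"] -= plant.beta * phi
    elif location == "root":
        d["dpiN_dur"] -= plant.beta * phi
        if partials_mode == "derived":
            d["dpiC_dur"] -= plant.alpha * phi
    return d


def plant_gradient(
    strategy: PlantStrategy,
    env: Environment,
    plant: PlantParams,
    phi: float = 0.0,
    location: Location = "none",
    partials_mode: PartialsMode = "derived",
) -> tuple[float, float]:
    """Chain-rule gradient ``(dG/du_r, dG/du_s)`` of plant fitness.

    Only defined on the live branch; evaluating at a dead-plant point
    raises :class:`~herbigame.params.DeadPlantError`.
    """
    pi_C = net_carbon(strategy, env, plant, phi, location)
    pi_N = net_nitrogen(strategy, env, plant, phi, location)
    if pi_C <= 0.0 or pi_N <= 0.0:
        raise DeadPlantError(
            f"gradient undefined at dead-plant point (pi_C={pi_C:.4g}, pi_N={pi_N:.4g})"
        )
    p = resource_partials(strategy, env, plant, phi, location, partials_mode)
    a, b = plant.alpha, plant.beta
    common = plant.E * pi_C ** (a - 1.0) * pi_N ** (b - 1.0)
    dG_dur = common * (a * pi_N * p["dpiC_dur"] + b * pi_C * p["dpiN_dur"])
    dG_dus = common * (a * pi_N * p["dpiC_dus"] + b * pi_C * p["dpiN_dus"])
    return dG_dur, dG_dus
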