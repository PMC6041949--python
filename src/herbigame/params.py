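"""Parameter containers for the plant--herbivore allocation game.

The game has two players. The plant chooses season-total root and shoot
production (grams of tissue); its fitness is a Cobb-Douglas product of net
carbon and net nitrogen harvest, weighted by seed stoichiometry.  The
herbivore chooses foraging time; it consumes a saturating fraction
``1 - exp(-a * u_h)`` of the attacked tissue.  All parameters are in the
abstract "example units" of the source model; only ratios matter to the
equilibrium structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal, Mapping

import yaml

Location = Literal["shoot", "root", "none"]

#: Flat config keys accepted by :func:`params_from_config`.
CONFIG_KEYS = (
    "alpha", "Vc", "Vn", "c_cs", "c_cr", "c_ns", "c_nr", "E",
    "a", "c_h", "C", "N",
)


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain invariants."""


class DeadPlantError(ValueError):
    """Raised when a quantity is requested at a point where the plant is
    dead (non-positive net harvest of carbon or nitrogen)."""


@dataclass(frozen=True)
class PlantParams:
    """Physiological constants defining the plant's fitness surface.

    Parameters
    ----------
    alpha : float
        Carbon fraction of seed/tissue mass.  The nitrogen fraction is
        ``beta = 1 - alpha`` by assumption (constant returns to scale), so
        beta is a derived property, not an independent field.
    Vc, Vn : float
        Encounter rates between photosynthetic apparatus and CO2 (per unit
        shoot) and between uptake apparatus and inorganic N (per unit root).
    c_cs, c_cr : float
        Carbon construction + maintenance cost per unit shoot / root.
    c_ns, c_nr : float
        Nitrogen cost per unit shoot / root.
    E : float
        Conversion factor from the resource-harvest product to reproductive
        output.
    """

    alpha: float = 0.95
    Vc: float = 1.0
    Vn: float = 1.0
    c_cs: float = 3.0
    c_cr: float = 1.2
    c_ns: float = 0.03
    c_nr: float = 0.01
    E: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("Vc", "Vn", "c_cs", "c_cr", "c_ns", "c_nr", "E"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def beta(self) -> float:
        """Nitrogen fraction of seed mass, ``1 - alpha`` (enforced)."""
        return 1.0 - self.alpha


@dataclass(frozen=True)
class HerbivoreParams:
    """Herbivore foraging constants and attack location.

    ``a`` is the encounter rate between herbivore and plant tissue (search
    efficiency, per day); ``c_h`` the plant-tissue mass required to fuel one
    unit of foraging time.  ``location='none'`` denotes the herbivore-free
    game (foraging time identically zero).
    """

    a: float = 0.7
    c_h: float = 1.0
    location: Location = "shoot"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ParameterError(f"a must be > 0, got {self.a}")
        if self.c_h <= 0:
            raise ParameterError(f"c_h must be > 0, got {self.c_h}")
        if self.location not in ("shoot", "root", "none"):
            raise ParameterError(f"location must be shoot|root|none, got {self.location!r}")


@dataclass(frozen=True)
class Environment:
    """Season resource totals: maximum harvestable carbon and nitrogen."""

    C: float = 5000.0
    N: float = 50.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.N <= 0:
            raise ParameterError(f"C and N must be > 0, got C={self.C}, N={self.N}")


@dataclass(frozen=True)
class PlantStrategy:
    """The plant's decision variables: root and shoot production (g)."""

    u_r: float
    u_s: float

    def __post_init__(self) -> None:
        if self.u_r < 0 or self.u_s < 0:
            raise ParameterError(
                f"strategies must be non-negative, got u_r={self.u_r}, u_s={self.u_s}"
            )

    def attacked_mass(self, location: Location) -> float:
        """Mass of the attacked tissue ``u_i`` (0 when no herbivore)."""
        if location == "shoot":
            return self.u_s
        if location == "root":
            return self.u_r
        return 0.0


@dataclass(frozen=True)
class Payoffs:
    """Realised payoffs at a strategy profile.

    ``phi`` is the consumed fraction of the attacked tissue,
    ``1 - exp(-a*u_h)``; ``G_plant`` is zero whenever either net harvest is
    non-positive (dead-plant convention).
    """

    pi_C: float
    pi_N: float
    G_plant: float
    G_herb: float
    phi: float


@dataclass(frozen=True)
class DamageSpec:
    """How herbivore damage enters a game.

    mode='none'
        Herbivore-free game; consumed fraction is identically zero.
    mode='fixed'
        The consumed fraction is held exogenously at ``D_fixed`` while the
        plant plays a best response (clipping-style damage).
    mode='dynamic'
        The consumed fraction is co-determined with plant growth by the
        herbivore's own optimal foraging.
    """

    mode: Literal["none", "fixed", "dynamic"] = "none"
    D_fixed: float = 0.0
    location: Location = "shoot"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed", "dynamic"):
            raise ParameterError(f"unknown damage mode {self.mode!r}")
        if self.mode == "fixed" and not 0.0 <= self.D_fixed < 1.0:
            raise ParameterError(f"fixed damage must lie in [0, 1), got {self.D_fixed}")
        if self.mode in ("fixed", "dynamic") and self.location not in ("shoot", "root"):
            raise ParameterError("fixed/dynamic damage requires location shoot|root")


def params_to_config(
    plant: PlantParams, herb: HerbivoreParams, env: Environment
) -> dict[str, float]:
    """Flatten a parameter set to the canonical key-value config mapping."""
    return {
        "alpha": plant.alpha, "Vc": plant.Vc, "Vn": plant.Vn,
        "c_cs": plant.c_cs, "c_cr": plant.c_cr,
        "c_ns": plant.c_ns, "c_nr": plant.c_nr, "E": plant.E,
        "a": herb.a, "c_h": herb.c_h,
        "C": env.C, "N": env.N,
    }


def params_from_config(
    mapping: Mapping[str, float],
    location: Location = "shoot",
) -> tuple[PlantParams, HerbivoreParams, Environment]:
    """Build parameter objects from a flat config mapping.

    Unknown keys are rejected; missing keys fall back to the defaults.
    """
    unknown = set(mapping) - set(CONFIG_KEYS)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    m = dict(mapping)
    plant = PlantParams(
        alpha=m.get("alpha", 0.95), Vc=m.get("Vc", 1.0), Vn=m.get("Vn", 1.0),
        c_cs=m.get("c_cs", 3.0), c_cr=m.get("c_cr", 1.2),
        c_ns=m.get("c_ns", 0.03), c_nr=m.get("c_nr", 0.01), E=m.get("E", 0.1),
    )
    herb = HerbivoreParams(a=m.get("a", 0.7), c_h=m.get("c_h", 1.0), location=location)
    env = Environment(C=m.get("C", 5000.0), N=m.get("N", 50.0))
    return plant, herb, env


def save_config(path, plant: PlantParams, herb: HerbivoreParams, env: Environment) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_config(plant, herb, env), fh, sort_keys=False)


def load_config(path, location: Location = "shoot"):
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ParameterError("config file must hold a flat key-value mapping")
    return params_from_config(mapping, location=location)
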