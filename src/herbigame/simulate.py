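"""Synthetic randomized-complete-block clipping experiments.

The generator emulates the greenhouse design the analysis module targets:
``n_blocks`` blocks, each holding one plant per clipping level, with
multiplicative (log-normal) block and residual noise around known
per-tissue compensation curves.  Because the noise is multiplicative, the
block-paired lnRR of a generated dataset is exactly

.. math:: \\mathrm{lnRR}_{b,d} = \\mathrm{truth}(d) + \\epsilon_{b,d} - \\epsilon_{b,0},

with Gaussian ``epsilon`` — the recovery algebra for the analysis pipeline
is transparent, and the generating truth is available from
:func:`truth_report` for parameter-recovery tests.

Truth curves come either from per-tissue linear log-effect slopes
(``effect='parametric'``) or from the allocation game itself
(``effect='model'``: fixed-damage ESS solutions at a chosen nitrogen
level, low by default to mimic a nutrient-limited pot experiment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import SolverOptions, solve_fixed_damage, solve_undamaged
from .params import Environment, ParameterError, PlantParams
from .sweeps import ln_rr

DEFAULT_D_LEVELS = (0.0, 0.15, 0.30, 0.45, 0.60)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic experiment.

    Defaults follow the design the analysis emulates: 18 blocks x clipping
    levels {0, 15, 30, 45, 60}%.  Baseline control masses are round
    numbers (only ratios reach any downstream statistic); block and
    residual scales are log-normal standard deviations / coefficients of
    variation on the natural-log scale.
    """

    n_blocks: int = 18
    d_levels: tuple[float, ...] = DEFAULT_D_LEVELS
    baseline_spike: float = 2.0
    baseline_shoot: float = 10.0
    baseline_root: float = 5.0
    block_sd: float = 0.25
    residual_cv: float = 0.15
    effect: str = "parametric"          # 'parametric' | 'model'
    slopes: tuple[float, float, float] = (-0.8, -1.0, -0.3)  # fruit, shoot, root
    model_N: float = 20.0
    model_location: str = "shoot"
    partials_mode: str = "derived"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ParameterError("need at least 2 blocks")
        if 0.0 not in self.d_levels:
            raise ParameterError("d_levels must include the control (0)")
        if any(not 0.0 <= d < 1.0 for d in self.d_levels):
            raise ParameterError("d_levels must lie in [0, 1)")
        for name in ("baseline_spike", "baseline_shoot", "baseline_root"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.block_sd < 0 or self.residual_cv < 0:
            raise ParameterError("noise scales must be >= 0")
        if self.effect not in ("parametric", "model"):
            raise ParameterError("effect must be 'parametric' or 'model'")


def truth_report(spec: GeneratorSpec) -> pd.DataFrame:
    """The generating lnRR curves, one row per treatment level with
    columns ``lnRR_fruit``, ``lnRR_shoot``, ``lnRR_root``."""
    d = np.asarray(sorted(spec.d_levels), dtype=float)
    if spec.effect == "parametric":
        sf, ss, sr = spec.slopes
        return pd.DataFrame({
            "d": d, "lnRR_fruit": sf * d, "lnRR_shoot": ss * d, "lnRR_root": sr * d,
        })
    plant = PlantParams()
    env = Environment(N=spec.model_N)
    base = solve_undamaged(env, plant, spec.partials_mode)
    if not base.converged:
        raise ParameterError("model-linked truth: undamaged game did not converge")
    rows = []
    warm = np.log([base.u_r_star, base.u_s_star])
    for dv in d:
        if dv == 0.0:
            rows.append({"d": 0.0, "lnRR_fruit": 0.0, "lnRR_shoot": 0.0, "lnRR_root": 0.0})
            continue
        eq = solve_fixed_damage(env, plant, float(dv), spec.model_location,
                                spec.partials_mode, x0=warm)
        if not eq.converged:
            raise ParameterError(f"model-linked truth: no ESS at d={dv}")
        rows.append({
            "d": float(dv),
            "lnRR_fruit": ln_rr(eq.payoffs.G_plant, base.payoffs.G_plant),
            "lnRR_shoot": ln_rr(eq.u_s_star, base.u_s_star),
            "lnRR_root": ln_rr(eq.u_r_star, base.u_r_star),
        })
    return pd.DataFrame(rows)


def generate_experiment(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw one synthetic experiment as a tidy records table.

    Per block: a multiplicative log-normal block intercept shared by all
    tissues; per plant and tissue: expected mass = baseline x
    exp(truth lnRR(d)) x block intercept x log-normal residual.  Clipping
    accounting: the season-total shoot production is split as
    ``clippings = d * total`` and ``standing = (1 - d) * total`` —
    clipping removes fraction ``d`` of every leaf, so the saved clippings
    are that fraction of total production.

    Deterministic under the spec's seed; the truth curves are
    seed-invariant.
    """
    rng = np.random.default_rng(spec.seed)
    truth = truth_report(spec).set_index("d")
    base = {"fruit": spec.baseline_spike, "shoot": spec.baseline_shoot,
            "root": spec.baseline_root}
    rows = []
    for b in range(1, spec.n_blocks + 1):
        block_effect = math.exp(rng.normal(0.0, spec.block_sd))
        for d in sorted(spec.d_levels):
            mass = {}
            for tissue in ("fruit", "shoot", "root"):
                eps = rng.normal(0.0, spec.residual_cv)
                mass[tissue] = (base[tissue] * math.exp(truth.loc[d, f"lnRR_{tissue}"])
                                * block_effect * math.exp(eps))
            clippings = d * mass["shoot"]
            if clippings > mass["shoot"]:
                raise ParameterError("clipping accounting produced clippings > total")
            rows.append({
                "block": f"B{b:02d}", "d": float(d),
                "spike_g": mass["fruit"],
                "shoot_standing_g": mass["shoot"] - clippings,
                "clippings_g": clippings,
                "root_g": mass["root"],
            })
    return pd.DataFrame(rows)


def write_experiment_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
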