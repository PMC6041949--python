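import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbigame import (
    DamageSpec,
    Environment,
    HerbivoreParams,
    PlantHerbivoreGame,
    PlantParams,
    PlantStrategy,
    grid_oracle,
    herbivore_best_response,
    herbivore_fitness,
    nash_residual,
    plant_fitness,
    solve_dynamic,
    solve_fixed_damage,
    solve_undamaged,
)
from conftest import random_live_point


class TestHerbivoreBestResponse:
    def test_break_even_boundary_and_clamp(self, shoot_herb):
        boundary = shoot_herb.c_h / shoot_herb.a
        assert herbivore_best_response(boundary, shoot_herb) == 0.0
        assert herbivore_best_response(0.5 * boundary, shoot_herb) == 0.0
        assert herbivore_best_response(0.0, shoot_herb) == 0.0

    def test_closed_form_matches_grid_search(self, shoot_herb):
        u_i = 10.0
        star = herbivore_best_response(u_i, shoot_herb)
        assert star == pytest.approx(math.log(7.0) / 0.7, rel=1e-12)
        grid = np.linspace(0.0, 20.0, 200001)
        payoff = u_i * (1 - np.exp(-shoot_herb.a * grid)) - shoot_herb.c_h * grid
        assert abs(grid[int(np.argmax(payoff))] - star) < 2e-4

    @settings(derandomize=True, max_examples=60)
    @given(u_i=st.floats(0.0, 1e4), a=st.floats(0.05, 5.0), c_h=st.floats(0.05, 5.0))
    def test_best_response_dominates_any_finite_deviation(self, u_i, a, c_h):
        from herbigame import HerbivoreParams, herbivore_fitness

        herb = HerbivoreParams(a=a, c_h=c_h, location="shoot")
        star = herbivore_best_response(u_i, herb)
        g_star = herbivore_fitness(star, u_i, herb)
        for u_h in (0.0, 0.5 * star, 2.0 * star + 0.1, 10.0):
            assert herbivore_fitness(u_h, u_i, herb) <= g_star + 1e-9 * max(1, abs(g_star))

    def test_interior_solution_zeroes_marginal_fitness(self, rng, shoot_herb):
        # a*ui*exp(-a*uh) - c_h vanishes to machine precision when unclamped
        for u_i in rng.uniform(2.0, 50.0, size=20):
            uh = herbivore_best_response(u_i, shoot_herb)
            assert uh > 0
            marginal = shoot_herb.a * u_i * math.exp(-shoot_herb.a * uh) - shoot_herb.c_h
            assert abs(marginal) < 1e-12


class TestPlantBestResponse:
    def test_undamaged_matches_dense_grid_optimum(self, env, plant):
        eq = solve_undamaged(env, plant)
        assert eq.converged and eq.soc_ok
        u_r, u_s, g_best = grid_oracle(env, plant)
        assert eq.payoffs.G_plant >= g_best - 1e-6
        assert eq.u_r_star == pytest.approx(u_r, rel=2e-3)
        assert eq.u_s_star == pytest.approx(u_s, rel=2e-3)
        assert eq.u_r_star == pytest.approx(5.35, abs=0.01)
        assert eq.u_s_star == pytest.approx(7.37, abs=0.01)
        assert eq.foc_residual < 1e-10

    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(6):
            plant, env, _, phi, loc = random_live_point(rng, phi_max=0.7)
            eq = PlantHerbivoreGame(
                plant, env=env,
                damage=DamageSpec(mode="fixed", D_fixed=phi, location=loc)
                if loc != "none" else DamageSpec(mode="none"),
            ).fit()
            if not eq.converged:
                continue
            _, _, g_best = grid_oracle(env, plant, eq.phi_star, loc, n_grid=300)
            assert eq.payoffs.G_plant == pytest.approx(g_best, rel=1e-3)

    def test_fitness_monotone_in_resources(self, plant):
        g_n = [solve_undamaged(Environment(C=5000, N=n), plant).payoffs.G_plant
               for n in (5.0, 20.0, 50.0, 100.0)]
        assert all(a < b for a, b in zip(g_n, g_n[1:]))
        g_c = [solve_undamaged(Environment(C=c, N=50), plant).payoffs.G_plant
               for c in (1000.0, 3000.0, 5000.0)]
        assert all(a < b for a, b in zip(g_c, g_c[1:]))

    def test_shoot_saturates_in_carbon(self, plant):
        # saturating harvest + linear cost keeps u_s* bounded as C grows
        us = [solve_undamaged(Environment(C=c, N=50), plant).u_s_star
              for c in (5e3, 5e5, 5e7)]
        assert us[-1] < 25.0

    def test_infeasible_environment_reports_nonconvergence(self, plant):
        eq = solve_fixed_damage(Environment(C=5000, N=1e-3), plant, 0.9, "root")
        assert not eq.converged
        assert math.isnan(eq.u_r_star)


class TestFixedDamage:
    def test_zero_damage_equals_undamaged(self, env, plant):
        a = solve_undamaged(env, plant)
        b = solve_fixed_damage(env, plant, 0.0, "shoot")
        assert (a.u_r_star, a.u_s_star, a.payoffs) == (b.u_r_star, b.u_s_star, b.payoffs)

    def test_compensation_band_for_shoot_damage(self, env, plant):
        base = solve_undamaged(env, plant)
        eq = solve_fixed_damage(env, plant, 0.5, "shoot")
        lnrr = math.log(eq.u_s_star / base.u_s_star)
        assert math.log(0.5) <= lnrr <= 0.0

    def test_heavy_shoot_damage_shrinks_shoots(self, env, plant):
        base = solve_undamaged(env, plant)
        eq = solve_fixed_damage(env, plant, 0.99, "shoot")
        assert eq.converged
        assert eq.u_s_star < base.u_s_star

    def test_root_tolerance_improves_with_nitrogen(self, plant):
        # under the tabulated partials, root damage is tolerated poorly at
        # low N but better than shoot damage once N is plentiful
        def lnrrs(N):
            env = Environment(C=5000, N=N)
            base = solve_undamaged(env, plant, "table2")
            sh = solve_fixed_damage(env, plant, 0.5, "shoot", "table2")
            rt = solve_fixed_damage(env, plant, 0.5, "root", "table2")
            return (math.log(sh.u_s_star / base.u_s_star),
                    math.log(rt.u_r_star / base.u_r_star))

        lo_shoot, lo_root = lnrrs(5.0)
        hi_shoot, hi_root = lnrrs(100.0)
        assert abs(lo_root) > abs(lo_shoot)
        assert abs(hi_root) < abs(hi_shoot)
        assert abs(hi_root) < abs(lo_root)

    def test_implied_foraging_time_consistent(self, env, plant):
        eq = solve_fixed_damage(env, plant, 0.5, "shoot")
        assert eq.u_h_star == pytest.approx(-math.log(0.5) / 0.7, rel=1e-12)


class TestDynamicGame:
    def test_expensive_herbivore_never_forages(self, env, plant):
        herb = HerbivoreParams(a=0.7, c_h=1e4, location="shoot")
        eq = solve_dynamic(env, plant, herb)
        base = solve_undamaged(env, plant)
        assert eq.u_h_star == 0.0
        assert eq.D == 0.0
        assert eq.u_s_star == pytest.approx(base.u_s_star, rel=1e-9)

    @pytest.mark.parametrize("location", ["shoot", "root"])
    def test_no_profitable_unilateral_deviation(self, env, plant, location):
        herb = HerbivoreParams(location=location)
        eq = solve_dynamic(env, plant, herb)
        assert eq.converged
        # plant deviation scan at the equilibrium consumed fraction
        g_star = plant_fitness(eq.strategy, env, plant, eq.phi_star, location)
        grid = np.geomspace(1e-2, 1e3, 150)
        for u_r in grid:
            for u_s in grid[::5]:
                g = plant_fitness(PlantStrategy(u_r, u_s), env, plant,
                                  eq.phi_star, location)
                assert g <= g_star * (1 + 1e-9)
        # herbivore deviation scan against the equilibrium plant
        u_i = eq.strategy.attacked_mass(location)
        h_star = herbivore_fitness(eq.u_h_star, u_i, herb)
        for u_h in np.linspace(0, 5 * (eq.u_h_star + 1), 500):
            assert herbivore_fitness(u_h, u_i, herb) <= h_star + 1e-9

    def test_interior_damage_identity(self, env, plant, shoot_herb):
        # D = 1 - c_h / (a u_i*) whenever the herbivore forages
        eq = solve_dynamic(env, plant, shoot_herb)
        assert eq.u_h_star > 0
        expect = 1 - shoot_herb.c_h / (shoot_herb.a * eq.u_s_star)
        assert eq.D == pytest.approx(expect, rel=1e-9)
        assert nash_residual(eq, env, plant, shoot_herb) < 1e-8

    def test_lethal_herbivore_flagged_dead(self, plant):
        herb = HerbivoreParams(a=5.0, c_h=1e-6, location="root")
        eq = solve_dynamic(Environment(C=5000, N=0.2), plant, herb)
        if not eq.converged:
            assert eq.plant_dead or math.isnan(eq.u_r_star)
            assert eq.payoffs.G_plant == 0.0


class TestGridOracle:
    def test_solver_dominates_coarse_grid(self, env, plant):
        _, _, g_best = grid_oracle(env, plant, n_grid=60, refine=False)
        eq = solve_undamaged(env, plant)
        assert eq.payoffs.G_plant >= g_best

    def test_degenerate_environment(self, plant):
        u_r, u_s, g = grid_oracle(Environment(C=5000, N=1e-3), plant, n_grid=80)
        assert g < 1e-2  # effectively no fitness available


class TestModelObject:
    def test_game_dispatches_by_damage_mode(self, env, plant, shoot_herb):
        undam = PlantHerbivoreGame(plant, env=env).fit()
        fixed = PlantHerbivoreGame(
            plant, env=env, damage=DamageSpec(mode="fixed", D_fixed=0.3,
                                              location="shoot")).fit()
        dyn = PlantHerbivoreGame(
            plant, shoot_herb, env, DamageSpec(mode="dynamic", location="shoot")).fit()
        assert undam.mode == "none" and fixed.mode == "fixed" and dyn.mode == "dynamic"
        assert fixed.phi_star == 0.3
        assert dyn.u_h_star > 0

    def test_summary_mentions_key_quantities(self, env, plant):
        text = PlantHerbivoreGame(plant, env=env).fit().summary()
        assert "u_r*" in text and "u_s*" in text and "fitness" in text
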