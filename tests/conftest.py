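import numpy as np
import pytest

from herbigame import Environment, HerbivoreParams, PlantParams


@pytest.fixture
def plant():
    return PlantParams()


@pytest.fixture
def env():
    return Environment(C=5000.0, N=50.0)


@pytest.fixture
def shoot_herb():
    return HerbivoreParams(location="shoot")


@pytest.fixture
def root_herb():
    return HerbivoreParams(location="root")


@pytest.fixture
def rng():
    return np.random.default_rng(20180602)


def random_live_point(rng, phi_max=0.9):
    """A random parameter set + strategy on the live branch (both net
    harvests positive), used by gradient and solver property tests."""
    from herbigame import PlantStrategy, net_carbon, net_nitrogen

    while True:
        plant = PlantParams(
            alpha=rng.uniform(0.7, 0.98),
            Vc=rng.uniform(0.5, 2.0),
            Vn=rng.uniform(0.5, 2.0),
            c_cs=rng.uniform(1.0, 5.0),
            c_cr=rng.uniform(0.5, 2.0),
            c_ns=rng.uniform(0.01, 0.1),
            c_nr=rng.uniform(0.005, 0.05),
            E=rng.uniform(0.05, 0.5),
        )
        env = Environment(C=rng.uniform(500, 10000), N=rng.uniform(5, 100))
        loc = rng.choice(["shoot", "root", "none"])
        phi = 0.0 if loc == "none" else rng.uniform(0.0, phi_max)
        s = PlantStrategy(u_r=rng.uniform(0.5, 8.0), u_s=rng.uniform(0.5, 8.0))
        if (net_carbon(s, env, plant, phi, loc) > 1.0
                and net_nitrogen(s, env, plant, phi, loc) > 1.0):
            return plant, env, s, phi, loc
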