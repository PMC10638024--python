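import math

import numpy as np
import pytest

from empop import fixtures, morph, sim


@pytest.fixture(scope="session")
def ball_and_stick() -> morph.Morphology:
    """Soma + tapering basal stick + AIS/myelin, the standard active fixture."""
    sec = morph.Section(
        id=0,
        stype="basal",
        points=np.array([[0, 0, 0, 2.0], [0, 200, 0, 1.5], [0, 400, 0, 1.0]]),
    )
    m = morph.Morphology(soma_radius=8.0, soma_length=8.0, sections={0: sec})
    return morph.attach_ais_and_myelin(m, 1.2)


@pytest.fixture(scope="session")
def spiking_params() -> dict:
    return {**fixtures.BASE_PARAMS, **fixtures.P_TRUE}


@pytest.fixture(scope="session")
def spiking_cell(ball_and_stick, spiking_params) -> sim.CompartmentalCell:
    return sim.build_cell(ball_and_stick, spiking_params)


@pytest.fixture(scope="session")
def passive_point_cell() -> sim.CompartmentalCell:
    """Isopotential passive cell with R_in = 1000 MOhm, tau = 10 ms."""
    return sim.point_cell(1e-5, {"somatic.pas.g": 1e-4, "somatic.pas.e": -70.0})


@pytest.fixture(scope="session")
def y_tree() -> morph.Morphology:
    """Soma + basal Y: stem 100 um, children 30 um and 70 um."""
    stem = morph.Section(
        id=0, stype="basal", points=np.array([[0, 0, 0, 2.0], [0, 100, 0, 2.0]])
    )
    short = morph.Section(
        id=1, stype="basal",
        points=np.array([[0, 100, 0, 1.0], [30, 130, 0, 1.0]]), parent=0,
    )
    # renormalize child lengths to exactly 30 and 70
    short.points[1, :3] = short.points[0, :3] + np.array([30 / math.sqrt(2), 30 / math.sqrt(2), 0])
    long = morph.Section(
        id=2, stype="basal",
        points=np.array([[0, 100, 0, 1.0], [0, 170, 0, 1.0]]), parent=0,
    )
    m = morph.Morphology(soma_radius=8.0, soma_length=8.0, sections={0: stem, 1: short, 2: long})
    m.validate()
    return m


@pytest.fixture(scope="session")
def fixture_problem_small():
    """The packaged fixture problem at its default configuration (cached)."""
    return fixtures.fixture_problem(fixtures.FixtureConfig(seed=42))
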