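import numpy as np
import pytest

from hepregen import ModelParameters, simulate


@pytest.fixture(scope="session")
def nominal() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def nominal_trajectory(nominal):
    """Nominal rat 70% PHx run, 300 h, shared across tests."""
    return simulate(nominal)


@pytest.fixture(scope="session")
def nominal_trajectory_no_growth(nominal):
    return simulate(nominal.replace(include_growth=False))


@pytest.fixture(scope="session")
def mbf_trajectory(nominal):
    """Matrix-bound-factor extension on a fine early grid."""
    return simulate(nominal.replace(include_mbf=True), horizon=24.0,
                    output_grid=0.005)


def random_valid_state(rng: np.random.Generator) -> np.ndarray:
    """A random physiologically admissible state vector (14 entries)."""
    Q, P, R = rng.uniform(0.0, 3.0, size=3)
    if Q + P + R < 1e-3:
        Q = 0.5
    G = rng.uniform(0.5, 3.0)
    A = rng.uniform(0.0, 1.0)
    IL6, JAK, ST3, SOC, IE = rng.uniform(0.1, 50.0, size=5)
    GF = rng.uniform(1.0, 25.0)
    ECM = rng.uniform(0.05, 2.0)
    MBe = rng.uniform(0.0, 50.0)
    MBf = rng.uniform(0.0, 30.0)
    return np.array([Q, P, R, G, A, IL6, JAK, ST3, SOC, IE, GF, ECM, MBe, MBf])
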