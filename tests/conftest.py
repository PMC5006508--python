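import numpy as np
import pytest

from galshuttle.model import (
    DosageConfig,
    ModelParameters,
    SpatialGrid,
    reference_parameters,
)


@pytest.fixture(scope="session")
def grid401():
    return SpatialGrid.uniform(401)


@pytest.fixture(scope="session")
def grid201():
    return SpatialGrid.uniform(201)


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


def random_parameters(rng: np.random.Generator) -> ModelParameters:
    """One random parameter set from the documented physiological ranges."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ModelParameters(
        lambda_g=lu(0.05, 0.4), lambda_r=lu(0.05, 0.4),
        chi=lu(0.1, 30.0) if rng.random() < 0.8 else 0.0,
        mu=lu(0.1, 300.0), nu=lu(0.01, 5.0), beta=lu(0.1, 5.0),
        rho_c=lu(0.1, 5.0), K_r=lu(0.01, 1.0), n_r=rng.uniform(1.0, 6.0),
        K_z=lu(0.1, 20.0), n_z=rng.uniform(1.0, 4.0))


def random_dosage(rng: np.random.Generator) -> DosageConfig:
    q_r = float(rng.choice([0.0, 1.0, 2.0]))
    if rng.random() < 0.5:
        return DosageConfig.four_copy(q_r=q_r)
    return DosageConfig.two_copy(q_r=q_r, q_2x=float(rng.uniform(0.35, 0.65)))
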