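import numpy as np
import pytest

from mtmmsim import PopulationCell, build_model, population_covariance
from mtmmsim.model_space import Family, ModelSpec, ParameterPoint, compile_spec


@pytest.fixture(scope="session")
def all_specs():
    return {
        Family.UM_CONSTRAINED: build_model(Family.UM_CONSTRAINED),
        Family.CMM1: build_model(Family.CMM1, 1),
        Family.UM_UNCONSTRAINED: build_model(Family.UM_UNCONSTRAINED),
        Family.CM: build_model(Family.CM),
    }


@pytest.fixture(scope="session")
def mid_cells():
    """Mid-grid population cells, one per population family."""
    return {
        Family.UM_CONSTRAINED: PopulationCell(
            Family.UM_CONSTRAINED, 1000, 0.5, 0.7, 0.0, jitter_seed=11
        ),
        Family.CMM1: PopulationCell(Family.CMM1, 1000, 0.5, 0.7, 0.5, jitter_seed=13),
    }


@pytest.fixture(scope="session")
def mid_sigmas(mid_cells):
    return {fam: population_covariance(cell) for fam, cell in mid_cells.items()}


def random_admissible_point(spec: ModelSpec, rng: np.random.Generator) -> ParameterPoint:
    """A random parameter point with PD implied covariance.

    Loadings in [0.15, 0.8], error variances in [0.2, 1.0], correlations in
    [-0.6, 0.6] (jointly PD for the three-correlation CM structure at this
    range with high probability; rejection-sampled otherwise).
    """
    cm = compile_spec(spec)
    for _ in range(100):
        vec = np.empty(cm.n_free)
        loading = np.zeros(cm.n_free, dtype=bool)
        loading[cm.lam_idx] = True
        vec[loading] = rng.uniform(0.15, 0.8, loading.sum())
        vec[cm.theta_idx] = rng.uniform(0.2, 1.0, 9)
        if len(cm.rho_idx):
            vec[cm.rho_idx] = rng.uniform(-0.6, 0.6, len(cm.rho_idx))
        _, psi, _ = cm.matrices(vec)
        if np.linalg.eigvalsh(psi)[0] > 1e-6:
            return ParameterPoint.from_vector(spec, vec)
    raise AssertionError("failed to draw an admissible point")
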