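"""Population synthesis: design-grid cells, parameter algebra and sampling.

Each cell of the design grid fixes a population family, sample size N,
consistency level, reliability base and (for CMm1 populations) the
correlation between the two non-reference method factors.  Population
loadings follow from two identities with all factor and indicator variances
fixed at 1:

    consistency  con = lam^2 / (lam^2 + gam^2)
    reliability  rel = lam^2 + gam^2

so lam = sqrt(rel * con), gam = sqrt(rel * (1 - con)) and the error
variance is 1 - rel.  Reference-method indicators of a CMm1 population have
no method factor: gam = 0 and lam = sqrt(rel).

Indicator reliabilities are jittered around the cell's base level by
(Beta(3,3) - 0.5) * 0.05, once per cell; the resulting population
covariance matrix is held fixed across the cell's replications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_space import (
    Family,
    ModelSpec,
    ParameterPoint,
    build_model,
    implied_covariance,
)

CONSISTENCY_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
RELIABILITY_LEVELS = (0.6, 0.7, 0.8)
METHOD_CORRELATION_LEVELS = (0.2, 0.5, 0.8)
SAMPLE_SIZES = (250, 1000)


@dataclass(frozen=True)
class PopulationCell:
    """One cell of the design grid (population side)."""

    population_family: Family
    sample_size: int
    consistency: float
    reliability_base: float
    method_correlation: float = 0.0
    jitter_seed: int = 0

    def __post_init__(self):
        if self.population_family not in (Family.UM_CONSTRAINED, Family.CMM1):
            raise ValueError(
                f"population family must be UM_constrained or CMm1, got {self.population_family}"
            )
        if not 0.0 < self.consistency <= 1.0:
            raise ValueError("consistency must be in (0, 1]")
        if not 0.0 < self.reliability_base < 1.0:
            raise ValueError("reliability base must be in (0, 1)")
        if self.population_family is Family.UM_CONSTRAINED and self.method_correlation != 0.0:
            raise ValueError("UM_constrained populations have method correlation fixed 0")

    @property
    def cell_id(self) -> str:
        base = (
            f"{self.population_family.value}_N{self.sample_size}"
            f"_con{self.consistency:g}_rel{self.reliability_base:g}"
        )
        if self.population_family is Family.CMM1:
            base += f"_r{self.method_correlation:g}"
        return base

    def model_spec(self) -> ModelSpec:
        if self.population_family is Family.CMM1:
            return build_model(Family.CMM1, 1)
        return build_model(Family.UM_CONSTRAINED)


def jitter_reliabilities(
    reliability_base: float, jitter_seed: int, n_draws: int = 9
) -> np.ndarray:
    """Perturbed indicator reliabilities: base + (Beta(3,3) - 0.5) * 0.05.

    Each value lies within (base - 0.025, base + 0.025) and is centered on
    the base (Beta(3,3) has mean 1/2).  Reproducible from ``jitter_seed``.
    """
    if not 0.0 < reliability_base < 1.0:
        raise ValueError("reliability base must be in (0, 1)")
    rng = np.random.default_rng(jitter_seed)
    b = rng.beta(3.0, 3.0, size=n_draws)
    return reliability_base + (b - 0.5) * 0.05


def cell_reliabilities(cell: PopulationCell) -> np.ndarray:
    """Jittered reliabilities of the 9 indicators, in variable order.

    UM_constrained populations draw one value per indicator i (3 draws,
    reused across methods) so the equality constraints of the family remain
    exact in the population; CMm1 populations draw all 9 independently.
    """
    if cell.population_family is Family.UM_CONSTRAINED:
        per_indicator = jitter_reliabilities(cell.reliability_base, cell.jitter_seed, 3)
        return np.tile(per_indicator, 3)
    return jitter_reliabilities(cell.reliability_base, cell.jitter_seed, 9)


def derive_population_point(
    cell: PopulationCell, reliabilities: Optional[np.ndarray] = None
) -> ParameterPoint:
    """Population parameter values implied by the cell's design levels.

    ``reliabilities`` is the length-9 vector in method-major variable order;
    when omitted it is drawn from the cell's jitter seed.  Recomputing
    consistency and reliability from the returned point reproduces the
    inputs exactly.
    """
    if reliabilities is None:
        reliabilities = cell_reliabilities(cell)
    rel = np.asarray(reliabilities, dtype=float)
    if rel.shape != (9,):
        raise ValueError("reliabilities must be a length-9 vector")
    con = cell.consistency
    if con <= 0.0:
        raise ValueError("consistency 0 leaves the trait factor unidentified")

    spec = cell.model_spec()
    values: dict = {}
    for m in range(1, 4):
        for i in range(1, 4):
            r = rel[(m - 1) * 3 + (i - 1)]
            tl = spec.trait_loading_pattern[(i, m)]
            gl = spec.method_loading_pattern[(i, m)]
            if gl is None:  # CMm1 reference method: all true-score variance is trait
                values[tl] = np.sqrt(r)
            else:
                values[tl] = np.sqrt(r * con)
                values[gl] = np.sqrt(r * (1.0 - con))
            values[spec.error_pattern[(i, m)]] = 1.0 - r
    for lab in spec.free_correlations:
        values[lab] = cell.method_correlation
    return ParameterPoint(values)


def population_covariance(cell: PopulationCell) -> np.ndarray:
    """The cell's fixed population covariance matrix (unit diagonal)."""
    return implied_covariance(cell.model_spec(), derive_population_point(cell))


def sample_dataset(sigma_pop: np.ndarray, n: int, seed) -> tuple:
    """Draw an N x 9 multivariate-normal sample; return (data, S).

    S is the sample covariance with divisor N - 1, the convention paired
    with the Wishart chi-square multiplier in the estimator.  ``seed`` may
    be an int or a numpy SeedSequence/Generator.
    """
    sigma_pop = np.asarray(sigma_pop, dtype=float)
    p = sigma_pop.shape[0]
    if sigma_pop.shape != (p, p) or not np.allclose(sigma_pop, sigma_pop.T):
        raise ValueError("population covariance must be square symmetric")
    try:
        chol = np.linalg.cholesky(sigma_pop)
    except np.linalg.LinAlgError as exc:
        raise ValueError("population covariance is not positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = rng.standard_normal((n, p)) @ chol.T
    s = np.cov(data, rowvar=False, ddof=1)
    return data, s


def population_manifest(cell: PopulationCell) -> dict:
    """JSON-ready record of a cell: levels, jittered reliabilities, point."""
    rel = cell_reliabilities(cell)
    point = derive_population_point(cell, rel)
    return {
        "cell_id": cell.cell_id,
        "population_family": cell.population_family.value,
        "sample_size": cell.sample_size,
        "consistency": cell.consistency,
        "reliability_base": cell.reliability_base,
        "method_correlation": cell.method_correlation,
        "jitter_seed": cell.jitter_seed,
        "reliabilities": rel.tolist(),
        "population_point": {k: float(v) for k, v in point.values.items()},
    }
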