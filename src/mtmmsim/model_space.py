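"""The four single-trait MTMM factor structures and their implied covariances.

Every model measures one trait by three methods with three indicators per
method, giving nine observed variables Y_im (indicator i, method m).  The
observed-variable ordering is method-major throughout the package:
Y_11, Y_21, Y_31, Y_12, ..., Y_33.

Families
--------
UM_constrained
    Interchangeable methods: one trait factor T and three mutually
    uncorrelated method factors M_m.  Trait loadings lam_i and method
    loadings gam_i are equal for the same indicator across methods
    (equality constraints encoded by shared parameter labels).
UM_unconstrained
    Same structure with all 18 loadings free.
CMm1
    "Correlated methods minus one": the reference method (default method 1)
    has no method factor, the remaining two method factors are correlated.
CM
    Correlated methods: three method factors with all three correlations
    free.

All factor variances are fixed to 1, trait-method covariances to 0, and the
error covariance Theta is diagonal with one free variance per variable.  No
mean structure is modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np
import yaml

N_METHODS = 3
N_INDICATORS = 3
N_VARS = N_METHODS * N_INDICATORS


class Family(str, Enum):
    """The four fitted/population model families."""

    UM_CONSTRAINED = "UM_constrained"
    UM_UNCONSTRAINED = "UM_unconstrained"
    CMM1 = "CMm1"
    CM = "CM"


def var_index(i: int, m: int) -> int:
    """Position of Y_im in the canonical method-major variable order."""
    if not (1 <= i <= N_INDICATORS and 1 <= m <= N_METHODS):
        raise ValueError(f"indicator/method out of range: ({i}, {m})")
    return (m - 1) * N_INDICATORS + (i - 1)


VAR_NAMES = tuple(f"Y_{i}{m}" for m in range(1, 4) for i in range(1, 4))


@dataclass(frozen=True)
class ModelSpec:
    """Loading pattern, constraint groups and latent covariance structure.

    ``trait_loading_pattern`` and ``method_loading_pattern`` map (i, m) to a
    parameter label; equality constraints are encoded by sharing a label
    across several positions.  A ``None`` entry in the method pattern means
    the loading is fixed to 0 (reference-method indicators of CMm1).
    ``free_correlations`` maps a label to the pair of correlated method
    factors.  ``method_factors`` lists the methods that carry a factor.
    """

    family: Family
    reference_method: Optional[int] = None
    trait_loading_pattern: Mapping[tuple, str] = field(default_factory=dict)
    method_loading_pattern: Mapping[tuple, Optional[str]] = field(default_factory=dict)
    method_factors: tuple = ()
    free_correlations: Mapping[str, tuple] = field(default_factory=dict)
    error_pattern: Mapping[tuple, str] = field(default_factory=dict)

    @property
    def free_labels(self) -> tuple:
        """Distinct free-parameter labels in canonical order.

        Order: trait loadings, method loadings, error variances,
        correlations — each group ordered by first occurrence in the
        method-major variable order.
        """
        labels: list = []
        for pattern in (self.trait_loading_pattern, self.method_loading_pattern):
            for m in range(1, 4):
                for i in range(1, 4):
                    lab = pattern.get((i, m))
                    if lab is not None and lab not in labels:
                        labels.append(lab)
        for m in range(1, 4):
            for i in range(1, 4):
                labels.append(self.error_pattern[(i, m)])
        labels.extend(self.free_correlations.keys())
        return tuple(labels)

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "reference_method": self.reference_method,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @staticmethod
    def from_dict(d: Mapping) -> "ModelSpec":
        return build_model(Family(d["family"]), d.get("reference_method"))

    @staticmethod
    def from_yaml(text: str) -> "ModelSpec":
        return ModelSpec.from_dict(yaml.safe_load(text))

    @staticmethod
    def from_json(text: str) -> "ModelSpec":
        return ModelSpec.from_dict(json.loads(text))


@dataclass
class ParameterPoint:
    """A complete assignment of values to the free parameters of a spec.

    Values are unbounded: negative error variances and correlations outside
    [-1, 1] are representable so that improper solutions can be observed
    rather than masked.
    """

    values: dict

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def validate(self, spec: ModelSpec) -> None:
        free = set(spec.free_labels)
        have = set(self.values)
        if free != have:
            missing = free - have
            extra = have - free
            raise ValueError(
                f"parameter point does not match spec: missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )

    def as_vector(self, spec: ModelSpec) -> np.ndarray:
        self.validate(spec)
        return np.array([self.values[lab] for lab in spec.free_labels], dtype=float)

    @staticmethod
    def from_vector(spec: ModelSpec, vec: np.ndarray) -> "ParameterPoint":
        labels = spec.free_labels
        if len(vec) != len(labels):
            raise ValueError("vector length does not match number of free labels")
        return ParameterPoint(dict(zip(labels, (float(v) for v in vec))))


def build_model(family: Family | str, reference_method: Optional[int] = None) -> ModelSpec:
    """Construct the ModelSpec for one of the four families.

    ``reference_method`` must be supplied only for CMm1 (default 1 when the
    family is CMm1 and no value is given).
    """
    family = Family(family)
    if family is Family.CMM1:
        if reference_method is None:
            reference_method = 1
        if reference_method not in (1, 2, 3):
            raise ValueError(f"reference_method must be in 1..3, got {reference_method}")
    elif reference_method is not None:
        raise ValueError(f"reference_method is only meaningful for CMm1, not {family.value}")

    trait: dict = {}
    method: dict = {}
    error: dict = {}
    for m in range(1, 4):
        for i in range(1, 4):
            error[(i, m)] = f"theta_{i}_{m}"
            if family is Family.UM_CONSTRAINED:
                trait[(i, m)] = f"lam_{i}"
                method[(i, m)] = f"gam_{i}"
            else:
                trait[(i, m)] = f"lam_{i}_{m}"
                if family is Family.CMM1 and m == reference_method:
                    method[(i, m)] = None  # fixed 0: no factor for the reference method
                else:
                    method[(i, m)] = f"gam_{i}_{m}"

    if family is Family.CMM1:
        factors = tuple(m for m in range(1, 4) if m != reference_method)
        a, b = factors
        corr = {f"rho_{a}_{b}": (a, b)}
    elif family is Family.CM:
        factors = (1, 2, 3)
        corr = {"rho_1_2": (1, 2), "rho_1_3": (1, 3), "rho_2_3": (2, 3)}
    else:
        factors = (1, 2, 3)
        corr = {}

    return ModelSpec(
        family=family,
        reference_method=reference_method,
        trait_loading_pattern=trait,
        method_loading_pattern=method,
        method_factors=factors,
        free_correlations=corr,
        error_pattern=error,
    )


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of distinct free parameters (loadings + variances + correlations)."""
    return len(spec.free_labels)


class CompiledModel:
    """Index-array form of a ModelSpec for fast repeated evaluation.

    Factor columns: column 0 is the trait, followed by the method factors of
    ``spec.method_factors`` in increasing method order.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        labels = spec.free_labels
        self.labels = labels
        self.index = {lab: j for j, lab in enumerate(labels)}
        self.n_free = len(labels)
        self.k = 1 + len(spec.method_factors)
        self.factor_col = {m: 1 + pos for pos, m in enumerate(spec.method_factors)}

        lam_rows, lam_cols, lam_idx = [], [], []
        for m in range(1, 4):
            for i in range(1, 4):
                v = var_index(i, m)
                lam_rows.append(v)
                lam_cols.append(0)
                lam_idx.append(self.index[spec.trait_loading_pattern[(i, m)]])
                glab = spec.method_loading_pattern[(i, m)]
                if glab is not None:
                    lam_rows.append(v)
                    lam_cols.append(self.factor_col[m])
                    lam_idx.append(self.index[glab])
        self.lam_rows = np.array(lam_rows, dtype=np.intp)
        self.lam_cols = np.array(lam_cols, dtype=np.intp)
        self.lam_idx = np.array(lam_idx, dtype=np.intp)

        self.theta_idx = np.array(
            [self.index[spec.error_pattern[(i, m)]] for m in range(1, 4) for i in range(1, 4)],
            dtype=np.intp,
        )

        rho_a, rho_b, rho_idx = [], [], []
        for lab, (ma, mb) in spec.free_correlations.items():
            rho_a.append(self.factor_col[ma])
            rho_b.append(self.factor_col[mb])
            rho_idx.append(self.index[lab])
        self.rho_a = np.array(rho_a, dtype=np.intp)
        self.rho_b = np.array(rho_b, dtype=np.intp)
        self.rho_idx = np.array(rho_idx, dtype=np.intp)

    def matrices(self, theta: np.ndarray):
        """Assemble (Lambda, Psi, theta_diag) from a free-parameter vector."""
        lam = np.zeros((N_VARS, self.k))
        lam[self.lam_rows, self.lam_cols] = theta[self.lam_idx]
        psi = np.eye(self.k)
        if len(self.rho_idx):
            psi[self.rho_a, self.rho_b] = theta[self.rho_idx]
            psi[self.rho_b, self.rho_a] = theta[self.rho_idx]
        return lam, psi, theta[self.theta_idx]

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, psi, th = self.matrices(theta)
        sig = lam @ psi @ lam.T
        sig[np.diag_indices(N_VARS)] += th
        return sig

    def dsigma_stack(self, theta: np.ndarray) -> np.ndarray:
        """Stack of dSigma/dtheta_j matrices, shape (n_free, 9, 9)."""
        lam, psi, _ = self.matrices(theta)
        lp = lam @ psi  # 9 x k
        d = np.zeros((self.n_free, N_VARS, N_VARS))
        # loadings: dSigma = E_rc Psi Lam' + Lam Psi E_rc' accumulated over
        # the positions sharing the label
        for r, c, j in zip(self.lam_rows, self.lam_cols, self.lam_idx):
            d[j, r, :] += lp[:, c]
            d[j, :, r] += lp[:, c]
        # error variances
        for v, j in enumerate(self.theta_idx):
            d[j, v, v] += 1.0
        # correlations: dPsi has 1 at (a,b) and (b,a)
        for a, b, j in zip(self.rho_a, self.rho_b, self.rho_idx):
            d[j] += np.outer(lam[:, a], lam[:, b]) + np.outer(lam[:, b], lam[:, a])
        return d


_COMPILED_CACHE: dict = {}


def compile_spec(spec: ModelSpec) -> CompiledModel:
    key = (spec.family, spec.reference_method)
    if key not in _COMPILED_CACHE:
        _COMPILED_CACHE[key] = CompiledModel(spec)
    return _COMPILED_CACHE[key]


def implied_covariance(spec: ModelSpec, point: ParameterPoint) -> np.ndarray:
    """Model-implied covariance Sigma = Lambda Psi Lambda' + Theta (9 x 9)."""
    vec = point.as_vector(spec)
    return compile_spec(spec).sigma(vec)
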