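"""Fit indices (chi-square, RMSEA, CFI, SRMR) and accept/reject rules.

The test statistic is T = c * F_ML where the multiplier c is N - 1 under
the "wishart" dialect (default, pairing with the N - 1 covariance divisor)
or N under the "normal" dialect.  The RMSEA denominator switches with the
same flag.  The CFI baseline is the independence model (diagonal
covariance), which has the closed-form solution Sigma_b = diag(S) and
T_b = c * [sum_i ln S_ii - ln|S|] with 36 degrees of freedom.

Rejection rules, with boundary values counting as acceptable fit:
p-value < 0.05, RMSEA > 0.05, CFI < 0.95, SRMR > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimator import FitResult
from .model_space import ModelSpec, compile_spec, count_free_parameters, N_VARS

N_MOMENTS = N_VARS * (N_VARS + 1) // 2  # 45 distinct covariance moments
BASELINE_DF = N_MOMENTS - N_VARS  # independence model: 9 free variances
BASELINE_N_PARAMS = N_VARS

P_CUTOFF = 0.05
RMSEA_CUTOFF = 0.05
CFI_CUTOFF = 0.95
SRMR_CUTOFF = 0.05


@dataclass(frozen=True)
class FitIndices:
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    srmr: float


def degrees_of_freedom(spec: ModelSpec) -> int:
    return N_MOMENTS - count_free_parameters(spec)


def _multiplier(n: int, dialect: str) -> float:
    if dialect == "wishart":
        return float(n - 1)
    if dialect == "normal":
        return float(n)
    raise ValueError(f"unknown chi-square dialect: {dialect!r}")


def baseline_chi_square(s: np.ndarray, n: int, dialect: str = "wishart") -> float:
    """Independence-model test statistic, closed form (no optimizer)."""
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("S is not positive definite")
    f_b = float(np.sum(np.log(np.diag(s))) - logdet_s)
    return _multiplier(n, dialect) * f_b


def srmr(s: np.ndarray, sigma_hat: np.ndarray) -> float:
    """Standardized root-mean-square residual over all 45 unique cells.

    Residuals are standardized by the sample standard deviations; the
    diagonal cells are included (one of the two common variants).
    """
    d = np.sqrt(np.diag(s))
    std = np.outer(d, d)
    resid = (s - sigma_hat) / std
    tril = np.tril_indices(s.shape[0])
    return float(np.sqrt(np.mean(resid[tril] ** 2)))


def compute_indices(
    fit: FitResult,
    spec: ModelSpec,
    s: np.ndarray,
    n: int,
    dialect: str = "wishart",
) -> FitIndices:
    """Chi-square, RMSEA, CFI and SRMR for a converged fit."""
    if not fit.converged:
        raise ValueError("fit indices are only defined for converged fits")
    df = degrees_of_freedom(spec)
    if df <= 0:
        raise ValueError("model has no positive degrees of freedom")
    c = _multiplier(n, dialect)
    t = c * fit.discrepancy
    p = float(stats.chi2.sf(t, df))
    excess = max(t - df, 0.0)
    rmsea_val = float(np.sqrt(excess / (df * c)))
    t_b = baseline_chi_square(s, n, dialect)
    denom = max(t - df, t_b - BASELINE_DF, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    sigma_hat = compile_spec(spec).sigma(fit.point.as_vector(spec))
    return FitIndices(
        chi_square=float(t),
        df=df,
        p_value=p,
        rmsea=rmsea_val,
        cfi=float(cfi),
        srmr=srmr(s, sigma_hat),
    )


@dataclass(frozen=True)
class RejectionFlags:
    reject_chi2: bool
    reject_rmsea: bool
    reject_cfi: bool
    reject_srmr: bool


def classify_fit(indices: FitIndices) -> RejectionFlags:
    """Per-criterion rejection; boundary values count as acceptable fit."""
    return RejectionFlags(
        reject_chi2=indices.p_value < P_CUTOFF,
        reject_rmsea=indices.rmsea > RMSEA_CUTOFF,
        reject_cfi=indices.cfi < CFI_CUTOFF,
        reject_srmr=indices.srmr > SRMR_CUTOFF,
    )
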