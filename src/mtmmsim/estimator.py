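"""Normal-theory maximum-likelihood estimation of covariance structures.

Minimizes the ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over the free parameters of a model spec, with equality constraints
enforced by construction (shared labels move in lockstep).  Estimates are
unbounded: negative error variances (Heywood cases) and correlations
outside [-1, 1] are representable so improper solutions are observable.

The optimizer is BFGS with the analytic gradient

    dF/dtheta_j = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma/dtheta_j]

and a backtracking line search that rejects any step at which
Sigma(theta) leaves the positive-definite cone.  A fit is converged when
max|gradient| falls below ``gtol`` (default 5e-5, the magnitude of the
derivative-based convergence test documented for the quasi-Newton ML
estimator of the mainstream SEM software this study design mirrors);
optionally a relative-parameter-change condition ``xtol`` can be AND-ed in
for a stricter dialect.  Otherwise the fit is non-converged at the
iteration cap (default 1000) or when the line search stalls completely.
Non-convergence *rates* are optimizer-dependent; the criteria are fixed
and documented so rates are reproducible.

Standard errors come from the expected (Fisher) information of the normal
covariance-structure likelihood (N - 1)/2 * F_ML:

    I_jk = (N - 1)/2 * tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .model_space import (
    ModelSpec,
    ParameterPoint,
    compile_spec,
    N_VARS,
)

GRAD_TOL = 5e-5
STEP_TOL = None
MAX_HALVINGS = 50
ARMIJO_C1 = 1e-4
NPD_TOL = 1e-8


@dataclass
class FitResult:
    """Outcome of one ML fit."""

    spec: ModelSpec
    point: ParameterPoint
    standard_errors: dict
    converged: bool
    iterations: int
    discrepancy: float
    theta_npd: bool
    psi_npd: bool
    n: int
    log_notes: list = field(default_factory=list)

    @property
    def chi_square(self) -> float:
        """(N - 1) * F_ML under the Wishart convention."""
        return (self.n - 1) * self.discrepancy


def ml_discrepancy(sigma: np.ndarray, s: np.ndarray) -> float:
    """F_ML between two positive-definite matrices.

    Nonnegative for any PD pair, zero iff sigma equals s.
    """
    p = s.shape[0]
    ld_sig = _logdet_pd(np.asarray(sigma, dtype=float))
    ld_s = _logdet_pd(np.asarray(s, dtype=float))
    if ld_sig is None or ld_s is None:
        raise ValueError("both matrices must be positive definite")
    logdet_sig, cho = ld_sig
    sig_inv = cho_solve(cho, np.eye(p), check_finite=False)
    return float(logdet_sig + np.sum(sig_inv * s) - ld_s[0] - p)


def check_npd(matrix: np.ndarray, tolerance: float = NPD_TOL) -> bool:
    """True iff the symmetric matrix has an eigenvalue below -tolerance."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("check_npd requires a square matrix")
    return bool(np.linalg.eigvalsh(matrix)[0] < -tolerance)


def _logdet_pd(matrix: np.ndarray):
    """(log-determinant, cholesky factor) or None if not positive definite."""
    try:
        c, low = cho_factor(matrix, lower=True, check_finite=False)
    except (LinAlgError, ValueError):
        return None
    return 2.0 * np.sum(np.log(np.diag(c))), (c, low)


def default_start(spec: ModelSpec, s: np.ndarray) -> np.ndarray:
    """Scale-aware deterministic start values.

    Trait loadings start at sqrt(0.5 * S_ii), method loadings at
    sqrt(0.25 * S_ii), error variances at 0.5 * S_ii, correlations at 0;
    a shared label uses the mean S_ii over the positions it constrains.
    """
    cm = compile_spec(spec)
    diag = np.diag(s)
    start = np.zeros(cm.n_free)
    counts = np.zeros(cm.n_free)
    acc = np.zeros(cm.n_free)
    for r, c, j in zip(cm.lam_rows, cm.lam_cols, cm.lam_idx):
        acc[j] += diag[r]
        counts[j] += 1.0
    loading = counts > 0
    mean_var = np.where(loading, acc / np.maximum(counts, 1.0), 0.0)
    trait_like = np.zeros(cm.n_free, dtype=bool)
    trait_like[cm.lam_idx[cm.lam_cols == 0]] = True
    start[loading & trait_like] = np.sqrt(0.5 * mean_var[loading & trait_like])
    start[loading & ~trait_like] = np.sqrt(0.25 * mean_var[loading & ~trait_like])
    start[cm.theta_idx] = 0.5 * diag
    # correlations already 0
    return start


def fit_ml(
    spec: ModelSpec,
    s: np.ndarray,
    n: int,
    start: Optional[ParameterPoint] = None,
    max_iterations: int = 1000,
    compute_se: bool = True,
    gtol: float = GRAD_TOL,
    xtol: Optional[float] = STEP_TOL,
    engine: str = "auto",
) -> FitResult:
    """Fit a model spec to a sample covariance matrix by ML.

    Parameters
    ----------
    spec : ModelSpec
    s : (9, 9) sample covariance (divisor N - 1)
    n : sample size, must exceed the number of observed variables
    start : optional explicit starting point; defaults to `default_start`
    max_iterations : iteration cap; hitting it marks the fit non-converged
    compute_se : compute expected-information standard errors on convergence
    gtol : convergence threshold on max|dF/dtheta|
    xtol : optional additional threshold on the relative parameter change
        of the accepted step (None disables the condition)
    engine : "auto" (compiled loop when numba is importable), "numba", or
        "numpy" (pure-NumPy reference implementation of the same algorithm)
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (N_VARS, N_VARS):
        raise ValueError(f"S must be {N_VARS}x{N_VARS}")
    if n <= N_VARS:
        raise ValueError("sample size must exceed the number of observed variables")
    ld_s = _logdet_pd(s)
    if ld_s is None:
        raise ValueError("S is not positive definite")
    logdet_s, _ = ld_s

    cm = compile_spec(spec)
    x = start.as_vector(spec) if start is not None else default_start(spec, s)
    notes: list = []

    from . import _fastfit

    if engine == "auto":
        engine = "numba" if _fastfit.NUMBA_AVAILABLE else "numpy"
    if engine == "numba":
        if not _fastfit.NUMBA_AVAILABLE:
            raise RuntimeError("numba engine requested but numba is not importable")
        x_out, f_out, converged, iterations, stalled, start_fallback = _fastfit.bfgs_core(
            s, logdet_s, x,
            cm.lam_rows, cm.lam_cols, cm.lam_idx, cm.theta_idx,
            cm.rho_a, cm.rho_b, cm.rho_idx, cm.k,
            max_iterations, gtol, 0.0 if xtol is None else xtol, xtol is not None,
            MAX_HALVINGS, ARMIJO_C1,
        )
        if start_fallback:
            notes.append("default start not PD; diagonal fallback used")
        if stalled:
            notes.append(f"iter {iterations}: line search stalled")
        return _finalize(spec, cm, x_out, float(f_out), bool(converged),
                         int(iterations), s, n, compute_se, notes)
    if engine != "numpy":
        raise ValueError(f"unknown engine {engine!r}")

    def evaluate(theta):
        sig = cm.sigma(theta)
        ld = _logdet_pd(sig)
        if ld is None:
            return None
        logdet, cho = ld
        sig_inv = cho_solve(cho, np.eye(N_VARS), check_finite=False)
        f = logdet + float(np.sum(sig_inv * s)) - logdet_s - N_VARS
        return f, sig_inv

    def gradient(theta, sig_inv):
        a = sig_inv - sig_inv @ s @ sig_inv
        lam, psi, _ = cm.matrices(theta)
        g = np.zeros(cm.n_free)
        g_lam = 2.0 * (a @ lam @ psi)
        g += np.bincount(cm.lam_idx, weights=g_lam[cm.lam_rows, cm.lam_cols],
                         minlength=cm.n_free)
        g[cm.theta_idx] += np.diag(a)
        if len(cm.rho_idx):
            g_psi = lam.T @ a @ lam
            g[cm.rho_idx] += 2.0 * g_psi[cm.rho_a, cm.rho_b]
        return g

    ev = evaluate(x)
    if ev is None:
        # scale-aware start should always be PD; fall back to a safe diagonal start
        x = np.zeros(cm.n_free)
        x[cm.theta_idx] = np.diag(s)
        ev = evaluate(x)
        notes.append("default start not PD; diagonal fallback used")
    f, sig_inv = ev
    g = gradient(x, sig_inv)

    h = np.eye(cm.n_free)  # inverse-Hessian approximation
    converged = False
    iterations = 0

    for iterations in range(1, max_iterations + 1):
        d = -h @ g
        gd = float(g @ d)
        if not np.isfinite(gd) or gd >= 0.0:
            h = np.eye(cm.n_free)
            d = -g
            gd = -float(g @ g)
            notes.append(f"iter {iterations}: H reset (non-descent direction)")
        alpha = 1.0
        accepted = None
        for _ in range(MAX_HALVINGS + 1):
            cand = x + alpha * d
            ev = evaluate(cand)
            if ev is not None and ev[0] <= f + ARMIJO_C1 * alpha * gd:
                accepted = (cand, ev)
                break
            alpha *= 0.5
        if accepted is None:
            notes.append(f"iter {iterations}: line search stalled")
            break
        x_new, (f_new, sig_inv_new) = accepted
        g_new = gradient(x_new, sig_inv_new)
        step = x_new - x
        y = g_new - g
        sy = float(step @ y)
        if iterations == 1 and sy > 1e-12:
            # standard initial scaling of the inverse-Hessian approximation
            h *= sy / float(y @ y)
        if sy > 1e-12:
            rho = 1.0 / sy
            hy = h @ y
            h += (
                np.outer(step, step) * (rho * rho * float(y @ hy) + rho)
                - rho * (np.outer(hy, step) + np.outer(step, hy))
            )
        rel_change = float(np.max(np.abs(step) / np.maximum(1.0, np.abs(x_new))))
        x, f, g = x_new, f_new, g_new
        if np.max(np.abs(g)) < gtol and (xtol is None or rel_change < xtol):
            converged = True
            break

    return _finalize(spec, cm, x, float(f), converged, iterations, s, n,
                     compute_se, notes)


def _finalize(spec, cm, x, f, converged, iterations, s, n, compute_se, notes):
    point = ParameterPoint.from_vector(spec, x)
    theta_npd = False
    psi_npd = False
    ses: dict = {}
    if converged:
        theta_npd = bool(np.any(x[cm.theta_idx] < 0.0))
        _, psi, _ = cm.matrices(x)
        psi_npd = check_npd(psi)
        if compute_se:
            ses = standard_errors(spec, point, s, n, _notes=notes)

    return FitResult(
        spec=spec,
        point=point,
        standard_errors=ses,
        converged=converged,
        iterations=iterations,
        discrepancy=f,
        theta_npd=theta_npd,
        psi_npd=psi_npd,
        n=n,
        log_notes=notes,
    )


def standard_errors(
    spec: ModelSpec,
    point: ParameterPoint,
    s: np.ndarray,
    n: int,
    _notes: Optional[list] = None,
) -> dict:
    """Expected-information standard errors at a parameter point.

    Returns a map from free label to SE; labels whose information entry is
    degenerate (singular information matrix or non-positive variance) are
    absent from the map.
    """
    cm = compile_spec(spec)
    x = point.as_vector(spec)
    sig = cm.sigma(x)
    ld = _logdet_pd(sig)
    if ld is None:
        if _notes is not None:
            _notes.append("SEs unavailable: implied covariance not PD")
        return {}
    _, cho = ld
    sig_inv = cho_solve(cho, np.eye(N_VARS), check_finite=False)
    d = cm.dsigma_stack(x)
    m = sig_inv @ d @ sig_inv  # (n_free, 9, 9)
    info = 0.5 * (n - 1) * np.einsum("aij,bij->ab", m, d)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        if _notes is not None:
            _notes.append("SEs unavailable: singular information matrix")
        return {}
    variances = np.diag(cov)
    ses = {}
    for j, lab in enumerate(cm.labels):
        if np.isfinite(variances[j]) and variances[j] > 0.0:
            ses[lab] = float(np.sqrt(variances[j]))
        elif _notes is not None:
            _notes.append(f"SE dropped for {lab}: non-positive information variance")
    return ses
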