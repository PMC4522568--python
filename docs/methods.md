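# Methods

`mtmmsim` reimplements, as a tested pipeline, a Monte Carlo study of what
happens when the wrong multitrait-multimethod (MTMM) confirmatory factor
model is fit to data: convergence failures, improper solutions
("Heywood cases" and non-positive-definite latent covariance matrices),
fit-index behavior, and the collapse of method factors.  This note
documents the models, the data-generating process, the estimator, the
outcome definitions, the numerical choices, and the limitations.

## The model space

All models measure a single trait with three methods and three indicators
per method: nine observed variables Y_im (indicator i, method m), ordered
method-major (Y_11, Y_21, Y_31, Y_12, ..., Y_33) everywhere.  Each model is
a linear factor structure

    Y_im = lam_im * T + gam_im * M_m + eps_im,
    Sigma(theta) = Lambda Psi Lambda' + Theta,

with all factor variances fixed at 1 for identification, trait-method
covariances fixed at 0, diagonal error covariance Theta (one free variance
per indicator), and no mean structure.  The four families differ in their
constraints:

| family            | trait loadings | method loadings | method correlations | free params | df |
|-------------------|----------------|-----------------|---------------------|-------------|----|
| UM_constrained    | 3 (equal across methods) | 3 (equal across methods) | fixed 0 | 15 | 30 |
| CMm1              | 9              | 6 (none for the reference method) | 1 | 25 | 20 |
| UM_unconstrained  | 9              | 9               | fixed 0             | 27 | 18 |
| CM                | 9              | 9               | 3                   | 30 | 15 |

UM_constrained is the model for *interchangeable* methods (e.g., randomly
sampled raters), whose exchangeability implies loading invariance across
methods.  CMm1 ("correlated methods minus one") is the model for
*structurally different* methods: one method (here always method 1) is the
reference and carries no method factor; the two remaining method factors
may correlate.  UM_unconstrained and CM are the commonly used
over-parameterized alternatives.  Equality constraints are encoded by
label sharing in the loading patterns, which makes them declarative and
testable; degrees of freedom are 45 distinct covariance moments minus the
free-parameter count.

The ordering of families by free parameters (15 < 25 < 27 < 30) and the
nesting relations (UM_constrained ⊂ UM_unconstrained ⊂ CM, CMm1 ⊂ CM) are
enforced by tests that refit the nesting family to implied covariances of
the nested one.

## Synthetic populations

A design cell fixes: population family (UM_constrained or CMm1), sample
size N in {250, 1000}, consistency con in {0.1, ..., 0.9}, reliability
base rel in {0.6, 0.7, 0.8}, and — for CMm1 populations — the correlation
corr(M2, M3) in {0.2, 0.5, 0.8}.  That gives 54 + 162 = 216 population
cells; crossed with the four fitted families, 864 grid entries, and
864 000 fits at the full 1000-replication profile.

With all variances fixed at 1 the design levels determine the loadings:

    con = lam^2 / (lam^2 + gam^2),   rel = lam^2 + gam^2
    =>  lam = sqrt(rel * con),  gam = sqrt(rel * (1 - con)),  Theta = 1 - rel,

taking positive roots throughout (signs are not identified; positivity
matches the consistency parameterization).  Reference-method indicators of
a CMm1 population have gam = 0 and lam = sqrt(rel).  Consistency 0 is
rejected (it would leave the trait factor empirically undefined in the
uncorrelated-methods family).

Indicator reliabilities are jittered around the base as
rel_im = rel + (Beta(3,3) - 0.5) * 0.05, keeping each value within
±0.025 of the base and centered on it.  Two deliberate choices:

- **Jitter is drawn once per cell** and the resulting population
  covariance held fixed across that cell's replications.  Redrawing per
  replication would turn each cell's rates into a mixture over
  populations; a fixed population makes cell-level rates interpretable
  and exactly reproducible from the cell's jitter seed.
- **UM_constrained populations jitter per indicator** (3 draws shared
  across methods, 9 for CMm1 populations).  Method-varying jitter would
  contradict the loading-invariance the interchangeable-methods family is
  defined by, making the "correctly specified" arm slightly misspecified.

Samples are i.i.d. multivariate normal with mean zero; the sample
covariance S uses divisor N - 1, paired with the Wishart chi-square
convention below.

## Estimation

Each fit minimizes the normal-theory ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma^-1(theta)) - ln|S| - 9

over the free parameters, with shared labels moving in lockstep.
Estimates are deliberately *unbounded*: negative error variances and
out-of-range correlations must remain representable, because improper
solutions are one of the study's outcomes.

The optimizer is BFGS with the analytic gradient
tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma_j].  The line search backtracks
by halving (at most 50 times) and rejects any step at which Sigma(theta)
leaves the positive-definite cone; a fully stalled line search ends the
fit as non-converged.  Starting values are scale-aware and deterministic:
trait loadings sqrt(0.5 S_ii), method loadings sqrt(0.25 S_ii), error
variances 0.5 S_ii, correlations 0 (shared labels use the mean S_ii over
their positions).  The iteration cap is 1000; reaching it marks the fit
non-converged.

**Convergence criterion.**  Non-convergence *rates* — a headline outcome —
depend directly on the stopping rule, and the CM family makes the
dependence severe: fit to data lacking its structure, the CT-CM model is
empirically underidentified, so the minimum is a nearly flat manifold on
which the gradient decays very slowly.  We verified that this is a
property of the surface, not of the implementation: at a strict tolerance
(max|grad| < 1e-5 plus a 1e-6 relative-step condition) our BFGS, SciPy's
reference BFGS, and a Levenberg-regularized Fisher-scoring variant all
fail to converge on essentially the same large fraction of CM fits.  The
package therefore uses the derivative-only criterion at the magnitude the
mainstream SEM software's quasi-Newton estimator documents as its default,

    converged  <=>  max_j |dF/dtheta_j| < 5e-5,

within the 1000-iteration cap.  The stricter dialect remains available
(`fit_ml(..., gtol=1e-5, xtol=1e-6)`) and is what the exact-identity tests
use, since at a true isolated optimum it buys parameter accuracy at
trivial cost.  Absolute non-convergence rates under any criterion other
than the original software's exact (undocumented) test can differ beyond
sampling error; the qualitative ordering across families is robust.

**Implementation.**  The inner BFGS loop exists twice: a pure-NumPy
reference and a numba-compiled kernel (the default when numba is
importable) with a hand-written 9x9 Cholesky factorization whose
positive-definiteness check is a returned flag rather than an exception.
The two paths implement the same algorithm and are cross-checked in the
test suite; on degenerate surfaces (non-converging CM fits) their
trajectories can diverge in the last floating-point digit over hundreds
of iterations, so individual borderline convergence flags may differ
between engines while pooled rates agree to sampling noise.  The engine
is selectable per fit (`fit_ml(..., engine="numpy")`).

**Standard errors** come from the expected (Fisher) information of
(N - 1)/2 * F_ML: I_jk = (N - 1)/2 tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k),
inverted once per converged fit.  Labels with a singular or non-positive
information entry are reported without an SE and logged; downstream
significance tests treat such loadings as indeterminate (excluded by
default, countable as non-significant via a flag).

**Improper solutions** are evaluated for converged fits only, with
requested replications as the denominator (matching the study's outcome
definitions): a Theta error is any negative estimated error variance
(Theta is diagonal); a Psi error is a smallest eigenvalue below -1e-8 of
the latent correlation matrix assembled from the estimated method-factor
correlations.  UM-family fits fix Psi = I and can never produce Psi
errors.

## Fit evaluation

T = c * F_ML with multiplier c = N - 1 (the "wishart" dialect, pairing
with the N - 1 covariance divisor; c = N available as the "normal"
dialect, and the RMSEA denominator switches with the same flag).  The
p-value uses the chi-square distribution at df = 45 minus the number of
free parameters.  RMSEA = sqrt(max(T - df, 0) / (df * c)).  The CFI
baseline is the independence model, fit in closed form (Sigma_b = diag(S),
T_b = c [sum ln S_ii - ln|S|], df_b = 36).  SRMR averages squared
standardized residuals over all 45 unique cells, diagonal included (the
variant choice matters little here because every family frees one error
variance per indicator, leaving near-zero diagonal residuals).

Rejection rules: p < 0.05, RMSEA > 0.05, CFI < 0.95, SRMR > 0.05, with
boundary values counting as acceptable.  Rejection rates are reported
among converged fits by default (the denominator is recorded and
switchable).  Two small-sample facts worth knowing when reading the
output: at N = 250 and nine indicators, sampling noise alone puts SRMR
near its 0.05 cutoff, so a correct 30-df model is "rejected" by SRMR
roughly 40% of the time — a property of the cutoff, not of the model; and
with within-method correlations equal to the reliability (>= 0.6), the
independence baseline is rejected so decisively that CFI has essentially
no power to reject a correct model (the population baseline statistic
minus its df is at least ~750 at N = 250 across the whole constrained
grid, so CFI < 0.95 would require a chi-square excess with probability
~1e-4).

## Loading significance and method-factor collapse

A loading is non-significant when its Wald 95% confidence interval
contains 0; significance requires |estimate|/SE strictly greater than
1.959964 (a closed interval, so the boundary counts as non-significant).
Loadings are grouped in six method-wise sets (Sets 1-3 trait, Sets 4-6
method loadings); a method factor *collapses* when all three of its
loadings are jointly non-significant.  In fitted CMm1 models the
reference-method set is structurally zero and excluded.  Collapse rates
are computed over converged fits; replications with improper solutions
are kept (their removal is a flag on the summary consumer side, as the
original report is silent on this).

## Simulation harness and reproducibility

One dataset is drawn per (cell, replication) and every requested family is
fit to that same dataset.  Per-replication seeds derive from
(master seed, CRC-32 of the cell id, replication index) through numpy's
`SeedSequence`, so any subset of cells run in any order reproduces the
full run's numbers exactly; cell-level jitter seeds derive the same way.
A crashed fit is contained, logged, and counted as non-converged.

## Problem sizes for the shipped runs

The package's own scaled profiles (chosen to keep a complete rerun on one
CPU in minutes; all tables carry their replication counts):

- acceptance script: CM fits at 100 reps/cell on the 54 constrained cells
  and 50 reps/cell on the 162 methods-minus-one cells; correctly
  specified fits at 100 reps/cell; the full 864-entry grid at 20
  reps/cell; the CFI check at 200 reps/cell on the 27 constrained
  N = 250 cells.
- test suite: the same design at 20/10 reps per cell, plus targeted
  cells at up to 300 replications for rate calibration checks.

Binomial noise at these sizes is a few percentage points on pooled rates;
the comparisons in the tests carry tolerances sized accordingly.

## Known limitations

- Absolute non-convergence and improper-solution rates are tied to the
  convergence criterion (see above); only their qualitative ordering
  across model families should be read as substantive.
- The generator covers complete multivariate-normal data only — no
  missingness, non-normality, or ordinal indicators — and single-trait
  designs; multi-trait variants, mean structures, and cross-loadings are
  out of scope.
- Reliability jitter fixed per cell (rather than redrawn per replication)
  is a documented interpretation of an ambiguous design detail; rates in
  cells with extreme consistency are mildly sensitive to it.
- Passing tests on these synthetic populations show the pipeline
  reproduces the *simulated* phenomena; they say nothing about any
  particular empirical MTMM dataset beyond what the model assumptions
  warrant.
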