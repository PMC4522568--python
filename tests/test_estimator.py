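"""Maximum-likelihood estimation: identities, recovery, SEs, diagnostics."""

import numpy as np
import pytest

from mtmmsim import (
    PopulationCell,
    build_model,
    check_npd,
    derive_population_point,
    fit_ml,
    ml_discrepancy,
    population_covariance,
    sample_dataset,
)
from mtmmsim.model_space import Family, compile_spec, implied_covariance
from conftest import random_admissible_point


def _own_population(fam, seed=3):
    if fam in (Family.UM_CONSTRAINED, Family.UM_UNCONSTRAINED):
        cell = PopulationCell(Family.UM_CONSTRAINED, 1000, 0.5, 0.7, 0.0, jitter_seed=seed)
    else:
        cell = PopulationCell(Family.CMM1, 1000, 0.5, 0.7, 0.5, jitter_seed=seed)
    return cell, population_covariance(cell)


@pytest.mark.parametrize("fam", list(Family))
def test_perfect_fit_recovers_population(fam):
    """Fitting a correctly specified family to its own population covariance
    reaches zero discrepancy and the generating point."""
    cell, sig = _own_population(fam)
    spec = build_model(fam, 1 if fam is Family.CMM1 else None)
    fit = fit_ml(spec, sig, 1000, gtol=1e-5, xtol=1e-6)
    assert fit.converged
    assert fit.discrepancy <= 1e-9
    if fam is cell.population_family:
        pop = derive_population_point(cell)
        err = max(abs(fit.point[k] - v) for k, v in pop.values.items())
        assert err <= 1e-5


def test_fixed_point_identity():
    """Refitting a model to its own fitted covariance gives discrepancy 0."""
    cell, sig = _own_population(Family.CMM1)
    _, s = sample_dataset(sig, 250, 10)
    spec = build_model(Family.CMM1, 1)
    fit = fit_ml(spec, s, 250, compute_se=False)
    assert fit.converged
    sigma_hat = implied_covariance(spec, fit.point)
    refit = fit_ml(spec, sigma_hat, 250, compute_se=False)
    assert refit.discrepancy <= 1e-8


def test_discrepancy_nonnegative_on_random_pd_pairs():
    """F_ML >= 0 with equality iff the two matrices coincide."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        a = rng.standard_normal((9, 12))
        b = rng.standard_normal((9, 12))
        s1 = a @ a.T / 12 + 0.1 * np.eye(9)
        s2 = b @ b.T / 12 + 0.1 * np.eye(9)
        assert ml_discrepancy(s1, s2) > 0
        assert abs(ml_discrepancy(s1, s1)) < 1e-10


def test_nested_discrepancy_ordering():
    """On one dataset, more general families reach lower discrepancies."""
    _, sig = _own_population(Family.CMM1)
    for seed in range(8):
        _, s = sample_dataset(sig, 1000, seed)
        fits = {
            fam: fit_ml(build_model(fam, 1 if fam is Family.CMM1 else None), s, 1000,
                        compute_se=False)
            for fam in Family
        }
        if not all(f.converged for f in fits.values()):
            continue
        slack = 1e-6
        assert fits[Family.CM].discrepancy <= fits[Family.UM_UNCONSTRAINED].discrepancy + slack
        assert (fits[Family.UM_UNCONSTRAINED].discrepancy
                <= fits[Family.UM_CONSTRAINED].discrepancy + slack)
        assert fits[Family.CM].discrepancy <= fits[Family.CMM1].discrepancy + slack
        return
    raise AssertionError("no replication with four converged fits")


def test_unconstrained_fit_recovers_constrained_population():
    """UM_unconstrained nests UM_constrained: fitted to the constrained
    population covariance it reaches F=0 with method-wise equal loadings."""
    cell, sig = _own_population(Family.UM_CONSTRAINED)
    spec = build_model(Family.UM_UNCONSTRAINED)
    fit = fit_ml(spec, sig, 1000, compute_se=False, gtol=1e-5, xtol=1e-6)
    assert fit.converged and fit.discrepancy <= 1e-9
    for i in (1, 2, 3):
        lams = [abs(fit.point[f"lam_{i}_{m}"]) for m in (1, 2, 3)]
        assert max(lams) - min(lams) < 1e-4


def test_standard_errors_positive_and_shrink_with_n():
    """SEs are positive and scale roughly as 1/sqrt(N)."""
    cell, sig = _own_population(Family.UM_CONSTRAINED)
    spec = build_model(Family.UM_CONSTRAINED)
    ratios = []
    for seed in range(40):
        _, s_small = sample_dataset(sig, 250, 1000 + seed)
        _, s_large = sample_dataset(sig, 1000, 2000 + seed)
        f_small = fit_ml(spec, s_small, 250)
        f_large = fit_ml(spec, s_large, 1000)
        if not (f_small.converged and f_large.converged):
            continue
        assert all(v > 0 for v in f_small.standard_errors.values())
        lab = "lam_1"
        ratios.append(f_large.standard_errors[lab] / f_small.standard_errors[lab])
    mean_ratio = np.mean(ratios)
    assert 0.4 < mean_ratio < 0.6  # 0.5 +- 20%


def test_loading_z_ratios_all_significant_in_easy_condition():
    """Correct UM_constrained at rel 0.8, con 0.5, N = 1000: every loading
    z-ratio exceeds 1.96 in nearly all replications."""
    cell = PopulationCell(Family.UM_CONSTRAINED, 1000, 0.5, 0.8, 0.0, jitter_seed=6)
    sig = population_covariance(cell)
    spec = build_model(Family.UM_CONSTRAINED)
    n_all_sig = n_conv = 0
    for seed in range(60):
        _, s = sample_dataset(sig, 1000, 3000 + seed)
        fit = fit_ml(spec, s, 1000)
        if not fit.converged:
            continue
        n_conv += 1
        zs = [
            abs(fit.point[lab]) / fit.standard_errors[lab]
            for lab in [f"lam_{i}" for i in (1, 2, 3)] + [f"gam_{i}" for i in (1, 2, 3)]
        ]
        n_all_sig += all(z > 1.96 for z in zs)
    assert n_conv >= 55
    assert n_all_sig / n_conv >= 0.97


def test_compiled_and_reference_engines_agree():
    """The compiled fit loop and the pure-NumPy reference implement the same
    algorithm: on well-behaved fits they return the same solution."""
    cell = PopulationCell(Family.CMM1, 1000, 0.5, 0.8, 0.5, jitter_seed=4)
    sig = population_covariance(cell)
    spec = build_model(Family.CMM1, 1)
    for seed in range(5):
        _, s = sample_dataset(sig, 1000, 40 + seed)
        fa = fit_ml(spec, s, 1000, engine="numba")
        fb = fit_ml(spec, s, 1000, engine="numpy")
        assert fa.converged and fb.converged
        assert abs(fa.discrepancy - fb.discrepancy) < 1e-8
        err = max(abs(fa.point[k] - fb.point[k]) for k in fa.point.values)
        assert err < 1e-5


def test_determinism():
    _, sig = _own_population(Family.CM)
    _, s = sample_dataset(sig, 250, 4)
    spec = build_model(Family.CM)
    f1 = fit_ml(spec, s, 250)
    f2 = fit_ml(spec, s, 250)
    assert f1.converged == f2.converged and f1.iterations == f2.iterations
    assert f1.point.values == f2.point.values
    assert f1.standard_errors == f2.standard_errors


@pytest.mark.parametrize(
    "matrix,expected",
    [
        (np.eye(3), False),
        (np.diag([1.0, -0.01]), True),
        (np.array([[1.0, 1.2], [1.2, 1.0]]), True),  # eigenvalues 2.2, -0.2
        (np.array([[1.0, 0.9], [0.9, 1.0]]), False),
    ],
)
def test_check_npd(matrix, expected):
    assert check_npd(matrix) is expected


def test_check_npd_rejects_nonsquare():
    with pytest.raises(ValueError):
        check_npd(np.zeros((2, 3)))


def test_fit_input_validation():
    spec = build_model(Family.CM)
    with pytest.raises(ValueError):
        fit_ml(spec, np.eye(8), 100)
    with pytest.raises(ValueError):
        fit_ml(spec, np.eye(9), 5)
    npd = np.eye(9)
    npd[0, 0] = -1.0
    with pytest.raises(ValueError):
        fit_ml(spec, npd, 100)


def test_improper_solution_flags_on_synthetic_extremes():
    """A fit forced onto a non-PD psi or negative theta is flagged."""
    spec = build_model(Family.CM)
    rng = np.random.default_rng(1)
    point = random_admissible_point(spec, rng)
    point.values["theta_1_1"] = -0.05
    sig = compile_spec(spec).sigma(point.as_vector(spec))
    # the implied covariance can stay PD with one slightly negative error
    if np.linalg.eigvalsh(sig)[0] > 1e-6:
        fit = fit_ml(spec, sig, 1000, compute_se=False)
        if fit.converged and fit.discrepancy < 1e-8:
            assert fit.theta_npd
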