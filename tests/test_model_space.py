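"""Structure and implied covariance of the four model families."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtmmsim import build_model, count_free_parameters, implied_covariance, fit_ml
from mtmmsim.model_space import (
    Family,
    ModelSpec,
    ParameterPoint,
    var_index,
    N_VARS,
)
from conftest import random_admissible_point


def hand_expanded_covariance(spec, point):
    """Independent oracle: expand the linear factor model entry by entry.

    cov(Y_im, Y_jm') = lam lam' + gam gam' * corr(M_m, M_m'), plus the error
    variance on the diagonal; corr is 1 for the same method factor, a free
    correlation when the spec correlates the two factors, else 0.
    """
    corr = {}
    for lab, (a, b) in spec.free_correlations.items():
        corr[(a, b)] = corr[(b, a)] = point[lab]
    sig = np.zeros((9, 9))
    for m1 in range(1, 4):
        for i1 in range(1, 4):
            for m2 in range(1, 4):
                for i2 in range(1, 4):
                    v1, v2 = var_index(i1, m1), var_index(i2, m2)
                    lam1 = point[spec.trait_loading_pattern[(i1, m1)]]
                    lam2 = point[spec.trait_loading_pattern[(i2, m2)]]
                    g1 = spec.method_loading_pattern[(i1, m1)]
                    g2 = spec.method_loading_pattern[(i2, m2)]
                    val = lam1 * lam2
                    if g1 is not None and g2 is not None:
                        rho = 1.0 if m1 == m2 else corr.get((m1, m2), 0.0)
                        val += point[g1] * point[g2] * rho
                    if v1 == v2:
                        val += point[spec.error_pattern[(i1, m1)]]
                    sig[v1, v2] = val
    return sig


@pytest.mark.parametrize(
    "family,ref,n_params",
    [
        (Family.UM_CONSTRAINED, None, 15),
        (Family.CMM1, 1, 25),
        (Family.UM_UNCONSTRAINED, None, 27),
        (Family.CM, None, 30),
    ],
)
def test_free_parameter_counts(family, ref, n_params):
    assert count_free_parameters(build_model(family, ref)) == n_params


def test_parameter_count_ordering():
    counts = [
        count_free_parameters(build_model(f, 1 if f is Family.CMM1 else None))
        for f in (Family.UM_CONSTRAINED, Family.CMM1, Family.UM_UNCONSTRAINED, Family.CM)
    ]
    assert counts == sorted(counts) and len(set(counts)) == 4


def test_family_constraint_structure(all_specs):
    um_c = all_specs[Family.UM_CONSTRAINED]
    assert len(set(um_c.trait_loading_pattern.values())) == 3
    assert len(set(um_c.method_loading_pattern.values())) == 3
    assert not um_c.free_correlations

    um_u = all_specs[Family.UM_UNCONSTRAINED]
    assert len(set(um_u.trait_loading_pattern.values())) == 9
    assert len(set(um_u.method_loading_pattern.values())) == 9

    cmm1 = all_specs[Family.CMM1]
    ref_gammas = [cmm1.method_loading_pattern[(i, 1)] for i in (1, 2, 3)]
    assert ref_gammas == [None, None, None]
    assert len(cmm1.free_correlations) == 1
    assert cmm1.method_factors == (2, 3)

    cm = all_specs[Family.CM]
    assert len(cm.free_correlations) == 3


def test_build_model_errors():
    with pytest.raises(ValueError):
        build_model("nonsense")
    with pytest.raises(ValueError):
        build_model(Family.CMM1, 4)
    with pytest.raises(ValueError):
        build_model(Family.CM, 1)  # reference method only for CMm1


def test_incomplete_point_rejected(all_specs):
    spec = all_specs[Family.CM]
    with pytest.raises(ValueError):
        implied_covariance(spec, ParameterPoint({"lam_1_1": 0.5}))


def test_implied_covariance_all_zero_loadings(all_specs):
    spec = all_specs[Family.UM_UNCONSTRAINED]
    values = {lab: 0.0 for lab in spec.free_labels}
    for m in range(1, 4):
        for i in range(1, 4):
            values[spec.error_pattern[(i, m)]] = 0.3 + 0.01 * var_index(i, m)
    sig = implied_covariance(spec, ParameterPoint(values))
    assert np.allclose(sig, np.diag([values[spec.error_pattern[(i, m)]]
                                     for m in range(1, 4) for i in range(1, 4)]))


def test_implied_covariance_um_constrained_example(all_specs):
    """lam_i = gam_i = sqrt(0.4), theta = 0.2: unit variances, within-method
    covariance 0.8, cross-method covariance 0.4."""
    spec = all_specs[Family.UM_CONSTRAINED]
    v = np.sqrt(0.4)
    values = {f"lam_{i}": v for i in (1, 2, 3)}
    values |= {f"gam_{i}": v for i in (1, 2, 3)}
    values |= {lab: 0.2 for lab in spec.error_pattern.values()}
    point = ParameterPoint(values)
    sig = implied_covariance(spec, point)
    assert np.allclose(sig, hand_expanded_covariance(spec, point), atol=1e-12)
    assert np.allclose(np.diag(sig), 1.0)
    assert np.isclose(sig[var_index(1, 1), var_index(2, 1)], 0.8)  # same method
    assert np.isclose(sig[var_index(1, 1), var_index(1, 2)], 0.4)  # across methods


def test_implied_covariance_cmm1_correlated_methods(all_specs):
    """Cross-method covariance between the two non-reference methods carries
    the correlation-weighted gamma product."""
    spec = all_specs[Family.CMM1]
    rng = np.random.default_rng(5)
    point = random_admissible_point(spec, rng)
    point.values["rho_2_3"] = 0.8
    sig = implied_covariance(spec, point)
    assert np.allclose(sig, hand_expanded_covariance(spec, point), atol=1e-12)
    lam12, lam13 = point["lam_1_2"], point["lam_1_3"]
    g12, g13 = point["gam_1_2"], point["gam_1_3"]
    assert np.isclose(
        sig[var_index(1, 2), var_index(1, 3)], lam12 * lam13 + 0.8 * g12 * g13
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10**6), st.sampled_from(list(Family)))
def test_implied_covariance_symmetric_and_psd(seed, family):
    """Admissible points give symmetric PSD implied covariances."""
    spec = build_model(family, 1 if family is Family.CMM1 else None)
    point = random_admissible_point(spec, np.random.default_rng(seed))
    sig = implied_covariance(spec, point)
    assert np.allclose(sig, sig.T)
    assert np.linalg.eigvalsh(sig)[0] >= -1e-10


@pytest.mark.parametrize(
    "inner,outer",
    [
        (Family.UM_CONSTRAINED, Family.UM_UNCONSTRAINED),
        (Family.UM_CONSTRAINED, Family.CM),
        (Family.UM_UNCONSTRAINED, Family.CM),
        (Family.CMM1, Family.CM),
    ],
)
def test_nesting_attainability(inner, outer):
    """Every implied covariance of a nested family is attainable by the
    nesting family: refitting reaches discrepancy <= 1e-6."""
    inner_spec = build_model(inner, 1 if inner is Family.CMM1 else None)
    outer_spec = build_model(outer)
    rng = np.random.default_rng(42)
    for _ in range(5):
        point = random_admissible_point(inner_spec, rng)
        sig = implied_covariance(inner_spec, point)
        fit = fit_ml(outer_spec, sig, 1000, compute_se=False, gtol=1e-5, xtol=1e-6)
        assert fit.discrepancy <= 1e-6


def test_spec_serialization_roundtrip(all_specs):
    for spec in all_specs.values():
        assert ModelSpec.from_yaml(spec.to_yaml()) == spec
        assert ModelSpec.from_json(spec.to_json()) == spec
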