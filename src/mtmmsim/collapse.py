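"""Non-significant loadings and method-factor collapse detection.

A loading is non-significant when its Wald 95% confidence interval
contains 0, i.e. |estimate| <= z * SE with z = 1.959964; significance
requires the strict inequality |z-ratio| > 1.959964 (boundary values count
as non-significant, matching a closed confidence interval).

Loadings are grouped into six sets of three, one set per method: Sets 1-3
are the trait loadings of methods 1-3, Sets 4-6 the method loadings of
methods 1-3.  A method factor collapses when all three of its loadings are
jointly non-significant.  In a fitted CMm1 model the reference method's
loading set is structurally zero and excluded from collapse statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .estimator import FitResult
from .model_space import Family, ModelSpec

ALPHA = 0.05
Z_CRITICAL = float(stats.norm.ppf(1.0 - ALPHA / 2.0))  # 1.959964


@dataclass(frozen=True)
class LoadingSignificanceProfile:
    """Per-set non-significance counts and per-method-factor collapse flags.

    ``nonsig_counts`` maps set number (1-6) to the count (0-3) of
    non-significant loadings in that set; sets that are structurally zero
    in the fitted model map to None, as do the collapse flags of excluded
    method factors.  ``indeterminate`` counts loadings whose SE was
    unavailable (excluded from the non-significance counts by default).
    """

    nonsig_counts: dict
    collapse: dict
    indeterminate: int = 0


def loading_significance(
    fit: FitResult, alpha: float = ALPHA, count_indeterminate: bool = False
) -> dict:
    """Per-loading non-significance map (label -> bool or None).

    None marks an indeterminate loading (missing SE); ``count_indeterminate``
    turns those into non-significant instead.
    """
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    out: dict = {}
    spec = fit.spec
    for pattern in (spec.trait_loading_pattern, spec.method_loading_pattern):
        for key, lab in pattern.items():
            if lab is None or lab in out:
                continue
            se = fit.standard_errors.get(lab)
            if se is None or se <= 0.0:
                out[lab] = True if count_indeterminate else None
            else:
                out[lab] = not (abs(fit.point[lab]) > z * se)
    return out


def _set_labels(spec: ModelSpec, set_number: int) -> Optional[list]:
    """Labels of one of the six loading sets; None if structurally zero."""
    if set_number <= 3:
        m = set_number
        return [spec.trait_loading_pattern[(i, m)] for i in (1, 2, 3)]
    m = set_number - 3
    labs = [spec.method_loading_pattern[(i, m)] for i in (1, 2, 3)]
    if any(lab is None for lab in labs):
        return None
    return labs


def loading_profile(
    fit: FitResult, alpha: float = ALPHA, count_indeterminate: bool = False
) -> LoadingSignificanceProfile:
    """Group per-loading significance into the six method-wise sets."""
    sig = loading_significance(fit, alpha, count_indeterminate)
    counts: dict = {}
    indeterminate = 0
    for set_number in range(1, 7):
        labs = _set_labels(fit.spec, set_number)
        if labs is None:
            counts[set_number] = None
            continue
        # a shared label (UM_constrained) contributes its verdict to each set
        votes = [sig[lab] for lab in labs]
        indeterminate += sum(v is None for v in votes)
        counts[set_number] = sum(v is True for v in votes)
    collapse = _collapse_from_counts(fit.spec, counts)
    return LoadingSignificanceProfile(
        nonsig_counts=counts, collapse=collapse, indeterminate=indeterminate
    )


def _collapse_from_counts(spec: ModelSpec, counts: dict) -> dict:
    collapse: dict = {}
    for m in (1, 2, 3):
        c = counts[3 + m]
        collapse[m] = None if c is None else (c == 3)
    return collapse


def detect_collapse(fit: FitResult, spec: Optional[ModelSpec] = None, alpha: float = ALPHA) -> dict:
    """Per-method-factor collapse: all three method loadings non-significant.

    Returns a map method -> bool, with None for a structurally-zero factor
    (the CMm1 reference method, which has no method factor to collapse).
    """
    if spec is not None and spec.family is not fit.spec.family:
        raise ValueError("spec does not match the fitted model")
    return loading_profile(fit, alpha).collapse
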