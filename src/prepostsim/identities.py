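"""Exact algebra linking post-test and change-score regressions.

With the centered pre-test T1 among the predictors, the OLS fit with the
post-test as criterion (coefficients b) and the fit with the absolute
change as criterion (coefficients c) on the same dataset satisfy, exactly:

* ``b_pre = c_pre + 1`` — the change-score pre-test slope is the post-test
  slope minus one, hence negative whenever the pre/post regression slope is
  below 1 (which unreliable measures guarantee);
* ``b_k = c_k`` for every other slope;
* ``b_0 = c_0 + mean(uncentered pre)``.

A corollary is that the non-pre-test slopes are identical across the
post-test, absolute-change and residualized-change criteria, so the choice
among those three criteria is immaterial once the pre-test is in the model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .criteria import CriterionKind
from .regression import INTERCEPT, PRE, FitResult

__all__ = ["IdentityReport", "verify_change_identities", "verify_criterion_equivalence"]


@dataclass(frozen=True)
class TermCheck:
    term: str
    b: float
    c: float
    expected_b: float
    discrepancy: float
    passed: bool


@dataclass(frozen=True)
class IdentityReport:
    mean_pre_nc: float
    tolerance: float
    checks: tuple[TermCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def max_discrepancy(self) -> float:
        return max(abs(c.discrepancy) for c in self.checks)

    def as_dict(self) -> dict:
        return {
            "mean_pre_nc": self.mean_pre_nc,
            "tolerance": self.tolerance,
            "passed": self.passed,
            "checks": [vars(c) for c in self.checks],
        }


def _require_same_model(fit_a: FitResult, fit_b: FitResult) -> None:
    if fit_a.terms != fit_b.terms or fit_a.model_id != fit_b.model_id:
        raise ValueError("fits come from different model specifications")
    if fit_a.n_obs != fit_b.n_obs or fit_a.data_source != fit_b.data_source:
        raise ValueError("fits do not come from the same dataset")


def verify_change_identities(
    fit_post: FitResult,
    fit_change: FitResult,
    mean_pre_nc: float,
    tolerance: float = 1e-8,
) -> IdentityReport:
    """Check the post-test/change-score coefficient identities on two fits.

    ``fit_post`` and ``fit_change`` must be the same model (with the
    pre-test term) fitted on the same dataset with the post-test and
    absolute-change criteria respectively; ``mean_pre_nc`` is the mean of
    the uncentered pre-test scores.
    """
    _require_same_model(fit_post, fit_change)
    if fit_post.criterion is not CriterionKind.POST_TEST:
        raise ValueError(f"fit_post has criterion {fit_post.criterion.value}")
    if fit_change.criterion is not CriterionKind.ABSOLUTE_CHANGE:
        raise ValueError(f"fit_change has criterion {fit_change.criterion.value}")
    if PRE not in fit_post.terms:
        raise ValueError("the identities require the pre-test term in the model")

    checks = []
    for term in fit_post.terms:
        b = fit_post[term]
        c = fit_change[term]
        if term == PRE:
            expected = c + 1.0
        elif term == INTERCEPT:
            expected = c + mean_pre_nc
        else:
            expected = c
        disc = b - expected
        checks.append(
            TermCheck(
                term=term,
                b=b,
                c=c,
                expected_b=expected,
                discrepancy=disc,
                passed=abs(disc) <= tolerance,
            )
        )
    return IdentityReport(mean_pre_nc=mean_pre_nc, tolerance=tolerance, checks=tuple(checks))


def verify_criterion_equivalence(
    fits: dict[CriterionKind, FitResult] | list[FitResult],
    tolerance: float = 1e-8,
) -> dict[str, bool]:
    """Check that non-pre-test slopes agree across the three raw-unit criteria.

    ``fits`` must contain fits of one model (which includes the pre-test
    term) on one dataset for the post-test, absolute-change and
    residualized-change criteria.  Returns a pass flag per shared slope
    term.  The relative-change criterion lives on a different scale and is
    deliberately outside this equivalence.
    """
    if not isinstance(fits, dict):
        fits = {f.criterion: f for f in fits}
    needed = (
        CriterionKind.POST_TEST,
        CriterionKind.ABSOLUTE_CHANGE,
        CriterionKind.RESIDUAL_SCORE,
    )
    missing = [c.value for c in needed if c not in fits]
    if missing:
        raise ValueError(f"missing fits for criteria: {missing}")
    ref = fits[needed[0]]
    for other in needed[1:]:
        _require_same_model(ref, fits[other])
    if PRE not in ref.terms:
        raise ValueError(
            "criterion equivalence only holds when the pre-test is a predictor; "
            f"model {ref.model_id} does not include it"
        )

    result: dict[str, bool] = {}
    for term in ref.terms:
        if term in (INTERCEPT, PRE):
            continue  # these transform between criteria rather than agree
        values = [fits[c][term] for c in needed]
        result[term] = max(values) - min(values) <= tolerance
    return result
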