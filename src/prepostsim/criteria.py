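"""The four criterion (dependent) variables of the pre/post design.

post-test score, absolute change (post - pre), relative change in percent
(100 * (post - pre) / pre), and the residualized change score — residuals of
post regressed on pre in the pooled sample.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "CriterionKind",
    "post_test",
    "absolute_change",
    "relative_change",
    "residual_score",
    "compute_criterion",
]


class CriterionKind(str, enum.Enum):
    POST_TEST = "post_test"
    ABSOLUTE_CHANGE = "absolute_change"
    RELATIVE_CHANGE = "relative_change"
    RESIDUAL_SCORE = "residual_score"


def _as_pair(pre, post):
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"pre and post lengths differ: {pre.shape} vs {post.shape}")
    return pre, post


def post_test(pre, post) -> np.ndarray:
    _, post = _as_pair(pre, post)
    return post


def absolute_change(pre, post) -> np.ndarray:
    """post - pre, raw units."""
    pre, post = _as_pair(pre, post)
    return post - pre


def relative_change(pre, post) -> np.ndarray:
    """Percent change relative to the pre-test score: 100 * (post - pre) / pre."""
    pre, post = _as_pair(pre, post)
    zero = np.flatnonzero(pre == 0.0)
    if zero.size:
        raise ZeroDivisionError(
            f"relative change undefined: pre-test score is 0 at subject index {zero[0]}"
        )
    return 100.0 * (post - pre) / pre


def residual_score(pre, post) -> np.ndarray:
    """Residuals of post on pre from one pooled least-squares line.

    Both groups are fitted together, so group differences show up as mean
    residual differences (the treated group lies above the common line).
    The residuals have mean zero and zero sample correlation with pre.
    """
    pre, post = _as_pair(pre, post)
    if pre.size < 3:
        raise ValueError("residual score needs at least 3 subjects")
    sxx = np.sum((pre - pre.mean()) ** 2)
    if sxx == 0.0:
        raise ValueError("residual score undefined: pre-test has zero variance")
    slope = np.sum((pre - pre.mean()) * (post - post.mean())) / sxx
    fitted = post.mean() + slope * (pre - pre.mean())
    return post - fitted


_DISPATCH = {
    CriterionKind.POST_TEST: post_test,
    CriterionKind.ABSOLUTE_CHANGE: absolute_change,
    CriterionKind.RELATIVE_CHANGE: relative_change,
    CriterionKind.RESIDUAL_SCORE: residual_score,
}


def compute_criterion(pre, post, kind: CriterionKind | str) -> np.ndarray:
    return _DISPATCH[CriterionKind(kind)](pre, post)
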