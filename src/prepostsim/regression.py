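"""Design matrices for the five candidate prediction models and OLS fitting.

The five predictor sets range from "external predictors only" (Model 1) to
the full moderation model with pre-test, group and predictor-by-group
interactions (Model 4), plus the same without the pre-test (Model 5):

====== ==========================================
Model  Predictors
====== ==========================================
1      P1, P2
2      P1, P2, pre
3      P1, P2, pre, group
4      P1, P2, pre, group, P1:group, P2:group
5      P1, P2, group, P1:group, P2:group
====== ==========================================

Continuous predictors are centered at their full-sample means; group is a
0/1 dummy (0 = control, 1 = experimental); interaction columns are
centered-predictor times dummy.  Inference is textbook homoskedastic OLS:
coefficient covariance sigma^2 (X'X)^-1 with sigma^2 = RSS/(n-k) and
two-sided t p-values on n-k degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .criteria import CriterionKind, compute_criterion

__all__ = [
    "ModelSpec",
    "FitResult",
    "SingularDesignError",
    "build_design",
    "ols_fit",
    "fit_cell",
    "MODEL_IDS",
]

MODEL_IDS = (1, 2, 3, 4, 5)

# term identifiers, in design-matrix column order
INTERCEPT = "intercept"
P1, P2, PRE, GROUP = "p1", "p2", "pre", "group"
P1_GROUP, P2_GROUP = "p1:group", "p2:group"


class SingularDesignError(np.linalg.LinAlgError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """One of the five predictor sets."""

    model_id: int
    include_pre: bool
    include_group: bool
    include_interactions: bool

    def __post_init__(self) -> None:
        if self.include_interactions and not self.include_group:
            raise ValueError("interaction terms require the group dummy")

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        table = {
            1: (False, False, False),
            2: (True, False, False),
            3: (True, True, False),
            4: (True, True, True),
            5: (False, True, True),
        }
        if model_id not in table:
            raise ValueError(f"model_id must be in 1..5, got {model_id}")
        pre, grp, inter = table[model_id]
        return cls(model_id, include_pre=pre, include_group=grp, include_interactions=inter)

    def term_names(self, with_p2: bool = True) -> list[str]:
        terms = [INTERCEPT, P1]
        if with_p2:
            terms.append(P2)
        if self.include_pre:
            terms.append(PRE)
        if self.include_group:
            terms.append(GROUP)
        if self.include_interactions:
            terms.append(P1_GROUP)
            if with_p2:
                terms.append(P2_GROUP)
        return terms


@dataclass(frozen=True)
class FitResult:
    """OLS estimates for one (dataset, criterion, model) combination."""

    model_id: int
    criterion: CriterionKind
    data_source: str
    terms: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    df_resid: int
    n_obs: int

    def __getitem__(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def p_value(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "criterion": self.criterion.value,
            "data_source": self.data_source,
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "terms": [
                {
                    "term": t,
                    "estimate": float(b),
                    "standard_error": float(se),
                    "p_value": float(p),
                }
                for t, b, se, p in zip(
                    self.terms, self.estimates, self.standard_errors, self.p_values
                )
            ],
        }


def build_design(data, criterion: CriterionKind | str, model: ModelSpec | int):
    """Assemble (X, y, term names) for one model/criterion on one dataset.

    ``data`` is anything exposing ``pre``, ``post``, ``p1``, ``group`` (and
    optionally ``p2``) as 1-d arrays — a true dataset, an observed dataset,
    or user-supplied tabular data.  The response is computed on the
    *uncentered* pre/post scores; predictors are centered afterwards.
    """
    if isinstance(model, int):
        model = ModelSpec.from_id(model)
    criterion = CriterionKind(criterion)

    p2 = getattr(data, "p2", None)
    terms = model.term_names(with_p2=p2 is not None)
    n = data.pre.size
    if n < len(terms) + 2:
        raise ValueError(f"need at least {len(terms) + 2} subjects for {len(terms)} terms")

    y = compute_criterion(data.pre, data.post, criterion)
    group = np.asarray(data.group, dtype=float)

    columns = {INTERCEPT: np.ones(n)}
    columns[P1] = np.asarray(data.p1, dtype=float) - np.mean(data.p1)
    if p2 is not None:
        columns[P2] = np.asarray(p2, dtype=float) - np.mean(p2)
    if model.include_pre:
        columns[PRE] = np.asarray(data.pre, dtype=float) - np.mean(data.pre)
    if model.include_group:
        columns[GROUP] = group
    if model.include_interactions:
        columns[P1_GROUP] = columns[P1] * group
        if p2 is not None:
            columns[P2_GROUP] = columns[P2] * group

    for name in terms[1:]:
        if np.ptp(columns[name]) == 0.0:
            raise ValueError(f"predictor column {name!r} has zero variance")

    X = np.column_stack([columns[t] for t in terms])
    return X, y, terms


def ols_fit(
    X: np.ndarray,
    y: np.ndarray,
    terms,
    *,
    model_id: int = 0,
    criterion: CriterionKind = CriterionKind.POST_TEST,
    data_source: str = "observed",
) -> FitResult:
    """Ordinary least squares via QR, with classical SEs and t p-values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"no residual degrees of freedom: n={n}, terms={k}")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if np.min(diag) < 1e-10 * max(np.max(diag), 1.0):
        raise SingularDesignError("design matrix is rank deficient")

    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    r_inv = np.linalg.solve(R, np.eye(k))
    se = np.sqrt(sigma2 * np.einsum("ij,ij->i", r_inv, r_inv))
    with np.errstate(divide="ignore"):
        t_stat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)

    return FitResult(
        model_id=model_id,
        criterion=CriterionKind(criterion),
        data_source=data_source,
        terms=tuple(terms),
        estimates=beta,
        standard_errors=se,
        p_values=p,
        df_resid=df,
        n_obs=n,
    )


def fit_cell(data, criterion: CriterionKind | str, model: ModelSpec | int) -> FitResult:
    """Build the design for one model/criterion and fit it by OLS."""
    if isinstance(model, int):
        model = ModelSpec.from_id(model)
    criterion = CriterionKind(criterion)
    X, y, terms = build_design(data, criterion, model)
    return ols_fit(
        X,
        y,
        terms,
        model_id=model.model_id,
        criterion=criterion,
        data_source=getattr(data, "data_source", "observed"),
    )
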