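"""Classical-test-theory measurement layer.

Observed score = true score + independent zero-mean Gaussian noise whose SD
is tied to the measure's true SD and the target reliability
(:func:`prepostsim.truth.error_sd`).  Each of the six measures (pre and post
in both groups, and the two predictors) gets its own independent noise draw;
the experimental post-test noise is scaled to that measure's larger true SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .truth import EXPERIMENTAL, TrueDataset, error_sd

__all__ = ["ObservedDataset", "apply_noise", "empirical_reliability"]


@dataclass
class ObservedDataset:
    """Noisy measurements of a :class:`TrueDataset` at one reliability."""

    truth: TrueDataset = field(repr=False)
    reliability: float
    pre_obs: np.ndarray
    post_obs: np.ndarray
    p1_obs: np.ndarray
    p2_obs: np.ndarray

    data_source = "observed"

    @property
    def group(self) -> np.ndarray:
        return self.truth.group

    @property
    def n_total(self) -> int:
        return self.truth.n_total

    @property
    def pre(self) -> np.ndarray:
        return self.pre_obs

    @property
    def post(self) -> np.ndarray:
        return self.post_obs

    @property
    def p1(self) -> np.ndarray:
        return self.p1_obs

    @property
    def p2(self) -> np.ndarray:
        return self.p2_obs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": np.arange(self.n_total),
                "group": self.truth.group_labels(),
                "pre": self.pre_obs,
                "post": self.post_obs,
                "p1": self.p1_obs,
                "p2": self.p2_obs,
            }
        )


def apply_noise(
    truth: TrueDataset,
    reliability: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> ObservedDataset:
    """Measure a true dataset at the given reliability.

    At reliability 1.0 the observed scores equal the true scores exactly
    (no degenerate noise draws).  Noise is independent across subjects and
    across the four measured variables.
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError(f"reliability must be in (0, 1], got {reliability}")

    spec = truth.spec
    n = truth.n_total
    if reliability == 1.0:
        return ObservedDataset(
            truth=truth,
            reliability=1.0,
            pre_obs=truth.t1_true.copy(),
            post_obs=truth.t2_true.copy(),
            p1_obs=truth.p1_true.copy(),
            p2_obs=truth.p2_true.copy(),
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_pre = error_sd(spec.sd_pre, reliability)
    e_p = error_sd(spec.sd_p, reliability)
    # the post-test error SD follows each group's own true SD: reliability is
    # a variance ratio per measure, and the experimental post-test is wider
    e_post = np.where(
        truth.group == EXPERIMENTAL,
        error_sd(spec.sd_post_exp, reliability),
        error_sd(spec.sd_post_ctl, reliability),
    )

    return ObservedDataset(
        truth=truth,
        reliability=reliability,
        pre_obs=truth.t1_true + rng.normal(0.0, e_pre, n),
        post_obs=truth.t2_true + e_post * rng.standard_normal(n),
        p1_obs=truth.p1_true + rng.normal(0.0, e_p, n),
        p2_obs=truth.p2_true + rng.normal(0.0, e_p, n),
    )


def empirical_reliability(truth_values, observed_values) -> float:
    """Squared Pearson correlation between true and observed scores.

    Under CTT this estimates the reliability of the observed measure
    (shared variance with the true score over total variance).
    """
    t = np.asarray(truth_values, dtype=float)
    o = np.asarray(observed_values, dtype=float)
    if t.shape != o.shape or t.ndim != 1 or t.size < 3:
        raise ValueError("need two equal-length 1-d sequences of at least 3 values")
    if np.std(t) == 0.0 or np.std(o) == 0.0:
        raise ValueError("reliability is undefined for zero-variance input")
    r = np.corrcoef(t, o)[0, 1]
    return float(r * r)
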