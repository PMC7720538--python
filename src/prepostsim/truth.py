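"""True-score generative model for a 2 (group) x 2 (pre/post) intervention design.

The model emulates a cognitive-training-style study: a control and an
experimental group are measured before and after an intervention on a
T-scaled test (mean 50, SD 10), together with two external predictors
(e.g. age and education, also T-scaled).  The experimental group improves
with a medium standardized change (dz = 0.50) and its improvement is
moderately correlated (r = .30) with the first predictor; the second
predictor is a pure null.  The control group shows only a negligible shift
(dz = 0.05).

Effects are defined on *observed* (noisy) scores at a reference reliability
and converted once into constant true-score effects
(:func:`calibrate_true_effects`); the measurement layer
(:mod:`prepostsim.noise`) then attenuates them at whatever reliability a
study cell uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrueModelSpec",
    "CalibratedEffects",
    "TrueDataset",
    "error_sd",
    "attenuate",
    "calibrate_true_effects",
    "generate_true_dataset",
]

CONTROL, EXPERIMENTAL = 0, 1
GROUP_LABELS = {CONTROL: "control", EXPERIMENTAL: "experimental"}


class CalibrationError(ValueError):
    """Raised when the requested targets cannot be realized by any true model."""


def error_sd(sd_true: float, reliability: float) -> float:
    """Standard deviation of classical-test-theory measurement noise.

    Under CTT, reliability is the ratio of true-score variance to observed
    variance, so a measure with true SD ``sd_true`` needs independent
    Gaussian noise with SD ``sd_true * sqrt((1 - reliability)/reliability)``
    for the observed score to have the stated reliability.

    Parameters
    ----------
    sd_true : float
        True-score standard deviation, raw units; must be positive.
    reliability : float
        Target reliability in (0, 1]; 1.0 means error-free measurement.
    """
    if sd_true <= 0:
        raise ValueError(f"sd_true must be positive, got {sd_true}")
    if not 0.0 < reliability <= 1.0:
        raise ValueError(f"reliability must be in (0, 1], got {reliability}")
    return sd_true * math.sqrt((1.0 - reliability) / reliability)


def attenuate(r_true: float, rel_x: float, rel_y: float) -> float:
    """Attenuate a true-score correlation by unreliable measurement.

    The observed correlation equals the true correlation multiplied by the
    square root of the product of the two reliabilities — e.g. a true
    r = .50 measured with reliability .60 on both sides is observed as .30.
    """
    if abs(r_true) > 1:
        raise ValueError(f"|r_true| must be <= 1, got {r_true}")
    for rel in (rel_x, rel_y):
        if not 0.0 < rel <= 1.0:
            raise ValueError(f"reliability must be in (0, 1], got {rel}")
    return r_true * math.sqrt(rel_x * rel_y)


@dataclass(frozen=True)
class TrueModelSpec:
    """Observed-scale targets of the generative model.

    All moments refer to observed scores at ``reference_reliability``; the
    pre-test and both predictors use the T-scale norms (50, 10), the
    experimental post-test SD is inflated to 13 to reflect the common
    finding of larger variance after treatment.
    """

    mean_pre: float = 50.0
    sd_pre: float = 10.0
    sd_post_exp: float = 13.0
    sd_post_ctl: float = 10.0
    dz_exp_target: float = 0.50
    dz_ctl_target: float = 0.05
    r_p1_gain_target: float = 0.30
    r_p2_gain_target: float = 0.00
    mean_p: float = 50.0
    sd_p: float = 10.0
    reference_reliability: float = 0.80

    def __post_init__(self) -> None:
        for name in ("sd_pre", "sd_post_exp", "sd_post_ctl", "sd_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.reference_reliability <= 1.0:
            raise ValueError("reference_reliability must be in (0, 1]")
        if not -1.0 < self.r_p1_gain_target < 1.0:
            raise ValueError("r_p1_gain_target must be in (-1, 1)")
        if self.sd_post_exp < self.sd_pre:
            raise ValueError(
                "sd_post_exp must be >= sd_pre: the experimental gain variance "
                "is sd_post_exp^2 - sd_pre^2 and cannot be negative"
            )
        if self.r_p2_gain_target != 0.0:
            raise CalibrationError(
                "the second predictor is a null predictor by design; "
                "r_p2_gain_target must be 0"
            )


@dataclass(frozen=True)
class CalibratedEffects:
    """Constant true-score effects backed out of the observed-scale targets."""

    mu_delta_exp: float
    mu_delta_ctl: float
    var_delta_exp: float
    r_true_p1: float
    beta_true_p1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mu_delta_exp": self.mu_delta_exp,
            "mu_delta_ctl": self.mu_delta_ctl,
            "var_delta_exp": self.var_delta_exp,
            "r_true_p1": self.r_true_p1,
            "beta_true_p1": self.beta_true_p1,
        }


def calibrate_true_effects(spec: TrueModelSpec) -> CalibratedEffects:
    """Convert observed-scale targets into constant true-score effects.

    The targets (dz, r) are defined on observed scores at the reference
    reliability, but the generator needs true-score parameters that stay
    fixed while reliability varies.  The conversion uses:

    * true gain variance from the pre/post variance decomposition with zero
      pre/gain covariance: ``var_delta = sd_post_exp^2 - sd_pre^2``;
    * the attenuation law, with the reliability of the observed change
      score being ``var_delta / (var_delta + e_pre^2 + e_post^2)`` because
      observed change = true gain + post noise - pre noise;
    * dz targets scaled by the observed change SD (for the control group
      the true gain is a deterministic shift, so its observed change SD is
      pure noise).

    Raises
    ------
    CalibrationError
        If disattenuation pushes the true correlation to or beyond |1|.
    """
    rel = spec.reference_reliability
    e_pre = error_sd(spec.sd_pre, rel)
    e_post_exp = error_sd(spec.sd_post_exp, rel)
    e_post_ctl = error_sd(spec.sd_post_ctl, rel)

    var_delta_exp = spec.sd_post_exp**2 - spec.sd_pre**2
    var_gain_obs_exp = var_delta_exp + e_pre**2 + e_post_exp**2
    var_gain_obs_ctl = e_pre**2 + e_post_ctl**2

    if var_delta_exp == 0.0 and spec.r_p1_gain_target != 0.0:
        raise CalibrationError(
            "a predictor cannot correlate with a gain that has zero variance"
        )
    if spec.r_p1_gain_target == 0.0:
        r_true_p1 = 0.0
    else:
        rel_gain_obs = var_delta_exp / var_gain_obs_exp
        r_true_p1 = spec.r_p1_gain_target / math.sqrt(rel * rel_gain_obs)
        if abs(r_true_p1) >= 1.0:
            raise CalibrationError(
                f"disattenuated predictor/gain correlation is {r_true_p1:.3f}; "
                "targets are infeasible at this reliability"
            )

    sd_delta_exp = math.sqrt(var_delta_exp)
    return CalibratedEffects(
        mu_delta_exp=spec.dz_exp_target * math.sqrt(var_gain_obs_exp),
        mu_delta_ctl=spec.dz_ctl_target * math.sqrt(var_gain_obs_ctl),
        var_delta_exp=var_delta_exp,
        r_true_p1=r_true_p1,
        beta_true_p1=r_true_p1 * sd_delta_exp / spec.sd_p,
    )


@dataclass
class TrueDataset:
    """Noise-free per-subject scores for one simulated study.

    ``group`` holds integer codes (0 = control, 1 = experimental); the first
    half of every dataset is the control group.  ``spec`` is carried along so
    the measurement layer knows each measure's true SD.
    """

    group: np.ndarray
    t1_true: np.ndarray
    delta_true: np.ndarray
    p1_true: np.ndarray
    p2_true: np.ndarray
    spec: TrueModelSpec = field(repr=False)

    data_source = "true"

    @property
    def t2_true(self) -> np.ndarray:
        return self.t1_true + self.delta_true

    @property
    def n_total(self) -> int:
        return self.group.size

    # uniform accessors shared with ObservedDataset so the regression layer
    # can fit either representation through one code path
    @property
    def pre(self) -> np.ndarray:
        return self.t1_true

    @property
    def post(self) -> np.ndarray:
        return self.t2_true

    @property
    def p1(self) -> np.ndarray:
        return self.p1_true

    @property
    def p2(self) -> np.ndarray:
        return self.p2_true

    def group_labels(self) -> np.ndarray:
        return np.where(self.group == EXPERIMENTAL, "experimental", "control")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "group": self.group_labels(),
                "t1_true": self.t1_true,
                "t2_true": self.t2_true,
                "delta_true": self.delta_true,
                "p1_true": self.p1_true,
                "p2_true": self.p2_true,
            }
        )


def generate_true_dataset(
    effects: CalibratedEffects,
    spec: TrueModelSpec,
    n_total: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> TrueDataset:
    """Draw one noise-free study of ``n_total`` subjects (half per group).

    Pre-test scores and both predictors are independent Gaussians.  The
    control group gains a deterministic ``mu_delta_ctl``; experimental gains
    are ``mu_delta_exp + beta_true_p1 * (p1 - mean_p) + eps`` with the
    residual variance chosen so the total gain variance equals
    ``var_delta_exp``.
    """
    if n_total % 2 != 0:
        raise ValueError(f"n_total must be even for equal group sizes, got {n_total}")
    if n_total < 8:
        raise ValueError(f"n_total must be at least 8, got {n_total}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_half = n_total // 2
    group = np.repeat([CONTROL, EXPERIMENTAL], n_half)

    t1 = rng.normal(spec.mean_pre, spec.sd_pre, n_total)
    p1 = rng.normal(spec.mean_p, spec.sd_p, n_total)
    p2 = rng.normal(spec.mean_p, spec.sd_p, n_total)

    resid_var = effects.var_delta_exp * (1.0 - effects.r_true_p1**2)
    eps = rng.normal(0.0, math.sqrt(resid_var), n_half) if resid_var > 0 else np.zeros(n_half)

    delta = np.empty(n_total)
    delta[:n_half] = effects.mu_delta_ctl
    delta[n_half:] = (
        effects.mu_delta_exp
        + effects.beta_true_p1 * (p1[n_half:] - spec.mean_p)
        + eps
    )
    return TrueDataset(group=group, t1_true=t1, delta_true=delta, p1_true=p1, p2_true=p2, spec=spec)
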