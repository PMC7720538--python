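"""Factorial simulation study: grid execution and aggregation.

For every cell (sample size x reliability) the runner draws independent
replicate studies, measures them with CTT noise, fits every requested
model x criterion combination on both the observed and the noise-free
scores, and aggregates per coefficient:

* ``M``  — mean of the estimates across replications,
* ``SE`` — SD of the estimates across replications (an estimate of the
  coefficient's standard error),
* ``P``  — proportion of replications with p < alpha (power for true
  effects, alpha error for null ones),
* studentized bias — mean(observed - true estimate), paired per replicate,
  divided by SD(observed estimates) * sqrt(n).

The replicate seed is a deterministic function of
(master_seed, n, reliability, replicate index), so any single replicate can
be regenerated in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CriterionKind
from .noise import apply_noise
from .regression import ModelSpec, fit_cell
from .truth import (
    CalibratedEffects,
    TrueModelSpec,
    calibrate_true_effects,
    generate_true_dataset,
)

__all__ = [
    "StudyConfig",
    "CellSummary",
    "BiasSummary",
    "significance_rate",
    "studentized_bias",
    "replicate_seed",
    "run_cell",
    "run_study",
    "count_planned_fits",
]

logger = logging.getLogger(__name__)

DEFAULT_N_GRID = (50, 100, 150, 200, 250, 300, 400, 500)
DEFAULT_RELIABILITY_GRID = (0.60, 0.70, 0.80, 0.90)

_MAX_FAILURE_FRACTION = 0.01


@dataclass(frozen=True)
class StudyConfig:
    """Full factorial study configuration."""

    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    reliability_grid: tuple[float, ...] = DEFAULT_RELIABILITY_GRID
    replications: int = 1000
    alpha: float = 0.05
    master_seed: int = 0
    model_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    criteria: tuple[CriterionKind, ...] = tuple(CriterionKind)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_grid", tuple(int(n) for n in self.n_grid))
        object.__setattr__(
            self, "reliability_grid", tuple(float(r) for r in self.reliability_grid)
        )
        object.__setattr__(
            self, "criteria", tuple(CriterionKind(c) for c in self.criteria)
        )
        object.__setattr__(self, "model_ids", tuple(int(m) for m in self.model_ids))
        if not self.n_grid or not self.reliability_grid:
            raise ValueError("n_grid and reliability_grid must be non-empty")
        for n in self.n_grid:
            if n % 2 != 0 or n < 8:
                raise ValueError(f"every n must be even and >= 8, got {n}")
        for r in self.reliability_grid:
            if not 0.0 < r <= 1.0:
                raise ValueError(f"reliability must be in (0, 1], got {r}")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.model_ids) - {1, 2, 3, 4, 5}
        if bad or not self.model_ids:
            raise ValueError(f"model_ids must be a non-empty subset of 1..5, got {self.model_ids}")
        if not self.criteria:
            raise ValueError("criteria must be non-empty")


@dataclass(frozen=True)
class CellSummary:
    """Aggregated M / SE / P per term for one (model, criterion, n, reliability)."""

    model_id: int
    criterion: CriterionKind
    data_source: str
    n: int
    reliability: float
    replications_used: int
    terms: tuple[str, ...]
    M: dict[str, float]
    SE: dict[str, float]
    P: dict[str, float]


@dataclass(frozen=True)
class BiasSummary:
    """Mean and spread of studentized bias per term for one cell."""

    model_id: int
    criterion: CriterionKind
    n: int
    reliability: float
    terms: tuple[str, ...]
    mean_studentized_bias: dict[str, float]
    sd_studentized_bias: dict[str, float]


def significance_rate(p_values, alpha: float = 0.05) -> float:
    """Fraction of p-values strictly below alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("significance_rate of an empty sequence is undefined")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.mean(p < alpha))


def studentized_bias(observed_estimates, true_estimates, n_sample: int) -> float:
    """Mean paired bias scaled to SD units.

    bias_i = observed_i - true_i (paired by replicate); the mean bias is
    divided by SD(observed estimates) * sqrt(n_sample) so that the measure
    is comparable across criteria with different units and across sample
    sizes.
    """
    obs = np.asarray(observed_estimates, dtype=float)
    tru = np.asarray(true_estimates, dtype=float)
    if obs.shape != tru.shape:
        raise ValueError("observed and true estimate sequences must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 replicates")
    sd = float(np.std(obs, ddof=1))
    if sd == 0.0:
        raise ValueError("studentized bias undefined: estimates have zero SD")
    return float(np.mean(obs - tru) / (sd * math.sqrt(n_sample)))


def replicate_seed(master_seed: int, n: int, reliability: float, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed.

    The reliability enters as an integer in units of 1/1000 so that the
    entropy tuple is exact; the returned SeedSequence is spawned into one
    child for the true-score draw and one for the noise draw.
    """
    return np.random.SeedSequence(
        entropy=(int(master_seed), int(n), int(round(reliability * 1000)), int(replicate))
    )


def run_cell(
    config: StudyConfig,
    effects: CalibratedEffects,
    spec: TrueModelSpec,
    n: int,
    reliability: float,
) -> tuple[list[CellSummary], list[BiasSummary]]:
    """Run all replications of one (n, reliability) cell and aggregate.

    Replicates where any fit fails (singular design) are dropped entirely —
    keeping the observed/true pairing intact — and counted; the cell fails
    if more than 1% of replicates are lost.
    """
    combos = [
        (m, c) for m in config.model_ids for c in config.criteria
    ]
    models = {m: ModelSpec.from_id(m) for m in config.model_ids}
    # per (model, criterion): lists over replicates of (est, p) for both sources
    store: dict[tuple, dict[str, list]] = {
        key: {"obs_est": [], "obs_p": [], "true_est": [], "true_p": []} for key in combos
    }
    terms_of: dict[tuple, tuple[str, ...]] = {}

    n_failed = 0
    for rep in range(config.replications):
        truth_seed, noise_seed = replicate_seed(
            config.master_seed, n, reliability, rep
        ).spawn(2)
        truth = generate_true_dataset(effects, spec, n, truth_seed)
        observed = apply_noise(truth, reliability, noise_seed)
        try:
            fits = {
                key: (
                    fit_cell(observed, key[1], models[key[0]]),
                    fit_cell(truth, key[1], models[key[0]]),
                )
                for key in combos
            }
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as exc:
            n_failed += 1
            logger.warning("replicate %d failed at n=%d rel=%.2f: %s", rep, n, reliability, exc)
            continue
        for key, (fit_obs, fit_true) in fits.items():
            terms_of[key] = fit_obs.terms
            store[key]["obs_est"].append(fit_obs.estimates)
            store[key]["obs_p"].append(fit_obs.p_values)
            store[key]["true_est"].append(fit_true.estimates)
            store[key]["true_p"].append(fit_true.p_values)

    if n_failed > _MAX_FAILURE_FRACTION * config.replications:
        raise RuntimeError(
            f"{n_failed}/{config.replications} replicates failed at n={n}, "
            f"reliability={reliability}"
        )
    if n_failed:
        logger.info("cell n=%d rel=%.2f: %d replicates excluded", n, reliability, n_failed)

    n_ok = config.replications - n_failed
    cell_summaries: list[CellSummary] = []
    bias_summaries: list[BiasSummary] = []
    for key in combos:
        model_id, criterion = key
        terms = terms_of[key]
        obs_est = np.vstack(store[key]["obs_est"])
        obs_p = np.vstack(store[key]["obs_p"])
        true_est = np.vstack(store[key]["true_est"])
        true_p = np.vstack(store[key]["true_p"])
        for source, est, pvals in (("observed", obs_est, obs_p), ("true", true_est, true_p)):
            cell_summaries.append(
                CellSummary(
                    model_id=model_id,
                    criterion=criterion,
                    data_source=source,
                    n=n,
                    reliability=reliability,
                    replications_used=n_ok,
                    terms=terms,
                    M={t: float(np.mean(est[:, j])) for j, t in enumerate(terms)},
                    SE={t: float(np.std(est[:, j], ddof=1)) for j, t in enumerate(terms)},
                    P={
                        t: significance_rate(pvals[:, j], config.alpha)
                        for j, t in enumerate(terms)
                    },
                )
            )
        sd_obs = np.std(obs_est, axis=0, ddof=1)
        per_rep = (obs_est - true_est) / (sd_obs * math.sqrt(n))
        bias_summaries.append(
            BiasSummary(
                model_id=model_id,
                criterion=criterion,
                n=n,
                reliability=reliability,
                terms=terms,
                mean_studentized_bias={
                    t: float(np.mean(per_rep[:, j])) for j, t in enumerate(terms)
                },
                sd_studentized_bias={
                    t: float(np.std(per_rep[:, j], ddof=1)) for j, t in enumerate(terms)
                },
            )
        )
    return cell_summaries, bias_summaries


def summaries_to_frame(
    cell_summaries: list[CellSummary], bias_summaries: list[BiasSummary]
) -> pd.DataFrame:
    """Tidy long table: one row per (model, criterion, source, n, reliability, term)."""
    bias_lookup = {
        (b.model_id, b.criterion, b.n, b.reliability): b for b in bias_summaries
    }
    rows = []
    for cs in cell_summaries:
        bias = bias_lookup.get((cs.model_id, cs.criterion, cs.n, cs.reliability))
        for term in cs.terms:
            rows.append(
                {
                    "model_id": cs.model_id,
                    "criterion": cs.criterion.value,
                    "data_source": cs.data_source,
                    "n": cs.n,
                    "reliability": cs.reliability,
                    "term": term,
                    "M": cs.M[term],
                    "SE": cs.SE[term],
                    "P": cs.P[term],
                    "studentized_bias": (
                        bias.mean_studentized_bias[term]
                        if bias is not None and cs.data_source == "observed"
                        else np.nan
                    ),
                    "n_ok": cs.replications_used,
                }
            )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, spec: TrueModelSpec | None = None) -> pd.DataFrame:
    """Execute the full grid; returns the tidy results table."""
    spec = spec or TrueModelSpec()
    effects = calibrate_true_effects(spec)
    frames = []
    for reliability in config.reliability_grid:
        for n in config.n_grid:
            logger.info("running cell n=%d reliability=%.2f", n, reliability)
            cells, biases = run_cell(config, effects, spec, n, reliability)
            frames.append(summaries_to_frame(cells, biases))
    return pd.concat(frames, ignore_index=True)


def count_planned_fits(config: StudyConfig) -> int:
    """Closed-form count of regressions the configuration will run.

    models x criteria x sample sizes x reliabilities x replications x 2
    (each replicate is fitted on observed and on true scores).
    """
    return (
        len(config.model_ids)
        * len(config.criteria)
        * len(config.n_grid)
        * len(config.reliability_grid)
        * config.replications
        * 2
    )
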