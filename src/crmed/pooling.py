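"""Meta-analytic pooling of dose-finding results across strata.

When a stratum under-recruits, its data are pooled with a neighbouring
stratum and a single recommendation is produced: per-dose success/failure
counts are summed, the observed marginal response frequencies define a
simulation truth (with model-smoothed estimates filling doses never
allocated), a large number of CRM trials is simulated under that truth, and
each dose is weighted by the fraction of all simulated patient allocations
it received. The pooled recommended dose is the maximal-weight dose, ties
going to the lower dose — CRM allocation concentrates at the dose it would
recommend, so the allocation weight is a Monte-Carlo vote for the
recommendation under the observed frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import DesignConfig, PriorSpec
from .model import DoseOutcomeData, compute_posterior
from .simulate import SIM_N_GRID, Scenario, simulate_trial

__all__ = [
    "StratumData",
    "WeightTable",
    "PooledResult",
    "pool_counts",
    "allocation_weights",
    "pooled_recommendation",
    "pool_and_recommend",
]


@dataclass(frozen=True)
class StratumData:
    """Per-dose outcome counts observed in one stratum."""

    label: str
    counts: DoseOutcomeData


@dataclass(frozen=True)
class WeightTable:
    """Fraction of simulated patient allocations received by each dose."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)


@dataclass
class PooledResult:
    """Pooled counts, observed frequencies, simulation weights, recommendation."""

    pooled_counts: DoseOutcomeData
    observed_probs: np.ndarray  # NaN at doses with no observations
    weights: WeightTable
    recommended: int


def pool_counts(strata: Sequence[StratumData]) -> DoseOutcomeData:
    """Elementwise sum of per-dose success/failure counts across strata."""
    if not strata:
        raise ValueError("no strata to pool")
    sizes = {len(s.counts.n_success) for s in strata}
    if len(sizes) != 1:
        raise ValueError("strata use different dose grids")
    n = sizes.pop()
    out = DoseOutcomeData.empty(n)
    s = np.zeros(n)
    f = np.zeros(n)
    for st in strata:
        s += st.counts.n_success
        f += st.counts.n_failure
    return DoseOutcomeData(s, f)


def _simulation_truth(
    pooled: DoseOutcomeData, config: DesignConfig, prior: PriorSpec
) -> np.ndarray:
    """Observed marginal frequencies, model-smoothed at unobserved doses.

    Doses never allocated have no frequency; the working model fitted to the
    pooled counts (posterior point estimates under the calibrated prior)
    supplies their response probability.
    """
    n = pooled.n_success + pooled.n_failure
    if not (n > 0).any():
        raise ValueError("no observed data at any dose")
    state = compute_posterior(
        pooled, prior, config.skeleton, variant=config.estimator_variant
    )
    truth = state.mean_probs.copy()
    mask = n > 0
    truth[mask] = pooled.n_success[mask] / n[mask]
    return truth


def allocation_weights(
    pooled: DoseOutcomeData,
    config: DesignConfig,
    prior: PriorSpec,
    n_sims: int = 5000,
    seed: int = 0,
) -> WeightTable:
    """Per-dose fraction of patient allocations over simulated CRM trials.

    Each simulated trial runs the stage-1 design (cohorts, allocation rule,
    stopping rules, per-stratum cap) with responses drawn Bernoulli at the
    observed marginal frequency of the allocated dose. Reproducible for a
    fixed seed; every replicate uses an independent child seed.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000 for stable weights")
    truth = _simulation_truth(pooled, config, prior)
    scenario = Scenario(tuple(truth), stratum_label="pooled-weights")
    alloc = np.zeros(len(config.grid))
    for child in np.random.SeedSequence(seed).spawn(n_sims):
        rng = np.random.default_rng(child)
        trial = simulate_trial(
            scenario, config, prior, rng=rng, with_stage2=False, n_grid=SIM_N_GRID
        )
        for rec in trial.history.records:
            alloc[rec.dose_index] += rec.n
    return WeightTable(alloc / alloc.sum())


def pooled_recommendation(
    weights: WeightTable, pooled: DoseOutcomeData, config: DesignConfig
) -> int:
    """Maximal-weight dose; ties break toward the lower dose."""
    w = weights.weights
    return int(np.flatnonzero(w >= w.max() - 1e-12)[0])


def pool_and_recommend(
    strata: Sequence[StratumData],
    config: DesignConfig,
    prior: PriorSpec,
    n_sims: int = 5000,
    seed: int = 0,
) -> PooledResult:
    """Full pooling pipeline: counts -> weights -> pooled recommendation."""
    pooled = pool_counts(strata)
    n = pooled.n_success + pooled.n_failure
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(n > 0, pooled.n_success / np.where(n > 0, n, 1), np.nan)
    weights = allocation_weights(pooled, config, prior, n_sims=n_sims, seed=seed)
    rec = pooled_recommendation(weights, pooled, config)
    return PooledResult(
        pooled_counts=pooled, observed_probs=observed, weights=weights, recommended=rec
    )
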