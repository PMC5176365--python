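"""Two-stage sequential trial engine: replay, allocation, stopping, stage 2.

Stage 1 runs the continual reassessment method: after each cohort the
posterior is updated and the next cohort is allocated to the dose whose
estimated success probability is closest to the target. Stage 1 stops when
(1) the per-stratum cap is reached, (2) the response probability is credibly
too low at every dose, or (3) one further cohort could no longer move the
estimates appreciably (the predictive-gain rule). Stage 2, entered on early
stopping, accrues further cohorts at the estimated minimum effective dose
(MED) until its credibility interval is tight enough.

`replay` re-runs the sequential analysis from a recorded history and checks
the recorded allocations against the model's recommendations; mismatches on
cohorts not flagged as forced are reported as discrepancies rather than
raised, since validating a recorded trial is the main use of this function.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice
from typing import Iterable, Iterator, Sequence

import numpy as np

from .design import DesignConfig, PriorSpec
from .model import (
    DoseOutcomeData,
    PosteriorState,
    compute_posterior,
    credible_interval,
    recommend_dose,
)

__all__ = [
    "CohortRecord",
    "TrialHistory",
    "ReplayStep",
    "ReplayReport",
    "Stage2Report",
    "STOP_CONTINUE",
    "STOP_MAX_N",
    "STOP_ALL_LOW",
    "STOP_PREDICTIVE_GAIN",
    "replay",
    "next_dose",
    "check_stage1_stop",
    "predictive_gain",
    "run_stage2",
]

STOP_CONTINUE = "continue"
STOP_MAX_N = "stop_max_n"
STOP_ALL_LOW = "stop_all_low"
STOP_PREDICTIVE_GAIN = "stop_predictive_gain"


@dataclass(frozen=True)
class CohortRecord:
    """One cohort's recorded allocation and outcomes."""

    cohort_id: int
    dose_index: int
    n: int
    n_success: int
    forced: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort must contain at least one patient")
        if not 0 <= self.n_success <= self.n:
            raise ValueError("need 0 <= n_success <= n")


@dataclass(frozen=True)
class TrialHistory:
    """Ordered sequence of cohort records for one stratum."""

    stratum_label: str
    records: tuple

    def __init__(self, stratum_label: str, records: Sequence[CohortRecord]):
        records = tuple(records)
        for k, r in enumerate(records, start=1):
            if r.cohort_id != k:
                raise ValueError("cohort ids must be consecutive from 1")
        object.__setattr__(self, "stratum_label", stratum_label)
        object.__setattr__(self, "records", records)

    @property
    def total_n(self) -> int:
        return sum(r.n for r in self.records)

    def counts(self, n_doses: int) -> DoseOutcomeData:
        data = DoseOutcomeData.empty(n_doses)
        for r in self.records:
            data = data.add(r.dose_index, r.n, r.n_success)
        return data


@dataclass
class ReplayStep:
    """Posterior snapshot after one cohort during replay."""

    cohort_id: int
    dose_index: int
    n: int
    n_success: int
    forced: bool
    mean_probs: np.ndarray
    med_estimate: int
    recommended_next: int
    stop_decision: str
    discrepancy: bool = False  # next recorded dose differs from recommendation


@dataclass
class ReplayReport:
    """Full replay of a recorded trial: steps plus the final summary."""

    stratum_label: str
    steps: list
    final_state: PosteriorState
    med: int
    med_mean_prob: float
    ci: tuple
    stop_reason: str

    @property
    def discrepancies(self) -> list:
        return [s.cohort_id for s in self.steps if s.discrepancy]


def next_dose(state: PosteriorState, config: DesignConfig) -> int:
    """Allocation rule: dose with estimated success probability closest to target.

    No dose-skipping restriction is imposed (the recorded trial moved
    between non-adjacent doses).
    """
    return recommend_dose(state, config.target)


def _posterior_prob_below(state: PosteriorState, dose_index: int, threshold: float) -> float:
    """P(p_dose < threshold | data) by quadrature over the parameter posterior."""
    P = state.prob_matrix()[:, dose_index]
    mask = P < threshold
    if not mask.any():
        return 0.0
    w = np.where(mask, state.density, 0.0)
    return float(np.trapezoid(w, state.grid))


def predictive_gain(state: PosteriorState, dose_index: int, cohort_size: int) -> float:
    """Expected maximum change in any dose's estimate from one further cohort.

    Enumerates the ``cohort_size + 1`` possible success counts of a cohort
    at ``dose_index``, weights each by its posterior-predictive probability,
    and averages the maximum absolute change over doses of the point
    estimates after that hypothetical update.
    """
    from math import comb

    p = state.prob_matrix()[:, dose_index]
    q = 1.0 - p
    ks = np.arange(cohort_size + 1)
    # posterior predictive: E[ Binom(cohort_size, p_dose) pmf ] under the posterior
    pmf = np.array([comb(cohort_size, int(k)) for k in ks])[None, :] * (
        p[:, None] ** ks[None, :]
    ) * (q[:, None] ** (cohort_size - ks)[None, :])
    pred = np.trapezoid(state.density[:, None] * pmf, state.grid, axis=0)
    pred = pred / pred.sum()
    gain = 0.0
    for k, pk in zip(ks, pred):
        nxt = state.update(dose_index, cohort_size, int(k))
        gain += pk * float(np.abs(nxt.mean_probs - state.mean_probs).max())
    return gain


def check_stage1_stop(
    state: PosteriorState, history: TrialHistory, config: DesignConfig
) -> str:
    """Stage-1 discontinuation decision after the latest cohort.

    Checked in order: per-stratum cap reached; all doses credibly below the
    target by more than ``stop_low_margin``; predictive gain of a further
    cohort below ``predictive_gain_eps``.
    """
    if history.total_n >= config.max_n:
        return STOP_MAX_N
    top = len(config.grid) - 1
    p_low = _posterior_prob_below(state, top, config.target - config.stop_low_margin)
    if p_low > config.stop_low_confidence:
        return STOP_ALL_LOW
    rec = next_dose(state, config)
    if predictive_gain(state, rec, config.cohort_size) < config.predictive_gain_eps:
        return STOP_PREDICTIVE_GAIN
    return STOP_CONTINUE


def replay(
    history: TrialHistory, config: DesignConfig, prior: PriorSpec
) -> ReplayReport:
    """Re-run the sequential Bayesian analysis over a recorded history.

    Step k's posterior conditions on cohorts 1..k. The recommendation after
    step k is compared with the dose actually given to cohort k+1; on
    cohorts not flagged forced a mismatch sets the step's ``discrepancy``
    flag. The final step carries the MED estimate and its credibility
    interval.
    """
    if not history.records:
        raise ValueError("empty trial history")
    n_doses = len(config.grid)
    data = DoseOutcomeData.empty(n_doses)
    partial = TrialHistory(history.stratum_label, ())
    steps: list[ReplayStep] = []
    state = None
    for idx, rec in enumerate(history.records):
        data = data.add(rec.dose_index, rec.n, rec.n_success)
        partial = TrialHistory(
            history.stratum_label, history.records[: idx + 1]
        )
        state = compute_posterior(
            data, prior, config.skeleton, variant=config.estimator_variant
        )
        med = recommend_dose(state, config.target)
        stop = check_stage1_stop(state, partial, config)
        step = ReplayStep(
            cohort_id=rec.cohort_id,
            dose_index=rec.dose_index,
            n=rec.n,
            n_success=rec.n_success,
            forced=rec.forced,
            mean_probs=state.mean_probs.copy(),
            med_estimate=med,
            recommended_next=med,
            stop_decision=stop,
        )
        if idx + 1 < len(history.records):
            nxt = history.records[idx + 1]
            if not nxt.forced and nxt.dose_index != med:
                step.discrepancy = True
        steps.append(step)
    med = steps[-1].med_estimate
    ci = credible_interval(state, med, config.ci_level)
    return ReplayReport(
        stratum_label=history.stratum_label,
        steps=steps,
        final_state=state,
        med=med,
        med_mean_prob=float(state.mean_probs[med]),
        ci=ci,
        stop_reason=steps[-1].stop_decision,
    )


@dataclass
class Stage2Report:
    """Outcome of the stage-2 reliability expansion at the MED."""

    med: int
    mean_prob: float
    ci: tuple
    n_stage2: int
    shifted: bool  # the updated recommendation moved off the MED
    new_recommendation: int
    complete: bool  # interval criterion met (or cap reached) with full cohorts
    state: PosteriorState


def run_stage2(
    state: PosteriorState,
    med: int,
    config: DesignConfig,
    response_source: Iterable[int],
    stop_on_shift: bool = True,
) -> Stage2Report:
    """Accrue fixed-dose cohorts at the MED until its interval is tight.

    Outcomes are consumed from ``response_source`` (an iterable of 0/1) in
    cohorts of ``config.cohort_size``. Stops when the credibility interval
    half-width at the MED is at most ``config.stage2_ci_halfwidth`` or the
    per-stratum cap is reached (counting patients already conditioned on in
    ``state``). If the updated recommendation moves off the MED, accrual
    halts and control is meant to return to stage-1 allocation; the report
    flags the shift and the new recommendation. An exhausted outcome stream
    yields a report flagged incomplete. With ``stop_on_shift=False`` the
    fixed-dose accrual runs to the interval (or cap) criterion regardless of
    where the updated recommendation points, which is how the interval's
    frequentist reliability is assessed in simulation.
    """
    outcomes: Iterator[int] = iter(response_source)
    n_added = 0
    shifted = False
    complete = True
    while True:
        lo, hi = credible_interval(state, med, config.ci_level)
        if (hi - lo) / 2.0 <= config.stage2_ci_halfwidth:
            break
        if state.data.total_n >= config.max_n:
            break
        room = int(min(config.cohort_size, config.max_n - state.data.total_n))
        batch = list(islice(outcomes, room))
        if len(batch) < room:
            complete = False
            if batch:
                state = state.update(med, len(batch), int(sum(batch)))
                n_added += len(batch)
            break
        state = state.update(med, room, int(sum(batch)))
        n_added += room
        rec = recommend_dose(state, config.target)
        if rec != med:
            shifted = True
            if stop_on_shift:
                break
    lo, hi = credible_interval(state, med, config.ci_level)
    return Stage2Report(
        med=med,
        mean_prob=float(state.mean_probs[med]),
        ci=(lo, hi),
        n_stage2=n_added,
        shifted=shifted,
        new_recommendation=recommend_dose(state, config.target),
        complete=complete,
        state=state,
    )
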