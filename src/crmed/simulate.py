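"""Synthetic data generation: simulated trials, operating characteristics,
and pH traces with prescribed reflux structure.

Patient responses are independent Bernoulli given dose — the implicit
assumption of the sequential design — drawn from a scenario's true
dose-response curve. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import DesignConfig, PriorSpec
from .engine import (
    STOP_CONTINUE,
    STOP_MAX_N,
    CohortRecord,
    Stage2Report,
    TrialHistory,
    check_stage1_stop,
    next_dose,
    run_stage2,
)
from .model import DoseOutcomeData, compute_posterior, recommend_dose
from .ph import PhTrace

__all__ = [
    "Scenario",
    "SimulatedTrial",
    "OperatingCharacteristics",
    "simulate_trial",
    "operating_characteristics",
    "synth_ph_trace",
]

#: Quadrature resolution used inside simulation loops; coarser than the
#: reporting default but amply accurate for allocation decisions.
SIM_N_GRID = 1501


@dataclass(frozen=True)
class Scenario:
    """Simulation truth: per-dose success probabilities and a seed."""

    true_probs: tuple
    stratum_label: str = "simulated"
    seed: int = 0

    def __init__(self, true_probs: Sequence[float], stratum_label: str = "simulated", seed: int = 0):
        probs = tuple(float(p) for p in true_probs)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("true probabilities must lie in [0, 1]")
        object.__setattr__(self, "true_probs", probs)
        object.__setattr__(self, "stratum_label", stratum_label)
        object.__setattr__(self, "seed", int(seed))


@dataclass
class SimulatedTrial:
    """A complete simulated trial: stage-1 history plus final summaries."""

    history: TrialHistory
    stop_reason: str
    med: int | None
    mean_probs: np.ndarray
    stage2: Stage2Report | None = None

    @property
    def final_med(self) -> int | None:
        if self.stage2 is not None:
            return self.stage2.new_recommendation if self.stage2.shifted else self.stage2.med
        return self.med


def simulate_trial(
    scenario: Scenario,
    config: DesignConfig,
    prior: PriorSpec,
    rng: np.random.Generator | None = None,
    start_dose: int | None = None,
    with_stage2: bool = True,
    n_grid: int = SIM_N_GRID,
) -> SimulatedTrial:
    """Simulate one two-stage trial under a true dose-response curve.

    The starting dose is drawn uniformly from the grid when not given
    (mirroring the trial's randomly selected starting dose). Stage 1 runs
    the CRM with all three discontinuation rules; on early stopping with an
    MED in hand, stage 2 accrues at the MED from the same Bernoulli truth.
    """
    if len(scenario.true_probs) != len(config.grid):
        raise ValueError("scenario length must match the dose grid")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    truth = np.asarray(scenario.true_probs)

    data = DoseOutcomeData.empty(len(config.grid))
    state = compute_posterior(
        data, prior, config.skeleton, variant=config.estimator_variant, n_grid=n_grid
    )
    dose = int(rng.integers(len(config.grid))) if start_dose is None else int(start_dose)
    records: list[CohortRecord] = []
    stop = STOP_CONTINUE
    total = 0
    while stop == STOP_CONTINUE:
        m = int(min(config.cohort_size, config.max_n - total))
        successes = int(rng.binomial(m, truth[dose]))
        records.append(
            CohortRecord(len(records) + 1, dose, m, successes, forced=False)
        )
        total += m
        state = state.update(dose, m, successes)
        history = TrialHistory(scenario.stratum_label, records)
        stop = check_stage1_stop(state, history, config)
        if stop == STOP_CONTINUE:
            dose = next_dose(state, config)

    history = TrialHistory(scenario.stratum_label, records)
    med = recommend_dose(state, config.target) if stop != "stop_all_low" else None
    trial = SimulatedTrial(
        history=history, stop_reason=stop, med=med, mean_probs=state.mean_probs.copy()
    )
    if with_stage2 and med is not None and stop != STOP_MAX_N:
        def stream():
            while True:
                yield int(rng.random() < truth[med])

        trial.stage2 = run_stage2(state, med, config, stream())
    return trial


@dataclass
class OperatingCharacteristics:
    """Aggregated behaviour of the design over simulated replicates."""

    selection_freq: np.ndarray  # per dose; final MED selections
    allocation_freq: np.ndarray  # per dose; fraction of all patients
    mean_sample_size: float
    stop_reason_freq: dict
    none_selected_freq: float  # replicates ending with no MED (all-low stop)


def operating_characteristics(
    scenario: Scenario,
    config: DesignConfig,
    prior: PriorSpec,
    n_reps: int = 1000,
    seed: int = 0,
    with_stage2: bool = False,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the design under a scenario.

    Each replicate uses an independent child seed spawned from the master
    seed, so results are deterministic per (seed, n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_doses = len(config.grid)
    sel = np.zeros(n_doses)
    alloc = np.zeros(n_doses)
    none_sel = 0
    sizes = []
    reasons: dict[str, int] = {}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        trial = simulate_trial(scenario, config, prior, rng=rng, with_stage2=with_stage2)
        med = trial.final_med
        if med is None:
            none_sel += 1
        else:
            sel[med] += 1
        for rec in trial.history.records:
            alloc[rec.dose_index] += rec.n
        n_total = trial.history.total_n + (trial.stage2.n_stage2 if trial.stage2 else 0)
        if trial.stage2 is not None:
            alloc[trial.stage2.med] += trial.stage2.n_stage2
        sizes.append(n_total)
        reasons[trial.stop_reason] = reasons.get(trial.stop_reason, 0) + 1
    n_selected = sel.sum()
    return OperatingCharacteristics(
        selection_freq=sel / n_selected if n_selected else sel,
        allocation_freq=alloc / alloc.sum(),
        mean_sample_size=float(np.mean(sizes)),
        stop_reason_freq={k: v / n_reps for k, v in reasons.items()},
        none_selected_freq=none_sel / n_reps,
    )


def synth_ph_trace(
    target_ri: float,
    duration: float = 86400.0,
    n_episodes: int = 3,
    sampling_interval: float = 4.0,
    seed: int = 0,
) -> PhTrace:
    """Step pH trace with a prescribed reflux index and episode count.

    Builds a regularly sampled trace (default 4 s, typical of antimony-probe
    recorders) whose fraction of time below pH 4 matches ``target_ri``
    within one sampling interval's worth of percentage, distributed over
    exactly ``n_episodes`` disjoint sub-4 episodes placed at seeded random
    positions. Baseline samples are drawn in pH 5-7, acidic samples in
    pH 2-3.5.
    """
    if not 0.0 <= target_ri <= 100.0:
        raise ValueError("target_ri must lie in [0, 100]")
    if duration <= 0 or sampling_interval <= 0:
        raise ValueError("duration and sampling_interval must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration / sampling_interval))
    n_below = int(round(target_ri / 100.0 * n_samples))
    if target_ri > 0 and n_below == 0:
        n_below = 1
    if n_below == 0:
        n_episodes = 0
    elif n_episodes < 1:
        raise ValueError("positive target_ri needs at least one episode")
    if n_episodes and n_below < n_episodes:
        n_below = n_episodes
    # feasibility: episodes + a separating sample between consecutive ones
    if n_below + max(n_episodes - 1, 0) > n_samples:
        raise ValueError("episode layout infeasible for this duration")

    ph = rng.uniform(5.0, 7.0, size=n_samples)
    if n_episodes:
        # split n_below acidic samples into n_episodes positive run lengths
        if n_episodes > 1:
            cuts = np.sort(
                rng.choice(np.arange(1, n_below), size=n_episodes - 1, replace=False)
            )
        else:
            cuts = np.array([], dtype=int)
        lengths = np.diff(np.concatenate([[0], cuts, [n_below]])).astype(int)
        # distribute the baseline samples into n_episodes + 1 gaps; the
        # n_episodes - 1 interior gaps need at least one sample each so the
        # runs stay disjoint
        spare = n_samples - n_below - (n_episodes - 1)
        extra = rng.multinomial(spare, np.ones(n_episodes + 1) / (n_episodes + 1))
        gaps = extra.copy()
        gaps[1:-1] += 1
        pos = 0
        for g, length in zip(gaps[:-1], lengths):
            pos += int(g)
            ph[pos : pos + length] = rng.uniform(2.0, 3.5, size=length)
            pos += length
    timestamps = np.arange(n_samples) * sampling_interval
    return PhTrace(timestamps=timestamps, ph_values=ph, duration=float(duration))
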