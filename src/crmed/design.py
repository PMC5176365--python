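"""Trial design containers: dose grid, skeleton, prior, and design configuration.

The design mirrors a Bayesian efficacy-targeted dose-finding trial run with
the continual reassessment method (CRM): a fixed grid of doses, a skeleton of
prior success probabilities (one per dose), a one-parameter working model that
deforms the skeleton, and cohort-wise sequential allocation toward the dose
whose estimated success probability is closest to a predefined target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DoseGrid",
    "Skeleton",
    "PriorSpec",
    "DesignConfig",
    "PRIOR_FAMILIES",
    "SKELETON_CLIP",
    "DEFAULT_DOSES",
    "DEFAULT_SKELETON",
    "default_design",
    "default_prior",
]

#: Prior families supported for the model parameter `a` (all zero-centred,
#: scale-parameterised; the scale is calibrated, see crmed.model.calibrate).
PRIOR_FAMILIES = ("normal", "laplace", "cauchy")

#: Skeleton values at or above 1 are degenerate under a power-type working
#: model (the dose could never fail); they are clipped to this value.
SKELETON_CLIP = 0.99

#: The omeprazole dose grid of the neonatal reflux trial, in mg/kg/day.
DEFAULT_DOSES = (1.0, 1.5, 2.0, 2.5, 3.0)

#: Elicited prior success probabilities for the default grid. The highest
#: dose was elicited at 100% but enters the model clipped to 0.99.
DEFAULT_SKELETON = (0.50, 0.70, 0.85, 0.95, 0.99)


@dataclass(frozen=True)
class DoseGrid:
    """Ordered grid of candidate doses.

    Parameters
    ----------
    doses : sequence of float
        Strictly increasing, positive dose values (mg/kg/day).
    labels : sequence of str, optional
        Display labels; defaults to the formatted dose values.
    """

    doses: tuple
    labels: tuple = ()

    def __init__(self, doses: Sequence[float], labels: Sequence[str] | None = None):
        doses = tuple(float(d) for d in doses)
        if len(doses) < 2:
            raise ValueError("a dose grid needs at least 2 doses")
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if labels is None:
            labels = tuple(f"{d:g}" for d in doses)
        else:
            labels = tuple(str(s) for s in labels)
            if len(labels) != len(doses):
                raise ValueError("labels must match doses in length")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.doses)

    def index_of(self, dose: float) -> int:
        """Exact-value lookup of a dose in the grid."""
        for i, d in enumerate(self.doses):
            if d == float(dose):
                return i
        raise ValueError(f"dose {dose!r} not in grid {self.doses}")


@dataclass(frozen=True)
class Skeleton:
    """Prior (elicited) success probability at each dose.

    Values must be strictly increasing. Values >= 1 are clipped to
    ``SKELETON_CLIP`` (a probability of exactly 1 can never be revised
    downward under a power-type model), with a warning.
    """

    prior_probs: tuple

    def __init__(self, prior_probs: Sequence[float]):
        import warnings

        probs = [float(p) for p in prior_probs]
        if any(p >= 1.0 for p in probs):
            warnings.warn(
                f"skeleton values >= 1 clipped to {SKELETON_CLIP}", stacklevel=2
            )
            probs = [min(p, SKELETON_CLIP) for p in probs]
        if any(not 0.0 < p < 1.0 for p in probs):
            raise ValueError("skeleton probabilities must lie in (0, 1)")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValueError("skeleton must be strictly increasing")
        object.__setattr__(self, "prior_probs", tuple(probs))

    def __len__(self) -> int:
        return len(self.prior_probs)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.prior_probs, dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Zero-centred prior on the working-model parameter ``a``.

    The family is one of ``PRIOR_FAMILIES``; ``scale`` is the spread
    parameter (standard deviation for the normal family). The shipped
    default scale is calibrated against the trial's first printed
    posterior update (see :func:`crmed.model.calibrate`).
    """

    family: str = "normal"
    scale: float = 1.0

    def __post_init__(self):
        if self.family not in PRIOR_FAMILIES:
            raise ValueError(f"prior family must be one of {PRIOR_FAMILIES}")
        if not self.scale > 0:
            raise ValueError("prior scale must be positive")

    def log_density(self, a: np.ndarray) -> np.ndarray:
        """Unnormalised log prior density evaluated on an array of `a` values."""
        z = np.asarray(a, dtype=float) / self.scale
        if self.family == "normal":
            return -0.5 * z * z
        if self.family == "laplace":
            return -np.abs(z)
        return -np.log1p(z * z)  # cauchy


@dataclass(frozen=True)
class DesignConfig:
    """Full design configuration of the two-stage sequential trial.

    Attributes
    ----------
    grid, skeleton :
        Dose grid and elicited prior success probabilities.
    target : float
        Efficacy target; allocation aims at the dose whose estimated
        success probability is closest to it (0.95 in the reflux trial).
    cohort_size : int
        Patients per posterior update (3).
    max_n : int
        Cap on patients per stratum (30).
    ci_level : float
        Credibility level for interval reporting (0.95).
    stop_low_margin, stop_low_confidence : float
        Stage-1 futility rule: stop when the posterior probability that
        even the highest dose's success probability falls below
        ``target - stop_low_margin`` exceeds ``stop_low_confidence``.
    predictive_gain_eps : float
        Stage-1 convergence rule: stop when the posterior-predictive
        expected maximum change in any dose's estimate from one further
        cohort falls below this threshold.
    stage2_ci_halfwidth : float
        Stage-2 terminates once the credibility interval at the MED has
        half-width at or below this value.
    estimator_variant : str
        ``"plug-in"`` (skeleton raised to exp of the posterior mean of a)
        or ``"full-posterior-mean"`` (posterior expectation of each dose's
        success probability).
    """

    grid: DoseGrid
    skeleton: Skeleton
    target: float = 0.95
    cohort_size: int = 3
    max_n: int = 30
    ci_level: float = 0.95
    stop_low_margin: float = 0.10
    stop_low_confidence: float = 0.90
    predictive_gain_eps: float = 0.01
    stage2_ci_halfwidth: float = 0.05
    estimator_variant: str = "plug-in"

    def __post_init__(self):
        if len(self.grid) != len(self.skeleton):
            raise ValueError("grid and skeleton lengths differ")
        if not 0.0 < self.target < 1.0:
            raise ValueError("target must be in (0, 1)")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.max_n < self.cohort_size:
            raise ValueError("max_n must be >= cohort_size")
        if self.estimator_variant not in ("plug-in", "full-posterior-mean"):
            raise ValueError("unknown estimator variant")

    def with_(self, **kwargs) -> "DesignConfig":
        return replace(self, **kwargs)


def default_design(**overrides) -> DesignConfig:
    """The neonatal omeprazole trial design: 5 doses, target 0.95, cohorts of 3."""
    cfg = DesignConfig(grid=DoseGrid(DEFAULT_DOSES), skeleton=Skeleton(DEFAULT_SKELETON))
    return cfg.with_(**overrides) if overrides else cfg


def default_prior() -> PriorSpec:
    """The shipped calibrated prior (see crmed.model.DEFAULT_PRIOR_SCALE)."""
    from .model import DEFAULT_PRIOR_SCALE

    return PriorSpec(family="normal", scale=DEFAULT_PRIOR_SCALE)
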