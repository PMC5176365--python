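"""Esophageal pH-metry endpoint arithmetic.

The trial's efficacy endpoint is the reflux index (RI): the percentage of a
24-hour intra-esophageal pH recording spent with pH strictly below 4.
Treatment success is RI < 5% (strict; an RI of exactly 5% is a failure, as
the trial's inclusion threshold was RI >= 5%). Secondary metrics are the
number of reflux episodes per hour and the duration of the longest episode.

Traces are step functions: each sample's pH holds from its timestamp until
the next (hold-last-value, matching clinical pH recorders); the last sample
holds until the end of the recording. Linear interpolation is available as
an option for episode detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PhTrace",
    "RefluxEpisode",
    "EndpointSummary",
    "detect_episodes",
    "summarize",
    "REFLUX_PH_THRESHOLD",
    "SUCCESS_RI_PERCENT",
]

REFLUX_PH_THRESHOLD = 4.0
SUCCESS_RI_PERCENT = 5.0


@dataclass(frozen=True)
class PhTrace:
    """Time-stamped intra-esophageal pH samples.

    ``timestamps`` are seconds from recording start, strictly increasing;
    ``duration`` is the total record length and must cover the last sample.
    """

    timestamps: np.ndarray
    ph_values: np.ndarray
    duration: float

    def __init__(self, timestamps: Sequence[float], ph_values: Sequence[float], duration: float | None = None):
        t = np.asarray(timestamps, dtype=float)
        v = np.asarray(ph_values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ValueError("timestamps and ph_values must be equal-length 1-d arrays")
        if (np.diff(t) <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if (v < 0).any() or (v > 14).any():
            raise ValueError("pH values must lie in [0, 14]")
        if duration is None:
            dt = np.median(np.diff(t)) if t.size > 1 else 1.0
            duration = float(t[-1] + dt)
        duration = float(duration)
        if duration < t[-1]:
            raise ValueError("duration must cover the last timestamp")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "ph_values", v)
        object.__setattr__(self, "duration", duration)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class RefluxEpisode:
    """One maximal contiguous interval with pH below threshold (seconds)."""

    start: float
    end: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("episode end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class EndpointSummary:
    """Derived pH-metry metrics; ``success`` is the trial's efficacy endpoint."""

    reflux_index: float  # percent of record with pH < 4
    time_below_4: float  # minutes
    episodes_per_hour: float
    longest_episode: float  # minutes
    success: bool


def _step_intervals(trace: PhTrace) -> tuple[np.ndarray, np.ndarray]:
    """(start, end) of the holding interval of each sample."""
    starts = trace.timestamps
    ends = np.concatenate([trace.timestamps[1:], [trace.duration]])
    return starts, ends


def detect_episodes(
    trace: PhTrace,
    min_duration: float = 0.0,
    threshold: float = REFLUX_PH_THRESHOLD,
    interpolation: str = "step",
) -> list[RefluxEpisode]:
    """Maximal contiguous intervals with pH strictly below the threshold.

    Under step interpolation each sample's value holds until the next
    timestamp; under linear interpolation threshold crossings are located
    between samples. Episodes shorter than ``min_duration`` seconds are
    discarded (default 0: no filtering, since the trial defines the reflux
    index without an episode filter).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if interpolation not in ("step", "linear"):
        raise ValueError("interpolation must be 'step' or 'linear'")

    episodes: list[RefluxEpisode] = []
    if interpolation == "step":
        below = trace.ph_values < threshold
        starts, ends = _step_intervals(trace)
        open_start = None
        for b, s, e in zip(below, starts, ends):
            if b and open_start is None:
                open_start = s
            elif not b and open_start is not None:
                episodes.append(RefluxEpisode(open_start, s))
                open_start = None
        if open_start is not None:
            episodes.append(RefluxEpisode(open_start, trace.duration))
    else:
        t, v = trace.timestamps, trace.ph_values
        below = v < threshold
        open_start = None
        if below[0]:
            open_start = t[0]
        for i in range(1, len(t)):
            if below[i] and not below[i - 1]:
                # crossing between i-1 and i
                frac = (v[i - 1] - threshold) / (v[i - 1] - v[i])
                open_start = t[i - 1] + frac * (t[i] - t[i - 1])
            elif not below[i] and below[i - 1]:
                frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
                cross = t[i - 1] + frac * (t[i] - t[i - 1])
                episodes.append(RefluxEpisode(open_start, cross))
                open_start = None
        if open_start is not None:
            episodes.append(RefluxEpisode(open_start, trace.duration))
    return [ep for ep in episodes if ep.duration >= min_duration or min_duration <= 0]


def summarize(trace: PhTrace, episodes: Sequence[RefluxEpisode]) -> EndpointSummary:
    """Endpoint metrics from a trace and its detected episodes."""
    if trace.duration <= 0:
        raise ValueError("zero-duration trace")
    total_below = float(sum(ep.duration for ep in episodes))
    ri = 100.0 * total_below / trace.duration
    longest = max((ep.duration for ep in episodes), default=0.0)
    return EndpointSummary(
        reflux_index=ri,
        time_below_4=total_below / 60.0,
        episodes_per_hour=len(episodes) / (trace.duration / 3600.0),
        longest_episode=longest / 60.0,
        success=ri < SUCCESS_RI_PERCENT,
    )
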