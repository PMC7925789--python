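"""Trajectory feature extraction: threshold crossings, episode statistics,
monotonicity and equilibrium residuals.

All features are pure functions of a :class:`~reifnet.engine.Trajectory`;
threshold crossings report grid times without interpolation (simulated
curves are read qualitatively, sub-grid precision would be spurious).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .engine import Trajectory, detect_equilibrium
from .errors import SpecificationError

__all__ = [
    "EpisodeStats",
    "FeatureReport",
    "time_to_threshold",
    "episode_stats",
    "monotone_after",
    "monotone_segments",
    "feature_report",
]

Direction = Literal["up", "down"]


def time_to_threshold(trajectory: Trajectory, state: str, theta: float) -> float | None:
    """Earliest grid time at which ``state`` reaches ``theta``; None if never."""
    if not (0.0 <= theta <= 1.0):
        raise SpecificationError(f"time_to_threshold: theta={theta} outside [0, 1]")
    series = trajectory.series(state)
    hits = np.nonzero(series >= theta)[0]
    if not hits.size:
        return None
    return float(trajectory.times[hits[0]])


@dataclass(frozen=True)
class EpisodeStats:
    index: int
    kind: str  # "off" | "on"
    start: float
    end: float
    min: float
    max: float
    mean: float


def episode_stats(
    trajectory: Trajectory,
    period_on: float,
    period_off: float,
    state: str,
    off_first: bool = True,
) -> list[EpisodeStats]:
    """Per-episode min/max/mean of one state.

    Episodes alternate (off first by default, matching schedules where the
    stimulus starts silent) and must partition the horizon.  Each episode
    window is [start, end); the final grid point belongs to the last episode.
    """
    if period_on <= 0 or period_off <= 0:
        raise SpecificationError("episode_stats: episode lengths must be positive")
    horizon = float(trajectory.times[-1] - trajectory.times[0])
    cycle = period_on + period_off
    n_cycles = horizon / cycle
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise SpecificationError(
            f"episode_stats: periods ({period_off}+{period_on}) do not divide the "
            f"horizon {horizon}"
        )
    series = trajectory.series(state)
    t0 = float(trajectory.times[0])
    out: list[EpisodeStats] = []
    start = t0
    kind = "off" if off_first else "on"
    idx = 0
    end_time = float(trajectory.times[-1])
    while start < end_time - 1e-9:
        length = period_off if kind == "off" else period_on
        end = start + length
        last = end >= end_time - 1e-9
        if last:
            mask = (trajectory.times >= start - 1e-9) & (trajectory.times <= end + 1e-9)
        else:
            mask = (trajectory.times >= start - 1e-9) & (trajectory.times < end - 1e-9)
        vals = series[mask]
        out.append(
            EpisodeStats(
                idx, kind, start, end,
                float(vals.min()), float(vals.max()), float(vals.mean()),
            )
        )
        start = end
        kind = "on" if kind == "off" else "off"
        idx += 1
    return out


def monotone_after(
    trajectory: Trajectory,
    state: str,
    t0: float,
    direction: Direction,
    slack: float = 1e-3,
) -> tuple[bool, float]:
    """Does ``state`` move monotonically in ``direction`` after ``t0``?

    Returns ``(ok, max_violation)`` where the violation is the largest
    per-step move against the direction; moves within ``slack`` per step are
    tolerated.
    """
    if direction not in ("up", "down"):
        raise SpecificationError(f"monotone_after: direction must be 'up' or 'down'")
    if t0 > trajectory.times[-1]:
        raise SpecificationError(f"monotone_after: t0={t0} beyond the horizon")
    sub = trajectory.window(t0, float(trajectory.times[-1]))
    diffs = np.diff(sub.series(state))
    against = -diffs if direction == "up" else diffs
    max_violation = float(against.max(initial=0.0))
    return max_violation <= slack, max_violation


def monotone_segments(
    trajectory: Trajectory, state: str, tol: float = 1e-6
) -> list[tuple[float, float, str]]:
    """Maximal (start, end, 'up'|'down'|'flat') segments of one state."""
    t = trajectory.times
    d = np.diff(trajectory.series(state))
    sign = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    segs: list[tuple[float, float, str]] = []
    names = {1: "up", -1: "down", 0: "flat"}
    start = 0
    for k in range(1, len(sign) + 1):
        if k == len(sign) or sign[k] != sign[start]:
            segs.append((float(t[start]), float(t[k]), names[int(sign[start])]))
            start = k
    return segs


@dataclass
class FeatureReport:
    """Summary features of a trajectory (JSON-serialisable)."""

    scenario_id: str
    horizon: float
    final: dict[str, float]
    time_to: dict[str, dict[str, float | None]]  # per threshold, per state
    episodes: dict[str, list[EpisodeStats]]
    equilibrium_time: float | None
    monotone: dict[str, list[tuple[float, float, str]]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario_id": self.scenario_id,
                "horizon": self.horizon,
                "final": self.final,
                "time_to": self.time_to,
                "episodes": {
                    s: [e.__dict__ for e in eps] for s, eps in self.episodes.items()
                },
                "equilibrium_time": self.equilibrium_time,
                "monotone_segments": self.monotone,
            },
            indent=2,
            allow_nan=False,
        )


def feature_report(
    trajectory: Trajectory,
    states: Sequence[str] | None = None,
    thresholds: Sequence[float] = (0.5, 0.9),
    episode: tuple[float, float] | None = None,
    eq_tol: float = 1e-4,
    eq_window: float = 10.0,
) -> FeatureReport:
    """Standard feature bundle used by the CLI ``features`` command."""
    states = list(states) if states is not None else list(trajectory.ids)
    final = {s: float(trajectory.final(s)) for s in states}
    time_to = {
        f"{theta:g}": {s: time_to_threshold(trajectory, s, theta) for s in states}
        for theta in thresholds
    }
    episodes: dict[str, list[EpisodeStats]] = {}
    if episode is not None:
        on, off = episode
        horizon = float(trajectory.times[-1] - trajectory.times[0])
        if math.fmod(horizon + 1e-9, on + off) < 2e-9 or abs(
            math.remainder(horizon, on + off)
        ) < 1e-6:
            episodes = {s: episode_stats(trajectory, on, off, s) for s in states}
    eq = detect_equilibrium(trajectory, tol=eq_tol, window=eq_window)
    monotone = {s: monotone_segments(trajectory, s, tol=1e-4) for s in states}
    return FeatureReport(
        trajectory.scenario_id,
        float(trajectory.times[-1]),
        final,
        time_to,
        episodes,
        eq,
        monotone,
    )
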