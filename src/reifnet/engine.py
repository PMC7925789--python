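"""Discrete-time simulation core for reified temporal-causal networks.

Every state ``Y`` follows the first-order update

    Y(t + dt) = Y(t) + eta_Y * [aggimpact_Y(t) - Y(t)] * dt

where ``aggimpact_Y(t) = c_Y(omega_{X1,Y} X1(t), ..., omega_{Xk,Y} Xk(t))``
is the per-state combination of the single causal impacts.  Adaptive
characteristics (connection weights, speeds, function parameters) are
*reified*: their value at time ``t`` is the activation of a self-model
state, read from the same snapshot.  The update is synchronous
(Jacobi-style): all aggregated impacts and all reified characteristics are
read at ``t`` before any state is written, so results do not depend on
state ordering.  Exogenous stimulus states are overwritten from the
scenario schedule after each step; they are world states, not dynamical
ones.

The engine itself is deterministic: identical inputs give identical
trajectories, bit for bit.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import combinators
from .errors import EngineError, SpecificationError
from .model_spec import NetworkSpec

__all__ = [
    "Snapshot",
    "Trajectory",
    "SimulationConfig",
    "ScenarioSchedule",
    "CompiledNetwork",
    "aggimpact",
    "step",
    "simulate",
    "detect_equilibrium",
    "plot_trajectory",
]


@dataclass(frozen=True)
class Snapshot:
    """All state activations at one time point."""

    t: float
    values: Mapping[str, float]

    def __getitem__(self, state_id: str) -> float:
        return self.values[state_id]


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings of a run.

    dt : Euler step, model time units (default 0.5).
    horizon : end time; if None the schedule's horizon is used.
    clamp_mode : clip activations to [0, 1] after each step.
    eq_tol / eq_window : defaults for equilibrium detection (max rate of
        change per unit time, and how long it must stay below).
    """

    dt: float = 0.5
    horizon: float | None = None
    clamp_mode: bool = True
    eq_tol: float = 1e-4
    eq_window: float = 10.0

    def __post_init__(self):
        if self.dt <= 0:
            raise SpecificationError("SimulationConfig: dt must be positive")


@dataclass
class ScenarioSchedule:
    """Piecewise-constant exogenous input signals over [0, horizon].

    ``signals`` maps an input state id to a time-sorted list of
    ``(start_time, value)`` breakpoints; the signal holds each value until
    the next breakpoint.  ``overlay`` optionally overrides initial values of
    arbitrary states at t = 0 (used e.g. to start a run with already-formed
    self-model traces).
    """

    scenario_id: str
    horizon: float
    signals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    overlay: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for sid, bps in self.signals.items():
            bps.sort(key=lambda p: p[0])
            if not bps or bps[0][0] > 0.0:
                raise SpecificationError(
                    f"schedule {self.scenario_id!r}: signal {sid!r} undefined at t=0"
                )
            for t, v in bps:
                if not (0.0 <= v <= 1.0):
                    raise SpecificationError(
                        f"schedule {self.scenario_id!r}: signal {sid!r} value {v} outside [0, 1]"
                    )

    @property
    def inputs(self) -> list[str]:
        return list(self.signals)

    def value_at(self, state_id: str, t: float) -> float:
        bps = self.signals[state_id]
        k = bisect_right(bps, (t, math.inf)) - 1
        return bps[max(k, 0)][1]

    def to_json_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "horizon": self.horizon,
            "signals": {k: [list(p) for p in v] for k, v in self.signals.items()},
            "overlay": dict(self.overlay),
        }

    @classmethod
    def from_json_dict(cls, raw: dict) -> "ScenarioSchedule":
        return cls(
            scenario_id=raw["scenario_id"],
            horizon=float(raw["horizon"]),
            signals={k: [(float(t), float(v)) for t, v in bps] for k, bps in raw["signals"].items()},
            overlay={k: float(v) for k, v in raw.get("overlay", {}).items()},
        )


@dataclass
class Trajectory:
    """A simulated run: uniform time grid and a (T, N) activation matrix."""

    ids: list[str]
    times: np.ndarray
    values: np.ndarray
    dt: float
    scenario_id: str = ""

    def __post_init__(self):
        self._col = {sid: k for k, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.times)

    def series(self, state_id: str) -> np.ndarray:
        try:
            return self.values[:, self._col[state_id]]
        except KeyError:
            raise SpecificationError(f"trajectory has no state {state_id!r}") from None

    def snapshot(self, k: int) -> Snapshot:
        return Snapshot(float(self.times[k]), dict(zip(self.ids, self.values[k])))

    def final(self, state_id: str) -> float:
        return float(self.series(state_id)[-1])

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory on [t0, t1] (inclusive grid points)."""
        mask = (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)
        return Trajectory(self.ids, self.times[mask], self.values[mask], self.dt, self.scenario_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.ids)
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, scenario_id: str = "") -> "Trajectory":
        df = pd.read_csv(path)
        if "t" not in df.columns:
            raise SpecificationError(f"{path}: trajectory CSV must have a 't' column")
        times = df["t"].to_numpy(float)
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        ids = [c for c in df.columns if c != "t"]
        return cls(ids, times, df[ids].to_numpy(float), dt, scenario_id)


# ---------------------------------------------------------------------------
# compilation: turn a NetworkSpec into index-based update tables
# ---------------------------------------------------------------------------


class _CState:
    __slots__ = (
        "sid", "src", "wconst", "apos", "asrc", "eta_const", "eta_src",
        "funcs", "single", "skip",
    )


class CompiledNetwork:
    """Index-compiled network: one pass of the synchronous Euler step.

    Built once per simulation; holds, per state, the incoming indices,
    constant weights with the positions/sources of adaptive slots, the speed
    source, and the combination-function assignments with parameter
    references resolved to state indices.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.ids = spec.ids
        self.index = {sid: k for k, sid in enumerate(self.ids)}
        m = spec.matrices
        self.cstates: list[_CState] = []
        for i, sid in enumerate(self.ids):
            cs = _CState()
            cs.sid = sid
            row = m.mb.get(sid, [])
            cs.skip = not row
            cs.src = np.array([self.index[s] for s in row], dtype=np.intp)
            wv = m.mcwv.get(sid, [])
            wa = m.mcwa.get(sid, [])
            wconst = np.zeros(len(row))
            apos, asrc = [], []
            for slot in range(len(row)):
                if slot < len(wa) and wa[slot] is not None:
                    apos.append(slot)
                    asrc.append(self.index[wa[slot]])
                elif slot < len(wv) and wv[slot] is not None:
                    wconst[slot] = wv[slot]
                elif row:
                    raise SpecificationError(
                        f"state {sid!r} slot {slot + 1}: no weight source"
                    )
            cs.wconst = wconst
            cs.apos = np.array(apos, dtype=np.intp)
            cs.asrc = np.array(asrc, dtype=np.intp)
            if m.msa.get(sid) is not None:
                cs.eta_src = self.index[m.msa[sid]]
                cs.eta_const = 0.0
            else:
                cs.eta_src = -1
                cs.eta_const = float(m.msv.get(sid) or 0.0)
            funcs = []
            for a in spec.function_assignments(sid):
                const_params = {
                    k: float(v) for k, v in a.params.items() if not isinstance(v, str)
                }
                ref_params = {
                    k: self.index[v] for k, v in a.params.items() if isinstance(v, str)
                }
                if isinstance(a.blend_weight, str):
                    blend_const, blend_src = 0.0, self.index[a.blend_weight]
                else:
                    blend_const, blend_src = float(a.blend_weight), -1
                funcs.append((a.function_id, const_params, ref_params, blend_const, blend_src))
            if not cs.skip and not funcs:
                raise SpecificationError(
                    f"state {sid!r}: incoming connections but no combination function"
                )
            cs.funcs = funcs
            cs.single = len(funcs) == 1 and funcs[0][4] == -1
            self.cstates.append(cs)

    # -- one synchronous step -------------------------------------------
    def step_values(
        self,
        y: np.ndarray,
        t_next: float,
        schedule: ScenarioSchedule | None,
        dt: float,
        clamp: bool,
    ) -> np.ndarray:
        out = np.empty_like(y)
        for i, cs in enumerate(self.cstates):
            if cs.skip:
                out[i] = y[i]
                continue
            w = cs.wconst
            if len(cs.apos):
                w = w.copy()
                w[cs.apos] = y[cs.asrc]
            impacts = w * y[cs.src]
            agg = self._aggregate(cs, impacts, y, i, clamp)
            if not math.isfinite(agg):
                raise EngineError(
                    f"non-finite aggregated impact for state {cs.sid!r} at t={t_next - dt:g}"
                )
            eta = y[cs.eta_src] if cs.eta_src >= 0 else cs.eta_const
            out[i] = y[i] + eta * (agg - y[i]) * dt
        if clamp:
            np.clip(out, 0.0, 1.0, out=out)
        if schedule is not None:
            for sid in schedule.inputs:
                out[self.index[sid]] = schedule.value_at(sid, t_next)
        return out

    def _aggregate(self, cs: _CState, impacts, y, i, clamp) -> float:
        num = 0.0
        den = 0.0
        for fid, cp, rp, bconst, bsrc in cs.funcs:
            gamma = y[bsrc] if bsrc >= 0 else bconst
            if gamma == 0.0 and not cs.single:
                continue
            if fid == "hebb":
                mu = y[rp["mu"]] if "mu" in rp else cp["mu"]
                val = combinators.hebb(impacts[0], impacts[1], y[i], mu, clamp=clamp)
            elif fid == "alogistic":
                sigma = y[rp["sigma"]] if "sigma" in rp else cp.get("sigma", 1.0)
                tau = y[rp["tau"]] if "tau" in rp else cp.get("tau", 0.0)
                val = combinators.alogistic(impacts, sigma, tau, clamp=bool(cp.get("clamp", 1.0)))
            elif fid == "eucl":
                val = combinators.eucl(impacts, cp.get("n", 1.0), cp.get("lam", 1.0))
            elif fid == "identity":
                val = combinators.identity(impacts)
            else:  # custom registry entries
                params = dict(cp)
                params.update({k: y[s] for k, s in rp.items()})
                val = combinators.evaluate(fid, list(impacts), params, {"w": y[i]})
            if cs.single:
                return val
            num += gamma * val
            den += gamma
        if den <= 0.0:
            raise EngineError(f"state {cs.sid!r}: all blend weights zero at run time")
        return num / den


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def aggimpact(
    weights: Sequence[float],
    source_values: Sequence[float],
    assignments: Sequence[combinators.FunctionAssignment],
    extra: Mapping[str, float] | None = None,
) -> float:
    """Aggregated causal impact: single impacts ``omega*X`` combined by ``c_Y``."""
    if len(weights) != len(source_values):
        raise EngineError(
            f"aggimpact: {len(weights)} weights but {len(source_values)} source values"
        )
    impacts = [w * v for w, v in zip(weights, source_values)]
    return combinators.combine(assignments, impacts, extra)


def step(
    spec: NetworkSpec,
    snapshot: Snapshot,
    schedule: ScenarioSchedule | None = None,
    dt: float = 0.5,
    clamp_mode: bool = True,
) -> Snapshot:
    """One synchronous update of every state from ``t`` to ``t + dt``."""
    net = CompiledNetwork(spec)
    missing = [sid for sid in net.ids if sid not in snapshot.values]
    if missing:
        raise EngineError(f"snapshot missing state(s) {missing[:5]}")
    y = np.array([float(snapshot.values[sid]) for sid in net.ids])
    out = net.step_values(y, snapshot.t + dt, schedule, dt, clamp_mode)
    return Snapshot(snapshot.t + dt, dict(zip(net.ids, out.tolist())))


def simulate(
    spec: NetworkSpec,
    schedule: ScenarioSchedule | None = None,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Iterate the synchronous Euler step over the scenario horizon.

    The first snapshot is the spec's initial values with the schedule's
    overlay and t=0 signal values applied.  The trajectory has
    ``horizon/dt + 1`` grid points and is fully deterministic.
    """
    config = config or SimulationConfig()
    horizon = config.horizon
    if horizon is None:
        if schedule is None:
            raise SpecificationError("simulate: either a schedule or config.horizon required")
        horizon = schedule.horizon
    net = CompiledNetwork(spec)
    if schedule is not None:
        for sid in list(schedule.signals) + list(schedule.overlay):
            if sid not in net.index:
                raise SpecificationError(f"schedule refers to unknown state {sid!r}")
    y = np.array([s.initial_value for s in spec.states], dtype=float)
    if schedule is not None:
        for sid, v in schedule.overlay.items():
            y[net.index[sid]] = v
        for sid in schedule.inputs:
            y[net.index[sid]] = schedule.value_at(sid, 0.0)
    n_steps = int(round(horizon / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    values = np.empty((n_steps + 1, len(net.ids)))
    values[0] = y
    for k in range(n_steps):
        try:
            y = net.step_values(y, float(times[k + 1]), schedule, config.dt, config.clamp_mode)
        except EngineError as e:
            raise EngineError(f"t={times[k]:g}: {e}") from e
        values[k + 1] = y
    return Trajectory(
        net.ids, times, values, config.dt,
        schedule.scenario_id if schedule is not None else "",
    )


def detect_equilibrium(
    trajectory: Trajectory, tol: float = 1e-4, window: float = 10.0
) -> float | None:
    """Earliest grid time after which every state moves < ``tol`` per unit time.

    The criterion must hold from the returned time to the end of the
    trajectory, with at least ``window`` time units of evidence; returns
    ``None`` if it is never satisfied.
    """
    if len(trajectory) == 0:
        raise SpecificationError("detect_equilibrium: empty trajectory")
    if len(trajectory) == 1:
        return float(trajectory.times[0])
    rates = np.abs(np.diff(trajectory.values, axis=0)).max(axis=1) / trajectory.dt
    calm = rates < tol
    # earliest k such that calm[k:] is all True
    not_calm = np.nonzero(~calm)[0]
    k = 0 if not not_calm.size else int(not_calm[-1]) + 1
    if k >= len(calm):
        return None
    t_eq = float(trajectory.times[k])
    if float(trajectory.times[-1]) - t_eq + 1e-9 < window:
        return None
    return t_eq


def plot_trajectory(
    trajectory: Trajectory,
    states: Sequence[str],
    path: str | Path,
    title: str | None = None,
) -> None:
    """Line plot of selected states over time (PNG/SVG by file suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    for sid in states:
        ax.plot(trajectory.times, trajectory.series(sid), label=sid, linewidth=1.2)
    ax.set_xlabel("time")
    ax.set_ylabel("activation")
    ax.set_ylim(-0.05, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=140)
    plt.close(fig)
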