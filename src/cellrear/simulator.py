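"""Deterministic time integration of a compiled model with timed events.

Simulations follow the study protocol: an LSODA-style stiff/non-stiff
switching integrator over 10000 s with states reported every 25 s.  Timed
events (instantaneous parameter changes or species-pool reassignments)
split the integration; the state and rate vector are edited exactly at the
event time and integration restarts from there.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ode_builder import CompiledModel, active_pool, inactive_pool
from .wiring import StateAssignment

__all__ = [
    "SimulationSettings",
    "Event",
    "Trajectory",
    "TimeSeries",
    "SteadyStateReport",
    "IntegrationError",
    "simulate",
    "steady_state",
    "observable",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationSettings:
    t_end: float = 10000.0
    output_interval: float = 25.0
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        n = self.t_end / self.output_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("output_interval must divide t_end")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.output_interval))
        return np.linspace(0.0, self.t_end, n + 1)


@dataclass(frozen=True)
class Event:
    """An instantaneous model edit at a fixed time.

    ``set_parameter`` replaces a rate constant; ``set_species`` reassigns a
    species' named pool ("active" or "inactive"), moving the difference
    to/from the sibling pool so the conserved moiety is untouched.
    """

    time: float
    action: str  # set_parameter | set_species
    target: str
    value: float
    pool: str = "active"

    def __post_init__(self) -> None:
        if self.action not in ("set_parameter", "set_species"):
            raise ValueError(f"unknown event action {self.action!r}")
        if self.pool not in ("active", "inactive"):
            raise ValueError(f"unknown pool {self.pool!r}")


@dataclass(frozen=True)
class TimeSeries:
    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def final(self) -> float:
        return float(self.values[-1])

    def at(self, t: float) -> float:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-6 * max(1.0, abs(t)):
            raise KeyError(f"time {t} not on grid")
        return float(self.values[idx])


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (ntimes, npools)
    pools: tuple[str, ...]
    settings: SimulationSettings
    events: tuple[Event, ...] = ()
    model: CompiledModel | None = None

    def __post_init__(self) -> None:
        self.pool_index = {p: i for i, p in enumerate(self.pools)}

    def pool_series(self, pool: str) -> TimeSeries:
        return TimeSeries(self.times, self.states[:, self.pool_index[pool]], name=pool)

    def observable(self, species: str) -> TimeSeries:
        return observable(self, species)

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def conservation_error(self) -> float:
        """Worst relative moiety-conservation error over species and times."""
        if self.model is None or self.model.diagram is None:
            raise ValueError("trajectory carries no model/diagram for conservation checks")
        worst = 0.0
        for sp in self.model.diagram.species:
            idx = [self.pool_index[p] for p in self.model.moiety_pools(sp.name)]
            totals = self.states[:, idx].sum(axis=1)
            ref = totals[0] if totals[0] > 0 else 1.0
            worst = max(worst, float(np.max(np.abs(totals - totals[0])) / ref))
        return worst

    def to_csv(self, path=None) -> str | None:
        df = pd.DataFrame(self.states, columns=list(self.pools))
        df.insert(0, "time_s", self.times)
        text = df.to_csv(index=False, float_format="%.17g")
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_csv(cls, source, settings: SimulationSettings | None = None) -> "Trajectory":
        df = pd.read_csv(source, float_precision="round_trip")
        if df.columns[0] != "time_s":
            raise ValueError("first column must be time_s")
        times = df["time_s"].to_numpy()
        if settings is None:
            settings = SimulationSettings(
                t_end=float(times[-1]), output_interval=float(times[1] - times[0])
            )
        return cls(
            times=times,
            states=df.iloc[:, 1:].to_numpy(),
            pools=tuple(df.columns[1:]),
            settings=settings,
        )


@dataclass(frozen=True)
class SteadyStateReport:
    converged: bool
    final_state: np.ndarray
    max_rel_change: float
    window: float
    rel_tol: float
    worst_pool: str = ""


def _apply_event(
    event: Event, y: np.ndarray, k_overrides: dict[str, float], model: CompiledModel
) -> None:
    if event.action == "set_parameter":
        if event.target not in model.parameters:
            raise KeyError(f"event references unknown parameter {event.target!r}")
        k_overrides[event.target] = event.value
        return
    pool_name = active_pool(event.target) if event.pool == "active" else inactive_pool(event.target)
    sibling = inactive_pool(event.target) if event.pool == "active" else active_pool(event.target)
    if pool_name not in model.pool_index:
        raise KeyError(f"event references unknown species {event.target!r}")
    i, j = model.pool_index[pool_name], model.pool_index[sibling]
    delta = event.value - y[i]
    y[i] = event.value
    y[j] -= delta


def simulate(
    model: CompiledModel,
    ics: StateAssignment | np.ndarray,
    events: Sequence[Event] = (),
    settings: SimulationSettings | None = None,
) -> Trajectory:
    """Integrate ``model`` from ``ics`` with timed events.

    Returns the trajectory on the regular output grid (t = 0, interval, ...,
    t_end).  Events are applied instantaneously, in list order when
    simultaneous, and each one restarts the integrator.
    """
    if settings is None:
        settings = SimulationSettings()
    events = tuple(sorted(events, key=lambda e: e.time))
    for ev in events:
        if not (0.0 < ev.time < settings.t_end):
            raise ValueError(f"event time {ev.time} outside (0, {settings.t_end})")

    y = (
        model.initial_vector(ics)
        if isinstance(ics, StateAssignment)
        else np.asarray(ics, dtype=float).copy()
    )
    grid = settings.grid
    out = np.empty((len(grid), len(model.pools)))
    out[0] = y
    written = {0}

    k_overrides: dict[str, float] = {}
    k = model.rate_vector()
    boundaries = sorted({ev.time for ev in events} | {settings.t_end})
    t0 = 0.0
    for t1 in boundaries:
        if t1 > t0:
            mask = (grid > t0 + 1e-12) & (grid <= t1 + 1e-12)
            t_eval = grid[mask]
            sol = solve_ivp(
                model.derivative,
                (t0, t1),
                y,
                method=settings.method,
                t_eval=np.concatenate([t_eval, [t1]]) if (len(t_eval) == 0 or t_eval[-1] < t1 - 1e-9) else t_eval,
                rtol=settings.rtol,
                atol=settings.atol,
                args=(k,),
                jac=lambda t, yy, kk: model.jacobian(t, yy, kk),
            )
            if not sol.success:
                worst = int(np.argmax(np.abs(model.derivative(sol.t[-1], sol.y[:, -1], k))))
                raise IntegrationError(
                    f"integration failed at t={sol.t[-1]:.6g}: {sol.message} "
                    f"(largest derivative on pool {model.pools[worst]!r})"
                )
            for ti, yi in zip(sol.t, sol.y.T):
                hits = np.where(np.abs(grid - ti) <= 1e-9 * max(1.0, ti))[0]
                for h in hits:
                    out[h] = yi
                    written.add(int(h))
            y = sol.y[:, -1].copy()
        for ev in events:
            if ev.time == t1:
                _apply_event(ev, y, k_overrides, model)
        if k_overrides:
            k = model.rate_vector(k_overrides)
        t0 = t1
        # event times landing exactly on grid points report the post-event state
        hits = np.where(np.abs(grid - t1) <= 1e-9 * max(1.0, t1))[0]
        for h in hits:
            out[h] = y
            written.add(int(h))

    missing = set(range(len(grid))) - written
    if missing:
        raise IntegrationError(f"output grid points not produced: {sorted(missing)[:5]}")

    floor = -max(100.0 * settings.atol, 1e-9)
    if out.min() < floor:
        i, j = np.unravel_index(np.argmin(out), out.shape)
        raise IntegrationError(
            f"negative pool value {out[i, j]:.3e} for {model.pools[j]!r} at "
            f"t={grid[i]:g}: tighten tolerances"
        )
    return Trajectory(
        times=grid,
        states=out,
        pools=model.pools,
        settings=settings,
        events=events,
        model=model,
    )


def observable(trajectory: Trajectory, species: str) -> TimeSeries:
    """The species' active pool over time, read as % activity on 0-100."""
    pool = active_pool(species)
    if pool not in trajectory.pool_index:
        raise KeyError(f"unknown species {species!r}")
    return TimeSeries(trajectory.times, trajectory.states[:, trajectory.pool_index[pool]], species)


def steady_state(
    trajectory: Trajectory, window: float = 1000.0, rel_tol: float = 0.01
) -> SteadyStateReport:
    """Classify convergence from the trailing ``window`` of a trajectory.

    A pool has converged when its spread over the window is at most
    ``rel_tol`` relative to its final value (with a 1e-3 activity-unit
    floor so that empty pools cannot fail on roundoff noise).
    """
    if window > trajectory.times[-1] - trajectory.times[0]:
        raise ValueError("window exceeds trajectory span")
    mask = trajectory.times >= trajectory.times[-1] - window
    tail = trajectory.states[mask]
    final = trajectory.states[-1]
    spread = tail.max(axis=0) - tail.min(axis=0)
    scale = np.maximum(np.abs(final), 1e-3)
    rel = spread / scale
    worst = int(np.argmax(rel))
    return SteadyStateReport(
        converged=bool(rel[worst] <= rel_tol),
        final_state=final.copy(),
        max_rel_change=float(rel[worst]),
        window=window,
        rel_tol=rel_tol,
        worst_pool=trajectory.pools[worst],
    )
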