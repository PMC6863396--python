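"""Scaled parameter sensitivity of steady-state rear retraction.

For every rate constant k the scaled (logarithmic) sensitivity

    S_k = (k / R) * dR/dk

is estimated by central differences at the steady state R of the
unperturbed scenario.  For a mass-action system the S_k sum to zero at
steady state: scaling every rate by a common factor only rescales time, so
the steady state itself is invariant.  The sum is therefore a built-in
consistency check on both the steady state and the differencing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import pandas as pd

from .ode_builder import CompiledModel, RateParameter
from .simulator import SimulationSettings, observable, simulate, steady_state
from .wiring import default_initial_conditions

__all__ = [
    "SensitivityReport",
    "SweepEntry",
    "SweepReport",
    "SENSITIVITY_SETTINGS",
    "scaled_sensitivities",
    "rank_critical",
    "robustness_sweep",
]

#: Long horizon + coarse reporting grid used to evaluate steady states.
SENSITIVITY_SETTINGS = SimulationSettings(t_end=100000.0, output_interval=1000.0)

TARGET = "RearRetraction"


def _with_rate(model: CompiledModel, name: str, value: float) -> CompiledModel:
    params = dict(model.parameters)
    params[name] = replace(params[name], value=value)
    return CompiledModel(
        model.pools,
        model.reactions,
        params,
        model.observables,
        model.clamped_species,
        model.diagram,
    )


def _steady_target(model: CompiledModel, settings: SimulationSettings) -> float:
    traj = simulate(model, default_initial_conditions(model.diagram), settings=settings)
    return observable(traj, TARGET).final()


@dataclass
class SensitivityReport:
    target: str
    baseline: float
    delta: float
    sensitivities: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.sensitivities.values()))

    def to_frame(self, parameters: dict[str, RateParameter] | None = None) -> pd.DataFrame:
        rows = []
        for name, s in self.sensitivities.items():
            row = {"parameter": name, "sensitivity": s}
            if parameters is not None:
                row["value"] = parameters[name].value
                row["rate_class"] = parameters[name].rate_class
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path=None, *, indent: int = 2) -> str:
        doc = {
            "target": self.target,
            "baseline": self.baseline,
            "delta": self.delta,
            "total": self.total,
            "sensitivities": self.sensitivities,
        }
        text = json.dumps(doc, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def scaled_sensitivities(
    model: CompiledModel,
    delta: float = 0.01,
    settings: SimulationSettings = SENSITIVITY_SETTINGS,
    steady_rel_tol: float = 1e-6,
) -> SensitivityReport:
    """Central-difference scaled sensitivities of steady-state retraction.

    Each rate k_i is perturbed to k_i (1 +/- delta) in turn; the target is
    re-simulated to steady state and
    S_i = (k_i / R) [R(k_i(1+delta)) - R(k_i(1-delta))] / (2 k_i delta).
    """
    if model.diagram is None:
        raise ValueError("sensitivity analysis requires a model with a diagram")
    ics = default_initial_conditions(model.diagram)
    base_traj = simulate(model, ics, settings=settings)
    report = steady_state(base_traj, window=10 * settings.output_interval, rel_tol=steady_rel_tol)
    if not report.converged:
        raise RuntimeError(
            f"unperturbed scenario not at steady state (max relative change "
            f"{report.max_rel_change:.3g} in pool {report.worst_pool!r})"
        )
    R = observable(base_traj, TARGET).final()
    if R == 0.0:
        raise RuntimeError("steady-state target is zero; scaled sensitivity undefined")
    sens: dict[str, float] = {}
    for name, param in model.parameters.items():
        up = _steady_target(_with_rate(model, name, param.value * (1 + delta)), settings)
        down = _steady_target(_with_rate(model, name, param.value * (1 - delta)), settings)
        sens[name] = (up - down) / (2.0 * delta * R)
    return SensitivityReport(target=TARGET, baseline=R, delta=delta, sensitivities=sens)


def rank_critical(report: SensitivityReport, top_n: int = 5) -> list[str]:
    """Parameters ranked by |S| descending; ties broken by parameter order."""
    order = {name: i for i, name in enumerate(report.sensitivities)}
    ranked = sorted(report.sensitivities, key=lambda n: (-abs(report.sensitivities[n]), order[n]))
    return ranked[: max(top_n, 0)]


@dataclass(frozen=True)
class SweepEntry:
    parameter: str
    factor: float
    finals_with_input: dict[str, float]
    finals_without: dict[str, float]
    behavior: str


@dataclass
class SweepReport:
    baseline_behavior: str
    baseline_finals: dict[str, float]
    entries: list[SweepEntry]

    @property
    def all_unchanged(self) -> bool:
        return all(e.behavior == self.baseline_behavior for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": e.parameter,
                "factor": e.factor,
                "retraction_with_input": e.finals_with_input[TARGET],
                "retraction_without": e.finals_without[TARGET],
                "behavior": e.behavior,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def robustness_sweep(
    model: CompiledModel,
    parameters: list[str],
    factors: tuple[float, ...] = (0.5, 2.0),
    thresholds=None,
) -> SweepReport:
    """Halve/double sweep: rerun the with/without-input pair per perturbation.

    Each (parameter, factor) is applied alone; the behavior classification
    (ensemble module) of the perturbed model is compared with baseline.
    """
    from .ensemble import BehaviorThresholds, classify_behavior
    from .experiments import run_scenario

    if thresholds is None:
        thresholds = BehaviorThresholds()
    for name in parameters:
        if name not in model.parameters:
            raise KeyError(f"unknown parameter {name!r}")

    def classify(m) -> tuple[str, dict, dict]:
        with_input = run_scenario("unperturbed", m)
        without = run_scenario("no_input", m)
        label = classify_behavior(with_input, without, thresholds)
        return label, with_input.finals, without.finals

    base_label, base_with, _ = classify(model)
    entries = []
    for name in parameters:
        for factor in factors:
            m2 = _with_rate(model, name, model.parameters[name].value * factor)
            label, fin_with, fin_without = classify(m2)
            entries.append(SweepEntry(name, factor, fin_with, fin_without, label))
    return SweepReport(baseline_behavior=base_label, baseline_finals=base_with, entries=entries)
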