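"""Parameter-profile ensembles under order-of-magnitude uncertainty.

The study constrains rates only to decades (1e-n) with protein interactions
faster as a class than biophysical ones and turnover anchored at 0.01 for
the event-perturbed species.  The sampler draws whole profiles from that
constraint set; classifying each profile's with/without-input behavior
quantifies how much of the qualitative result follows from topology rather
than the particular calibrated rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .ode_builder import RateParameter, compile_model, default_profile
from .simulator import IntegrationError
from .wiring import WiringDiagram, canonical_wiring

__all__ = [
    "SamplerConfig",
    "BehaviorThresholds",
    "EnsembleReport",
    "sample_parameter_profiles",
    "classify_behavior",
    "ensemble_summary",
]

#: Exponent ranges (n in 1e-n) per rate class: overlapping but ordered.
DEFAULT_EXPONENT_RANGES: dict[str, tuple[int, int]] = {
    "protein": (1, 3),
    "biophysical": (2, 4),
    "turnover": (2, 3),
}

#: Rates pinned at their event baselines (the perturbation protocols state
#: "from 0.01"), so sampled profiles stay consistent with the experiments.
DEFAULT_ANCHORS: dict[str, float] = {
    "kturn_MembraneTension": 1e-2,
    "kturn_Actin": 1e-2,
    "kturn_ROCK1": 1e-2,
    "kturn_PKN2": 1e-2,
}


@dataclass(frozen=True)
class SamplerConfig:
    seed: int = 0
    n_profiles: int = 10
    exponent_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_EXPONENT_RANGES)
    )
    anchors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANCHORS))

    def __post_init__(self) -> None:
        for cls, (lo, hi) in self.exponent_ranges.items():
            if lo > hi:
                raise ValueError(f"empty exponent range for class {cls!r}")
        for name, value in self.anchors.items():
            n = round(-math.log10(value))
            if n < 1 or abs(value - 10.0 ** (-n)) > 1e-9 * value:
                raise ValueError(f"anchor {name}={value} is not on the 1e-n grid")


@dataclass(frozen=True)
class BehaviorThresholds:
    """Operational cutoffs for the qualitative labels.

    ``responsive_min`` (default 50) makes "high steady state" concrete and
    ``quiescent_max`` (default 5) "negligible"; convergence is judged over
    the trailing ``window`` at ``rel_tol``.
    """

    responsive_min: float = 50.0
    quiescent_max: float = 5.0
    window: float = 1000.0
    rel_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.quiescent_max >= self.responsive_min:
            raise ValueError("quiescent_max must be below responsive_min")


def sample_parameter_profiles(
    config: SamplerConfig, diagram: WiringDiagram | None = None
) -> list[dict[str, RateParameter]]:
    """Draw ``n_profiles`` rate profiles on the decade grid.

    Every non-anchored forward rate gets an exponent drawn uniformly from
    its class range; reverse steps follow at exactly 10% of their forward.
    Deterministic given the seed.
    """
    if diagram is None:
        diagram = canonical_wiring()
    template = default_profile(diagram)
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_profiles):
        profile: dict[str, RateParameter] = {}
        for name, param in template.items():
            if param.is_reverse:
                continue
            if name in config.anchors:
                value = config.anchors[name]
            else:
                lo, hi = config.exponent_ranges[param.rate_class]
                value = 10.0 ** (-int(rng.integers(lo, hi + 1)))
            profile[name] = RateParameter(name, value, param.rate_class)
        for name, param in template.items():
            if param.is_reverse:
                fwd = profile[param.paired_forward]
                profile[name] = RateParameter(
                    name, fwd.value * 0.1, param.rate_class, True, param.paired_forward
                )
        out.append({name: profile[name] for name in template})
    return out


def classify_behavior(
    result_with_input, result_without, thresholds: BehaviorThresholds | None = None
) -> str:
    """Label a with/without-input scenario pair.

    ``faithful``: retraction reaches a converged high steady state with the
    stiffness input and stays negligible without it.  Otherwise the label
    names the first failed clause: ``non_convergent``, ``non_responsive``
    (with-input final too low) or ``constitutive`` (retracts without input).
    """
    if thresholds is None:
        thresholds = BehaviorThresholds()
    final_with = result_with_input.finals["RearRetraction"]
    final_without = result_without.finals["RearRetraction"]
    if final_with < thresholds.responsive_min:
        return "non_responsive"
    if not result_with_input.steady.converged:
        return "non_convergent"
    if final_without > thresholds.quiescent_max:
        return "constitutive"
    return "faithful"


@dataclass
class EnsembleReport:
    seed: int
    thresholds: BehaviorThresholds
    classifications: list[str]
    errors: list[str]

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.classifications:
            out[c] = out.get(c, 0) + 1
        return out

    @property
    def faithful_fraction(self) -> float:
        if not self.classifications:
            return 0.0
        return self.classifications.count("faithful") / len(self.classifications)

    def to_json(self, path=None, *, indent: int = 2) -> str:
        doc = {
            "seed": self.seed,
            "n_profiles": len(self.classifications),
            "faithful_fraction": self.faithful_fraction,
            "counts": self.counts,
            "classifications": self.classifications,
            "errors": self.errors,
            "thresholds": {
                "responsive_min": self.thresholds.responsive_min,
                "quiescent_max": self.thresholds.quiescent_max,
            },
        }
        text = json.dumps(doc, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def ensemble_summary(
    profiles: list[dict[str, RateParameter]],
    thresholds: BehaviorThresholds | None = None,
    diagram: WiringDiagram | None = None,
    seed: int = 0,
) -> EnsembleReport:
    """Classify every profile's with/without-input behavior pair.

    Integration failures are recorded per profile (label ``error``) rather
    than aborting the ensemble.
    """
    from .experiments import run_scenario

    if not profiles:
        raise ValueError("ensemble requires at least one profile")
    if thresholds is None:
        thresholds = BehaviorThresholds()
    if diagram is None:
        diagram = canonical_wiring()
    labels: list[str] = []
    errors: list[str] = []
    for i, profile in enumerate(profiles):
        try:
            model = compile_model(diagram, profile)
            with_input = run_scenario("unperturbed", model)
            without = run_scenario("no_input", model)
            labels.append(classify_behavior(with_input, without, thresholds))
        except (IntegrationError, RuntimeError, ValueError) as exc:
            labels.append("error")
            errors.append(f"profile {i}: {exc}")
    return EnsembleReport(seed=seed, thresholds=thresholds, classifications=labels, errors=errors)
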