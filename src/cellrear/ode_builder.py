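"""Compile a wiring diagram into an elementary mass-action reaction system.

Every interaction expands into elementary reactions according to its
mechanism:

two-step activation ``A -> B`` (active A binds inactive B, then converts)::

    bind:            A_a + B_i -> A:B
    convert:         A:B       -> A_a + B_a
    unbind*:         A:B       -> A_a + B_i
    reverse-convert*: A_a + B_a -> A:B        (* only if the edge is reversible)

two-step inhibition swaps the roles of ``B_a`` and ``B_i``.  One-step
interactions are catalytic state changes (``X_a + Y_i -> X_a + Y_a`` for
activation), with a catalysed reverse step only on reversible edges.  Every
species except the clamped input and the p-MLC-like phospho-state receives a
first-order turnover reaction ``active -> inactive``.

All rate constants live on a decade grid (1e-n, integer n >= 1); reverse
steps run at exactly 10% of their paired forward step, the single point
chosen inside the "at most 10%" band.  Protein-class forward rates are never
slower than biophysical-class forward rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .wiring import (
    EdgeDef,
    SpeciesDef,
    StateAssignment,
    ValidationReport,
    Violation,
    WiringDiagram,
    validate_wiring,
)

__all__ = [
    "ElementaryReaction",
    "RateParameter",
    "CompiledModel",
    "expand_edge",
    "add_turnover",
    "compile_model",
    "check_parameter_constraints",
    "default_profile",
    "profile_to_json",
    "profile_from_json",
]

GRID_RTOL = 1e-9  # tolerance when testing membership of the 1e-n grid


def active_pool(species: str) -> str:
    return f"{species}_a"


def inactive_pool(species: str) -> str:
    return f"{species}_i"


def complex_pool(source: str, target: str) -> str:
    return f"{source}:{target}"


@dataclass(frozen=True)
class ElementaryReaction:
    """One irreversible mass-action reaction.

    Rate = k * product of reactant pool values (all stoichiometries here
    are 1 or 2, and the canonical network only ever uses 1).
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: str
    kind: str  # binding | conversion | one_step_state_change | turnover


@dataclass(frozen=True)
class RateParameter:
    name: str
    value: float
    rate_class: str  # protein | biophysical | turnover
    is_reverse: bool = False
    paired_forward: str | None = None


def _two_step_param_names(edge: EdgeDef) -> dict[str, str]:
    stem = f"{edge.source}_{edge.target}"
    return {
        "bind": f"kbind_{stem}",
        "unbind": f"kunbind_{stem}",
        "convert": f"kconv_{stem}",
        "revconv": f"krevconv_{stem}",
    }


def _one_step_param_names(edge: EdgeDef) -> dict[str, str]:
    stem = f"{edge.source}_{edge.target}"
    return {"fwd": f"kcat_{stem}", "rev": f"krev_{stem}"}


def turnover_param_name(species: str) -> str:
    return f"kturn_{species}"


def expand_edge(edge: EdgeDef, catalog: list[SpeciesDef]) -> list[ElementaryReaction]:
    """Expand one interaction edge into its elementary reactions."""
    cats = {sp.name: sp.category for sp in catalog}
    for endpoint in (edge.source, edge.target):
        if endpoint not in cats:
            raise ValueError(f"edge endpoint {endpoint!r} not in catalog")
    touches_biophysical = "biophysical" in (cats[edge.source], cats[edge.target])
    if touches_biophysical and edge.mechanism == "two_step":
        raise ValueError(
            f"{edge.source}->{edge.target}: interactions involving a biophysical "
            "entity must be one_step"
        )

    src_a = active_pool(edge.source)
    tgt_a = active_pool(edge.target)
    tgt_i = inactive_pool(edge.target)
    substrate, product = (tgt_i, tgt_a) if edge.effect == "activate" else (tgt_a, tgt_i)
    stem = f"{edge.source}_{edge.target}"
    out: list[ElementaryReaction] = []

    if edge.mechanism == "two_step":
        names = _two_step_param_names(edge)
        ab = complex_pool(edge.source, edge.target)
        out.append(
            ElementaryReaction(
                name=f"bind_{stem}",
                reactants=((src_a, 1), (substrate, 1)),
                products=((ab, 1),),
                rate_constant=names["bind"],
                kind="binding",
            )
        )
        if edge.reversible:
            out.append(
                ElementaryReaction(
                    name=f"unbind_{stem}",
                    reactants=((ab, 1),),
                    products=((src_a, 1), (substrate, 1)),
                    rate_constant=names["unbind"],
                    kind="binding",
                )
            )
        out.append(
            ElementaryReaction(
                name=f"convert_{stem}",
                reactants=((ab, 1),),
                products=((src_a, 1), (product, 1)),
                rate_constant=names["convert"],
                kind="conversion",
            )
        )
        if edge.reversible:
            out.append(
                ElementaryReaction(
                    name=f"revconvert_{stem}",
                    reactants=((src_a, 1), (product, 1)),
                    products=((ab, 1),),
                    rate_constant=names["revconv"],
                    kind="conversion",
                )
            )
    else:
        names = _one_step_param_names(edge)
        out.append(
            ElementaryReaction(
                name=f"onestep_{stem}",
                reactants=((src_a, 1), (substrate, 1)),
                products=((src_a, 1), (product, 1)),
                rate_constant=names["fwd"],
                kind="one_step_state_change",
            )
        )
        if edge.reversible:
            out.append(
                ElementaryReaction(
                    name=f"onestep_rev_{stem}",
                    reactants=((src_a, 1), (product, 1)),
                    products=((src_a, 1), (substrate, 1)),
                    rate_constant=names["rev"],
                    kind="one_step_state_change",
                )
            )
    return out


def add_turnover(catalog: list[SpeciesDef]) -> list[ElementaryReaction]:
    """First-order active -> inactive turnover for every eligible species.

    The clamped input (a boundary condition) and the turnover-exempt
    phospho-state species (p-MLC, whose inactivation is carried explicitly
    by its phosphatase) are excluded.
    """
    out = []
    for sp in catalog:
        if sp.is_clamped_input or not sp.has_turnover:
            continue
        out.append(
            ElementaryReaction(
                name=f"turnover_{sp.name}",
                reactants=((active_pool(sp.name), 1),),
                products=((inactive_pool(sp.name), 1),),
                rate_constant=turnover_param_name(sp.name),
                kind="turnover",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Default (calibrated) parameter profile
# ---------------------------------------------------------------------------

#: Class-wide fallbacks on the decade grid, used for edges of user-defined
#: diagrams that are not in the calibrated table below.
_CLASS_DEFAULTS = {
    "bind": 1e-2,
    "convert": 1e-1,
    "one_step": 1e-3,
    "turnover": 1e-2,
}

#: The shipped calibrated forward rates for the canonical network (reverse
#: steps always follow at 10%).  The profile realises the qualitative regime
#: the network is built for: quiescence without the stiffness input despite
#: the basally active Src pool (weak Src->caveolae coupling, a transient
#: Src-charged p190RhoGAP gate on RhoA, and Cofilin/MLCP as resting brakes
#: on the actin and p-MLC limbs), a high retracting steady state under
#: polarized stiffness, and self-sustained retraction after input removal
#: via the contractility -> decreased-tension -> caveolae feedback.
#: Calibration rationale and the resulting operating point are documented in
#: docs/methods.md.
_CALIBRATED_FORWARDS: dict[str, float] = {
    # caveolae module and RhoA gate
    "kbind_Src_Caveolae": 1e-6,
    "kconv_Src_Caveolae": 1e-3,
    "kbind_Caveolae_Src": 1e-1,
    "kconv_Caveolae_Src": 1e-1,
    "kbind_Src_p190RhoGAP": 1e-2,
    "kconv_Src_p190RhoGAP": 1e-3,
    "kbind_p190RhoGAP_RhoA": 1e-6,
    "kconv_p190RhoGAP_RhoA": 1e-3,
    "kbind_Caveolae_Ect2": 1e-6,
    "kconv_Caveolae_Ect2": 1e-1,
    "kbind_Ect2_RhoA": 1e-4,
    "kconv_Ect2_RhoA": 1e-1,
    # RhoA effector kinases
    "kbind_RhoA_ROCK1": 1e-4,
    "kconv_RhoA_ROCK1": 1e-1,
    "kbind_RhoA_PKN2": 1e-3,
    "kconv_RhoA_PKN2": 1e-1,
    # formin / actin limb
    "kbind_RhoA_DRF": 1e-3,
    "kconv_RhoA_DRF": 1e-1,
    "kbind_ROCK1_DRF": 1e-3,
    "kconv_ROCK1_DRF": 1e-1,
    "kbind_ROCK1_LIMK": 1e-1,
    "kconv_ROCK1_LIMK": 1e-1,
    "kbind_LIMK_Cofilin": 1e-3,
    "kconv_LIMK_Cofilin": 1e-3,
    "kbind_DRF_Actin": 1e-4,
    "kconv_DRF_Actin": 1e-1,
    "kbind_Cofilin_Actin": 1e-6,
    "kconv_Cofilin_Actin": 1e-2,
    # myosin limb
    "kbind_ROCK1_CPI17": 1e-2,
    "kconv_ROCK1_CPI17": 1e-2,
    "kbind_PKN2_CPI17": 1e-1,
    "kconv_PKN2_CPI17": 1e-2,
    "kbind_CPI17_MLCP": 1e-1,
    "kconv_CPI17_MLCP": 1e-1,
    "kcat_ROCK1_pMLC": 1e-4,
    "kcat_PKN2_pMLC": 1e-4,
    "kcat_MLCP_pMLC": 1e-2,
    # mechanical limb and feedback
    "kcat_PolarizedSubstrateStiffness_MembraneTension": 1e-5,
    "kcat_ActoMyosinContractility_MembraneTension": 1e-4,
    "kcat_MembraneTension_Caveolae": 1e-3,
    "kcat_Actin_ActinAlignment": 1e-4,
    "kcat_ActinAlignment_ActoMyosinContractility": 1e-4,
    "kcat_pMLC_ActoMyosinContractility": 1e-3,
    "kcat_ActoMyosinContractility_RearRetraction": 1e-3,
    "kcat_ActinAlignment_RearRetraction": 1e-3,
    # species-specific turnovers (all others default to 1e-2)
    "kturn_Cofilin": 1e-3,
    "kturn_MLCP": 1e-3,
    "kturn_p190RhoGAP": 1e-2,
}


def default_profile(diagram: WiringDiagram) -> dict[str, RateParameter]:
    """The shipped calibrated rate profile for a diagram.

    Two-step binding 1e-2 and conversion 1e-1, one-step (biophysical-class)
    steps 1e-3, all turnovers 1e-2, reverse steps at 10% of their forward;
    a small set of per-edge calibrated overrides (all on the grid) listed in
    ``_CALIBRATED_FORWARDS``.
    """
    params: dict[str, RateParameter] = {}

    def fwd(name: str, default: float, rate_class: str) -> float:
        value = _CALIBRATED_FORWARDS.get(name, default)
        params[name] = RateParameter(name, value, rate_class)
        return value

    def rev(name: str, forward_name: str, forward_value: float, rate_class: str) -> None:
        params[name] = RateParameter(
            name, forward_value * 0.1, rate_class, is_reverse=True, paired_forward=forward_name
        )

    for edge in diagram.edges:
        if edge.mechanism == "two_step":
            names = _two_step_param_names(edge)
            kb = fwd(names["bind"], _CLASS_DEFAULTS["bind"], edge.rate_class)
            kc = fwd(names["convert"], _CLASS_DEFAULTS["convert"], edge.rate_class)
            if edge.reversible:
                rev(names["unbind"], names["bind"], kb, edge.rate_class)
                rev(names["revconv"], names["convert"], kc, edge.rate_class)
        else:
            names = _one_step_param_names(edge)
            kf = fwd(names["fwd"], _CLASS_DEFAULTS["one_step"], edge.rate_class)
            if edge.reversible:
                rev(names["rev"], names["fwd"], kf, edge.rate_class)
    for sp in diagram.species:
        if sp.is_clamped_input or not sp.has_turnover:
            continue
        fwd(turnover_param_name(sp.name), _CLASS_DEFAULTS["turnover"], "turnover")
    return params


def _on_grid(value: float) -> bool:
    if value <= 0:
        return False
    n = round(-math.log10(value))
    if n < 1:
        return False
    return abs(value - 10.0 ** (-n)) <= GRID_RTOL * value


#: Allowed forward-rate bands per class, "overlapping but ordered": protein
#: interactions are faster as a class without every protein rate dominating
#: every biophysical one.  Reverse steps (fixed at 10% of a forward) are
#: exempt from the bands.
CLASS_BANDS: dict[str, tuple[float, float]] = {
    "protein": (1e-6, 1e-1),
    "biophysical": (1e-6, 1e-2),
    "turnover": (1e-3, 1e-2),
}


def check_parameter_constraints(profile: dict[str, RateParameter]) -> ValidationReport:
    """Validate a rate profile against the order-of-magnitude constraints.

    Checks: every value on the 1e-n decade grid (integer n >= 1); reverse
    steps at most 10% of their paired forward; every forward rate inside its
    class band (:data:`CLASS_BANDS`), which keeps protein-class rates faster
    than biophysical-class rates in the ordered-band sense.
    """
    out: list[Violation] = []
    for p in profile.values():
        if not _on_grid(p.value):
            out.append(
                Violation("grid", p.name, f"value {p.value!r} is not 1e-n with integer n >= 1")
            )
        if p.is_reverse:
            fwd = profile.get(p.paired_forward or "")
            if fwd is None:
                out.append(Violation("pairing", p.name, "paired forward parameter missing"))
            elif p.value > 0.10 * fwd.value * (1 + GRID_RTOL):
                out.append(
                    Violation(
                        "reversibility",
                        p.name,
                        f"reverse rate {p.value} exceeds 10% of forward {fwd.value}",
                    )
                )
        else:
            lo, hi = CLASS_BANDS[p.rate_class]
            if not (lo * (1 - GRID_RTOL) <= p.value <= hi * (1 + GRID_RTOL)):
                out.append(
                    Violation(
                        "class-ordering",
                        p.name,
                        f"{p.rate_class}-class forward rate {p.value} outside band "
                        f"[{lo}, {hi}]",
                    )
                )
    return ValidationReport(tuple(out))


def profile_to_json(profile: dict[str, RateParameter], path=None, *, indent: int = 2) -> str:
    doc = [asdict(profile[name]) for name in profile]
    text = json.dumps(doc, indent=indent)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def profile_from_json(source) -> dict[str, RateParameter]:
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("["):
            doc = json.loads(text)
        else:
            with open(text) as fh:
                doc = json.load(fh)
    out = {}
    for entry in doc:
        entry = dict(entry)
        entry["rate_class"] = entry.pop("rate_class")
        p = RateParameter(**entry)
        out[p.name] = p
    return out


# ---------------------------------------------------------------------------
# Compiled model
# ---------------------------------------------------------------------------


class CompiledModel:
    """An elementary reaction system with a vectorised derivative contract.

    State vectors follow ``pools`` order.  The derivative of every pool is
    the signed sum of mass-action fluxes over ``reactions``; pools of the
    clamped input species are held constant (their derivative rows are
    structurally zero).
    """

    def __init__(
        self,
        pools: tuple[str, ...],
        reactions: tuple[ElementaryReaction, ...],
        parameters: dict[str, RateParameter],
        observables: dict[str, str],
        clamped_species: tuple[str, ...] = (),
        diagram: WiringDiagram | None = None,
        initial_amounts: dict[str, float] | None = None,
    ):
        self.pools = tuple(pools)
        self.reactions = tuple(reactions)
        self.parameters = dict(parameters)
        self.observables = dict(observables)
        self.clamped_species = tuple(clamped_species)
        self.diagram = diagram
        self.initial_amounts = dict(initial_amounts) if initial_amounts else None
        self.pool_index = {p: i for i, p in enumerate(self.pools)}
        if len(self.pool_index) != len(self.pools):
            raise ValueError("duplicate pool names")
        for rx in self.reactions:
            if rx.rate_constant not in self.parameters:
                raise ValueError(f"reaction {rx.name}: missing parameter {rx.rate_constant}")
        self._build_arrays()

    def _build_arrays(self) -> None:
        npool, nrx = len(self.pools), len(self.reactions)
        N = np.zeros((npool, nrx))
        r1 = np.zeros(nrx, dtype=np.intp)
        r2 = np.full(nrx, -1, dtype=np.intp)
        for j, rx in enumerate(self.reactions):
            flat: list[int] = []
            for pool, stoich in rx.reactants:
                idx = self.pool_index[pool]
                N[idx, j] -= stoich
                flat.extend([idx] * stoich)
            for pool, stoich in rx.products:
                N[self.pool_index[pool], j] += stoich
            if not 1 <= len(flat) <= 2:
                raise ValueError(f"reaction {rx.name}: only uni/bimolecular supported")
            r1[j] = flat[0]
            if len(flat) == 2:
                r2[j] = flat[1]
        clamped_rows = [
            self.pool_index[pool]
            for sp in self.clamped_species
            for pool in (active_pool(sp), inactive_pool(sp))
            if pool in self.pool_index
        ]
        N[clamped_rows, :] = 0.0
        self._N = N
        self._r1 = r1
        self._r2 = r2
        self._bimolecular = r2 >= 0
        self.clamped_pool_indices = tuple(clamped_rows)

    # -- parameter vector ---------------------------------------------------

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.parameters)

    def rate_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        values = {name: p.value for name, p in self.parameters.items()}
        if overrides:
            for name, value in overrides.items():
                if name not in values:
                    raise KeyError(f"unknown parameter {name!r}")
                values[name] = value
        return np.array([values[rx.rate_constant] for rx in self.reactions])

    # -- derivative contract ------------------------------------------------

    def fluxes(self, y: np.ndarray, k: np.ndarray) -> np.ndarray:
        rates = k * y[self._r1]
        rates[self._bimolecular] *= y[self._r2[self._bimolecular]]
        return rates

    def derivative(self, t: float, y: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
        if k is None:
            k = self.rate_vector()
        return self._N @ self.fluxes(np.asarray(y), k)

    def jacobian(self, t: float, y: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
        if k is None:
            k = self.rate_vector()
        y = np.asarray(y)
        nrx, npool = len(self.reactions), len(self.pools)
        D = np.zeros((nrx, npool))
        j = np.arange(nrx)
        uni = ~self._bimolecular
        D[j[uni], self._r1[uni]] = k[uni]
        bi = self._bimolecular
        np.add.at(D, (j[bi], self._r1[bi]), k[bi] * y[self._r2[bi]])
        np.add.at(D, (j[bi], self._r2[bi]), k[bi] * y[self._r1[bi]])
        return self._N @ D

    # -- state helpers ------------------------------------------------------

    def initial_vector(self, state: StateAssignment) -> np.ndarray:
        y = np.zeros(len(self.pools))
        for sp, value in state.active.items():
            y[self.pool_index[active_pool(sp)]] = value
        for sp, value in state.inactive.items():
            y[self.pool_index[inactive_pool(sp)]] = value
        for pool, value in state.bound.items():
            y[self.pool_index[pool]] = value
        return y

    def species_names(self) -> tuple[str, ...]:
        return tuple(self.observables)

    def moiety_pools(self, species: str) -> list[str]:
        """All pools contributing to one species' conserved moiety."""
        out = [active_pool(species), inactive_pool(species)]
        for pool in self.pools:
            if ":" in pool and species in pool.split(":"):
                out.append(pool)
        return out


def compile_model(
    diagram: WiringDiagram, profile: dict[str, RateParameter] | None = None
) -> CompiledModel:
    """Expand a validated diagram into a :class:`CompiledModel`.

    Reactions are emitted in canonical order: per edge (diagram order) in
    bind/unbind/convert/reverse-convert order, then turnovers in roster
    order; compilation is deterministic.
    """
    report = validate_wiring(diagram)
    if not report.ok:
        first = report.violations[0]
        raise ValueError(f"invalid wiring diagram: [{first.rule}] {first.subject}: {first.message}")
    if profile is None:
        profile = default_profile(diagram)
    profile_report = check_parameter_constraints(profile)
    if not profile_report.ok:
        first = profile_report.violations[0]
        raise ValueError(
            f"invalid parameter profile: [{first.rule}] {first.subject}: {first.message}"
        )

    catalog = list(diagram.species)
    reactions: list[ElementaryReaction] = []
    pools: list[str] = []
    for sp in diagram.species:
        pools.append(active_pool(sp.name))
        pools.append(inactive_pool(sp.name))
    for edge in diagram.edges:
        reactions.extend(expand_edge(edge, catalog))
        if edge.mechanism == "two_step":
            pools.append(complex_pool(edge.source, edge.target))
    reactions.extend(add_turnover(catalog))

    observables = {sp.name: active_pool(sp.name) for sp in diagram.species}
    clamped = tuple(sp.name for sp in diagram.species if sp.is_clamped_input)
    return CompiledModel(
        pools=tuple(pools),
        reactions=tuple(reactions),
        parameters=profile,
        observables=observables,
        clamped_species=clamped,
        diagram=diagram,
    )
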