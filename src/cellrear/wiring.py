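"""Species roster and interaction topology of the rear-retraction network.

The model couples a mechanochemical positive feedback loop -- decreased rear
membrane tension promotes caveolae formation, caveolae recruit the RhoA GEF
Ect2, RhoA drives actomyosin contractility through ROCK1/PKN2, and
contractility feeds back by further decreasing rear membrane tension -- to a
single external input, polarized substrate stiffness.  The topology is held
as declarative data (:class:`WiringDiagram`) and validated structurally
before compilation into mass-action reactions.

Formulation rules enforced here:

* every variable is a conserved moiety with active, inactive and bound pools
  normalised to a 0-100 activity scale;
* protein-protein (and protein-complex) interactions are two-step (bind,
  then state change); any interaction touching a biophysical entity is a
  direct one-step state change;
* interactions mixing protein and biophysical endpoints are irreversible,
  as are the three designated edges (decreased tension -> caveolae, aligned
  actin -> contractility, p-MLC -> contractility).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Iterable

__all__ = [
    "SpeciesDef",
    "EdgeDef",
    "WiringDiagram",
    "StateAssignment",
    "Violation",
    "ValidationReport",
    "canonical_wiring",
    "validate_wiring",
    "default_initial_conditions",
    "apply_knockdown",
]

CATEGORIES = ("protein", "complex", "biophysical")
EFFECTS = ("activate", "inhibit")
MECHANISMS = ("two_step", "one_step")

#: Edges that are irreversible by fiat even though both endpoints share a
#: category class (tension->caveolae crosses classes anyway; listed for
#: completeness with the two contractility inputs).
DESIGNATED_IRREVERSIBLE = frozenset(
    {
        ("MembraneTension", "Caveolae"),
        ("ActinAlignment", "ActoMyosinContractility"),
        ("pMLC", "ActoMyosinContractility"),
    }
)


@dataclass(frozen=True)
class SpeciesDef:
    """One conserved moiety of the network.

    ``initial_active`` is the default initial condition for the active pool;
    the inactive pool starts at ``total_moiety - initial_active`` and every
    bound pool at zero.  For biophysical entities "active" means the *high*
    state of the quantity (for the tension node, high = *decreased* rear
    membrane tension).
    """

    name: str
    category: str
    total_moiety: float = 100.0
    initial_active: float = 0.0
    has_turnover: bool = True
    is_clamped_input: bool = False
    display_label: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")


@dataclass(frozen=True)
class EdgeDef:
    """A signed, mechanism-annotated interaction between two species."""

    source: str
    target: str
    effect: str
    mechanism: str
    reversible: bool
    rate_class: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.rate_class not in ("protein", "biophysical"):
            raise ValueError(f"unknown rate_class {self.rate_class!r}")


@dataclass(frozen=True)
class WiringDiagram:
    species: tuple[SpeciesDef, ...]
    edges: tuple[EdgeDef, ...]
    input_species: str

    def species_by_name(self, name: str) -> SpeciesDef:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    def to_dict(self) -> dict:
        return {
            "species": [asdict(sp) for sp in self.species],
            "edges": [asdict(e) for e in self.edges],
            "input_species": self.input_species,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "WiringDiagram":
        return cls(
            species=tuple(SpeciesDef(**sp) for sp in doc["species"]),
            edges=tuple(EdgeDef(**e) for e in doc["edges"]),
            input_species=doc["input_species"],
        )

    def to_json(self, path=None, *, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "WiringDiagram":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        return cls.from_dict(doc)


@dataclass(frozen=True)
class StateAssignment:
    """Pool values for every species: active, inactive and bound complexes.

    ``bound`` maps complex pool names (``"A:B"``) to amounts; each bound unit
    counts toward the conserved moiety of both partner species.
    """

    active: dict[str, float]
    inactive: dict[str, float]
    bound: dict[str, float] = field(default_factory=dict)

    def total(self, species: str) -> float:
        tot = self.active[species] + self.inactive[species]
        for pool, amount in self.bound.items():
            if species in pool.split(":"):
                tot += amount
        return tot

    def with_active(self, species: str, value: float) -> "StateAssignment":
        """Move amount between the active and inactive pools of one species."""
        delta = value - self.active[species]
        active = dict(self.active)
        inactive = dict(self.inactive)
        active[species] = value
        inactive[species] = inactive[species] - delta
        return StateAssignment(active, inactive, dict(self.bound))


@dataclass(frozen=True)
class Violation:
    rule: str
    subject: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "valid: no violations"
        return "\n".join(f"[{v.rule}] {v.subject}: {v.message}" for v in self.violations)


def _species_cat(diagram: WiringDiagram, name: str) -> str | None:
    try:
        return diagram.species_by_name(name).category
    except KeyError:
        return None


def validate_wiring(diagram: WiringDiagram) -> ValidationReport:
    """Check the structural invariants of a wiring diagram.

    Violations are returned as data, never raised: a report with zero
    violations certifies that compilation into elementary reactions is
    well-defined.
    """
    out: list[Violation] = []
    names = [sp.name for sp in diagram.species]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            out.append(Violation("unique-names", n, "duplicate species name"))
        seen.add(n)

    for sp in diagram.species:
        if not (0.0 <= sp.initial_active <= sp.total_moiety <= 100.0):
            out.append(
                Violation(
                    "pool-bounds",
                    sp.name,
                    f"requires 0 <= initial_active ({sp.initial_active}) <= "
                    f"total_moiety ({sp.total_moiety}) <= 100",
                )
            )

    clamped = [sp.name for sp in diagram.species if sp.is_clamped_input]
    if len(clamped) != 1:
        out.append(
            Violation(
                "single-input",
                ",".join(clamped) or "<none>",
                f"exactly one clamped input required, found {len(clamped)}",
            )
        )
    if diagram.input_species not in seen:
        out.append(Violation("unknown-input", diagram.input_species, "input_species not in roster"))
    elif clamped and clamped != [diagram.input_species]:
        out.append(
            Violation(
                "input-mismatch",
                diagram.input_species,
                f"input_species does not match the clamped species {clamped}",
            )
        )

    for edge in diagram.edges:
        label = f"{edge.source}->{edge.target}"
        cats = []
        for endpoint in (edge.source, edge.target):
            cat = _species_cat(diagram, endpoint)
            if cat is None:
                out.append(Violation("unknown-endpoint", label, f"unknown species {endpoint!r}"))
            cats.append(cat)
        if None in cats:
            continue
        src_cat, tgt_cat = cats
        touches_biophysical = "biophysical" in cats
        if touches_biophysical and edge.mechanism != "one_step":
            out.append(
                Violation(
                    "rule-v",
                    label,
                    "interactions involving a biophysical entity must be one_step",
                )
            )
        if not touches_biophysical:
            target_sp = diagram.species_by_name(edge.target)
            exempt = (not target_sp.has_turnover) and not target_sp.is_clamped_input
            if edge.mechanism != "two_step" and not exempt:
                out.append(
                    Violation(
                        "rule-iv",
                        label,
                        "protein/complex interactions must be two_step "
                        "(bind then state change) unless the target is the "
                        "turnover-exempt phospho-state species",
                    )
                )
        mixed = ("biophysical" in cats) and (src_cat != "biophysical" or tgt_cat != "biophysical")
        if mixed and edge.reversible:
            out.append(
                Violation(
                    "rule-vi",
                    label,
                    "interactions mixing protein and biophysical endpoints are irreversible",
                )
            )
        if (edge.source, edge.target) in DESIGNATED_IRREVERSIBLE and edge.reversible:
            out.append(
                Violation("rule-vi", label, "designated non-reversible interaction")
            )

    # Conserved-moiety bookkeeping expects at most one turnover-exempt
    # non-input species (the p-MLC-like phospho-state).
    exempt = [
        sp.name
        for sp in diagram.species
        if not sp.has_turnover and not sp.is_clamped_input
    ]
    if len(exempt) > 1:
        out.append(
            Violation(
                "turnover-exemption",
                ",".join(exempt),
                "at most one turnover-exempt non-input species is expected",
            )
        )
    return ValidationReport(tuple(out))


def canonical_wiring() -> WiringDiagram:
    """The 19-variable rear-retraction network.

    12 proteins, the caveolae complex as a single node, and 6 biophysical
    entities.  Polarized substrate stiffness is the clamped external input;
    the active state of the tension node represents *decreased* rear
    membrane tension.  Actin is a two-state moiety whose active pool is
    F-actin and inactive pool G-actin.
    """

    def protein(name: str, **kw) -> SpeciesDef:
        return SpeciesDef(name=name, category="protein", **kw)

    species = (
        protein("Src", initial_active=50.0, display_label="Src kinase"),
        protein("p190RhoGAP", display_label="p190RhoGAP"),
        protein("Ect2", display_label="Ect2 (RhoA GEF)"),
        protein("RhoA", display_label="RhoA GTPase"),
        protein("ROCK1", display_label="ROCK1"),
        protein("PKN2", display_label="PKN2"),
        protein("DRF", display_label="Diaphanous-related formin"),
        protein("LIMK", display_label="LIM kinase"),
        protein("Cofilin", initial_active=100.0, display_label="Cofilin"),
        protein("CPI17", display_label="CPI-17"),
        protein("MLCP", initial_active=100.0, display_label="Myosin light chain phosphatase"),
        protein("Actin", display_label="Actin (active = F-actin)"),
        SpeciesDef("Caveolae", category="complex", display_label="Caveolae (Cav-1 node)"),
        SpeciesDef(
            "PolarizedSubstrateStiffness",
            category="biophysical",
            initial_active=100.0,
            has_turnover=False,
            is_clamped_input=True,
            display_label="Polarized substrate stiffness (input)",
        ),
        SpeciesDef(
            "MembraneTension",
            category="biophysical",
            display_label="Decreased rear membrane tension",
        ),
        SpeciesDef("ActinAlignment", category="biophysical", display_label="Rear F-actin alignment"),
        SpeciesDef(
            "pMLC",
            category="biophysical",
            has_turnover=False,
            display_label="Phospho-myosin light chain",
        ),
        SpeciesDef(
            "ActoMyosinContractility",
            category="biophysical",
            display_label="Actomyosin contractility",
        ),
        SpeciesDef("RearRetraction", category="biophysical", display_label="Rear retraction"),
    )

    def pp(source, target, effect, provenance=""):
        # protein/complex two-step interaction, reversible per rule vi
        return EdgeDef(source, target, effect, "two_step", True, "protein", provenance)

    def bio(source, target, effect, reversible, provenance=""):
        return EdgeDef(source, target, effect, "one_step", reversible, "biophysical", provenance)

    edges = (
        bio("PolarizedSubstrateStiffness", "MembraneTension", "activate", True,
            "stiffness input decreases rear membrane tension via front adhesions"),
        bio("ActoMyosinContractility", "MembraneTension", "activate", True,
            "contractility feedback further decreases rear tension"),
        bio("MembraneTension", "Caveolae", "activate", False,
            "decreased tension drives caveolae assembly (designated irreversible)"),
        pp("Src", "Caveolae", "activate", "Src phosphorylates Cav1 Y14, promoting caveolae"),
        pp("Caveolae", "Src", "inhibit", "pY14-Cav1 recruits/activates Csk, an Src inhibitor"),
        pp("Src", "p190RhoGAP", "activate", "Src controls p190RhoGAP activity"),
        pp("p190RhoGAP", "RhoA", "inhibit", "GAP directly inactivates RhoA"),
        pp("Caveolae", "Ect2", "activate", "caveolae recruit Ect2 to the cell rear"),
        pp("Ect2", "RhoA", "activate", "GEF promotes GDP->GTP exchange on RhoA"),
        pp("RhoA", "ROCK1", "activate"),
        pp("RhoA", "PKN2", "activate"),
        pp("RhoA", "DRF", "activate", "formins activated directly by RhoA"),
        pp("ROCK1", "DRF", "activate", "formins activated by ROCK1"),
        pp("ROCK1", "LIMK", "activate", "ROCK phosphorylates LIMK1 T508"),
        pp("LIMK", "Cofilin", "inhibit", "LIMK phosphorylates cofilin S3"),
        pp("DRF", "Actin", "activate", "formin-driven F-actin polymerization"),
        pp("Cofilin", "Actin", "inhibit", "cofilin severs/disassembles F-actin"),
        pp("ROCK1", "CPI17", "activate", "CPI-17 T38 phosphorylation"),
        pp("PKN2", "CPI17", "activate", "CPI-17 T38 phosphorylation"),
        pp("CPI17", "MLCP", "inhibit", "phospho-CPI-17 inhibits MLCP"),
        bio("ROCK1", "pMLC", "activate", False, "direct MLC phosphorylation (one-step)"),
        bio("PKN2", "pMLC", "activate", False, "direct MLC phosphorylation (one-step)"),
        bio("MLCP", "pMLC", "inhibit", False, "MLCP dephosphorylates p-MLC"),
        bio("Actin", "ActinAlignment", "activate", False, "F-actin organises into aligned fibres"),
        bio("ActinAlignment", "ActoMyosinContractility", "activate", False,
            "designated irreversible"),
        bio("pMLC", "ActoMyosinContractility", "activate", False, "designated irreversible"),
        bio("ActoMyosinContractility", "RearRetraction", "activate", True,
            "contractility drives rear translocation"),
        bio("ActinAlignment", "RearRetraction", "activate", True,
            "retraction requires aligned actin constantly"),
    )

    return WiringDiagram(species=species, edges=edges, input_species="PolarizedSubstrateStiffness")


def default_initial_conditions(diagram: WiringDiagram) -> StateAssignment:
    """Initial state for unperturbed simulations.

    Each species starts with its declared ``initial_active`` amount (the
    clamped stiffness input at 100, Src at 50, the purely inhibitory
    Cofilin and MLCP at 100, everything else at 0), the remainder of the
    moiety inactive, and no bound complexes.
    """
    report = validate_wiring(diagram)
    if not report.ok:
        first = report.violations[0]
        raise ValueError(f"invalid wiring diagram: [{first.rule}] {first.subject}: {first.message}")
    active = {sp.name: float(sp.initial_active) for sp in diagram.species}
    inactive = {sp.name: float(sp.total_moiety - sp.initial_active) for sp in diagram.species}
    return StateAssignment(active=active, inactive=inactive, bound={})


def apply_knockdown(
    state: StateAssignment, species: str, fraction: float
) -> StateAssignment:
    """Rescale one species' moiety to ``fraction`` of its current total.

    Emulates an a-priori knockdown: both the active and inactive pools are
    scaled proportionally before simulation starts.  The species must have
    no bound complexes in ``state`` (rescaling a shared complex pool would
    be ambiguous).
    """
    if species not in state.active:
        raise KeyError(f"unknown species {species!r}")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    for pool, amount in state.bound.items():
        if species in pool.split(":") and amount != 0.0:
            raise ValueError(
                f"cannot knock down {species!r}: nonzero bound pool {pool!r}"
            )
    active = dict(state.active)
    inactive = dict(state.inactive)
    active[species] *= fraction
    inactive[species] *= fraction
    return StateAssignment(active=active, inactive=inactive, bound=dict(state.bound))
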