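"""SBML Level 3 Version 1 interchange for compiled models.

Every pool becomes one SBML species in a single unit compartment, every
elementary reaction one SBML reaction with an explicit mass-action kinetic
law (a MathML product of the rate constant and the reactant species), and
every rate constant a global parameter.  Category/class metadata that SBML
core cannot express rides in a small custom annotation namespace, so that a
document round-trips to an equivalent :class:`CompiledModel`.

Only mass-action kinetic laws are accepted on import; any other rate-law
form is rejected by name.
"""

from __future__ import annotations

import re

from lxml import etree

from .ode_builder import CompiledModel, ElementaryReaction, RateParameter, active_pool

__all__ = ["to_sbml", "from_sbml", "write_sbml", "read_sbml", "validate_document"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:cellrear:annotations"

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _sid(pool: str) -> str:
    # complex pools are named "A:B"; SBML SIds cannot contain ':'
    return pool.replace(":", "__")


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def to_sbml(model: CompiledModel) -> etree._ElementTree:
    """Serialise a compiled model as an SBML L3V1 document tree."""
    nsmap = {None: SBML_NS}
    sbml = etree.Element(_q(SBML_NS, "sbml"), nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    mdl = etree.SubElement(sbml, _q(SBML_NS, "model"))
    mdl.set("id", "cell_rear_retraction")
    mdl.set("name", "Mechanochemical model of cell rear retraction")

    comps = etree.SubElement(mdl, _q(SBML_NS, "listOfCompartments"))
    comp = etree.SubElement(comps, _q(SBML_NS, "compartment"))
    comp.set("id", "cell")
    comp.set("spatialDimensions", "3")
    comp.set("size", "1")
    comp.set("constant", "true")

    clamped_pools = {model.pools[i] for i in model.clamped_pool_indices}
    species_list = etree.SubElement(mdl, _q(SBML_NS, "listOfSpecies"))
    if model.initial_amounts is not None:
        initial = dict(model.initial_amounts)
    elif model.diagram is not None:
        from .wiring import default_initial_conditions

        state = default_initial_conditions(model.diagram)
        y0 = model.initial_vector(state)
        initial = {pool: y0[i] for i, pool in enumerate(model.pools)}
    else:
        initial = {}
    for pool in model.pools:
        sp = etree.SubElement(species_list, _q(SBML_NS, "species"))
        sp.set("id", _sid(pool))
        sp.set("name", pool)
        sp.set("compartment", "cell")
        sp.set("initialAmount", repr(float(initial.get(pool, 0.0))))
        sp.set("hasOnlySubstanceUnits", "true")
        sp.set("boundaryCondition", "true" if pool in clamped_pools else "false")
        sp.set("constant", "false")
        annot = etree.SubElement(sp, _q(SBML_NS, "annotation"))
        meta = etree.SubElement(annot, _q(ANNOT_NS, "pool"), nsmap={"cr": ANNOT_NS})
        meta.set("poolName", pool)
        meta.set("clamped", "true" if pool in clamped_pools else "false")

    params_list = etree.SubElement(mdl, _q(SBML_NS, "listOfParameters"))
    for name, p in model.parameters.items():
        el = etree.SubElement(params_list, _q(SBML_NS, "parameter"))
        el.set("id", name)
        el.set("value", repr(float(p.value)))
        el.set("constant", "true")
        annot = etree.SubElement(el, _q(SBML_NS, "annotation"))
        meta = etree.SubElement(annot, _q(ANNOT_NS, "rate"), nsmap={"cr": ANNOT_NS})
        meta.set("rateClass", p.rate_class)
        meta.set("isReverse", "true" if p.is_reverse else "false")
        if p.paired_forward:
            meta.set("pairedForward", p.paired_forward)

    rx_list = etree.SubElement(mdl, _q(SBML_NS, "listOfReactions"))
    for rx in model.reactions:
        el = etree.SubElement(rx_list, _q(SBML_NS, "reaction"))
        el.set("id", _sid(rx.name))
        el.set("reversible", "false")
        el.set("fast", "false")
        annot = etree.SubElement(el, _q(SBML_NS, "annotation"))
        meta = etree.SubElement(annot, _q(ANNOT_NS, "reaction"), nsmap={"cr": ANNOT_NS})
        meta.set("kind", rx.kind)
        reactants = etree.SubElement(el, _q(SBML_NS, "listOfReactants"))
        for pool, stoich in rx.reactants:
            ref = etree.SubElement(reactants, _q(SBML_NS, "speciesReference"))
            ref.set("species", _sid(pool))
            ref.set("stoichiometry", repr(float(stoich)))
            ref.set("constant", "true")
        products = etree.SubElement(el, _q(SBML_NS, "listOfProducts"))
        for pool, stoich in rx.products:
            ref = etree.SubElement(products, _q(SBML_NS, "speciesReference"))
            ref.set("species", _sid(pool))
            ref.set("stoichiometry", repr(float(stoich)))
            ref.set("constant", "true")
        law = etree.SubElement(el, _q(SBML_NS, "kineticLaw"))
        math = etree.SubElement(law, _q(MATHML_NS, "math"), nsmap={None: MATHML_NS})
        apply_ = etree.SubElement(math, _q(MATHML_NS, "apply"))
        etree.SubElement(apply_, _q(MATHML_NS, "times"))
        k = etree.SubElement(apply_, _q(MATHML_NS, "ci"))
        k.text = f" {rx.rate_constant} "
        for pool, stoich in rx.reactants:
            for _ in range(int(stoich)):
                ci = etree.SubElement(apply_, _q(MATHML_NS, "ci"))
                ci.text = f" {_sid(pool)} "
    return etree.ElementTree(sbml)


def write_sbml(model: CompiledModel, path) -> None:
    doc = to_sbml(model)
    doc.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def validate_document(doc: etree._ElementTree) -> list[str]:
    """Structural validation of the SBML subset this package reads/writes.

    Checks well-formed structure, SId syntax, unique ids and resolvable
    references; returns problem strings (empty means valid).
    """
    problems: list[str] = []
    root = doc.getroot()
    if root.tag != _q(SBML_NS, "sbml"):
        return [f"root element is {root.tag!r}, not SBML level 3 core"]
    if root.get("level") != "3":
        problems.append(f"unsupported SBML level {root.get('level')!r}")
    mdl = root.find(_q(SBML_NS, "model"))
    if mdl is None:
        return problems + ["missing <model>"]
    seen: set[str] = set()
    species_ids: set[str] = set()
    for sp in mdl.iterfind(f"{_q(SBML_NS, 'listOfSpecies')}/{_q(SBML_NS, 'species')}"):
        sid = sp.get("id") or ""
        if not _SID_OK.match(sid):
            problems.append(f"bad species id {sid!r}")
        if sid in seen:
            problems.append(f"duplicate id {sid!r}")
        seen.add(sid)
        species_ids.add(sid)
        if sp.get("compartment") != "cell":
            problems.append(f"species {sid!r}: unknown compartment {sp.get('compartment')!r}")
    param_ids = set()
    for el in mdl.iterfind(f"{_q(SBML_NS, 'listOfParameters')}/{_q(SBML_NS, 'parameter')}"):
        pid = el.get("id") or ""
        if not _SID_OK.match(pid):
            problems.append(f"bad parameter id {pid!r}")
        if pid in seen:
            problems.append(f"duplicate id {pid!r}")
        seen.add(pid)
        param_ids.add(pid)
        try:
            float(el.get("value", ""))
        except ValueError:
            problems.append(f"parameter {pid!r}: non-numeric value")
    for rx in mdl.iterfind(f"{_q(SBML_NS, 'listOfReactions')}/{_q(SBML_NS, 'reaction')}"):
        rid = rx.get("id") or ""
        if rid in seen:
            problems.append(f"duplicate id {rid!r}")
        seen.add(rid)
        for ref in rx.iterfind(f".//{_q(SBML_NS, 'speciesReference')}"):
            if ref.get("species") not in species_ids:
                problems.append(f"reaction {rid!r}: unknown species {ref.get('species')!r}")
        math = rx.find(f"{_q(SBML_NS, 'kineticLaw')}/{_q(MATHML_NS, 'math')}")
        if math is None:
            problems.append(f"reaction {rid!r}: missing kinetic law")
    return problems


def _parse_mass_action(rid: str, math: etree._Element, param_ids: set[str]) -> tuple[str, list[str]]:
    """Return (rate constant, reactant species ids) of a mass-action law."""
    children = [c for c in math if isinstance(c.tag, str)]
    if len(children) == 1 and children[0].tag == _q(MATHML_NS, "apply"):
        apply_ = children[0]
        ops = [c for c in apply_ if isinstance(c.tag, str)]
        if not ops or ops[0].tag != _q(MATHML_NS, "times"):
            raise ValueError(f"reaction {rid!r}: kinetic law is not a plain product (mass action)")
        cis = ops[1:]
    elif len(children) == 1 and children[0].tag == _q(MATHML_NS, "ci"):
        cis = children
    else:
        raise ValueError(f"reaction {rid!r}: unsupported kinetic-law structure")
    names = []
    for ci in cis:
        if ci.tag != _q(MATHML_NS, "ci"):
            raise ValueError(
                f"reaction {rid!r}: non-mass-action kinetic law (found {ci.tag.split('}')[-1]!r})"
            )
        names.append((ci.text or "").strip())
    if not names or names[0] not in param_ids:
        raise ValueError(f"reaction {rid!r}: first factor is not a model parameter")
    return names[0], names[1:]


def from_sbml(source) -> CompiledModel:
    """Rebuild a compiled model from an SBML document (tree, path or bytes).

    The document must use pure mass-action kinetic laws; anything else is
    rejected naming the offending reaction.  Wiring-level information
    (diagram) is not reconstructed: the returned model carries pools,
    reactions, parameters and observables only.
    """
    if isinstance(source, etree._ElementTree):
        doc = source
    elif isinstance(source, bytes):
        doc = etree.ElementTree(etree.fromstring(source))
    else:
        doc = etree.parse(str(source))
    problems = validate_document(doc)
    if problems:
        raise ValueError("invalid SBML document: " + "; ".join(problems[:3]))
    mdl = doc.getroot().find(_q(SBML_NS, "model"))

    pools: list[str] = []
    sid_to_pool: dict[str, str] = {}
    clamped_species: list[str] = []
    initial_amounts: dict[str, float] = {}
    for sp in mdl.iterfind(f"{_q(SBML_NS, 'listOfSpecies')}/{_q(SBML_NS, 'species')}"):
        sid = sp.get("id")
        meta = sp.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'pool')}")
        pool = meta.get("poolName") if meta is not None else sp.get("name") or sid
        pools.append(pool)
        sid_to_pool[sid] = pool
        initial_amounts[pool] = float(sp.get("initialAmount", "0"))
        if (sp.get("boundaryCondition") == "true") and pool.endswith("_a"):
            clamped_species.append(pool[:-2])

    parameters: dict[str, RateParameter] = {}
    for el in mdl.iterfind(f"{_q(SBML_NS, 'listOfParameters')}/{_q(SBML_NS, 'parameter')}"):
        pid = el.get("id")
        meta = el.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'rate')}")
        rate_class = meta.get("rateClass") if meta is not None else "protein"
        is_reverse = meta is not None and meta.get("isReverse") == "true"
        paired = meta.get("pairedForward") if meta is not None else None
        parameters[pid] = RateParameter(pid, float(el.get("value")), rate_class, is_reverse, paired)

    reactions: list[ElementaryReaction] = []
    for rx in mdl.iterfind(f"{_q(SBML_NS, 'listOfReactions')}/{_q(SBML_NS, 'reaction')}"):
        rid = rx.get("id")

        def refs(tag: str) -> list[tuple[str, int]]:
            out = []
            for ref in rx.iterfind(f"{_q(SBML_NS, tag)}/{_q(SBML_NS, 'speciesReference')}"):
                out.append((sid_to_pool[ref.get("species")], int(float(ref.get("stoichiometry", "1")))))
            return out

        math = rx.find(f"{_q(SBML_NS, 'kineticLaw')}/{_q(MATHML_NS, 'math')}")
        k_name, law_species = _parse_mass_action(rid, math, set(parameters))
        reactants = refs("listOfReactants")
        law_pools = sorted(sid_to_pool.get(s, s) for s in law_species)
        flat = sorted(p for p, n in reactants for _ in range(n))
        if law_pools != flat:
            raise ValueError(f"reaction {rid!r}: kinetic law disagrees with reactant list")
        meta = rx.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'reaction')}")
        kind = meta.get("kind") if meta is not None else "conversion"
        reactions.append(
            ElementaryReaction(
                name=rid,
                reactants=tuple(reactants),
                products=tuple(refs("listOfProducts")),
                rate_constant=k_name,
                kind=kind,
            )
        )

    observables = {
        pool[:-2]: pool for pool in pools if pool.endswith("_a") and ":" not in pool
    }
    return CompiledModel(
        pools=tuple(pools),
        reactions=tuple(reactions),
        parameters=parameters,
        observables=observables,
        clamped_species=tuple(clamped_species),
        diagram=None,
        initial_amounts=initial_amounts,
    )


def read_sbml(path) -> CompiledModel:
    return from_sbml(path)
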