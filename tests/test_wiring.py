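import dataclasses

import pytest
from hypothesis import given, strategies as st

from cellrear.wiring import (
    EdgeDef,
    SpeciesDef,
    WiringDiagram,
    apply_knockdown,
    canonical_wiring,
    default_initial_conditions,
    validate_wiring,
)


class TestCanonicalRoster:
    def test_species_counts(self, diagram):
        assert len(diagram.species) == 19
        assert sum(sp.category == "protein" for sp in diagram.species) == 12
        assert sum(sp.category == "complex" for sp in diagram.species) == 1

    def test_single_clamped_input(self, diagram):
        clamped = [sp.name for sp in diagram.species if sp.is_clamped_input]
        assert clamped == ["PolarizedSubstrateStiffness"]
        assert diagram.input_species == "PolarizedSubstrateStiffness"

    def test_pmlc_is_the_only_turnover_exempt_species(self, diagram):
        exempt = [
            sp.name
            for sp in diagram.species
            if not sp.has_turnover and not sp.is_clamped_input
        ]
        assert exempt == ["pMLC"]

    def test_tension_caveolae_edge_is_irreversible(self, diagram):
        edge = next(
            e for e in diagram.edges
            if e.source == "MembraneTension" and e.target == "Caveolae"
        )
        assert edge.effect == "activate"
        assert edge.mechanism == "one_step"
        assert not edge.reversible

    def test_designated_contractility_inputs_irreversible(self, diagram):
        for src in ("ActinAlignment", "pMLC"):
            edge = next(
                e for e in diagram.edges
                if e.source == src and e.target == "ActoMyosinContractility"
            )
            assert not edge.reversible

    def test_canonical_diagram_validates_clean(self, diagram):
        assert validate_wiring(diagram).ok

    def test_json_round_trip(self, diagram, tmp_path):
        path = tmp_path / "wiring.json"
        diagram.to_json(path)
        assert WiringDiagram.from_json(path) == diagram


class TestValidation:
    def test_unknown_endpoint_is_reported(self, diagram):
        bad = WiringDiagram(
            species=diagram.species,
            edges=diagram.edges
            + (EdgeDef("Src", "Nonexistent", "activate", "two_step", True, "protein"),),
            input_species=diagram.input_species,
        )
        report = validate_wiring(bad)
        assert not report.ok
        assert any(v.rule == "unknown-endpoint" for v in report.violations)

    def test_protein_pair_must_be_two_step(self, diagram):
        # a protein->protein activation marked one_step breaks the binding rule
        edges = list(diagram.edges)
        i = next(
            j for j, e in enumerate(edges) if (e.source, e.target) == ("Ect2", "RhoA")
        )
        edges[i] = dataclasses.replace(edges[i], mechanism="one_step")
        report = validate_wiring(
            WiringDiagram(diagram.species, tuple(edges), diagram.input_species)
        )
        assert any(v.rule == "rule-iv" for v in report.violations)

    def test_biophysical_edge_must_be_one_step(self, diagram):
        edges = list(diagram.edges)
        i = next(
            j for j, e in enumerate(edges)
            if (e.source, e.target) == ("ActoMyosinContractility", "RearRetraction")
        )
        edges[i] = dataclasses.replace(edges[i], mechanism="two_step")
        report = validate_wiring(
            WiringDiagram(diagram.species, tuple(edges), diagram.input_species)
        )
        assert any(v.rule == "rule-v" for v in report.violations)

    def test_mixed_category_edge_cannot_be_reversible(self, diagram):
        edges = list(diagram.edges)
        i = next(
            j for j, e in enumerate(edges) if (e.source, e.target) == ("Actin", "ActinAlignment")
        )
        edges[i] = dataclasses.replace(edges[i], reversible=True)
        report = validate_wiring(
            WiringDiagram(diagram.species, tuple(edges), diagram.input_species)
        )
        assert any(v.rule == "rule-vi" for v in report.violations)

    def test_two_clamped_inputs_rejected(self, diagram):
        species = list(diagram.species)
        i = next(j for j, sp in enumerate(species) if sp.name == "RearRetraction")
        species[i] = dataclasses.replace(species[i], is_clamped_input=True)
        report = validate_wiring(
            WiringDiagram(tuple(species), diagram.edges, diagram.input_species)
        )
        assert any(v.rule == "single-input" for v in report.violations)


class TestInitialConditions:
    def test_stated_actives(self, ics):
        assert ics.active["PolarizedSubstrateStiffness"] == 100.0
        assert ics.active["Src"] == 50.0
        assert ics.active["Cofilin"] == 100.0
        assert ics.active["MLCP"] == 100.0

    def test_everything_else_starts_inactive(self, ics):
        started = {"PolarizedSubstrateStiffness", "Src", "Cofilin", "MLCP"}
        for name, value in ics.active.items():
            if name not in started:
                assert value == 0.0

    def test_conservation_forced_inactive_pools(self, ics, diagram):
        assert ics.inactive["Src"] == 50.0
        for sp in diagram.species:
            assert ics.total(sp.name) == pytest.approx(sp.total_moiety)

    def test_invalid_diagram_rejected(self, diagram):
        bad = WiringDiagram(diagram.species, diagram.edges, input_species="Nope")
        with pytest.raises(ValueError, match="invalid wiring"):
            default_initial_conditions(bad)


class TestKnockdown:
    def test_twelve_percent_knockdown(self, ics):
        state = apply_knockdown(ics, "RhoA", 0.12)
        assert state.total("RhoA") == pytest.approx(12.0)
        assert state.total("Src") == pytest.approx(100.0)

    def test_identity_at_fraction_one(self, ics):
        assert apply_knockdown(ics, "RhoA", 1.0) == ics

    def test_full_knockdown_keeps_conservation(self, ics):
        state = apply_knockdown(ics, "Caveolae", 0.0)
        assert state.active["Caveolae"] == 0.0
        assert state.inactive["Caveolae"] == 0.0
        assert state.total("Src") == pytest.approx(100.0)

    def test_unknown_species_rejected(self, ics):
        with pytest.raises(KeyError):
            apply_knockdown(ics, "NotASpecies", 0.5)

    def test_bound_pools_block_knockdown(self, ics):
        from cellrear.wiring import StateAssignment

        state = StateAssignment(
            dict(ics.active), dict(ics.inactive), {"Ect2:RhoA": 5.0}
        )
        with pytest.raises(ValueError, match="bound pool"):
            apply_knockdown(state, "RhoA", 0.5)

    @given(
        a=st.floats(0.01, 1.0),
        b=st.floats(0.01, 1.0),
    )
    def test_knockdown_is_multiplicative(self, a, b):
        ics = default_initial_conditions(canonical_wiring())
        double = apply_knockdown(apply_knockdown(ics, "RhoA", a), "RhoA", b)
        direct = apply_knockdown(ics, "RhoA", a * b)
        assert double.active["RhoA"] == pytest.approx(direct.active["RhoA"])
        assert double.inactive["RhoA"] == pytest.approx(direct.inactive["RhoA"])
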