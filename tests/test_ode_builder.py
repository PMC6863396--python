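import numpy as np
import pytest
from hypothesis import given, strategies as st

from cellrear.ode_builder import (
    RateParameter,
    add_turnover,
    check_parameter_constraints,
    compile_model,
    default_profile,
    expand_edge,
    profile_from_json,
    profile_to_json,
)
from cellrear.wiring import EdgeDef, SpeciesDef, canonical_wiring


def _edge(diagram, source, target):
    return next(e for e in diagram.edges if (e.source, e.target) == (source, target))


class TestExpandEdge:
    def test_reversible_two_step_activation_gives_four_reactions(self, diagram):
        rxs = expand_edge(_edge(diagram, "Ect2", "RhoA"), list(diagram.species))
        assert len(rxs) == 4
        kinds = [r.kind for r in rxs]
        assert kinds.count("binding") == 2 and kinds.count("conversion") == 2
        bind = rxs[0]
        assert set(p for p, _ in bind.reactants) == {"Ect2_a", "RhoA_i"}
        assert [p for p, _ in bind.products] == ["Ect2:RhoA"]

    def test_irreversible_one_step_gives_single_reaction(self, diagram):
        rxs = expand_edge(_edge(diagram, "MembraneTension", "Caveolae"), list(diagram.species))
        assert len(rxs) == 1
        (rx,) = rxs
        # catalytic: the tension node appears on both sides
        assert ("MembraneTension_a", 1) in rx.reactants
        assert ("MembraneTension_a", 1) in rx.products
        assert ("Caveolae_i", 1) in rx.reactants
        assert ("Caveolae_a", 1) in rx.products

    def test_two_step_inhibition_consumes_active_target(self, diagram):
        rxs = expand_edge(_edge(diagram, "LIMK", "Cofilin"), list(diagram.species))
        assert len(rxs) == 4
        bind, unbind, convert, revconv = rxs
        assert ("Cofilin_a", 1) in bind.reactants
        assert ("Cofilin_i", 1) in convert.products

    def test_mechanism_category_mismatch_rejected(self, diagram):
        bad = EdgeDef("Actin", "ActinAlignment", "activate", "two_step", False, "biophysical")
        with pytest.raises(ValueError, match="one_step"):
            expand_edge(bad, list(diagram.species))


class TestTurnover:
    def test_canonical_catalog_gives_seventeen(self, diagram):
        rxs = add_turnover(list(diagram.species))
        assert len(rxs) == 17  # 19 species minus the clamped input and p-MLC
        names = {r.reactants[0][0] for r in rxs}
        assert "pMLC_a" not in names
        assert "PolarizedSubstrateStiffness_a" not in names

    def test_single_species_catalog(self):
        sp = SpeciesDef("X", category="protein")
        (rx,) = add_turnover([sp])
        assert rx.reactants == (("X_a", 1),)
        assert rx.products == (("X_i", 1),)

    def test_pmlc_alone_yields_nothing(self):
        sp = SpeciesDef("pMLC", category="biophysical", has_turnover=False)
        assert add_turnover([sp]) == []


class TestCompile:
    def test_reaction_count(self, model):
        # 17 reversible two-step edges x 4, 11 one-step edges + 4 reverses,
        # 17 turnovers: 68 + 15 + 17
        assert len(model.reactions) == 100

    def test_pool_count(self, model):
        # active+inactive per species plus one complex pool per two-step edge
        assert len(model.pools) == 2 * 19 + 17

    def test_every_rate_on_decade_grid(self, model):
        for p in model.parameters.values():
            n = round(-np.log10(p.value))
            assert n >= 1
            assert p.value == pytest.approx(10.0 ** (-n), rel=1e-12)

    def test_compilation_is_deterministic(self, diagram, model):
        again = compile_model(diagram)
        assert [r.name for r in again.reactions] == [r.name for r in model.reactions]
        assert again.pools == model.pools

    def test_zero_flux_at_default_ics_for_retraction(self, model, ics):
        y = model.initial_vector(ics)
        dy = model.derivative(0.0, y)
        assert dy[model.pool_index["RearRetraction_a"]] == 0.0

    def test_clamped_input_derivative_is_zero_everywhere(self, model):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.uniform(0.0, 100.0, len(model.pools))
            dy = model.derivative(0.0, y)
            assert dy[model.pool_index["PolarizedSubstrateStiffness_a"]] == 0.0
            assert dy[model.pool_index["PolarizedSubstrateStiffness_i"]] == 0.0


class TestDerivativeOracle:
    def _brute_force(self, model, y):
        """Loop over reactions accumulating mass-action fluxes."""
        k = {name: p.value for name, p in model.parameters.items()}
        dy = {pool: 0.0 for pool in model.pools}
        clamped = {model.pools[i] for i in model.clamped_pool_indices}
        for rx in model.reactions:
            rate = k[rx.rate_constant]
            for pool, stoich in rx.reactants:
                rate *= y[model.pool_index[pool]] ** stoich
            for pool, stoich in rx.reactants:
                dy[pool] -= stoich * rate
            for pool, stoich in rx.products:
                dy[pool] += stoich * rate
        for pool in clamped:
            dy[pool] = 0.0
        return np.array([dy[p] for p in model.pools])

    def test_vectorised_derivative_matches_brute_force(self, model):
        rng = np.random.default_rng(11)
        for _ in range(10):
            y = rng.uniform(0.0, 100.0, len(model.pools))
            np.testing.assert_allclose(
                model.derivative(0.0, y), self._brute_force(model, y), rtol=1e-12, atol=1e-12
            )

    def test_jacobian_matches_finite_differences(self, model):
        rng = np.random.default_rng(13)
        y = rng.uniform(1.0, 50.0, len(model.pools))
        k = model.rate_vector()
        J = model.jacobian(0.0, y, k)
        eps = 1e-6
        for j in rng.choice(len(model.pools), size=8, replace=False):
            yp = y.copy(); yp[j] += eps
            ym = y.copy(); ym[j] -= eps
            col = (model.derivative(0.0, yp, k) - model.derivative(0.0, ym, k)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], col, rtol=1e-5, atol=1e-7)

    def test_moiety_conservation_is_structural(self, model, diagram):
        # every reaction's net stoichiometry over a species' pools is zero
        for sp in diagram.species:
            pools = set(model.moiety_pools(sp.name))
            for rx in model.reactions:
                net = 0
                for pool, stoich in rx.reactants:
                    if pool in pools:
                        net -= stoich
                for pool, stoich in rx.products:
                    if pool in pools:
                        net += stoich
                assert net == 0, f"{rx.name} violates {sp.name} conservation"


class TestParameterConstraints:
    def test_shipped_defaults_pass(self, diagram):
        assert check_parameter_constraints(default_profile(diagram)).ok

    def test_off_grid_value_flagged(self, diagram):
        prof = default_profile(diagram)
        prof["kturn_Src"] = RateParameter("kturn_Src", 0.05, "turnover")
        report = check_parameter_constraints(prof)
        assert any(v.rule == "grid" for v in report.violations)

    def test_reverse_rate_above_ten_percent_flagged(self, diagram):
        prof = default_profile(diagram)
        fwd = prof["kbind_Ect2_RhoA"]
        prof["kunbind_Ect2_RhoA"] = RateParameter(
            "kunbind_Ect2_RhoA", 0.2 * fwd.value, "protein", True, "kbind_Ect2_RhoA"
        )
        report = check_parameter_constraints(prof)
        assert any(v.rule == "reversibility" for v in report.violations)

    def test_turnover_outside_band_flagged(self, diagram):
        prof = default_profile(diagram)
        prof["kturn_Src"] = RateParameter("kturn_Src", 1e-4, "turnover")
        report = check_parameter_constraints(prof)
        assert any(v.rule == "class-ordering" for v in report.violations)

    def test_profile_json_round_trip(self, diagram, tmp_path):
        prof = default_profile(diagram)
        path = tmp_path / "profile.json"
        profile_to_json(prof, path)
        back = profile_from_json(path)
        assert back == prof
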