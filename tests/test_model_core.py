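"""Model representation, RHS assembly, parameter handling and SBML import."""

import logging

import numpy as np
import pytest
import sympy as sp

import glosens as g
from glosens import fixtures as fx
from glosens.errors import (
    CompletenessError,
    ModelFormatError,
    ModelInvariantError,
    SymbolResolutionError,
    UnsupportedFeatureError,
)
from glosens.model import Compartment, KineticModel, Parameter, Reaction, Species


def _bad_model(**kw):
    base = dict(
        species=[Species("A", 1.0)],
        compartments=[Compartment("default", 1.0)],
        reactions=[Reaction("r", {"A": -1.0}, sp.Symbol("k") * sp.Symbol("A"))],
        parameters=[Parameter("k", 1.0)],
    )
    base.update(kw)
    return KineticModel(**base)


class TestInvariants:
    def test_duplicate_species_rejected(self):
        m = _bad_model(species=[Species("A", 1.0), Species("A", 2.0)])
        with pytest.raises(ModelInvariantError, match="unique"):
            m.validate()

    def test_unknown_symbol_rejected_at_build_time(self):
        m = _bad_model(
            reactions=[Reaction("r", {"A": -1.0}, sp.Symbol("mystery") * sp.Symbol("A"))]
        )
        with pytest.raises(SymbolResolutionError, match="mystery"):
            g.build_rhs(m)

    def test_empty_stoichiometry_rejected(self):
        m = _bad_model(reactions=[Reaction("r", {}, sp.Symbol("k"))])
        with pytest.raises(ModelInvariantError, match="stoichiometry"):
            m.validate()

    def test_model_needs_reactions_or_rules(self):
        m = _bad_model(reactions=[])
        with pytest.raises(ModelInvariantError):
            m.validate()

    @pytest.mark.parametrize("fixture", sorted(fx.FIXTURES))
    def test_rhs_finite_at_reference(self, fixture):
        model, _ = fx.FIXTURES[fixture]()
        f = g.build_rhs(model)
        dy = f(model.reference_state(), model.reference_parameters())
        assert np.all(np.isfinite(dy))


class TestBuildRhs:
    def test_chain_rhs_at_zero(self, chain):
        model, _ = chain
        f = g.build_rhs(model)
        dy = f([1.0, 0.0], model.reference_parameters())
        assert dy[model.species_index("S1")] == pytest.approx(2.0)

    def test_chain_rhs_at_steady_state(self, chain):
        model, _ = chain
        f = g.build_rhs(model)
        dy = f([1.0, 0.5], model.reference_parameters())
        assert dy == pytest.approx([0.0, 0.0])

    def test_boundary_species_frozen(self, chain):
        model, _ = chain
        f = g.build_rhs(model)
        dy = f([1.0, 0.1], model.reference_parameters())
        assert dy[model.species_index("X0")] == 0.0


class TestApplyParameters:
    def test_reference_view_matches_model(self, chain):
        model, _ = chain
        view = g.apply_parameters(model, model.reference_parameters())
        state = np.array([1.0, 0.3])
        assert view.rates(state) == pytest.approx([2.0, 1.2])

    def test_doubling_k_doubles_rate(self, chain):
        model, _ = chain
        params = model.reference_parameters()
        doubled = g.ParameterSet(params)
        doubled["k1"] *= 2
        state = np.array([1.0, 0.3])
        base = g.apply_parameters(model, params).rates(state)
        new = g.apply_parameters(model, doubled).rates(state)
        assert new[0] == pytest.approx(2 * base[0])
        assert new[1] == pytest.approx(base[1])

    def test_partial_parameter_set_rejected(self, chain):
        model, _ = chain
        with pytest.raises(CompletenessError) as err:
            g.apply_parameters(model, {"k1": 2.0})
        assert "k2" in err.value.missing


class TestParameterDomain:
    def test_zero_band_collapses_to_reference(self, chain):
        model, _ = chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.0)
        assert dom.sample_at(0, 0) == model.reference_parameters()
        assert dom.sample_at(0, 99) == model.reference_parameters()

    def test_negative_reference_interval_ordered(self):
        dom = g.ParameterDomain(g.ParameterSet({"a": -2.0}), 0.5)
        lo, hi = dom.bounds()
        assert lo[0] == pytest.approx(-3.0) and hi[0] == pytest.approx(-1.0)
        assert dom.contains(dom.sample_at(0, 5))

    def test_negative_band_rejected(self):
        with pytest.raises(ModelInvariantError):
            g.ParameterDomain(g.ParameterSet({"a": 1.0}), -0.1)


@pytest.mark.parametrize("fixture", sorted(fx.FIXTURES))
def test_parameter_round_trip_preserves_rhs(fixture):
    """Extract parameters from a model, re-apply unchanged, get identical
    RHS evaluations at random states."""
    model, _ = fx.FIXTURES[fixture]()
    f = g.build_rhs(model)
    extracted = g.ParameterSet(model.reference_parameters())
    rng = np.random.default_rng(42)
    scale = np.abs(model.reference_state()) + 1.0
    for _ in range(10):
        state = rng.random(len(model.species)) * scale
        a = f(state, model.reference_parameters())
        b = f(state, extracted)
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)


@pytest.mark.parametrize("fixture", sorted(fx.FIXTURES))
def test_json_round_trip_preserves_rhs(fixture):
    model, _ = fx.FIXTURES[fixture]()
    clone = KineticModel.from_json(model.to_json())
    assert clone.parameter_ids == model.parameter_ids
    f, f2 = g.build_rhs(model), g.build_rhs(clone)
    rng = np.random.default_rng(7)
    for _ in range(5):
        state = rng.random(len(model.species)) + 0.1
        np.testing.assert_allclose(
            f(state, model.reference_parameters()),
            f2(state, clone.reference_parameters()),
            rtol=0,
            atol=1e-12,
        )


class TestSbmlImport:
    def test_loads_species_parameters_reactions(self, sbml_chain_path):
        m = g.load_sbml(sbml_chain_path)
        assert [s.id for s in m.species] == ["X0", "S1"]
        assert m.species[0].boundary and not m.species[1].boundary
        # local parameter flattened under "<reaction name>.<id>", global kept
        assert m.parameter_ids == ["k1", "second step.k1"]
        assert m.reference_parameters() == {"k1": 2.0, "second step.k1": 4.0}

    def test_function_definition_and_assignment_rule_inlined(self, sbml_chain_path):
        m = g.load_sbml(sbml_chain_path)
        view = g.apply_parameters(m, m.reference_parameters())
        # massaction(k1, X0) = k1*X0 = 2;  ratefactor(=1) * local k1 * S1
        assert view.rates(np.array([1.0, 0.5])) == pytest.approx([2.0, 2.0])

    def test_local_parameter_shadows_global(self, sbml_chain_path):
        m = g.load_sbml(sbml_chain_path)
        r2 = next(r for r in m.reactions if r.id == "R2")
        assert sp.Symbol("second step.k1") in r2.rate_law.free_symbols

    def test_steady_state_of_loaded_model(self, sbml_chain_path):
        m = g.load_sbml(sbml_chain_path)
        ss = g.find_steady_state(m, m.reference_parameters())
        assert ss.concentrations[m.species_index("S1")] == pytest.approx(0.5)
        assert ss.fluxes == pytest.approx([2.0, 2.0])

    def test_events_ignored_with_warning(self, sbml_chain_path, caplog):
        with caplog.at_level(logging.WARNING, logger="glosens.sbml"):
            g.load_sbml(sbml_chain_path)
        assert any("event" in rec.message for rec in caplog.records)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("")
        with pytest.raises(ModelFormatError):
            g.load_sbml(str(path))

    def test_garbage_file_is_format_error(self, tmp_path):
        path = tmp_path / "garbage.xml"
        path.write_text("<not-sbml/>")
        with pytest.raises(ModelFormatError):
            g.load_sbml(str(path))

    def test_algebraic_rule_unsupported(self, tmp_path, sbml_chain_path):
        text = open(sbml_chain_path).read().replace(
            '<assignmentRule variable="ratefactor">',
            "<algebraicRule>",
        ).replace("</assignmentRule>", "</algebraicRule>")
        path = tmp_path / "algebraic.xml"
        path.write_text(text)
        with pytest.raises(UnsupportedFeatureError, match="algebraic"):
            g.load_sbml(str(path))

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            g.load_sbml("/no/such/model.xml")
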