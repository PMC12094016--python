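"""Model I/O, validation, knockouts and flux-vector checks."""

import pytest
from cobra import Metabolite, Model, Reaction

from pyroflux.analysis import maximize
from pyroflux.model import (
    ModelFormatError,
    ModelValidationError,
    carbon_atoms,
    check_flux_vector,
    knock_out,
    load_model,
    validate_model,
    write_model,
)

MINIMAL_YAML = """\
name: minimal
objective: CONV
metabolites:
  - {id: a_c, compartment: c, formula: C2}
  - {id: b_c, compartment: c, formula: C2}
reactions:
  - id: EX_a_c
    stoichiometry: {a_c: -1}
    lower_bound: -10
    upper_bound: 0
  - id: CONV
    stoichiometry: {a_c: -1, b_c: 1}
"""


def _model_from_yaml(tmp_path, text, name="m.yaml"):
    path = tmp_path / name
    path.write_text(text)
    return load_model(path)


class TestLoadModel:
    def test_minimal_yaml_model(self, tmp_path):
        model = _model_from_yaml(tmp_path, MINIMAL_YAML)
        assert len(model.reactions) == 2
        assert [r.id for r in model.boundary] == ["EX_a_c"]
        # omitted bounds on an irreversible reaction default to (0, 1000)
        assert model.reactions.CONV.bounds == (0.0, 1000.0)

    def test_reversible_flag_defaults_bounds(self, tmp_path):
        text = MINIMAL_YAML.replace(
            "stoichiometry: {a_c: -1, b_c: 1}",
            "stoichiometry: {a_c: -1, b_c: 1}\n    reversible: true")
        model = _model_from_yaml(tmp_path, text)
        assert model.reactions.CONV.bounds == (-1000.0, 1000.0)

    def test_dangling_metabolite_reference_is_named(self, tmp_path):
        text = MINIMAL_YAML.replace("{a_c: -1, b_c: 1}", "{a_c: -1, ghost_c: 1}")
        with pytest.raises(ModelValidationError, match="ghost_c"):
            _model_from_yaml(tmp_path, text)

    def test_parse_failure_raises_format_error(self, tmp_path):
        with pytest.raises(ModelFormatError):
            _model_from_yaml(tmp_path, "reactions: [:::")

    def test_unknown_suffix_needs_dialect(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(MINIMAL_YAML)
        with pytest.raises(ModelFormatError):
            load_model(path)
        assert load_model(path, dialect="yaml").id == "minimal"


class TestRoundTrip:
    @pytest.mark.parametrize("dialect,suffix", [("yaml", ".yaml"), ("sbml", ".xml")])
    def test_core_round_trip_preserves_structure(self, core, tmp_path, dialect, suffix):
        path = tmp_path / f"core{suffix}"
        write_model(core, path, dialect)
        back = load_model(path, dialect)
        assert {r.id for r in back.reactions} == {r.id for r in core.reactions}
        for rxn in core.reactions:
            other = back.reactions.get_by_id(rxn.id)
            assert other.bounds == rxn.bounds
            assert {m.id: c for m, c in other.metabolites.items()} == \
                   {m.id: c for m, c in rxn.metabolites.items()}
        for met in core.metabolites:
            assert carbon_atoms(back.metabolites.get_by_id(met.id)) == \
                   carbon_atoms(met)


class TestValidateModel:
    def test_generated_core_is_clean(self, core):
        assert validate_model(core).is_clean

    def test_forced_carbon_imbalance_is_found(self, core):
        model = core.copy()
        bad = Reaction("BAD_DECARB", lower_bound=0, upper_bound=10)
        model.add_reactions([bad])
        bad.add_metabolites({model.metabolites.accoa_c: -1,
                             model.metabolites.co2_c: 1})  # 23 C -> 1 C
        report = validate_model(model)
        findings = report.by_kind("carbon_imbalance")
        assert [f.subject for f in findings] == ["BAD_DECARB"]

    def test_bound_violation_and_orphan_are_reported(self, core):
        model = core.copy()
        rxn = model.reactions.get_by_id("ALS")
        rxn._lower_bound, rxn._upper_bound = 5.0, 1.0  # bypass cobra's guard
        model.add_metabolites([Metabolite("lonely_c", compartment="c")])
        report = validate_model(model)
        assert {f.subject for f in report.by_kind("bound_violation")} == {"ALS"}
        assert {f.subject for f in report.by_kind("orphan_metabolite")} == {"lonely_c"}


class TestKnockOut:
    def test_knockout_never_increases_optimum(self, core):
        before, _ = maximize(core, "EX_etoh_c")
        after, _ = maximize(knock_out(core, "AdhF"), "EX_etoh_c")
        assert after <= before + 1e-9
        assert after == pytest.approx(0.0, abs=1e-9)  # sole ethanol route

    def test_knockout_of_closed_reaction_is_idempotent(self, core):
        ko = knock_out(core, "SHII")  # ships at (0, 0)
        assert maximize(ko, "EX_ac_c")[0] == pytest.approx(
            maximize(core, "EX_ac_c")[0])

    def test_acetate_route_knockout_zeroes_acetate(self, core):
        ko = knock_out(core, "ACS_acetate")
        assert maximize(ko, "EX_ac_c")[0] == pytest.approx(0.0, abs=1e-9)

    def test_original_model_is_untouched(self, core):
        bounds = core.reactions.AdhF.bounds
        knock_out(core, "AdhF")
        assert core.reactions.AdhF.bounds == bounds

    def test_unknown_reaction_id(self, core):
        with pytest.raises(KeyError, match="NOPE"):
            knock_out(core, "NOPE")


class TestFluxVectorChecks:
    def test_optimal_vertex_is_steady_and_bounded(self, prop):
        _, fluxes = maximize(prop, "EX_ppoh_e")
        ok, residual, violation = check_flux_vector(prop, fluxes.to_dict())
        assert ok
        assert residual <= 1e-6 and violation <= 1e-6

    def test_bound_breaking_vector_is_rejected(self, core):
        fluxes = {r.id: 0.0 for r in core.reactions}
        fluxes["EX_cellb_e"] = 5.0  # above its upper bound of 0
        ok, _, violation = check_flux_vector(core, fluxes)
        assert not ok and violation == pytest.approx(5.0)
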