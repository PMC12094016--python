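"""FBA/FVA correctness against independent oracles; sweeps and perturbations."""

import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction

from _oracles import linprog_max, vertex_enum_max
from pyroflux.analysis import (
    InfeasibleModelError,
    UnboundedModelError,
    flux_variability,
    maximize,
    perturbation_sweep,
    yield_sweep,
)
from pyroflux.pathway import add_free_energy_reaction
from pyroflux.synth import CoreModelParams, build_core_model, build_prop_model


def _chain_model(lb=-10.0, ub=10.0):
    model = Model("chain")
    a = Metabolite("a_c", compartment="c")
    model.add_metabolites([a])
    ex_in = Reaction("EX_in", lower_bound=lb, upper_bound=0.0)
    ex_out = Reaction("EX_out", lower_bound=0.0, upper_bound=ub)
    model.add_reactions([ex_in, ex_out])
    ex_in.add_metabolites({a: -1})  # negative flux = uptake
    ex_out.add_metabolites({a: -1})
    model.objective = "EX_out"
    return model


class TestMaximize:
    def test_hand_derivable_acetate_yield(self):
        """One cellobiose -> 2 glucose -> 4 pyruvate -> 4 acetate."""
        model = build_core_model(
            CoreModelParams(cellobiose_bound=1.0), verify=False)
        optimum, _ = maximize(model, "EX_ac_c")
        assert optimum == pytest.approx(4.0, rel=1e-9)
        assert vertex_enum_max(model, "EX_ac_c") == pytest.approx(4.0, rel=1e-7)

    def test_agrees_with_independent_solver_on_core(self, prop):
        optimum, _ = maximize(prop, "EX_ppoh_e")
        assert optimum == pytest.approx(
            linprog_max(prop, "EX_ppoh_e"), rel=1e-8)

    def test_closed_objective_gives_zero(self, core):
        with core as m:
            m.reactions.EX_ac_c.upper_bound = 0.0
            assert maximize(m, "EX_ac_c")[0] == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_model_reports(self, core):
        with core as m:
            m.reactions.EX_ac_c.lower_bound = 5.0
            m.reactions.EX_cellb_e.lower_bound = 0.0  # no substrate
            with pytest.raises(InfeasibleModelError):
                maximize(m, "EX_ac_c")

    def test_unbounded_model_reports(self):
        model = _chain_model(lb=-np.inf, ub=np.inf)
        with pytest.raises(UnboundedModelError):
            maximize(model, "EX_out")


class TestFluxVariability:
    def test_uncoupled_exchange_spans_its_bounds(self):
        assert flux_variability(_chain_model(), "EX_out") == \
               pytest.approx((0.0, 10.0))

    def test_optimal_vertex_inside_all_ranges(self, core):
        _, fluxes = maximize(core, "EX_ac_c")
        df = flux_variability(core, [r.id for r in core.reactions])
        for rid in df.index:
            assert df.loc[rid, "minimum"] - 1e-6 <= fluxes[rid] <= \
                   df.loc[rid, "maximum"] + 1e-6

    def test_pathway_entry_collapses_at_target_maximum(self, scan_model):
        top, _ = maximize(scan_model, "EX_ppoh_e")
        lo, hi = flux_variability(scan_model, "E1",
                                  fixed={"EX_ppoh_e": top})
        assert hi - lo == pytest.approx(0.0, abs=1e-6)
        assert lo > 0

    def test_infeasible_fixing_reports(self, core):
        with pytest.raises(InfeasibleModelError):
            flux_variability(core, "EX_ac_c", fixed={"EX_cellb_e": 1.0})


@pytest.fixture(scope="module")
def sweep(scan_model):
    return yield_sweep(scan_model, "EX_ppoh_e",
                       ["E1", "GAPOR", "ACS_acetate", "MBH"], n_steps=6)


class TestYieldSweep:
    def test_degenerate_sweep_matches_direct_fva(self, scan_model):
        result = yield_sweep(scan_model, "EX_ppoh_e", ["E1"], n_steps=2)
        top = result.steps[-1]
        lo0, hi0 = flux_variability(scan_model, "E1", fixed={"EX_ppoh_e": 0.0})
        lo1, hi1 = flux_variability(scan_model, "E1", fixed={"EX_ppoh_e": top})
        assert result.minimum["E1"].iloc[0] == pytest.approx(lo0, abs=1e-6)
        assert result.maximum["E1"].iloc[0] == pytest.approx(hi0, abs=1e-6)
        assert result.minimum["E1"].iloc[1] == pytest.approx(lo1, abs=1e-6)
        assert result.maximum["E1"].iloc[1] == pytest.approx(hi1, abs=1e-6)

    def test_steps_strictly_increasing_to_model_maximum(self, sweep, scan_model):
        top, _ = maximize(scan_model, "EX_ppoh_e")
        assert np.all(np.diff(sweep.steps) > 0)
        assert sweep.steps[-1] == pytest.approx(top)

    def test_pathway_minimum_flux_is_monotone_in_target(self, sweep):
        mins = sweep.minimum["E1"].to_numpy()
        assert np.all(np.diff(mins) >= -1e-6)

    def test_scaled_ranges_within_unit_interval(self, sweep):
        for frame in (sweep.scaled_minimum, sweep.scaled_maximum):
            assert (frame.to_numpy() >= -1 - 1e-9).all()
            assert (frame.to_numpy() <= 1 + 1e-9).all()

    def test_too_few_steps_rejected(self, scan_model):
        with pytest.raises(ValueError, match="n_steps"):
            yield_sweep(scan_model, "EX_ppoh_e", ["E1"], n_steps=1)


class TestPerturbationSweep:
    def test_zero_grid_equals_baseline(self, scan_model):
        model = add_free_energy_reaction(scan_model, "ATP")
        baseline, _ = maximize(scan_model, "EX_ppoh_e")
        curve = perturbation_sweep(model, "ATP", [0.0])
        assert curve.optimum[0] == pytest.approx(baseline, rel=1e-9)

    def test_atp_curve_rises_then_flattens_on_atp_limited_core(self):
        prop = build_prop_model(
            CoreModelParams(regime="ATP-limited", cellobiose_bound=2.0),
            verify=False)
        model = add_free_energy_reaction(prop, "ATP")
        grid = np.linspace(0.0, 40.0, 9)
        curve = perturbation_sweep(model, "ATP", grid)
        gains = np.diff(curve.optimum)
        assert gains[0] > 1e-6  # strictly increasing at the origin
        assert np.all(gains >= -1e-9)  # never decreasing (relaxation)
        assert gains[-1] == pytest.approx(0.0, abs=1e-6)  # another limit binds

    def test_nadph_curve_flat_on_atp_limited_core(self):
        prop = build_prop_model(CoreModelParams(regime="ATP-limited"),
                                verify=False)
        model = add_free_energy_reaction(prop, "NADPH")
        curve = perturbation_sweep(model, "NADPH", np.linspace(0, 20, 5))
        assert curve.is_flat

    def test_nadph_curve_rises_on_redox_limited_core(self):
        prop = build_prop_model(CoreModelParams(regime="redox-limited"),
                                verify=False)
        model = add_free_energy_reaction(prop, "NADPH")
        curve = perturbation_sweep(model, "NADPH", [0.0, 2.0])
        assert curve.gain_at_origin() > 1e-6

    def test_grid_beyond_cap_rejected(self, scan_model):
        model = add_free_energy_reaction(scan_model, "ATP", cap=1.0)
        with pytest.raises(ValueError, match="cap"):
            perturbation_sweep(model, "ATP", [0.0, 2.0])
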