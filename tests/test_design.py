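"""Design analytics: classification, recommendation, yields, sweep."""

import pytest

import glutaflux as gf
from glutaflux.design import classify_reactions
from glutaflux.solvers import FvaResult


class TestClassificationRule:
    @pytest.mark.parametrize("interval,expected", [
        ((0.0, 0.0), "blocked"),
        ((1e-9, 1e-8), "blocked"),
        ((-2.0, 3.0), "substitutable"),
        ((0.0, 4.0), "substitutable"),
        ((-4.0, 0.0), "substitutable"),
        ((1.5, 1.5), "essential"),
        ((1.0, 5.0), "essential"),
        ((-5.0, -1.0), "essential"),
    ])
    def test_interval_taxonomy(self, interval, expected):
        result = FvaResult(1.0, {"R": interval})
        rec = classify_reactions(result, epsilon=1e-6)[0]
        assert rec.essentiality == expected

    def test_partition_covers_every_reaction(self, core_model, leucine_essentiality):
        assert len(leucine_essentiality) == len(core_model.reactions)
        assert {r.reaction_id for r in leucine_essentiality} == set(core_model.reaction_ids)
        assert all(r.essentiality in ("essential", "substitutable", "blocked")
                   for r in leucine_essentiality)

    def test_fermentative_drains_substitutable_under_leucine_production(
        self, leucine_essentiality
    ):
        by = {r.reaction_id: r.essentiality for r in leucine_essentiality}
        assert by["LDH"] == "substitutable"
        assert by["ALATA"] == "substitutable"

    def test_tca_entry_reactions_essential(self, leucine_essentiality):
        by = {r.reaction_id: r.essentiality for r in leucine_essentiality}
        for rid in ("PDH", "CS", "ACONT", "ICDHx"):
            assert by[rid] == "essential"

    def test_closed_glyoxylate_shunt_blocked(self, leucine_essentiality):
        by = {r.reaction_id: r.essentiality for r in leucine_essentiality}
        assert by["ICL"] == "blocked"
        assert by["MALS"] == "blocked"

    def test_knocking_out_blocked_reaction_leaves_optimum_unchanged(
        self, core_model, sim_config, leucine_essentiality
    ):
        blocked = [r.reaction_id for r in leucine_essentiality
                   if r.essentiality == "blocked"]
        assert blocked
        before = gf.fba(core_model, sim_config).objective_value
        after = gf.fba(gf.knock_out(core_model, blocked), sim_config).objective_value
        assert after == pytest.approx(before, abs=1e-6)


class TestRecommendation:
    def test_paper_design_directions(self, growth_state, production_state,
                                     leucine_essentiality, sim_config):
        recs = gf.recommend_regulation(growth_state, production_state,
                                       leucine_essentiality,
                                       sim_config.classification_tolerance)
        by = {r.reaction_id: r.mode for r in recs}
        # TCA entry must be attenuated, not deleted, in the producer
        for rid in ("PDH", "CS", "ACONT", "ICDHx"):
            assert by[rid] == "D"
        # substitutable lactate drain carrying no production flux: delete
        assert by["LDH"] == "KO"
        # pathway reactions toward the product: upregulate
        for rid in ("ACLS", "IPPS", "LEUt", "EX_leu__L_e"):
            assert by[rid] == "U"

    def test_identical_states_give_none_or_ko(self, growth_state,
                                              leucine_essentiality, sim_config):
        recs = gf.recommend_regulation(growth_state, growth_state,
                                       leucine_essentiality,
                                       sim_config.classification_tolerance)
        assert all(r.mode in ("none", "KO") for r in recs)
        by = {r.reaction_id: r for r in recs}
        # equal nonzero flux in both states is "none" by definition
        assert by["BIOMASS"].mode == "none"

    def test_mismatched_reaction_sets_rejected(self, growth_state,
                                               leucine_essentiality):
        partial = gf.FluxDistribution({"PDH": 1.0}, 1.0, "optimal")
        with pytest.raises(ValueError, match="different reactions"):
            gf.recommend_regulation(growth_state, partial, leucine_essentiality)


class TestYields:
    @pytest.mark.parametrize("product,expected", [
        ("EX_ala__L_e", 2.0),
        ("EX_val__L_e", 1.0),
        ("EX_leu__L_e", 2.0 / 3.0),
    ])
    def test_theoretical_ceilings(self, core_model, sim_config, product, expected):
        report = gf.max_theoretical_yield(core_model, sim_config, product)
        assert report.status == "optimal"
        assert report.yield_mol_per_mol == pytest.approx(expected, abs=1e-9)

    def test_yield_respects_carbon_conservation(self, core_model, sim_config):
        carbon = {m.id: (m.formula or {}).get("C", 0) for m in core_model.metabolites}
        for exchange, met in [("EX_ala__L_e", "ala__L_e"),
                              ("EX_val__L_e", "val__L_e"),
                              ("EX_leu__L_e", "leu__L_e")]:
            y = gf.max_theoretical_yield(core_model, sim_config, exchange)
            assert y.yield_mol_per_mol * carbon[met] <= 6.0 + 1e-6

    def test_glyoxylate_consumes_two_acetyl_coa_per_malate(self):
        model = gf.apply_genotype(gf.build_core_model(), "acetate_media")
        model.set_bounds("DM_mal__L", 0.0, 1000.0)
        cfg = gf.SimulationConfig(substrate_exchange_id="EX_ac_e",
                                  substrate_uptake_max=1.0)
        report = gf.max_theoretical_yield(model, cfg, "DM_mal__L")
        assert report.yield_mol_per_mol == pytest.approx(0.5, abs=1e-9)


class TestProduction:
    def test_biomass_floor_respected(self, core_model, sim_config,
                                     growth_state, production_state):
        floor = sim_config.biomass_fraction * growth_state.objective_value
        assert production_state.fluxes["BIOMASS"] >= floor - 1e-6

    def test_ppc_knockout_changes_nothing(self, core_model, sim_config,
                                          growth_state, production_state):
        ko = gf.knock_out(core_model, ["PPC"])
        assert gf.fba(ko, sim_config).objective_value == pytest.approx(
            growth_state.objective_value, abs=1e-6)
        ko_prod = gf.simulate_production(ko, sim_config, "EX_leu__L_e")
        assert ko_prod.objective_value == pytest.approx(
            production_state.objective_value, abs=1e-6)

    def test_zero_biomass_fraction_reduces_to_unconstrained_optimum(self, core_model):
        cfg = gf.SimulationConfig(biomass_fraction=0.0, substrate_uptake_max=1.0)
        prod = gf.simulate_production(core_model, cfg, "EX_val__L_e")
        # maintenance still on (2 ATP), funded by respiring spare redox: the
        # carbon ceiling is unchanged
        assert prod.objective_value == pytest.approx(1.0, abs=1e-6)


class TestSweep:
    def test_control_row_reproduces_control_exactly(self, acn_sweep):
        frac, first = acn_sweep.rows[0]
        assert frac == 1.0
        assert first.fluxes == acn_sweep.control_state.fluxes

    def test_relative_matrix_control_row_is_all_ones(self, acn_sweep):
        row = acn_sweep.relative_flux_matrix()[1.0]
        assert all(v == pytest.approx(1.0) for v in row.values())

    def test_fractions_strictly_descending(self, acn_sweep):
        fracs = [f for f, _ in acn_sweep.rows]
        assert fracs == sorted(fracs, reverse=True)

    def test_target_respects_cap_in_every_row(self, acn_sweep):
        for frac, dist in acn_sweep.rows:
            if dist.optimal:
                assert dist.fluxes["ACONT"] <= frac * acn_sweep.control_flux + 1e-6

    def test_leucine_export_rises_as_aconitase_falls(self, acn_sweep):
        exports = [dist.fluxes["EX_leu__L_e"]
                   for _, dist in acn_sweep.rows if dist.optimal]
        assert len(exports) == len(acn_sweep.rows)
        for earlier, later in zip(exports, exports[1:]):
            assert later >= earlier - 1e-6
        assert exports[-1] > exports[0] + 0.5  # genuinely rises, not flat

    def test_zero_flux_target_rejected(self, core_model, sim_config):
        with pytest.raises(ValueError, match="no flux"):
            gf.sweep_relative_flux(core_model, sim_config, "ICL")

    def test_infeasible_rows_recorded_not_raised(self, sim_config):
        # capping aconitase in a model whose biomass floor cannot relax:
        # biomass lower bound pinned above what the cap allows
        model = gf.apply_genotype(gf.build_core_model(), "leucine_producer")
        mu = gf.fba(model, sim_config).objective_value
        model.reaction("BIOMASS").lower_bound = 0.9 * mu
        sweep = gf.sweep_relative_flux(model, sim_config, "ACONT")
        statuses = [d.status for _, d in sweep.rows]
        assert statuses[0] == "optimal"
        assert "infeasible" in statuses
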