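"""Generated core network: balance, closure, presets, bifido augmentation."""

import numpy as np
import pytest

import glutaflux as gf
from glutaflux.coremodel import GENOTYPE_PRESETS
from glutaflux.model import unchecked_reactions


def test_core_model_validates_and_balances(core_model):
    core_model.validate()
    assert gf.check_mass_balance(core_model) == []
    assert unchecked_reactions(core_model) == []


def test_generated_presets_validate_and_balance():
    for name in GENOTYPE_PRESETS:
        model = gf.apply_genotype(gf.build_core_model(), name)
        model.validate()
        assert gf.check_mass_balance(model) == []


def test_wild_type_grows_on_glucose(core_model, sim_config):
    sol = gf.fba(core_model, sim_config)
    assert sol.status == "optimal"
    assert sol.objective_value > 0.1


def test_carbon_closure_at_yield_optimum(sim_config):
    """With uptake 1 glucose and zero biomass, exported carbon totals 6."""
    model = gf.build_core_model()
    carbon = {m.id: (m.formula or {}).get("C", 0) for m in model.metabolites}
    model.set_bounds("EX_glc__D_e", -1.0, -1.0)
    model.reaction("ATPM").lower_bound = 0.0
    model.objective_id = "EX_leu__L_e"
    sol = gf.fba(model)
    total = sum(
        sol.fluxes[r.id] * carbon[next(iter(r.stoichiometry))]
        for r in model.reactions
        if r.is_exchange and r.id != "EX_glc__D_e"
    )
    assert total == pytest.approx(6.0, abs=1e-6)


class TestGenotypePresets:
    def test_unknown_preset_lists_known_ones(self, core_model):
        with pytest.raises(KeyError, match="LEU-28"):
            gf.apply_genotype(core_model, "no_such_strain")

    def test_anaplerosis_double_knockout_abolishes_growth(self, sim_config):
        model = gf.apply_genotype(gf.build_core_model(), "LEU-28")
        sol = gf.fba(model, sim_config)
        assert sol.status == "optimal"
        assert abs(sol.objective_value) < 1e-9

    def test_glyoxylate_rescue_restores_growth(self, sim_config):
        model = gf.apply_genotype(gf.build_core_model(), "LEU-29")
        assert gf.fba(model, sim_config).objective_value > 0.05

    def test_leu29_equals_leu28_plus_manual_edits(self):
        via_preset = gf.apply_genotype(gf.build_core_model(), "LEU-29")
        manual = gf.apply_genotype(gf.build_core_model(), "LEU-28")
        manual.set_bounds("ICL", 0.0, 1000.0)
        manual.set_bounds("MALS", 0.0, 1000.0)
        icd = manual.reaction("ICDHx")
        icd.lower_bound *= 0.2
        icd.upper_bound *= 0.2
        manual.annotations = via_preset.annotations
        assert via_preset.equals(manual)

    def test_pyc_knockout_shifts_anaplerosis_to_ppc(self, sim_config, growth_state):
        ko = gf.knock_out(gf.build_core_model(), ["PC"])
        ko_state = gf.geometric_fba(ko, sim_config)
        assert ko_state.fluxes["PPC"] > growth_state.fluxes["PPC"] + 1e-6


class TestBifidoShunt:
    def test_adds_exactly_two_reactions(self, core_model):
        augmented = gf.augment_with_bifido_shunt(core_model)
        assert len(augmented.reactions) == len(core_model.reactions) + 2
        assert gf.check_mass_balance(augmented) == []

    def test_double_augmentation_rejected(self, core_model):
        augmented = gf.augment_with_bifido_shunt(core_model)
        with pytest.raises(ValueError, match="already"):
            gf.augment_with_bifido_shunt(augmented)

    def test_acetyl_coa_ceiling_rises_from_2_to_3(self, sim_config):
        model = gf.build_core_model()
        model.set_bounds("DM_accoa", 0.0, 1000.0)
        before = gf.max_theoretical_yield(model, sim_config, "DM_accoa")
        after = gf.max_theoretical_yield(
            gf.augment_with_bifido_shunt(model), sim_config, "DM_accoa")
        assert before.yield_mol_per_mol == pytest.approx(2.0, abs=1e-6)
        assert after.yield_mol_per_mol == pytest.approx(3.0, abs=1e-6)


def test_leucine_pathway_stoichiometry(core_model, sim_config):
    """2 pyruvate + 1 acetyl-CoA in, 2 CO2 out per leucine along the pathway."""
    model = core_model.copy()
    model.set_bounds("EX_glc__D_e", -1.5, -1.5)
    model.reaction("ATPM").lower_bound = 0.0
    model.objective_id = "EX_leu__L_e"
    sol = gf.fba(model)
    leu = sol.objective_value
    assert leu == pytest.approx(1.0, abs=1e-6)  # 1.5 glucose -> 1 leucine
    assert sol.fluxes["ACLS"] == pytest.approx(leu, abs=1e-6)   # 2 pyr, 1 CO2
    assert sol.fluxes["IPPS"] == pytest.approx(leu, abs=1e-6)   # 1 accoa
    assert sol.fluxes["IPMD"] == pytest.approx(leu, abs=1e-6)   # 1 CO2


class TestToyNetworks:
    def test_chain_shape_and_optimum(self):
        model = gf.build_toy_network("chain")
        assert len(model.reactions) == 3
        assert gf.fba(model).objective_value == pytest.approx(10.0)

    def test_random_is_reproducible_from_seed(self):
        a = gf.build_toy_network("random", seed=7, size=5)
        b = gf.build_toy_network("random", seed=7, size=5)
        assert a.equals(b)

    def test_random_networks_are_feasible_with_positive_optimum(self):
        for seed in range(30):
            model = gf.build_toy_network("random", seed=seed, size=5)
            model.validate()
            sol = gf.fba(model)
            assert sol.status == "optimal"
            assert sol.objective_value > 0

    def test_size_cap_enforced(self):
        with pytest.raises(ValueError, match="12"):
            gf.build_toy_network("random", seed=1, size=20)
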