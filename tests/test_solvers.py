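"""LP solver layer: FBA/FVA/geometric FBA against trivial cases and the
brute-force vertex-enumeration oracle."""

import numpy as np
import pytest

import glutaflux as gf
from glutaflux.solvers import LpProblem, build_lp, solve_lp

from conftest import oracle_flux_range, oracle_optimum


def _box_problem(sense="maximize"):
    return LpProblem(
        variable_ids=["v"],
        objective=np.array([1.0]),
        sense=sense,
        lower=np.array([0.0]),
        upper=np.array([10.0]),
        a_eq=np.zeros((0, 1)),
        b_eq=np.zeros(0),
    )


class TestSolveLp:
    def test_box_maximum(self):
        sol = solve_lp(_box_problem())
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0)

    def test_contradictory_rows_infeasible(self):
        p = _box_problem()
        p.extra_rows = [(np.array([1.0]), ">=", 5.0), (np.array([1.0]), "<=", 3.0)]
        assert solve_lp(p).status == "infeasible"

    def test_unbounded_detected(self):
        p = _box_problem()
        p.upper = np.array([np.inf])
        assert solve_lp(p).status == "unbounded"

    def test_column_count_mismatch_rejected(self):
        p = _box_problem()
        p.a_eq = np.zeros((1, 2))
        with pytest.raises(ValueError, match="columns"):
            solve_lp(p)


class TestFba:
    def test_linear_chain_saturates_uptake(self):
        sol = gf.fba(gf.build_toy_network("chain"))
        assert sol.objective_value == pytest.approx(10.0)
        assert all(v == pytest.approx(10.0) for v in sol.fluxes.values())

    def test_steady_state_residual_within_tolerance(self, core_model, sim_config):
        sol = gf.fba(core_model, sim_config)
        S = core_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in core_model.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-6

    @pytest.mark.parametrize("seed", range(25))
    def test_random_networks_match_hand_assembled_lp(self, seed):
        model = gf.build_toy_network("random", seed=seed, size=4)
        via_fba = gf.fba(model)
        via_lp = solve_lp(build_lp(model))
        assert via_fba.objective_value == pytest.approx(via_lp.objective_value)


class TestVertexOracle:
    """FBA/FVA certified against exhaustive vertex enumeration (>= 100 seeds)."""

    @pytest.mark.parametrize("seed", range(100))
    def test_fba_matches_vertex_enumeration(self, seed):
        model = gf.build_toy_network("random", seed=seed, size=4)
        assert len(model.reactions) <= 6
        sol = gf.fba(model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(oracle_optimum(model), abs=1e-6)

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_fva_matches_vertex_enumeration(self, seed):
        model = gf.build_toy_network("random", seed=seed, size=4)
        opt = gf.fba(model).objective_value
        fraction = 0.8
        result = gf.fva(model, objective_fraction=fraction)
        for rid in model.reaction_ids[:3]:
            lo, hi = oracle_flux_range(model, rid, objective_floor=fraction * opt)
            assert result[rid][0] == pytest.approx(lo, abs=1e-6)
            assert result[rid][1] == pytest.approx(hi, abs=1e-6)

    @pytest.mark.parametrize("seed", [3, 11, 42])
    def test_no_sampled_point_beats_reported_optimum(self, seed):
        model = gf.build_toy_network("random", seed=seed, size=4)
        opt = gf.fba(model).objective_value
        rng = np.random.default_rng(seed)
        S = model.stoichiometric_matrix()
        j = model.reaction_ids.index(model.objective_id)
        vertices = np.array(enumerate_feasible(model))
        if len(vertices) >= 2:
            # random convex combinations of feasible vertices stay feasible
            for _ in range(200):
                w = rng.dirichlet(np.ones(len(vertices)))
                point = w @ vertices
                assert np.max(np.abs(S @ point)) < 1e-6
                assert point[j] <= opt + 1e-6


def enumerate_feasible(model):
    from conftest import enumerate_vertices
    S = model.stoichiometric_matrix()
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    return enumerate_vertices(S, np.zeros(S.shape[0]), lower, upper)


class TestFva:
    def test_chain_intervals_collapse_at_full_optimum(self):
        result = gf.fva(gf.build_toy_network("chain"), objective_fraction=1.0)
        for rid in ("R_in", "R_ab", "R_out"):
            assert result[rid] == (pytest.approx(10.0), pytest.approx(10.0))

    def test_diamond_branches_are_interchangeable(self):
        result = gf.fva(gf.build_toy_network("diamond"), objective_fraction=1.0)
        for rid in ("R_top", "R_bot"):
            assert result[rid][0] == pytest.approx(0.0, abs=1e-7)
            assert result[rid][1] == pytest.approx(10.0)

    def test_intervals_nest_as_fraction_rises(self, core_model, sim_config):
        tight = gf.fva(core_model, sim_config, objective_fraction=1.0)
        loose = gf.fva(core_model, sim_config, objective_fraction=0.5)
        for rid in core_model.reaction_ids:
            assert loose[rid][0] <= tight[rid][0] + 1e-6
            assert tight[rid][1] <= loose[rid][1] + 1e-6

    def test_pinning_reaction_at_interval_end_stays_feasible(self, sim_config):
        model = gf.build_toy_network("diamond")
        result = gf.fva(model, objective_fraction=1.0)
        for rid in ("R_top", "R_bot"):
            for end in result[rid]:
                pinned = model.copy()
                pinned.set_bounds(rid, end, end)
                sol = gf.fba(pinned)
                assert sol.status == "optimal"
                assert sol.objective_value >= 10.0 - 1e-6


class TestGeometricFba:
    def test_unique_optimum_equals_fba(self):
        model = gf.build_toy_network("chain")
        g = gf.geometric_fba(model)
        f = gf.fba(model)
        assert g.objective_value == pytest.approx(f.objective_value)
        for rid, v in f.fluxes.items():
            assert g.fluxes[rid] == pytest.approx(v, abs=1e-5)

    def test_symmetric_diamond_splits_evenly(self):
        g = gf.geometric_fba(gf.build_toy_network("diamond"))
        assert g.fluxes["R_top"] == pytest.approx(5.0, abs=1e-5)
        assert g.fluxes["R_bot"] == pytest.approx(5.0, abs=1e-5)

    def test_core_fluxes_lie_in_fva_intervals_and_attain_optimum(
        self, core_model, sim_config, growth_state
    ):
        assert growth_state.objective_value == pytest.approx(
            gf.fba(core_model, sim_config).objective_value, abs=1e-6
        )
        intervals = gf.fva(core_model, sim_config, objective_fraction=1.0)
        for rid, v in growth_state.fluxes.items():
            lo, hi = intervals[rid]
            assert lo - 1e-5 <= v <= hi + 1e-5

    def test_invariant_under_reaction_permutation(self, sim_config):
        model = gf.apply_genotype(gf.build_core_model(), "leucine_producer")
        permuted = model.copy()
        rng = np.random.default_rng(11)
        order = rng.permutation(len(permuted.reactions))
        permuted.reactions = [permuted.reactions[i] for i in order]
        a = gf.geometric_fba(model, sim_config)
        b = gf.geometric_fba(permuted, sim_config)
        for rid, v in a.fluxes.items():
            assert b.fluxes[rid] == pytest.approx(v, abs=1e-4)

    def test_invariant_under_uniform_scaling(self):
        model = gf.build_toy_network("diamond")
        scaled = model.copy()
        for r in scaled.reactions:
            r.stoichiometry = {k: 2.0 * v for k, v in r.stoichiometry.items()}
            r.lower_bound *= 2.0
            r.upper_bound *= 2.0
        a = gf.geometric_fba(model)
        b = gf.geometric_fba(scaled)
        for rid, v in a.fluxes.items():
            assert b.fluxes[rid] == pytest.approx(2.0 * v, abs=1e-4)


def test_cobra_reproduces_bundled_model_optimum(sim_config):
    """Independent cross-check: cobrapy's solver on the bundled SBML."""
    cobra = pytest.importorskip("cobra")
    from importlib import resources

    ref = resources.files("glutaflux.data") / "cglutamicum_core.xml"
    with resources.as_file(ref) as p:
        cm = cobra.io.read_sbml_model(str(p))
    ours = gf.fba(gf.build_core_model(), sim_config)
    assert cm.optimize().objective_value == pytest.approx(
        ours.objective_value, rel=1e-6
    )
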