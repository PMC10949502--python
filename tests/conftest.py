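"""Shared fixtures: core model states (computed once) and an independent
brute-force vertex-enumeration LP oracle used to certify the solvers."""

from __future__ import annotations

from itertools import combinations, product
from typing import List, Optional, Tuple

import numpy as np
import pytest

import glutaflux as gf


# ---------------------------------------------------------------------------
# vertex-enumeration oracle (independent of the scipy solver path)
# ---------------------------------------------------------------------------

def enumerate_vertices(
    a_eq: np.ndarray,
    b_eq: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    tol: float = 1e-8,
) -> List[np.ndarray]:
    """All vertices of {v : A v = b, l <= v <= u} by basis enumeration.

    Fixes every choice of (n - rank A) variables at a bound, solves the
    remaining square system and keeps unique, feasible solutions.  Exponential
    — intended only for tiny problems (n <= 8).
    """
    a_eq = np.atleast_2d(np.asarray(a_eq, dtype=float))
    n = a_eq.shape[1]
    r = np.linalg.matrix_rank(a_eq) if a_eq.size else 0
    n_fix = n - r
    vertices: List[np.ndarray] = []
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        a_free = a_eq[:, free] if free else np.zeros((a_eq.shape[0], 0))
        if free and np.linalg.matrix_rank(a_free) < len(free):
            continue  # solution not unique for this basis; another basis covers it
        for choice in product(*[(lower[j], upper[j]) for j in fixed]):
            v = np.empty(n)
            for j, val in zip(fixed, choice):
                v[j] = val
            rhs = b_eq - (a_eq[:, fixed] @ np.asarray(choice) if fixed else 0.0)
            if free:
                x, *_ = np.linalg.lstsq(a_free, rhs, rcond=None)
                if np.linalg.norm(a_free @ x - rhs) > tol:
                    continue
                for j, val in zip(free, x):
                    v[j] = val
            elif np.linalg.norm(rhs) > tol:
                continue
            if np.all(v >= lower - 1e-7) and np.all(v <= upper + 1e-7):
                vertices.append(v)
    return vertices


def oracle_optimum(model: gf.MetabolicModel, sense: str = "maximize") -> float:
    """Best objective over enumerated vertices (the LP optimum for bounded
    feasible problems, since an optimum is attained at a vertex)."""
    S = model.stoichiometric_matrix()
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    c = np.array([1.0 if r.id == model.objective_id else 0.0 for r in model.reactions])
    vertices = enumerate_vertices(S, np.zeros(S.shape[0]), lower, upper)
    assert vertices, "oracle found no feasible vertex"
    values = [float(c @ v) for v in vertices]
    return max(values) if sense == "maximize" else min(values)


def oracle_flux_range(
    model: gf.MetabolicModel,
    reaction_id: str,
    objective_floor: Optional[float] = None,
) -> Tuple[float, float]:
    """Min/max flux of one reaction over the polytope, optionally subject to
    ``objective >= objective_floor`` (added as an equality row with a slack)."""
    S = model.stoichiometric_matrix()
    m, n = S.shape
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    c = np.array([1.0 if r.id == model.objective_id else 0.0 for r in model.reactions])
    if objective_floor is not None:
        # c.v - s = floor, s in [0, s_max]
        s_max = float(np.abs(c) @ np.maximum(np.abs(lower), np.abs(upper))) - objective_floor
        a_eq = np.vstack([np.hstack([S, np.zeros((m, 1))]),
                          np.hstack([c, [-1.0]])])
        b_eq = np.concatenate([np.zeros(m), [objective_floor]])
        lower = np.concatenate([lower, [0.0]])
        upper = np.concatenate([upper, [max(s_max, 0.0)]])
    else:
        a_eq, b_eq = S, np.zeros(m)
    j = model.reaction_ids.index(reaction_id)
    vertices = enumerate_vertices(a_eq, b_eq, lower, upper)
    assert vertices, "oracle found no feasible vertex"
    vals = [v[j] for v in vertices]
    return min(vals), max(vals)


# ---------------------------------------------------------------------------
# expensive shared states (session scope: computed once)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sim_config() -> gf.SimulationConfig:
    return gf.SimulationConfig()


@pytest.fixture(scope="session")
def core_model() -> gf.MetabolicModel:
    return gf.build_core_model()


@pytest.fixture(scope="session")
def growth_state(core_model, sim_config) -> gf.FluxDistribution:
    return gf.geometric_fba(core_model, sim_config)


@pytest.fixture(scope="session")
def production_state(core_model, sim_config) -> gf.FluxDistribution:
    return gf.simulate_production(core_model, sim_config, "EX_leu__L_e")


@pytest.fixture(scope="session")
def leucine_essentiality(core_model, sim_config):
    return gf.essentiality_analysis(core_model, sim_config, "EX_leu__L_e")


@pytest.fixture(scope="session")
def acn_sweep(sim_config) -> gf.SweepResult:
    producer = gf.apply_genotype(gf.build_core_model(), "leucine_producer")
    return gf.sweep_relative_flux(producer, sim_config, "ACONT")
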