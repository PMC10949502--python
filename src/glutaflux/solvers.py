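"""Linear-programme flux solvers: FBA, FVA and geometric FBA.

All three are built on one narrow LP contract (:func:`solve_lp`), which in
turn delegates to scipy's HiGHS backend with fixed, deterministic options.

* FBA maximises the model objective subject to the steady state S.v = 0,
  flux bounds, and the substrate uptake cap.
* FVA reports, per reaction, the attainable flux interval while the objective
  is held at a fraction of its optimum.
* Geometric FBA selects a unique, central point among alternate FBA optima by
  iteratively shrinking FVA intervals toward their midpoints (L1 projection),
  making downstream flux comparisons well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, SimulationConfig

__all__ = [
    "LpProblem",
    "FluxDistribution",
    "FvaResult",
    "SolverError",
    "InfeasibleError",
    "GfbaConvergenceError",
    "solve_lp",
    "fba",
    "fva",
    "geometric_fba",
    "build_lp",
]


class SolverError(RuntimeError):
    """Numeric failure inside the LP backend."""


class InfeasibleError(RuntimeError):
    """A workflow step required feasibility that the model cannot provide."""


class GfbaConvergenceError(SolverError):
    """Geometric FBA hit its iteration cap; carries the last iterate."""

    def __init__(self, message: str, last_iterate: "FluxDistribution"):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class LpProblem:
    """max/min c.v  s.t.  A_eq.v = b_eq,  extra rows,  l <= v <= u."""

    variable_ids: List[str]
    objective: np.ndarray
    sense: str  # "maximize" | "minimize"
    lower: np.ndarray
    upper: np.ndarray
    a_eq: np.ndarray
    b_eq: np.ndarray
    # extra inequality rows, each (coeffs, relation in {"<=", ">="}, rhs)
    extra_rows: List[Tuple[np.ndarray, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.variable_ids)
        if self.a_eq.size and self.a_eq.shape[1] != n:
            raise ValueError(
                f"constraint matrix has {self.a_eq.shape[1]} columns for {n} variables"
            )
        for vec in (self.objective, self.lower, self.upper):
            if len(vec) != n:
                raise ValueError("objective/bounds length mismatch")
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"bad sense {self.sense!r}")


@dataclass
class FluxDistribution:
    """One flux vector with its objective value and solver status."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    """Per-reaction attainable flux intervals at a fixed objective fraction."""

    objective_fraction: float
    intervals: Dict[str, Tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.intervals[rxn_id]

    def width(self, rxn_id: str) -> float:
        lo, hi = self.intervals[rxn_id]
        return hi - lo


# ---------------------------------------------------------------------------
# LP contract
# ---------------------------------------------------------------------------

def solve_lp(problem: LpProblem) -> FluxDistribution:
    """Solve one LP deterministically (HiGHS dual simplex, fixed options)."""
    problem.validate()
    n = len(problem.variable_ids)
    sign = -1.0 if problem.sense == "maximize" else 1.0
    c = sign * problem.objective

    a_ub_rows: List[np.ndarray] = []
    b_ub: List[float] = []
    for coeffs, rel, rhs in problem.extra_rows:
        if rel == "<=":
            a_ub_rows.append(np.asarray(coeffs, dtype=float))
            b_ub.append(rhs)
        elif rel == ">=":
            a_ub_rows.append(-np.asarray(coeffs, dtype=float))
            b_ub.append(-rhs)
        else:
            raise ValueError(f"bad relation {rel!r}")
    a_ub = np.vstack(a_ub_rows) if a_ub_rows else None
    b_ub_arr = np.asarray(b_ub) if b_ub else None

    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub_arr,
        A_eq=problem.a_eq if problem.a_eq.size else None,
        b_eq=problem.b_eq if problem.a_eq.size else None,
        bounds=list(zip(problem.lower, problem.upper)),
        method="highs",
        options={"presolve": True},
    )
    if res.status == 0:
        fluxes = dict(zip(problem.variable_ids, (float(x) for x in res.x)))
        return FluxDistribution(fluxes, float(sign * res.fun), "optimal")
    if res.status == 2:
        return FluxDistribution({}, float("nan"), "infeasible")
    if res.status == 3:
        return FluxDistribution({}, float("nan"), "unbounded")
    raise SolverError(f"LP backend failure (status {res.status}): {res.message}")


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

def build_lp(
    model: MetabolicModel,
    config: Optional[SimulationConfig] = None,
    objective_id: Optional[str] = None,
    sense: Optional[str] = None,
) -> LpProblem:
    """Assemble the steady-state LP for a model.

    The substrate uptake cap from ``config`` is imposed as a lower bound of
    ``-substrate_uptake_max`` on the substrate exchange (uptake is negative),
    tightened against the reaction's own bounds.
    """
    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
    upper = np.array([r.upper_bound for r in model.reactions], dtype=float)

    if config is not None and model.has_reaction(config.substrate_exchange_id):
        j = rxn_ids.index(config.substrate_exchange_id)
        lower[j] = max(lower[j], -config.substrate_uptake_max)

    obj_id = objective_id if objective_id is not None else model.objective_id
    if not obj_id:
        raise ValueError("model has no objective reaction set")
    objective = np.zeros(n)
    objective[rxn_ids.index(obj_id)] = 1.0

    return LpProblem(
        variable_ids=list(rxn_ids),
        objective=objective,
        sense=sense or model.objective_sense,
        lower=lower,
        upper=upper,
        a_eq=model.stoichiometric_matrix(),
        b_eq=np.zeros(len(model.metabolites)),
    )


def fba(model: MetabolicModel, config: Optional[SimulationConfig] = None) -> FluxDistribution:
    """Flux balance analysis: optimise the model objective at steady state."""
    return solve_lp(build_lp(model, config))


def _objective_floor_row(problem: LpProblem, optimum: float, fraction: float) -> Tuple[np.ndarray, str, float]:
    """Constraint holding the objective at >= (<=) a fraction of its optimum.

    The fraction applies multiplicatively to a nonzero optimum and as-is
    (threshold 0) to a zero optimum, avoiding the degenerate fraction-of-zero.
    """
    if abs(optimum) > 1e-12:
        target = fraction * optimum
    else:
        target = 0.0
    rel = ">=" if problem.sense == "maximize" else "<="
    # for a negative maximisation optimum, fraction*opt would *relax* upward;
    # keep the floor on the attained side
    if problem.sense == "maximize" and optimum < 0:
        target = optimum  # hold at the optimum itself
    if problem.sense == "minimize" and optimum > 0:
        target = optimum
    return (problem.objective.copy(), rel, target)


def fva(
    model: MetabolicModel,
    config: Optional[SimulationConfig] = None,
    objective_fraction: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
) -> FvaResult:
    """Flux variability analysis.

    For each reaction, minimise and maximise its flux subject to all model
    constraints plus ``objective >= objective_fraction * FBA optimum`` (for a
    maximisation objective).  2N LP solves.
    """
    base = build_lp(model, config)
    opt = solve_lp(base)
    if not opt.optimal:
        raise InfeasibleError(
            f"model infeasible; cannot run FVA at fraction {objective_fraction}"
        )
    problem = build_lp(model, config)
    problem.extra_rows.append(_objective_floor_row(base, opt.objective_value, objective_fraction))
    return _fva_on_problem(problem, reactions, fraction=objective_fraction)


def _fva_on_problem(
    problem: LpProblem,
    reactions: Optional[Sequence[str]] = None,
    fraction: float = 1.0,
) -> FvaResult:
    ids = problem.variable_ids
    targets = list(reactions) if reactions is not None else list(ids)
    intervals: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = ids.index(rid)
        vec = np.zeros(len(ids))
        vec[j] = 1.0
        lo_p = LpProblem(ids, vec, "minimize", problem.lower, problem.upper,
                         problem.a_eq, problem.b_eq, list(problem.extra_rows))
        hi_p = LpProblem(ids, vec, "maximize", problem.lower, problem.upper,
                         problem.a_eq, problem.b_eq, list(problem.extra_rows))
        lo = solve_lp(lo_p)
        hi = solve_lp(hi_p)
        if not (lo.optimal and hi.optimal):
            raise InfeasibleError(f"FVA subproblem infeasible for reaction {rid!r}")
        vmin, vmax = lo.objective_value, hi.objective_value
        # clamp the numerically inevitable tiny inversions
        if vmin > vmax:
            vmin = vmax = 0.5 * (vmin + vmax)
        intervals[rid] = (vmin, vmax)
    return FvaResult(objective_fraction=fraction, intervals=intervals)


def geometric_fba(
    model: MetabolicModel,
    config: Optional[SimulationConfig] = None,
    objective_id: Optional[str] = None,
) -> FluxDistribution:
    """Geometric FBA: the unique central flux distribution at the FBA optimum.

    Iteratively (i) compute FVA intervals at fraction 1.0 within the current
    bounds, (ii) find the L1-closest feasible point to the interval midpoints,
    (iii) tighten bounds to the attainable intervals; stop once the widest
    interval is below sqrt(lp_tolerance) or after ``max_gfba_iter`` rounds.
    The result is independent of reaction ordering.
    """
    cfg = config or SimulationConfig()
    base = build_lp(model, cfg, objective_id=objective_id)
    opt = solve_lp(base)
    if not opt.optimal:
        return opt

    ids = base.variable_ids
    n = len(ids)
    lower = base.lower.copy()
    upper = base.upper.copy()
    floor = _objective_floor_row(base, opt.objective_value, 1.0)
    tol = np.sqrt(cfg.lp_tolerance)

    centre: Optional[np.ndarray] = None
    converged = False
    for _ in range(cfg.max_gfba_iter):
        problem = LpProblem(ids, base.objective, base.sense, lower, upper,
                            base.a_eq, base.b_eq, [floor])
        result = _fva_on_problem(problem)
        lo = np.array([result.intervals[r][0] for r in ids])
        hi = np.array([result.intervals[r][1] for r in ids])
        mid = 0.5 * (lo + hi)
        centre = _l1_project(problem, mid)
        if np.max(hi - lo) < tol:
            converged = True
            break
        # tighten toward the midpoints; widening to include the projection
        # point keeps the shrunk box provably feasible
        lower = np.minimum(centre, 0.5 * (lo + mid))
        upper = np.maximum(centre, 0.5 * (hi + mid))
    assert centre is not None
    if not converged:
        raise GfbaConvergenceError(
            f"geometric FBA did not converge within {cfg.max_gfba_iter} iterations",
            last_iterate=FluxDistribution(
                dict(zip(ids, (float(x) for x in centre))),
                opt.objective_value,
                "optimal",
            ),
        )
    fluxes = dict(zip(ids, (float(x) for x in centre)))
    return FluxDistribution(fluxes, opt.objective_value, "optimal")


def _l1_project(problem: LpProblem, target: np.ndarray) -> np.ndarray:
    """min sum|v - target| over the problem's feasible set (LP split form)."""
    n = len(problem.variable_ids)
    # variables: v (n), p (n), q (n) with v - target = p - q, p,q >= 0
    c = np.concatenate([np.zeros(n), np.ones(n), np.ones(n)])
    a_eq_top = np.hstack([problem.a_eq, np.zeros((problem.a_eq.shape[0], 2 * n))])
    link = np.hstack([np.eye(n), -np.eye(n), np.eye(n)])
    a_eq = np.vstack([a_eq_top, link])
    b_eq = np.concatenate([problem.b_eq, target])

    a_ub_rows = []
    b_ub = []
    for coeffs, rel, rhs in problem.extra_rows:
        row = np.concatenate([coeffs, np.zeros(2 * n)])
        if rel == "<=":
            a_ub_rows.append(row)
            b_ub.append(rhs)
        else:
            a_ub_rows.append(-row)
            b_ub.append(-rhs)

    bounds = list(zip(problem.lower, problem.upper)) + [(0, None)] * (2 * n)
    res = linprog(
        c,
        A_ub=np.vstack(a_ub_rows) if a_ub_rows else None,
        b_ub=np.asarray(b_ub) if b_ub else None,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    if res.status != 0:
        raise SolverError(f"L1 projection failed (status {res.status}): {res.message}")
    return np.asarray(res.x[:n], dtype=float)
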