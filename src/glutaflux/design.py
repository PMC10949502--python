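"""Strain-design analytics on top of the flux solvers.

The workflow mirrors model-guided producer design for pyruvate-derived amino
acids: classify every reaction's essentiality at a biomass-constrained state,
compare growth-optimal and production flux states to recommend up/down
regulation or knockout, compute theoretical product yields, and sweep a
target reaction's capacity downward to map the flux redistribution it forces.

Conventions
-----------
* The *production state* imposes ``biomass >= f * max_biomass`` (default
  f = 0.2) and maximises product export by geometric FBA, giving a unique,
  central distribution.
* Reaction essentiality is read off FVA intervals computed under the biomass
  floor with the production objective left free: an interval excluding zero
  is *essential*, an identically-zero interval is *blocked*, anything else
  (spanning or touching zero with nonzero width) is *substitutable*.
* Theoretical maximum yield is the stoichiometric ceiling: substrate uptake
  fixed at 1, biomass free at zero and maintenance disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import MetabolicModel, SimulationConfig
from .solvers import (
    FluxDistribution,
    FvaResult,
    GfbaConvergenceError,
    InfeasibleError,
    fba,
    fva,
    geometric_fba,
)

__all__ = [
    "EssentialityRecord",
    "DesignRecommendation",
    "YieldReport",
    "SweepResult",
    "classify_reactions",
    "essentiality_analysis",
    "recommend_regulation",
    "max_theoretical_yield",
    "simulate_production",
    "sweep_relative_flux",
    "production_constrained_model",
]

ATPM_ID = "ATPM"


@dataclass
class EssentialityRecord:
    reaction_id: str
    essentiality: str  # "essential" | "substitutable" | "blocked"
    v_min: float
    v_max: float


@dataclass
class DesignRecommendation:
    reaction_id: str
    mode: str  # "U" | "D" | "KO" | "none"
    growth_flux: float
    production_flux: float


@dataclass
class YieldReport:
    product_id: str
    substrate_id: str
    yield_mol_per_mol: float
    biomass_fraction_used: float
    status: str


@dataclass
class SweepResult:
    target_reaction_id: str
    control_flux: float
    control_state: FluxDistribution
    rows: List[Tuple[float, FluxDistribution]]

    def relative_flux_matrix(self) -> Dict[float, Dict[str, float]]:
        """fraction -> reaction -> flux / control flux (0/0 -> 1, x/0 -> inf)."""
        out: Dict[float, Dict[str, float]] = {}
        for frac, dist in self.rows:
            if not dist.optimal:
                continue
            row: Dict[str, float] = {}
            for rid, v in dist.fluxes.items():
                ref = self.control_state.fluxes.get(rid, 0.0)
                if abs(ref) < 1e-9:
                    row[rid] = 1.0 if abs(v) < 1e-9 else float("inf")
                else:
                    row[rid] = v / ref
            out[frac] = row
        return out


# ---------------------------------------------------------------------------
# essentiality
# ---------------------------------------------------------------------------

def classify_reactions(
    fva_result: FvaResult, epsilon: float = 1e-6
) -> List[EssentialityRecord]:
    """Partition reactions into essential / substitutable / blocked.

    blocked: |v_min| <= eps and |v_max| <= eps;
    essential: the eps-rounded interval excludes zero (this subsumes the
    narrower "min = max != 0" reading — a required-but-variable interval such
    as (1, 5) is still essential);
    substitutable: everything else.
    """
    records = []
    for rid in sorted(fva_result.intervals):
        vmin, vmax = fva_result.intervals[rid]
        lo = 0.0 if abs(vmin) <= epsilon else vmin
        hi = 0.0 if abs(vmax) <= epsilon else vmax
        if lo == 0.0 and hi == 0.0:
            cls = "blocked"
        elif lo * hi > 0.0:
            cls = "essential"
        else:
            cls = "substitutable"
        records.append(EssentialityRecord(rid, cls, vmin, vmax))
    return records


def production_constrained_model(
    model: MetabolicModel,
    config: SimulationConfig,
    product_exchange_id: Optional[str] = None,
) -> Tuple[MetabolicModel, float]:
    """Copy of ``model`` with the biomass floor installed.

    Solves FBA for the maximum biomass, sets ``biomass.lb = f * max`` and
    (when given) switches the objective to the product exchange.  Returns the
    constrained copy and the biomass maximum.
    """
    growth = fba(model, config)
    if not growth.optimal:
        raise InfeasibleError("model infeasible; no biomass optimum exists")
    mu_max = growth.objective_value
    out = model.copy()
    floor = config.biomass_fraction * mu_max
    bio = out.reaction(config.biomass_reaction_id)
    bio.lower_bound = max(bio.lower_bound, floor)
    if product_exchange_id is not None:
        out.objective_id = product_exchange_id
        out.objective_sense = "maximize"
    return out, mu_max


def essentiality_analysis(
    model: MetabolicModel,
    config: SimulationConfig,
    product_exchange_id: str,
) -> List[EssentialityRecord]:
    """The full classification workflow at the 20% biomass constraint.

    FVA runs over the biomass-floored model with the production objective
    free (fraction 0): the intervals are "the entire range of feasible flux"
    compatible with the biomass constraint, which is what distinguishes
    substitutable drains (can carry flux, need not) from essential ones.
    """
    constrained, _ = production_constrained_model(model, config, product_exchange_id)
    result = fva(constrained, config, objective_fraction=0.0)
    return classify_reactions(result, config.classification_tolerance)


# ---------------------------------------------------------------------------
# regulation recommendation
# ---------------------------------------------------------------------------

def recommend_regulation(
    growth_state: FluxDistribution,
    production_state: FluxDistribution,
    essentiality: Sequence[EssentialityRecord],
    epsilon: float = 1e-6,
) -> List[DesignRecommendation]:
    """Compare growth vs production fluxes into U/D/KO/none calls.

    U: production magnitude exceeds growth magnitude (needs upregulation);
    D: production magnitude falls short and the reaction is growth-essential
    (attenuate, do not delete); KO: substitutable or blocked with no
    production flux (delete); none: unchanged.  Ordered by reaction id.
    """
    if set(growth_state.fluxes) != set(production_state.fluxes):
        raise ValueError("growth and production states cover different reactions")
    classes = {rec.reaction_id: rec.essentiality for rec in essentiality}
    recs = []
    for rid in sorted(growth_state.fluxes):
        g = growth_state.fluxes[rid]
        p = production_state.fluxes[rid]
        cls = classes.get(rid, "substitutable")
        if abs(p) > abs(g) + epsilon:
            mode = "U"
        elif abs(p) < abs(g) - epsilon and cls == "essential":
            mode = "D"
        elif cls in ("substitutable", "blocked") and abs(p) <= epsilon:
            mode = "KO"
        else:
            mode = "none"
        recs.append(DesignRecommendation(rid, mode, g, p))
    return recs


# ---------------------------------------------------------------------------
# yields and production
# ---------------------------------------------------------------------------

def max_theoretical_yield(
    model: MetabolicModel,
    config: SimulationConfig,
    product_exchange_id: str,
) -> YieldReport:
    """Stoichiometric ceiling: mol product exported per mol substrate taken up.

    Substrate uptake is fixed at 1 mmol/gCDW/h, biomass is left free at its
    natural zero, maintenance is disabled, and product export is maximised.
    """
    work = model.copy()
    work.set_bounds(config.substrate_exchange_id, -1.0, -1.0)
    if work.has_reaction(ATPM_ID):
        rxn = work.reaction(ATPM_ID)
        rxn.lower_bound = 0.0
    work.objective_id = product_exchange_id
    work.objective_sense = "maximize"
    sol = fba(work)  # no config: the uptake is already pinned
    if not sol.optimal:
        return YieldReport(product_exchange_id, config.substrate_exchange_id,
                           float("nan"), 0.0, sol.status)
    uptake = -sol.fluxes[config.substrate_exchange_id]
    y = sol.objective_value / uptake if uptake > 0 else float("nan")
    return YieldReport(product_exchange_id, config.substrate_exchange_id,
                       y, 0.0, "optimal")


def simulate_production(
    model: MetabolicModel,
    config: SimulationConfig,
    product_exchange_id: str,
) -> FluxDistribution:
    """Biomass-constrained production state (geometric FBA).

    Imposes ``biomass >= biomass_fraction * max_biomass`` and maximises the
    product exchange, returning the unique central optimum.
    """
    constrained, _ = production_constrained_model(model, config, product_exchange_id)
    return geometric_fba(constrained, config)


# ---------------------------------------------------------------------------
# attenuation sweep
# ---------------------------------------------------------------------------

def sweep_relative_flux(
    model: MetabolicModel,
    config: SimulationConfig,
    target_reaction_id: str,
    equality: bool = False,
) -> SweepResult:
    """Capacity sweep of one reaction against the native (growth) state.

    The control is the geometric-FBA growth optimum of ``model`` with the
    substrate uptake fixed at its cap, so the carbon budget is identical in
    every row; relative flux 1.0 is the native target flux.  Each row caps
    the target's flux magnitude at ``r * control`` (upper bound by default;
    an equality variant pins it exactly) and re-solves growth by geometric
    FBA.  Infeasible rows are recorded and the sweep continues.
    """
    config.validate()
    work = model.copy()
    cap = config.substrate_uptake_max
    work.set_bounds(config.substrate_exchange_id, -cap, -cap)

    control = geometric_fba(work, config)
    if not control.optimal:
        raise InfeasibleError("control growth state is infeasible")
    control_flux = control.fluxes[target_reaction_id]
    if abs(control_flux) < config.classification_tolerance:
        raise ValueError(
            f"target reaction {target_reaction_id!r} carries no flux in the "
            "control state; a relative sweep is undefined"
        )

    rows: List[Tuple[float, FluxDistribution]] = []
    for frac in config.sweep_fractions:
        if frac == 1.0 and not equality:
            # r = 1.0 is the control by definition
            rows.append((frac, control))
            continue
        capped = work.copy()
        rxn = capped.reaction(target_reaction_id)
        level = frac * control_flux
        if equality:
            rxn.lower_bound = level
            rxn.upper_bound = level
        elif control_flux > 0:
            rxn.upper_bound = min(rxn.upper_bound, level)
        else:
            rxn.lower_bound = max(rxn.lower_bound, level)
        try:
            dist = geometric_fba(capped, config)
        except InfeasibleError:
            dist = FluxDistribution({}, float("nan"), "infeasible")
        except GfbaConvergenceError as exc:
            # a not-fully-centred iterate still attains the row optimum
            dist = exc.last_iterate
        rows.append((frac, dist))
    return SweepResult(target_reaction_id, control_flux, control, rows)
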