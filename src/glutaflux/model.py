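"""Stoichiometric network data model.

A :class:`MetabolicModel` is a plain in-memory description of a
constraint-based metabolic network: metabolites with (optional) elemental
formulas, reactions with signed stoichiometry and flux bounds, and a single
linear objective.  All solvers and design analytics in this package operate
on this structure; SBML/JSON/TSV round-tripping lives in :mod:`glutaflux.io`.

Units: fluxes are mmol/gCDW/h throughout; stoichiometric coefficients are
dimensionless mole ratios.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "SimulationConfig",
    "ModelValidationError",
    "check_mass_balance",
    "knock_out",
]

#: default magnitude used for "unbounded" fluxes (mmol/gCDW/h)
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A structural defect in a model: dangling ids, bad bounds, duplicates."""


@dataclass
class Metabolite:
    """A chemical species.

    ``formula`` maps element symbols to non-negative integer counts and may be
    ``None`` for lumped pseudo-species (e.g. biomass precursor sinks).  The
    bundled core model tracks carbon and nitrogen only; mass-balance checking
    is generic over whatever elements are present.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[Dict[str, int]] = None

    def validate(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite with empty id")
        if self.formula is not None:
            for elem, count in self.formula.items():
                if not isinstance(count, int) or count < 0:
                    raise ModelValidationError(
                        f"metabolite {self.id!r}: formula count for {elem!r} "
                        f"must be a non-negative integer, got {count!r}"
                    )


@dataclass
class Reaction:
    """A bounded stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``is_exchange`` marks boundary reactions (exactly one
    metabolite); ``is_pseudo`` marks lumped reactions (biomass, maintenance,
    demands) that are exempt from elemental balancing.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene: Optional[str] = None
    subsystem: Optional[str] = None
    is_exchange: bool = False
    is_pseudo: bool = False

    def validate(self, metabolite_ids: Optional[Iterable[str]] = None) -> None:
        if not self.id:
            raise ModelValidationError("reaction with empty id")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if metabolite_ids is not None:
            known = set(metabolite_ids)
            missing = sorted(m for m in self.stoichiometry if m not in known)
            if missing:
                raise ModelValidationError(
                    f"reaction {self.id!r} references unknown metabolite(s): "
                    + ", ".join(repr(m) for m in missing)
                )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one "
                f"metabolite, touches {len(self.stoichiometry)}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """Metabolites + reactions + one linear objective."""

    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective_id: str = ""
    objective_sense: str = "maximize"
    annotations: Dict[str, str] = field(default_factory=dict)

    # -- lookup helpers -------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    # -- structure ------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions); boundary species included."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any structural defect."""
        seen_m: set = set()
        for m in self.metabolites:
            m.validate()
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set = set()
        for r in self.reactions:
            r.validate(seen_m)
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
        if self.objective_id and self.objective_id not in seen_r:
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        if self.objective_sense not in ("maximize", "minimize"):
            raise ModelValidationError(
                f"objective sense must be maximize/minimize, got "
                f"{self.objective_sense!r}"
            )

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        rxn = self.reaction(rxn_id)
        if lower > upper:
            raise ModelValidationError(
                f"reaction {rxn_id!r}: lower bound {lower} > upper bound {upper}"
            )
        rxn.lower_bound = lower
        rxn.upper_bound = upper

    def equals(self, other: "MetabolicModel", tol: float = 1e-9) -> bool:
        """Field-for-field equality up to ``tol`` on numeric fields."""
        if self.id != other.id:
            return False
        if self.objective_id != other.objective_id:
            return False
        if self.objective_sense != other.objective_sense:
            return False
        if self.metabolite_ids != other.metabolite_ids:
            return False
        if self.reaction_ids != other.reaction_ids:
            return False
        for m1, m2 in zip(self.metabolites, other.metabolites):
            if (m1.name, m1.compartment, m1.formula) != (m2.name, m2.compartment, m2.formula):
                return False
        for r1, r2 in zip(self.reactions, other.reactions):
            if (r1.gene, r1.subsystem, r1.is_exchange, r1.is_pseudo) != (
                r2.gene, r2.subsystem, r2.is_exchange, r2.is_pseudo
            ):
                return False
            if abs(r1.lower_bound - r2.lower_bound) > tol:
                return False
            if abs(r1.upper_bound - r2.upper_bound) > tol:
                return False
            if set(r1.stoichiometry) != set(r2.stoichiometry):
                return False
            for met, c in r1.stoichiometry.items():
                if abs(c - r2.stoichiometry[met]) > tol:
                    return False
        return True


@dataclass
class SimulationConfig:
    """Knobs shared by all simulation workflows.

    Defaults reflect the study conditions: glucose uptake capped at
    4.67 mmol/gCDW/h, a 20% biomass floor during production simulation, and
    a relative-flux sweep descending 1.0 -> 0.1.
    """

    substrate_exchange_id: str = "EX_glc__D_e"
    substrate_uptake_max: float = 4.67
    biomass_reaction_id: str = "BIOMASS"
    biomass_fraction: float = 0.2
    lp_tolerance: float = 1e-9
    classification_tolerance: float = 1e-6
    sweep_fractions: Tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
    max_gfba_iter: int = 30

    def validate(self) -> None:
        if self.substrate_uptake_max <= 0:
            raise ValueError("substrate_uptake_max must be positive")
        if not 0.0 <= self.biomass_fraction <= 1.0:
            raise ValueError("biomass_fraction must lie in [0, 1]")
        if self.lp_tolerance <= 0 or self.classification_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        fr = list(self.sweep_fractions)
        if any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError("sweep fractions must lie in (0, 1]")
        if any(b >= a for a, b in zip(fr, fr[1:])):
            raise ValueError("sweep fractions must be strictly descending")


# ---------------------------------------------------------------------------
# structural checks and edits
# ---------------------------------------------------------------------------

def check_mass_balance(
    model: MetabolicModel,
) -> List[Tuple[str, str, float]]:
    """Elemental balance audit.

    Returns ``(reaction_id, element, imbalance)`` triples for every non-pseudo,
    non-exchange reaction whose metabolites all carry formulas and that fails
    to conserve some element.  Reactions touching a formula-less metabolite are
    skipped ("unchecked"), as are pseudo and exchange reactions.  An empty list
    therefore certifies every checkable internal reaction.
    """
    formulas = {m.id: m.formula for m in model.metabolites}
    problems: List[Tuple[str, str, float]] = []
    for rxn in model.reactions:
        if rxn.is_pseudo or rxn.is_exchange:
            continue
        if any(formulas[m] is None for m in rxn.stoichiometry):
            continue
        totals: Dict[str, float] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            for elem, count in formulas[met_id].items():  # type: ignore[union-attr]
                totals[elem] = totals.get(elem, 0.0) + coeff * count
        for elem in sorted(totals):
            if abs(totals[elem]) > 1e-9:
                problems.append((rxn.id, elem, totals[elem]))
    return problems


def unchecked_reactions(model: MetabolicModel) -> List[str]:
    """Internal reactions skipped by :func:`check_mass_balance` (missing formulas)."""
    formulas = {m.id: m.formula for m in model.metabolites}
    out = []
    for rxn in model.reactions:
        if rxn.is_pseudo or rxn.is_exchange:
            continue
        if any(formulas[m] is None for m in rxn.stoichiometry):
            out.append(rxn.id)
    return out


def knock_out(model: MetabolicModel, reaction_ids: Sequence[str]) -> MetabolicModel:
    """Return a copy with the named reactions' bounds pinned to (0, 0).

    Idempotent, commutes over disjoint id sets; the input is unmodified.
    """
    out = model.copy()
    for rid in reaction_ids:
        rxn = out.reaction(rid)  # raises KeyError on unknown id
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out
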