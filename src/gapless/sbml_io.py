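"""Simulation-ready metabolic models and their SBML (L3+FBC) serialization.

A :class:`MetabolicModel` holds reactions with rational stoichiometry and
flux bounds, single-species exchange reactions, and (typically two)
biomass pseudo-reactions of which one is the active objective.  Models
are uncompartmentalized: a single "cytosol" compartment.  Reading and
writing go through COBRApy's SBML layer, which applies reversible SId
escaping to composite identifiers (hyphens etc.) so ids survive the
round trip; inclusion status (scored / gap-fill / orphan) travels in
reaction notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import cobra
from cobra.util.solver import linear_reaction_coefficients

from gapless.chem_core import CompoundRecord, Formula, ReactionEquation, parse_formula

__all__ = [
    "ModelReaction",
    "MetabolicModel",
    "DEFAULT_BOUND",
    "bounds_for_direction",
    "add_exchange_reactions",
    "make_biomass_reaction",
    "to_cobra",
    "from_cobra",
    "write_sbml",
    "read_sbml",
]

DEFAULT_BOUND = 1000.0


def bounds_for_direction(direction: str, bound: float = DEFAULT_BOUND) -> tuple[float, float]:
    if direction == "forward":
        return (0.0, bound)
    if direction == "backward":
        return (-bound, 0.0)
    return (-bound, bound)


@dataclass
class ModelReaction:
    """A model reaction: stoichiometry, flux bounds and provenance status."""

    id: str
    equation: ReactionEquation
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    status: str | None = None  # scored | gap-fill | orphan | exchange | biomass
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"{self.id}: lower bound {self.lower_bound} > upper {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.equation.compound_ids) == 1


@dataclass
class MetabolicModel:
    """Reactions + species + exchanges + objectives, SBML-serializable."""

    id: str = "model"
    reactions: dict[str, ModelReaction] = field(default_factory=dict)
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    objectives: list[str] = field(default_factory=list)
    active_objective: str | None = None

    def add_reaction(self, rxn: ModelReaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id}")
        for cid in rxn.equation.compound_ids:
            self.compounds.setdefault(cid, CompoundRecord(cid))
        self.reactions[rxn.id] = rxn

    @property
    def exchanges(self) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if r.is_exchange)

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        used = set()
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"{rxn.id}: bounds inverted")
            used |= rxn.equation.compound_ids
        orphaned_species = set(self.compounds) - used
        if orphaned_species:
            raise ValueError(f"species in no reaction: {sorted(orphaned_species)}")
        for obj in self.objectives:
            if obj not in self.reactions:
                raise ValueError(f"objective {obj} not in model")
        if self.active_objective and self.active_objective not in self.reactions:
            raise ValueError(f"active objective {self.active_objective} not in model")


def add_exchange_reactions(
    model: MetabolicModel, compound_ids: Iterable[str]
) -> MetabolicModel:
    """Add one ``EX_<compound>`` boundary reaction per compound.

    Convention: the exchange consumes the species (export direction
    positive); default bounds close uptake and leave export open.
    Re-adding an existing exchange is an error.
    """
    for cid in compound_ids:
        ex_id = f"EX_{cid}"
        if ex_id in model.reactions:
            raise ValueError(f"exchange {ex_id} already present")
        model.compounds.setdefault(cid, CompoundRecord(cid))
        model.add_reaction(
            ModelReaction(
                id=ex_id,
                equation=ReactionEquation({cid: Fraction(1)}, {}),
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                status="exchange",
            )
        )
    return model


def make_biomass_reaction(
    rxn_id: str, coefficients: Mapping[str, float], name: str = "biomass"
) -> ModelReaction:
    """Biomass pseudo-reaction from signed mmol/g-CDW coefficients.

    Negative coefficients are consumed precursors, positive ones
    released by-products (ADP, phosphate); the reaction is irreversible
    and its flux carries the growth rate.
    """
    subs = {cid: Fraction(str(-c)) for cid, c in coefficients.items() if c < 0}
    prods = {cid: Fraction(str(c)) for cid, c in coefficients.items() if c > 0}
    return ModelReaction(
        id=rxn_id,
        equation=ReactionEquation(subs, prods),
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        status="biomass",
        name=name,
    )


_COMPARTMENT = "c"  # single cytosol compartment; models are uncompartmentalized


def to_cobra(model: MetabolicModel) -> cobra.Model:
    cm = cobra.Model(model.id)
    mets = {}
    for cid, rec in sorted(model.compounds.items()):
        met = cobra.Metabolite(
            cid,
            formula=rec.formula.to_hill() if rec.formula else None,
            charge=rec.charge,
            name=rec.names[0] if rec.names else cid,
            compartment=_COMPARTMENT,
        )
        mets[cid] = met
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rid, rxn in model.reactions.items():
        cr = cobra.Reaction(
            rid,
            name=rxn.name or rid,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rid, rxn in model.reactions.items():
        cr = cm.reactions.get_by_id(rid)
        cr.add_metabolites(
            {mets[cid]: float(c) for cid, c in rxn.equation.signed_coefficients().items()}
        )
        if rxn.status:
            cr.notes["status"] = rxn.status
        if rid in model.objectives:
            cr.notes["objective"] = "active" if rid == model.active_objective else "candidate"
        if rxn.is_exchange:
            # boundary reactions need the SBO term for cobra to list them
            cr.annotation.setdefault("sbo", "SBO:0000627")
    if model.active_objective:
        cm.objective = model.active_objective
    return cm


def from_cobra(cm: cobra.Model) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    for met in cm.metabolites:
        formula = None
        if met.formula:
            try:
                formula = parse_formula(met.formula)
            except Exception:
                formula = None
        model.compounds[met.id] = CompoundRecord(
            id=met.id,
            formula=formula,
            charge=int(met.charge or 0),
            names=[met.name] if met.name else [],
        )
    active = linear_reaction_coefficients(cm)
    active_ids = {r.id for r in active}
    for cr in cm.reactions:
        subs = {m.id: Fraction(repr(-c)) for m, c in cr.metabolites.items() if c < 0}
        prods = {m.id: Fraction(repr(c)) for m, c in cr.metabolites.items() if c > 0}
        rxn = ModelReaction(
            id=cr.id,
            equation=ReactionEquation(subs, prods),
            lower_bound=cr.lower_bound,
            upper_bound=cr.upper_bound,
            status=cr.notes.get("status"),
            name=cr.name if cr.name != cr.id else "",
        )
        model.reactions[cr.id] = rxn
        if cr.notes.get("objective") in ("active", "candidate"):
            model.objectives.append(cr.id)
        if cr.id in active_ids:
            model.active_objective = cr.id
    model.objectives = sorted(set(model.objectives) | active_ids)
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Serialize to SBML Level 3 with FBC bounds and objective."""
    model.validate()
    cobra.io.write_sbml_model(to_cobra(model), str(path))


def read_sbml(path: str | Path) -> MetabolicModel:
    """Parse an SBML model; raises on malformed documents."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse SBML {path}: {exc}") from exc
    return from_cobra(cm)
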