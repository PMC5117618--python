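"""Flux balance analysis validation protocols.

All protocols run linear programs over the steady-state constraint
S.v = 0 with the model's flux bounds, via COBRApy/GLPK.  The default
minimal medium supplies a bounded amount of glucose and unlimited
ammonia, phosphate, sulfate, water, oxygen and iron; everything else is
closed for uptake and open for export.  Every optimal solution is
re-verified for steady state and bound feasibility before being
reported, so solver quirks cannot leak through.

Covered protocols: growth maximization, per-compound maximal-production
panels, per-carbon-source growth panels, the carbon-conservation audit
(no product may carry more carbon than the medium supplies), and P/O
coupling of respiration to ATP phosphorylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from gapless.chem_core import ReactionEquation
from gapless.sbml_io import (
    DEFAULT_BOUND,
    MetabolicModel,
    ModelReaction,
    to_cobra,
)

__all__ = [
    "MediaSpec",
    "FluxResult",
    "DEFAULT_MEDIUM",
    "maximize_objective",
    "compound_production_panel",
    "carbon_source_growth_panel",
    "carbon_audit",
    "set_po_ratio",
    "load_media",
    "known_carbon_sources",
    "NOT_FOUND",
]

NOT_FOUND = "Not found in the model"

FEASIBILITY_TOL = 1e-9
# GLPK reports machine-precision solutions; re-verification allows a
# modest numerical slack above the solver's own tolerance.
VERIFY_TOL = 1e-6

#: Minimal medium: glucose bounded at 1 unit; nitrogen, phosphate,
#: water, oxygen, iron and sulfate unlimited.
DEFAULT_MEDIUM: dict[str, float] = {
    "C00031": 1.0,  # D-glucose
    "C00014": math.inf,  # ammonia
    "C00009": math.inf,  # phosphate
    "C00059": math.inf,  # sulfate
    "C00001": math.inf,  # water
    "C00007": math.inf,  # O2
    "C14818": math.inf,  # Fe2+
}


@dataclass
class MediaSpec:
    """Maximal uptake rate per exchanged compound (mmol/g CDW/h)."""

    uptake: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, bound in self.uptake.items():
            if bound < 0:
                raise ValueError(f"negative uptake bound for {cid}")

    @classmethod
    def minimal(cls, carbon_source: str = "C00031", amount: float = 1.0) -> "MediaSpec":
        uptake = dict(DEFAULT_MEDIUM)
        uptake.pop("C00031", None)
        uptake[carbon_source] = amount
        return cls(uptake)


@dataclass
class FluxResult:
    """LP outcome: objective value, flux vector and solver status."""

    objective_value: float
    fluxes: dict[str, float]
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _apply_media(cm, media: MediaSpec) -> None:
    for rxn in cm.reactions:
        if len(rxn.metabolites) != 1:
            continue
        if rxn.id.startswith("DM_"):
            continue  # demand sinks are export-only; media never opens them
        (met,) = rxn.metabolites
        coeff = rxn.metabolites[met]
        bound = media.uptake.get(met.id, 0.0)
        bound = DEFAULT_BOUND if math.isinf(bound) else float(bound)
        # exchange written as consumption (met ->): uptake = negative flux
        if coeff < 0:
            rxn.lower_bound = -bound
            rxn.upper_bound = DEFAULT_BOUND
        else:
            rxn.upper_bound = bound
            rxn.lower_bound = -DEFAULT_BOUND


def _verify(cm, fluxes: Mapping[str, float]) -> None:
    """Re-check steady state and bounds on an optimal solution."""
    balance: dict[str, float] = {}
    for rxn in cm.reactions:
        v = fluxes[rxn.id]
        if not (rxn.lower_bound - VERIFY_TOL <= v <= rxn.upper_bound + VERIFY_TOL):
            raise AssertionError(f"flux bound violated on {rxn.id}: {v}")
        for met, coeff in rxn.metabolites.items():
            balance[met.id] = balance.get(met.id, 0.0) + coeff * v
    worst = max((abs(d) for d in balance.values()), default=0.0)
    if worst > VERIFY_TOL * 10:
        raise AssertionError(f"steady state violated: max |S.v| = {worst}")


def maximize_objective(
    model: MetabolicModel,
    media: MediaSpec,
    objective: str,
) -> FluxResult:
    """Maximize one reaction's flux under S.v = 0 and media bounds.

    Infeasible problems are reported as value 0 with the solver status
    flag, never raised.
    """
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    cm = to_cobra(model)
    _apply_media(cm, media)
    cm.objective = objective
    cm.solver.configuration.tolerances.feasibility = FEASIBILITY_TOL
    solution = cm.optimize()
    if solution.status != "optimal":
        return FluxResult(0.0, {}, solution.status)
    fluxes = {rid: float(solution.fluxes[rid]) for rid in solution.fluxes.index}
    _verify(cm, fluxes)
    return FluxResult(float(solution.objective_value), fluxes, "optimal")


def _with_demand(model: MetabolicModel, cid: str) -> tuple[MetabolicModel, str]:
    """Copy of the model extended with an export-only demand for ``cid``.

    Production is always measured through a dedicated sink: a compound
    whose only boundary is its own uptake exchange cannot express
    production through that same flux variable.
    """
    import copy

    extended = copy.deepcopy(model)
    dm_id = f"DM_{cid}"
    if dm_id not in extended.reactions:
        extended.add_reaction(
            ModelReaction(
                id=dm_id,
                equation=ReactionEquation({cid: Fraction(1)}, {}),
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                status="demand",
            )
        )
    return extended, dm_id


def compound_production_panel(
    model: MetabolicModel,
    media: MediaSpec,
    compounds: Sequence[str],
    round_to_int: bool = False,
) -> dict[str, float | str]:
    """Maximal production rate per compound (one LP each).

    Compounds absent from the model report ``"Not found in the model"``.
    ``round_to_int`` applies the integer-rounding reporting convention
    used for production-panel figures.
    """
    out: dict[str, float | str] = {}
    for cid in compounds:
        if cid not in model.compounds:
            out[cid] = NOT_FOUND
            continue
        extended, export = _with_demand(model, cid)
        result = maximize_objective(extended, media, export)
        value = result.objective_value if result.optimal else 0.0
        out[cid] = int(round(value)) if round_to_int else value
    return out


def _carbon_count(model: MetabolicModel, cid: str) -> int | None:
    rec = model.compounds.get(cid)
    if rec is None or rec.formula is None or not rec.formula.resolvable:
        return None
    return rec.formula["C"]


def carbon_source_growth_panel(
    model: MetabolicModel,
    biomass_objective: str,
    sources: Sequence[str],
    base_media: MediaSpec | None = None,
    uptake: float = 1.0,
) -> dict[str, float | str]:
    """Growth rate per sole carbon source at one unit of uptake.

    For each source, its exchange is opened at ``uptake`` while every
    other carbon-containing uptake is closed; growth is maximized by
    FBA.  Sources absent from the model report
    ``"Not found in the model"``.
    """
    base = base_media or MediaSpec.minimal()
    out: dict[str, float | str] = {}
    for cid in sources:
        if cid not in model.compounds:
            out[cid] = NOT_FOUND
            continue
        uptake_map = {
            k: v
            for k, v in base.uptake.items()
            if not (_carbon_count(model, k) or 0)
        }
        uptake_map[cid] = uptake
        if f"EX_{cid}" in model.reactions:
            extended = model
        else:
            # no exchange in the model: feed through a bounded uptake sink
            import copy

            extended = copy.deepcopy(model)
            extended.add_reaction(
                ModelReaction(
                    id=f"UP_{cid}",
                    equation=ReactionEquation({cid: Fraction(1)}, {}),
                    lower_bound=-uptake,
                    upper_bound=0.0,
                    status="exchange",
                )
            )
        result = maximize_objective(extended, MediaSpec(uptake_map), biomass_objective)
        out[cid] = result.objective_value if result.optimal else 0.0
    return out


def carbon_audit(
    model: MetabolicModel,
    media: MediaSpec,
    compounds: Sequence[str],
    tolerance: float = 1e-6,
) -> list[dict]:
    """Flag compounds whose maximal yield creates carbon from nothing.

    A violation is recorded when max production x carbons(product)
    exceeds the total carbon available from the medium's bounded
    uptakes plus ``tolerance``.  Products at exactly the carbon bound
    are plausible, not violations.  Compounds with unknown formulas are
    skipped with a warning entry.
    """
    total_carbon = 0.0
    for cid, bound in media.uptake.items():
        n_c = _carbon_count(model, cid)
        if n_c and math.isinf(bound):
            raise ValueError(f"unbounded carbon source {cid} makes the audit vacuous")
        if n_c:
            total_carbon += bound * n_c
    violations: list[dict] = []
    panel = compound_production_panel(model, media, compounds)
    for cid, value in panel.items():
        if isinstance(value, str):
            continue
        n_c = _carbon_count(model, cid)
        if n_c is None:
            violations.append(
                {"compound": cid, "kind": "warning", "detail": "unknown formula"}
            )
            continue
        produced_carbon = value * n_c
        if produced_carbon > total_carbon + tolerance:
            violations.append(
                {
                    "compound": cid,
                    "kind": "violation",
                    "produced_carbon": produced_carbon,
                    "available_carbon": total_carbon,
                }
            )
    return violations


def set_po_ratio(
    model: MetabolicModel,
    ratio: float,
    oxidase_id: str = "r0438-YCM606-R00081",
    atpase_id: str = "r0226-YCM606-R00086",
    atp: str = "C00002",
    adp: str = "C00008",
    phosphate: str = "C00009",
    water: str = "C00001",
    oxygen: str = "C00007",
) -> MetabolicModel:
    """Couple respiration to ATP phosphorylation at a fixed P/O ratio.

    The terminal oxidase reaction is augmented with ``ratio`` mol of
    ADP + Pi -> ATP + H2O per mol of oxygen atoms it reduces (2 per O2).
    The phosphorylation half is a condensation and thus element- and
    electron-balanced, so the coupling cannot unbalance the model.
    Ratio 0 leaves respiration ATP-free.
    """
    for rid in (oxidase_id, atpase_id):
        if rid not in model.reactions:
            raise KeyError(f"designated reaction {rid!r} missing from model")
    oxidase = model.reactions[oxidase_id]
    o2_coeff = oxidase.equation.substrates.get(oxygen)
    if o2_coeff is None:
        raise ValueError(f"{oxidase_id} does not consume oxygen ({oxygen})")
    if ratio == 0:
        return model
    n_atp = Fraction(str(ratio)) * 2 * o2_coeff  # 2 O atoms per O2
    signed = oxidase.equation.signed_coefficients()
    for cid, delta in ((adp, -n_atp), (phosphate, -n_atp), (atp, n_atp), (water, n_atp)):
        signed[cid] = signed.get(cid, Fraction(0)) + delta
    subs = {cid: -c for cid, c in signed.items() if c < 0}
    prods = {cid: c for cid, c in signed.items() if c > 0}
    oxidase.equation = ReactionEquation(subs, prods)
    return model


def load_media(path) -> MediaSpec:
    """Read a media TSV (compound, max_uptake; 'inf' for unlimited)."""
    import csv

    uptake: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            raw = row["max_uptake"].strip().lower()
            uptake[row["compound"]] = math.inf if raw in ("inf", "unlimited") else float(raw)
    return MediaSpec(uptake)


def known_carbon_sources() -> dict[str, str | None]:
    """The packaged literature list of utilizable carbon sources.

    Maps source name to its KEGG compound id (None when the compound has
    no KEGG entry and therefore cannot appear in a model); intended as
    the input list for :func:`carbon_source_growth_panel`.
    """
    import csv
    from importlib import resources

    path = resources.files("gapless").joinpath("data", "carbon_sources.tsv")
    out: dict[str, str | None] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["name"]] = row.get("kegg_id") or None
    return out
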