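"""End-to-end orchestration: database -> scores -> reconstruction ->
biomass -> SBML -> validation.

A single YAML config names every stage input (source tables, evidence,
alpha/beta, connectivity mode, curation table, media) and the pipeline
executes the stages in order, writing per-stage artifacts and a final
quality report.  The report is a pure function of the serialized SBML
artifact: it can be recomputed from the model file alone, which is what
:func:`validate_model` does.

Iterative curation is supported by re-running the pipeline with an
updated curation table; each run stamps a provenance block (config
hash, seed) into the report.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from collections import OrderedDict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from gapless import biomass as biomass_mod
from gapless.enzyme_scoring import ec_score_table, load_evidence_table, score_reaction
from gapless.fba import MediaSpec, carbon_audit, compound_production_panel, load_media
from gapless.reaction_db import (
    DatabaseConfig,
    ReactionDatabase,
    UnifiedReaction,
    build_database,
    load_compound_table,
    load_curation_table,
    load_reaction_table,
)
from gapless.reconstruction import (
    ModelDraft,
    ReconstructionParams,
    build_connectivity_graph,
    dead_end_metrics,
    reconstruct,
)
from gapless.sbml_io import (
    MetabolicModel,
    ModelReaction,
    add_exchange_reactions,
    bounds_for_direction,
    make_biomass_reaction,
    read_sbml,
    write_sbml,
)

__all__ = [
    "ValidationReport",
    "run_pipeline",
    "validate_model",
    "validate_sbml",
    "assemble_model",
]

PRODUCIBILITY_EPS = 1e-9


@dataclass
class ValidationReport:
    """Model quality metrics in the comparison-table layout."""

    dead_end_reaction_pct: float
    dead_end_metabolite_pct: float
    gap_fill_pct: float
    biomass_components_produced_pct: float
    infeasible_yield_count: int
    provenance: dict | None = None

    def __post_init__(self) -> None:
        for label in (
            "dead_end_reaction_pct",
            "dead_end_metabolite_pct",
            "gap_fill_pct",
            "biomass_components_produced_pct",
        ):
            value = getattr(self, label)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{label} out of [0, 100]: {value}")
        if self.infeasible_yield_count < 0:
            raise ValueError("infeasible_yield_count must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _direction_from_bounds(lower: float, upper: float) -> str:
    if lower >= 0:
        return "forward"
    if upper <= 0:
        return "backward"
    return "bidirectional"


def _internal_reactions(model: MetabolicModel) -> dict[str, ModelReaction]:
    return {
        rid: rxn
        for rid, rxn in model.reactions.items()
        if not rxn.is_exchange and rxn.status != "biomass"
    }


def validate_model(
    model: MetabolicModel,
    media: MediaSpec,
    biomass_id: str | None = None,
) -> ValidationReport:
    """Recompute the quality report from a (possibly re-read) model.

    Combines structural dead-end metrics, per-biomass-component
    producibility (a component is produced iff its maximal production
    exceeds 1e-9) and the carbon-conservation audit.
    """
    if biomass_id is None:
        candidates = [
            rid for rid, r in model.reactions.items() if r.status == "biomass"
        ]
        if model.active_objective in candidates:
            biomass_id = model.active_objective
        elif candidates:
            biomass_id = sorted(candidates)[0]
        else:
            raise ValueError("model has no biomass reaction")
    components = sorted(model.reactions[biomass_id].equation.substrates)

    internal = _internal_reactions(model)
    draft = ModelDraft()
    db_reactions: OrderedDict[str, UnifiedReaction] = OrderedDict()
    for rid, rxn in internal.items():
        status = rxn.status if rxn.status in ("scored", "gap-fill", "orphan") else "scored"
        direction = _direction_from_bounds(rxn.lower_bound, rxn.upper_bound)
        draft.status[rid] = status
        draft.directions[rid] = direction
        db_reactions[rid] = UnifiedReaction(
            id=rid,
            equation=rxn.equation,
            representative_source="model",
            direction=direction,
        )
    db = ReactionDatabase(dict(model.compounds), db_reactions, {})
    exchanged = {
        next(iter(r.equation.compound_ids))
        for r in model.reactions.values()
        if r.is_exchange
    }
    dead = dead_end_metrics(draft, db, exchanges=exchanged)

    produced = 0
    present = 0
    panel = compound_production_panel(model, media, components)
    for cid, value in panel.items():
        if isinstance(value, str):
            continue  # not in the model
        present += 1
        if value > PRODUCIBILITY_EPS:
            produced += 1
    produced_pct = 100.0 * produced / len(components) if components else 100.0

    violations = [
        v
        for v in carbon_audit(model, media, components)
        if v.get("kind") == "violation"
    ]
    return ValidationReport(
        dead_end_reaction_pct=dead["dead_end_reaction_pct"],
        dead_end_metabolite_pct=dead["dead_end_metabolite_pct"],
        gap_fill_pct=dead["gap_fill_pct"],
        biomass_components_produced_pct=produced_pct,
        infeasible_yield_count=len(violations),
    )


def validate_sbml(
    path: str | Path, media: MediaSpec, biomass_id: str | None = None
) -> ValidationReport:
    """Validate straight from an SBML artifact on disk."""
    return validate_model(read_sbml(path), media, biomass_id)


def _load_biomass_tsv(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["kegg_id"]] = float(row["coefficient"])
    return out


def assemble_model(
    database: ReactionDatabase,
    draft: ModelDraft,
    exchanges: Sequence[str],
    biomass_equations: Mapping[str, Mapping[str, float]],
    active_objective: str,
    model_id: str = "model",
) -> MetabolicModel:
    """Turn a reconstruction draft into a simulation-ready model.

    Included reactions keep their database direction bounds (orphans
    too, flagged by status); exchanges and the biomass equations are
    appended and the active objective set.
    """
    model = MetabolicModel(id=model_id)
    for cid, rec in database.compounds.items():
        model.compounds[cid] = rec
    for rid in draft.included:
        rxn = database.reactions[rid]
        lb, ub = bounds_for_direction(draft.directions.get(rid, rxn.direction))
        model.add_reaction(
            ModelReaction(
                id=rid,
                equation=rxn.equation,
                lower_bound=lb,
                upper_bound=ub,
                status=draft.status[rid],
            )
        )
    add_exchange_reactions(model, exchanges)
    for rxn_id, coefficients in biomass_equations.items():
        model.add_reaction(make_biomass_reaction(rxn_id, coefficients))
        model.objectives.append(rxn_id)
    model.active_objective = active_objective
    # species that only the biomass equations mention are fine; drop
    # compound records unused anywhere to keep the SBML tight
    used = set()
    for rxn in model.reactions.values():
        used |= rxn.equation.compound_ids
    for cid in list(model.compounds):
        if cid not in used:
            del model.compounds[cid]
    return model


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path | None = None) -> dict:
    """Execute all stages named by the config; return artifact paths.

    Stage failures raise with the stage name; partial artifacts of
    completed stages remain on disk for inspection.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        cfg = yaml.safe_load(config_path.read_text()) or {}
        base = config_path.parent
        config_bytes = config_path.read_bytes()
    else:
        cfg = dict(config)
        base = Path(".")
        config_bytes = json.dumps(cfg, sort_keys=True, default=str).encode()
    out = Path(out_dir or cfg.get("out_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    stage = "build-db"
    try:
        compounds = load_compound_table(resolve(cfg["compounds"]))
        sources = []
        for path in cfg["reactions"]:
            sources.extend(load_reaction_table(resolve(path)))
        curation = (
            load_curation_table(resolve(cfg["curation"])) if cfg.get("curation") else None
        )
        db_config = DatabaseConfig(
            lipid_compounds=frozenset(cfg.get("lipid_compounds", ())),
        )
        source_index = dict(compounds)
        database = build_database(
            sources,
            list(compounds.values()),
            curation=curation,
            config=db_config,
            source_compounds=source_index,
        )
        database.to_dir(out / "db")

        stage = "score"
        species = cfg.get("species", "species")
        evidence = load_evidence_table(resolve(cfg["evidence"]))
        ec_scores = ec_score_table(evidence, species)
        scores = {}
        for rid, rxn in database.reactions.items():
            if rxn.ec_numbers:
                scores[rid] = score_reaction(rid, rxn.ec_numbers, ec_scores, species).score
            else:
                scores[rid] = 0.0
        with open(out / "scores.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["species", "reaction_id", "score", "supporting_ec"])
            for rid in sorted(scores):
                w.writerow([species, rid, repr(scores[rid]), ""])

        stage = "reconstruct"
        sources_cfg = cfg.get("sources", [])
        if isinstance(sources_cfg, str):
            source_mets = [
                line.strip()
                for line in resolve(sources_cfg).read_text().splitlines()
                if line.strip()
            ]
        else:
            source_mets = list(sources_cfg)
        params = ReconstructionParams(
            alpha=float(cfg.get("alpha", 0.5)),
            beta=int(cfg.get("beta", 2)),
            sources=tuple(source_mets),
            beta_mode=cfg.get("beta_mode", "count"),
        )
        graph = build_connectivity_graph(database, mode=cfg.get("mode", "compound"))
        draft = reconstruct(scores, database, graph, params)
        draft.to_json(out / "draft.json")

        stage = "biomass"
        comp_cfg = cfg.get("biomass_composition", "default")
        composition = (
            biomass_mod.default_composition()
            if comp_cfg == "default"
            else biomass_mod.load_composition(resolve(comp_cfg))
        )
        bio_cfg = cfg.get("biomass_config", "default")
        bconfig = (
            biomass_mod.default_config()
            if bio_cfg == "default"
            else biomass_mod.load_config(resolve(bio_cfg))
        )
        equation = biomass_mod.assemble_equation(composition, bconfig)
        equation.to_tsv(out / "biomass.tsv")
        biomass_equations = {"biomass_main": equation.coefficients}
        ref_cfg = cfg.get("reference_biomass")
        if ref_cfg:
            biomass_equations["biomass_reference"] = _load_biomass_tsv(resolve(ref_cfg))

        stage = "assemble"
        media = load_media(resolve(cfg["media"]))
        exchanges_cfg = cfg.get("exchanges")
        if isinstance(exchanges_cfg, str):
            exchanges = [
                line.strip()
                for line in resolve(exchanges_cfg).read_text().splitlines()
                if line.strip()
            ]
        elif exchanges_cfg:
            exchanges = list(exchanges_cfg)
        else:
            exchanges = sorted(media.uptake)
        model = assemble_model(
            database,
            draft,
            exchanges,
            biomass_equations,
            active_objective="biomass_main",
            model_id=cfg.get("model_id", species),
        )
        model_path = out / "model.xml"
        write_sbml(model, model_path)

        stage = "validate"
        report = validate_sbml(model_path, media)
        report.provenance = {
            "config_sha1": hashlib.sha1(config_bytes).hexdigest(),
            "seed": cfg.get("seed"),
            "alpha": params.alpha,
            "beta": params.beta,
            "mode": cfg.get("mode", "compound"),
        }
        report.to_json(out / "report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "db": str(out / "db"),
        "scores": str(out / "scores.tsv"),
        "draft": str(out / "draft.json"),
        "biomass": str(out / "biomass.tsv"),
        "model": str(model_path),
        "report": str(out / "report.json"),
    }
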