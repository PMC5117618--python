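"""Unified, deduplicated, direction-annotated reaction database assembly.

Reactions harvested from whole-genome metabolic models and from the
public pathway databases (KEGG, MetaCyc) are expressed over a unified
compound namespace, deduplicated by their participating-metabolite sets
(protons ignored, sides interchangeable), assigned a representative by
source priority, balanced or repaired (rejecting irreparable ones),
given directions harvested from the curated whole-genome models, and
filtered by the lipid-source policy.

Source priority favours manually curated whole-genome models over KEGG
over MetaCyc, so the representative of a duplicated reaction — and with
it the stored stoichiometry — always comes from the most trusted source
regardless of input order.
"""

from __future__ import annotations

import csv
import hashlib
import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from gapless.chem_core import (
    BalanceStatus,
    CompoundRecord,
    Formula,
    ReactionEquation,
    RebalanceError,
    check_balance,
    format_equation,
    parse_equation,
    parse_formula,
    rebalance,
)

__all__ = [
    "SourceReaction",
    "CompoundMapping",
    "UnifiedReaction",
    "ReactionDatabase",
    "DatabaseConfig",
    "map_compound",
    "mint_cluster_id",
    "canonical_key",
    "select_representative",
    "assign_direction",
    "apply_lipid_policy",
    "build_database",
    "load_compound_table",
    "load_reaction_table",
]

#: Default source priority: the S. cerevisiae community model first, then
#: the other curated whole-genome models, then KEGG, then MetaCyc.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "YCM606",
    "iMA871",
    "iWV1314",
    "iHD666",
    "iLC915",
    "iSS884",
    "iAL1006",
    "KEGG",
    "MetaCyc",
)

PUBLIC_SOURCES = frozenset({"KEGG", "MetaCyc"})

#: Compound ids treated as protons (ignored in canonical keys).
PROTON_IDS = frozenset({"C00080", "H+", "PROTON"})

DIRECTIONS = ("forward", "backward", "bidirectional", "unknown")


@dataclass
class SourceReaction:
    """A reaction as harvested from one source, over source-native ids."""

    source: str
    native_id: str
    equation: ReactionEquation
    ec_numbers: list[str] = field(default_factory=list)
    direction: str = "unknown"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class CompoundMapping:
    """How a source-native compound id maps into the unified namespace."""

    source_id: str
    unified_id: str | None
    method: str  # xref | structure | name-unique | minted | unmapped


@dataclass
class UnifiedReaction:
    """A deduplicated reaction with its representative and provenance."""

    id: str
    equation: ReactionEquation
    representative_source: str
    direction: str
    ec_numbers: list[str] = field(default_factory=list)
    members: list[SourceReaction] = field(default_factory=list)


@dataclass
class DatabaseConfig:
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    proton_ids: frozenset[str] = PROTON_IDS
    water_id: str = "C00001"
    max_coeff: int = 6
    lipid_compounds: frozenset[str] = frozenset()
    #: Sources whose lipid reactions survive the lipid policy.
    lipid_keep_sources: frozenset[str] = frozenset({"YCM7", "KEGG"})

    def rank(self, source: str) -> int:
        try:
            return self.priority.index(source)
        except ValueError:
            return len(self.priority)

    @property
    def model_sources(self) -> frozenset[str]:
        return frozenset(self.priority) - PUBLIC_SOURCES


def mint_cluster_id(names: Sequence[str], taken: Iterable[str] = ()) -> str:
    """Deterministic ``Cluster<N>`` id from a sorted-name hash.

    Same names always yield the same id, so database rebuilds are
    reproducible; collisions with ``taken`` ids are resolved by probing.
    """
    digest = hashlib.sha1("\x1f".join(sorted(n.lower() for n in names)).encode())
    n = int.from_bytes(digest.digest()[:4], "big") % 10_000_000
    taken = set(taken)
    candidate = f"Cluster{n}"
    while candidate in taken:
        n = (n + 1) % 10_000_000
        candidate = f"Cluster{n}"
    return candidate


class UnifiedCompoundIndex:
    """Lookup structure over the unified compound namespace."""

    def __init__(self, compounds: Iterable[CompoundRecord]):
        self.compounds: dict[str, CompoundRecord] = {}
        self._by_xref: dict[str, str] = {}
        self._by_structure: dict[str, str] = {}
        self._by_name: dict[str, list[str]] = {}
        for rec in compounds:
            self.add(rec)

    def add(self, rec: CompoundRecord) -> None:
        if rec.id in self.compounds:
            raise ValueError(f"duplicate unified compound id {rec.id}")
        self.compounds[rec.id] = rec
        self._by_xref[rec.id] = rec.id  # unified ids match themselves
        for key, value in rec.xrefs.items():
            if key in ("inchi", "structure"):
                self._by_structure.setdefault(value, rec.id)
            else:
                self._by_xref.setdefault(value, rec.id)
        for name in rec.names:
            self._by_name.setdefault(name.strip().lower(), []).append(rec.id)

    def lookup_xref(self, value: str) -> str | None:
        return self._by_xref.get(value)

    def lookup_structure(self, value: str) -> str | None:
        return self._by_structure.get(value)

    def lookup_name(self, name: str) -> list[str]:
        return self._by_name.get(name.strip().lower(), [])


def map_compound(
    source_compound: CompoundRecord, index: UnifiedCompoundIndex
) -> CompoundMapping:
    """Map a source-native compound into the unified namespace.

    Cross-reference matches are preferred over structure matches over
    unique-name matches; a name matching more than one unified compound
    is ambiguous and left unmapped (unmapped is a value, not an error).
    """
    sid = source_compound.id
    for value in (sid, *source_compound.xrefs.values()):
        hit = index.lookup_xref(value)
        if hit:
            return CompoundMapping(sid, hit, "xref")
    for key in ("inchi", "structure"):
        value = source_compound.xrefs.get(key)
        if value:
            hit = index.lookup_structure(value)
            if hit:
                return CompoundMapping(sid, hit, "structure")
    for name in source_compound.names:
        hits = index.lookup_name(name)
        if len(hits) == 1:
            return CompoundMapping(sid, hits[0], "name-unique")
        if len(hits) > 1:
            return CompoundMapping(sid, None, "unmapped")
    return CompoundMapping(sid, None, "unmapped")


def canonical_key(
    equation: ReactionEquation, proton_ids: frozenset[str] = PROTON_IDS
) -> frozenset[frozenset[str]]:
    """Hashable identity of a reaction: its participating-metabolite sets.

    Protons are removed, stoichiometric coefficients are ignored, and the
    key is symmetric under side swap so a reaction and its reverse
    collide.
    """
    subs = frozenset(equation.substrates) - proton_ids
    prods = frozenset(equation.products) - proton_ids
    return frozenset({subs, prods})


def _sanitize_native_id(native_id: str) -> str:
    return native_id.replace("_", "")


def select_representative(
    members: Sequence[SourceReaction], config: DatabaseConfig = DatabaseConfig()
) -> UnifiedReaction:
    """Choose the representative of a duplicate group by source priority.

    The composite identifier couples the representative's native id and
    source tag with the KEGG id when a KEGG member exists (e.g.
    ``r0226-YCM606-R00086``); E.C. annotations are unioned over members.
    """
    if not members:
        raise ValueError("empty member list")
    rep = min(members, key=lambda m: (config.rank(m.source), m.native_id))
    kegg = next((m for m in members if m.source == "KEGG"), None)
    if rep.source == "KEGG" or (rep is kegg):
        rid = rep.native_id
    elif kegg is not None:
        rid = f"{_sanitize_native_id(rep.native_id)}-{rep.source}-{kegg.native_id}"
    else:
        rid = f"{_sanitize_native_id(rep.native_id)}-{rep.source}"
    ecs = sorted({ec for m in members for ec in m.ec_numbers})
    direction = assign_direction(members, config)
    return UnifiedReaction(
        id=rid,
        equation=rep.equation,
        representative_source=rep.source,
        direction=direction,
        ec_numbers=ecs,
        members=list(members),
    )


def assign_direction(
    members: Sequence[SourceReaction], config: DatabaseConfig = DatabaseConfig()
) -> str:
    """Harvest a direction from the whole-genome-model members only.

    Model members that agree keep their direction; conflicting model
    directions, and reactions known only from KEGG/MetaCyc, become
    bidirectional (the public databases carry no reliable
    directionality).
    """
    model_dirs = {
        m.direction
        for m in members
        if m.source not in PUBLIC_SOURCES and m.direction != "unknown"
    }
    if "bidirectional" in model_dirs:
        return "bidirectional"
    if model_dirs == {"forward"}:
        return "forward"
    if model_dirs == {"backward"}:
        return "backward"
    if len(model_dirs) > 1:
        return "bidirectional"  # conflict
    return "bidirectional"  # KEGG/MetaCyc only, or no direction info


def apply_lipid_policy(
    reactions: Iterable[UnifiedReaction], config: DatabaseConfig
) -> tuple[list[UnifiedReaction], list[UnifiedReaction]]:
    """Drop reactions touching listed lipids unless from a trusted source.

    Returns (kept, removed).  Lipid metabolism is poorly represented in
    most sources, so only the designated gold-standard model and KEGG may
    contribute lipid reactions.
    """
    kept, removed = [], []
    for rxn in reactions:
        touches = bool(rxn.equation.compound_ids & config.lipid_compounds)
        if touches and rxn.representative_source not in config.lipid_keep_sources:
            removed.append(rxn)
        else:
            kept.append(rxn)
    return kept, removed


@dataclass
class ReactionDatabase:
    """The assembled database plus per-source accounting."""

    compounds: dict[str, CompoundRecord]
    reactions: "OrderedDict[str, UnifiedReaction]"
    accounting: dict[str, dict[str, float]]
    rejected: list[dict] = field(default_factory=list)
    merge_warnings: list[str] = field(default_factory=list)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "compounds.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "formula", "charge", "name", "xref_kegg", "xref_chebi"])
            for rec in self.compounds.values():
                w.writerow(
                    [
                        rec.id,
                        rec.formula.to_hill() if rec.formula else "",
                        rec.charge,
                        ";".join(rec.names),
                        rec.xrefs.get("kegg", ""),
                        rec.xrefs.get("chebi", ""),
                    ]
                )
        with open(path / "reactions.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "equation", "source"])
            for rxn in self.reactions.values():
                w.writerow(
                    [
                        rxn.id,
                        format_equation(rxn.equation, rxn.direction),
                        rxn.representative_source,
                    ]
                )
        with open(path / "directions.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "direction"])
            for rxn in self.reactions.values():
                w.writerow([rxn.id, rxn.direction])
        with open(path / "ec_map.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "ec"])
            for rxn in self.reactions.values():
                for ec in rxn.ec_numbers:
                    w.writerow([rxn.id, ec])
        with open(path / "accounting.json", "w") as fh:
            json.dump(self.accounting, fh, indent=2)

    @classmethod
    def from_dir(cls, path: str | Path) -> "ReactionDatabase":
        path = Path(path)
        compounds = load_compound_table(path / "compounds.tsv")
        directions: dict[str, str] = {}
        with open(path / "directions.tsv", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                directions[row["id"]] = row["direction"]
        ec_map: dict[str, list[str]] = {}
        ec_path = path / "ec_map.tsv"
        if ec_path.exists():
            with open(ec_path, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    ec_map.setdefault(row["id"], []).append(row["ec"])
        reactions: OrderedDict[str, UnifiedReaction] = OrderedDict()
        with open(path / "reactions.tsv", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                eq, _ = parse_equation(row["equation"])
                reactions[row["id"]] = UnifiedReaction(
                    id=row["id"],
                    equation=eq,
                    representative_source=row["source"],
                    direction=directions[row["id"]],
                    ec_numbers=ec_map.get(row["id"], []),
                )
        acc_path = path / "accounting.json"
        accounting = json.loads(acc_path.read_text()) if acc_path.exists() else {}
        return cls(dict(compounds), reactions, accounting)


def load_compound_table(path: str | Path) -> dict[str, CompoundRecord]:
    """Read a compound TSV (id, formula, charge, name, xref_kegg, xref_chebi)."""
    out: dict[str, CompoundRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            formula_text = (row.get("formula") or "").strip()
            formula = parse_formula(formula_text) if formula_text else None
            xrefs = {}
            for key in ("kegg", "chebi", "inchi"):
                value = (row.get(f"xref_{key}") or "").strip()
                if value:
                    xrefs[key] = value
            rec = CompoundRecord(
                id=row["id"],
                formula=formula,
                charge=int(row.get("charge") or 0),
                names=[n for n in (row.get("name") or "").split(";") if n],
                xrefs=xrefs,
            )
            out[rec.id] = rec
    return out


def load_reaction_table(path: str | Path) -> list[SourceReaction]:
    """Read a source reaction TSV (source, native_id, equation, ec, direction)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            eq, arrow_dir = parse_equation(row["equation"])
            direction = (row.get("direction") or "").strip() or arrow_dir
            out.append(
                SourceReaction(
                    source=row["source"],
                    native_id=row["native_id"],
                    equation=eq,
                    ec_numbers=[e for e in (row.get("ec") or "").split(";") if e],
                    direction=direction,
                )
            )
    return out


def load_curation_table(path: str | Path) -> dict[str, str]:
    """Read curation overrides: reaction id -> action.

    Actions: ``close`` (remove the reaction) or a direction
    (``forward``/``backward``/``bidirectional``) that overrides the
    harvested one.
    """
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            action = row["action"].strip()
            if action not in ("close", "forward", "backward", "bidirectional"):
                raise ValueError(f"bad curation action {action!r}")
            out[row["id"].strip()] = action
    return out


def build_database(
    source_reactions: Iterable[SourceReaction],
    compounds: Iterable[CompoundRecord] | UnifiedCompoundIndex,
    curation: Mapping[str, str] | None = None,
    config: DatabaseConfig = DatabaseConfig(),
    source_compounds: Mapping[str, CompoundRecord] | None = None,
) -> ReactionDatabase:
    """Run the full assembly pipeline.

    map -> canonical key -> dedupe -> representative selection ->
    balance/rebalance (rejecting irreparable reactions) -> direction
    harvesting -> curation overrides -> lipid policy, with per-source
    accounting in the layout (reactions, % matched, % balanced, selected
    as representative, representatives that balance).

    ``source_compounds`` supplies source-native compound records (for
    xref/name mapping); source ids already present in the unified index
    map to themselves.  Errors on individual reactions are aggregated,
    never fail-fast.
    """
    if isinstance(compounds, UnifiedCompoundIndex):
        index = compounds
    else:
        index = UnifiedCompoundIndex(compounds)
    curation = dict(curation or {})
    source_reactions = list(source_reactions)

    # --- compound mapping --------------------------------------------------
    mapping: dict[str, CompoundMapping] = {}
    needed = {
        cid for rxn in source_reactions for cid in rxn.equation.compound_ids
    }
    for cid in sorted(needed):
        src_rec = (source_compounds or {}).get(cid) or CompoundRecord(cid)
        entry = map_compound(src_rec, index)
        if entry.unified_id is None and src_rec.formula is not None:
            # novel structured compound: mint a reproducible Cluster id
            new_id = mint_cluster_id(src_rec.names or [cid], index.compounds)
            minted = CompoundRecord(
                new_id, src_rec.formula, src_rec.charge, src_rec.names, src_rec.xrefs
            )
            index.add(minted)
            entry = CompoundMapping(cid, new_id, "minted")
        mapping[cid] = entry

    rejected: list[dict] = []
    merge_warnings: list[str] = []
    per_source: dict[str, dict[str, float]] = {}

    def acct(source: str) -> dict[str, float]:
        return per_source.setdefault(
            source,
            {
                "reactions": 0,
                "matched": 0,
                "balanced": 0,
                "selected_as_representative": 0,
                "representatives_that_balance": 0,
            },
        )

    # --- map equations to unified ids, dedupe by canonical key -------------
    groups: OrderedDict[frozenset, list[SourceReaction]] = OrderedDict()
    for rxn in source_reactions:
        a = acct(rxn.source)
        a["reactions"] += 1
        ids = rxn.equation.compound_ids
        if any(mapping[cid].unified_id is None for cid in ids):
            rejected.append(
                {
                    "source": rxn.source,
                    "native_id": rxn.native_id,
                    "reason": "unmapped reactants",
                    "detail": sorted(
                        cid for cid in ids if mapping[cid].unified_id is None
                    ),
                }
            )
            continue
        a["matched"] += 1
        unified_eq = ReactionEquation(
            {mapping[c].unified_id: v for c, v in rxn.equation.substrates.items()},
            {mapping[c].unified_id: v for c, v in rxn.equation.products.items()},
        )
        mapped = SourceReaction(
            rxn.source, rxn.native_id, unified_eq, rxn.ec_numbers, rxn.direction
        )
        if check_balance(unified_eq, index.compounds).balanced:
            a["balanced"] += 1
        groups.setdefault(canonical_key(unified_eq, config.proton_ids), []).append(
            mapped
        )

    # --- representative selection + balancing ------------------------------
    unified: list[UnifiedReaction] = []
    for key, members in groups.items():
        coeff_sets = {
            tuple(sorted(m.equation.signed_coefficients().items())) for m in members
        }
        rep = select_representative(members, config)
        if len(coeff_sets) > 1:
            merge_warnings.append(
                f"{rep.id}: members disagree on stoichiometry; "
                f"kept {rep.representative_source} coefficients"
            )
        a = acct(rep.representative_source)
        a["selected_as_representative"] += 1
        report = check_balance(rep.equation, index.compounds)
        if not report.balanced:
            try:
                rep.equation = rebalance(
                    rep.equation,
                    index.compounds,
                    max_coeff=config.max_coeff,
                    water_id=config.water_id,
                )
            except (RebalanceError, KeyError) as exc:
                rejected.append(
                    {
                        "source": rep.representative_source,
                        "native_id": rep.id,
                        "reason": "unbalanceable",
                        "detail": str(exc),
                    }
                )
                continue
        a["representatives_that_balance"] += 1
        unified.append(rep)

    # --- curation overrides -------------------------------------------------
    curated: list[UnifiedReaction] = []
    for rxn in unified:
        action = curation.get(rxn.id)
        if action == "close":
            rejected.append(
                {
                    "source": rxn.representative_source,
                    "native_id": rxn.id,
                    "reason": "curation-closed",
                    "detail": "",
                }
            )
            continue
        if action in ("forward", "backward", "bidirectional"):
            rxn.direction = action
        curated.append(rxn)

    # --- lipid policy --------------------------------------------------------
    kept, removed = apply_lipid_policy(curated, config)
    for rxn in removed:
        rejected.append(
            {
                "source": rxn.representative_source,
                "native_id": rxn.id,
                "reason": "lipid-policy",
                "detail": "",
            }
        )

    # Table-1-style accounting with percentage columns.
    accounting: dict[str, dict[str, float]] = {}
    for source, a in sorted(per_source.items()):
        n = a["reactions"]
        accounting[source] = {
            "Reactions": n,
            "% of matched reactions": round(100.0 * a["matched"] / n, 1) if n else 0.0,
            "% of balanced reactions": round(100.0 * a["balanced"] / n, 1) if n else 0.0,
            "Selected as representative": a["selected_as_representative"],
            "Representatives that balance": a["representatives_that_balance"],
        }

    reactions: OrderedDict[str, UnifiedReaction] = OrderedDict()
    for rxn in sorted(kept, key=lambda r: r.id):
        if rxn.id in reactions:
            merge_warnings.append(f"duplicate unified id {rxn.id}; suffixed")
            suffix = 2
            while f"{rxn.id}~{suffix}" in reactions:
                suffix += 1
            rxn.id = f"{rxn.id}~{suffix}"
        reactions[rxn.id] = rxn

    return ReactionDatabase(
        compounds=dict(index.compounds),
        reactions=reactions,
        accounting=accounting,
        rejected=rejected,
        merge_warnings=merge_warnings,
    )
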