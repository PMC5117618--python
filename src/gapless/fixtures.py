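"""Seeded synthetic fixtures with analytically known answers.

Every stage of the reconstruction stack is testable without downloading
any reaction database: this module generates toy compound/reaction
universes (balanced by construction, with a controlled number of
planted imbalances), a carbon-conserving "valine" network whose maximal
product yield equals its carbon bound, and gap-filling fixtures with
planted sub-threshold bridges and wrong-way irreversible detours.

Fixture formulas use a closed element alphabet (C, H, N, O, P, S) so
electron counts stay trivial to verify by hand.  The same seed always
produces byte-identical files; each generator emits a manifest JSON
listing the planted ground truth, which the reconstruction and FBA
tests consume as their oracle.
"""

from __future__ import annotations

import json
import random
from collections import OrderedDict
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from gapless.chem_core import (
    CompoundRecord,
    Formula,
    ReactionEquation,
    check_balance,
    format_equation,
    parse_formula,
)
from gapless.reaction_db import ReactionDatabase, UnifiedReaction
from gapless.sbml_io import (
    MetabolicModel,
    ModelReaction,
    add_exchange_reactions,
    bounds_for_direction,
)

__all__ = [
    "FixtureSpec",
    "make_toy_universe",
    "make_valine_fixture",
    "make_gap_fixture",
    "VALINE_GLUCOSE_UPTAKE",
    "VALINE_CARBON_BOUND",
]


@dataclass
class FixtureSpec:
    """Parameters of the toy-universe generator."""

    seed: int = 1
    n_compounds: int = 10
    n_reactions: int = 12
    fraction_unbalanced: float = 0.0
    fraction_sub_threshold: float = 0.25
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.n_compounds < 4:
            raise ValueError("need at least 4 compounds")
        if not 0.0 <= self.fraction_unbalanced <= 1.0:
            raise ValueError("fraction_unbalanced must be in [0, 1]")
        if not 0.0 <= self.fraction_sub_threshold <= 1.0:
            raise ValueError("fraction_sub_threshold must be in [0, 1]")
        n_unbal = round(self.fraction_unbalanced * self.n_reactions)
        n_sub = round(self.fraction_sub_threshold * self.n_reactions)
        if n_unbal + n_sub > self.n_reactions:
            raise ValueError("more planted reactions than total reactions")


_ELEMENTS = ("C", "H", "N", "O", "P", "S")


def _random_formula(rng: random.Random) -> Formula:
    counts = {
        "C": rng.randint(1, 6),
        "H": rng.randint(1, 12),
        "O": rng.randint(1, 6),
    }
    if rng.random() < 0.3:
        counts["N"] = rng.randint(1, 2)
    if rng.random() < 0.15:
        counts["S"] = 1
    return Formula(counts)


def make_toy_universe(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Generate compound/reaction/evidence tables plus a manifest.

    Balanced reactions are condensations ``A + B -> C`` where C's
    formula is the elementwise sum of A's and B's, so element and
    electron conservation hold by construction.  Planted unbalanced
    reactions double one product coefficient; planted sub-threshold
    reactions receive evidence scores below ``spec.alpha``.  The
    manifest records which is which, with the expected balance deltas.
    """
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_primitive = max(2, spec.n_compounds // 2)
    compounds: dict[str, CompoundRecord] = {}
    primitives = []
    for i in range(n_primitive):
        cid = f"T{i:04d}"
        compounds[cid] = CompoundRecord(
            cid, _random_formula(rng), 0, [f"toy compound {i}"]
        )
        primitives.append(cid)
    composites = []
    for i in range(n_primitive, spec.n_compounds):
        a, b = rng.sample(primitives, 2)
        cid = f"T{i:04d}"
        compounds[cid] = CompoundRecord(
            cid,
            compounds[a].formula.merged(compounds[b].formula),
            0,
            [f"adduct of {a} and {b}"],
            xrefs={"parents": f"{a}+{b}"},
        )
        composites.append((cid, a, b))

    n_unbalanced = round(spec.fraction_unbalanced * spec.n_reactions)
    n_sub = round(spec.fraction_sub_threshold * spec.n_reactions)
    reactions = []
    manifest_rxns = {}
    for j in range(spec.n_reactions):
        if composites:
            cid, a, b = composites[j % len(composites)]
        else:
            raise ValueError("spec leaves no composite compounds to react")
        rid = f"RT{j:04d}"
        unbalanced = j < n_unbalanced
        coeff_c = Fraction(2) if unbalanced else Fraction(1)
        eq = ReactionEquation({a: Fraction(1), b: Fraction(1)}, {cid: coeff_c})
        direction = rng.choice(["forward", "bidirectional"])
        reactions.append((rid, eq, direction))
        report = check_balance(eq, compounds)
        manifest_rxns[rid] = {
            "balanced": report.balanced,
            "element_delta": {k: str(v) for k, v in report.per_element_delta.items()},
            "electron_delta": str(report.electron_delta),
        }
        if unbalanced:
            assert not report.balanced

    sub_ids = [rid for rid, _, _ in reactions[-n_sub:]] if n_sub else []
    scores = {}
    evidence_rows = []
    for j, (rid, _, _) in enumerate(reactions):
        if rid in sub_ids:
            score = round(rng.uniform(0.05, spec.alpha - 0.05), 3)
        else:
            score = round(rng.uniform(spec.alpha, 1.0), 3)
        scores[rid] = score
        ec = f"1.1.{1 + j // 100}.{1 + j % 100}"
        evidence_rows.append(("toyspecies", ec, score, round(score * rng.uniform(0, 1), 3)))
        manifest_rxns[rid]["score"] = score
        manifest_rxns[rid]["ec"] = ec

    with open(out_dir / "compounds.tsv", "w") as fh:
        fh.write("id\tformula\tcharge\tname\txref_kegg\txref_chebi\n")
        for rec in compounds.values():
            fh.write(
                f"{rec.id}\t{rec.formula.to_hill()}\t{rec.charge}\t"
                f"{';'.join(rec.names)}\t\t\n"
            )
    with open(out_dir / "reactions.tsv", "w") as fh:
        fh.write("source\tnative_id\tequation\tec\tdirection\n")
        for j, (rid, eq, direction) in enumerate(reactions):
            fh.write(
                f"TOY\t{rid}\t{format_equation(eq, direction)}\t"
                f"{manifest_rxns[rid]['ec']}\t{direction}\n"
            )
    with open(out_dir / "evidence.tsv", "w") as fh:
        fh.write("species\tec\tblast_score\tgtg_score\n")
        for species, ec, blast, gtg in evidence_rows:
            fh.write(f"{species}\t{ec}\t{blast}\t{gtg}\n")

    manifest = {
        "spec": {
            "seed": spec.seed,
            "n_compounds": spec.n_compounds,
            "n_reactions": spec.n_reactions,
            "fraction_unbalanced": spec.fraction_unbalanced,
            "fraction_sub_threshold": spec.fraction_sub_threshold,
            "alpha": spec.alpha,
        },
        "n_unbalanced": n_unbalanced,
        "sub_threshold": sub_ids,
        "reactions": manifest_rxns,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# -- the carbon-conserving valine network ------------------------------------

VALINE_GLUCOSE_UPTAKE = 10.0
#: 10 glucose x 6 C / 5 C per valine.
VALINE_CARBON_BOUND = 12.0

_VALINE_COMPOUNDS = {
    "C00031": ("D-Glucose", "C6H12O6"),
    "C00022": ("Pyruvate", "C3H4O3"),
    "C00183": ("L-Valine", "C5H11NO2"),
    "C00011": ("CO2", "CO2"),
    "C00014": ("Ammonia", "NH3"),
    "C00001": ("Water", "H2O"),
    "C00007": ("Oxygen", "O2"),
    "C00282": ("Hydrogen", "H2"),
}

_VALINE_REACTIONS = [
    # glycolysis surrogate: glucose -> 2 pyruvate + 2 reducing equivalents
    ("R_GLYC", {"C00031": 1}, {"C00022": 2, "C00282": 2}, "forward", "2.7.1.1"),
    # valine synthesis: amination + decarboxylation, NAD(P)H surrogate H2
    (
        "R_VAL",
        {"C00022": 2, "C00014": 1, "C00282": 2},
        {"C00183": 1, "C00011": 1, "C00001": 2},
        "forward",
        "2.6.1.42",
    ),
    # CO2-refixing carboxylase surrogate
    ("R_FIX", {"C00011": 3, "C00282": 5}, {"C00022": 1, "C00001": 3}, "forward", "6.4.1.1"),
    # redox shuttle closing the electron balance
    ("R_SPLIT", {"C00001": 2}, {"C00282": 2, "C00007": 1}, "bidirectional", "1.97.1.1"),
]

_VALINE_EXCHANGES = ["C00031", "C00014", "C00007", "C00001", "C00011", "C00183"]


def make_valine_fixture(out_dir: str | Path | None = None) -> tuple[MetabolicModel, dict]:
    """The packaged carbon-conserving valine network.

    A glycolysis surrogate, an aminating valine synthase, a CO2-refixing
    carboxylase and a redox shuttle, with exchanges for glucose, NH3,
    O2, H2O, CO2 and valine.  Every internal reaction is element- and
    electron-balanced, and the only carbon input is glucose, so the LP
    optimum for valine export at glucose uptake 10 equals the carbon
    bound 10 x 6 / 5 = 12.
    """
    model = MetabolicModel(id="valine_fixture")
    compounds = {
        cid: CompoundRecord(cid, parse_formula(formula), 0, [name])
        for cid, (name, formula) in _VALINE_COMPOUNDS.items()
    }
    model.compounds.update(compounds)
    for rid, subs, prods, direction, ec in _VALINE_REACTIONS:
        lb, ub = bounds_for_direction(direction)
        eq = ReactionEquation(
            {k: Fraction(v) for k, v in subs.items()},
            {k: Fraction(v) for k, v in prods.items()},
        )
        assert check_balance(eq, compounds).balanced, rid
        model.add_reaction(
            ModelReaction(rid, eq, lb, ub, status="scored", name=rid)
        )
    add_exchange_reactions(model, _VALINE_EXCHANGES)

    manifest = {
        "glucose_uptake": VALINE_GLUCOSE_UPTAKE,
        "carbon_bound": VALINE_CARBON_BOUND,
        "product": "C00183",
        "carbon_source": "C00031",
        "exchanges": [f"EX_{c}" for c in _VALINE_EXCHANGES],
        "reactions": [r[0] for r in _VALINE_REACTIONS],
        "scores": {r[0]: 0.9 for r in _VALINE_REACTIONS},
        "ecs": {r[0]: r[4] for r in _VALINE_REACTIONS},
        "sources": ["C00031", "C00014", "C00001", "C00007"],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "compounds.tsv", "w") as fh:
            fh.write("id\tformula\tcharge\tname\txref_kegg\txref_chebi\n")
            for cid, (name, formula) in _VALINE_COMPOUNDS.items():
                fh.write(f"{cid}\t{formula}\t0\t{name}\t{cid}\t\n")
        with open(out_dir / "reactions.tsv", "w") as fh:
            fh.write("source\tnative_id\tequation\tec\tdirection\n")
            for rid, subs, prods, direction, ec in _VALINE_REACTIONS:
                eq = ReactionEquation(
                    {k: Fraction(v) for k, v in subs.items()},
                    {k: Fraction(v) for k, v in prods.items()},
                )
                fh.write(f"VALFIX\t{rid}\t{format_equation(eq, direction)}\t{ec}\t{direction}\n")
        with open(out_dir / "evidence.tsv", "w") as fh:
            fh.write("species\tec\tblast_score\tgtg_score\n")
            for rid, *_rest, ec in [(r[0], r[4]) for r in _VALINE_REACTIONS]:
                fh.write(f"valfix\t{ec}\t0.9\t0.5\n")
        with open(out_dir / "sources.txt", "w") as fh:
            fh.write("\n".join(manifest["sources"]) + "\n")
        with open(out_dir / "media.tsv", "w") as fh:
            fh.write("compound\tmax_uptake\n")
            fh.write("C00031\t10\nC00014\tinf\nC00001\tinf\nC00007\tinf\n")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return model, manifest


def valine_database() -> tuple[ReactionDatabase, dict]:
    """The valine network as a reaction database (for reconstruction)."""
    compounds = {
        cid: CompoundRecord(cid, parse_formula(formula), 0, [name])
        for cid, (name, formula) in _VALINE_COMPOUNDS.items()
    }
    reactions: OrderedDict[str, UnifiedReaction] = OrderedDict()
    for rid, subs, prods, direction, ec in _VALINE_REACTIONS:
        eq = ReactionEquation(
            {k: Fraction(v) for k, v in subs.items()},
            {k: Fraction(v) for k, v in prods.items()},
        )
        reactions[rid] = UnifiedReaction(
            id=rid,
            equation=eq,
            representative_source="VALFIX",
            direction=direction,
            ec_numbers=[ec],
        )
    db = ReactionDatabase(compounds, reactions, {})
    _, manifest = make_valine_fixture()
    return db, manifest


def make_gap_fixture(
    n_bridges: int = 1,
    include_detour: bool = False,
    out_dir: str | Path | None = None,
) -> tuple[ReactionDatabase, dict]:
    """A planted gap-filling instance.

    A high-scoring target reaction consumes compound B, which is only
    reachable from the source S through ``n_bridges`` chained
    sub-threshold bridge reactions.  With ``include_detour`` an
    irreversible wrong-way reaction is added whose written equation
    would connect B in one step but whose permitted direction runs away
    from it — a direction-aware gap-filler must never select it.

    All compounds share one formula (isomerase chemistry), so every
    reaction balances trivially.  The manifest records the planted
    bridges, detour and scores.
    """
    if n_bridges < 1:
        raise ValueError("n_bridges must be >= 1")
    formula = "C6H12O6"
    chain = ["S", *[f"X{i}" for i in range(1, n_bridges)], "B"]
    cids = ["S", "A", "B", "P", *[f"X{i}" for i in range(1, n_bridges)]]
    if include_detour:
        cids.append("D")
    compounds = {
        cid: CompoundRecord(cid, parse_formula(formula), 0, [f"isomer {cid}"])
        for cid in cids
    }
    reactions: OrderedDict[str, UnifiedReaction] = OrderedDict()
    scores: dict[str, float] = {}

    def add(rid, subs, prods, direction, score):
        reactions[rid] = UnifiedReaction(
            id=rid,
            equation=ReactionEquation(
                {k: Fraction(1) for k in subs}, {k: Fraction(1) for k in prods}
            ),
            representative_source="GAPFIX",
            direction=direction,
            ec_numbers=["9.9.9.9"],
        )
        scores[rid] = score

    add("R_SRC_A", ["S"], ["A"], "forward", 0.9)
    add("R_TARGET", ["B"], ["P"], "forward", 0.8)
    bridges = []
    for i in range(n_bridges):
        rid = f"BRIDGE_{i + 1:02d}"
        add(rid, [chain[i]], [chain[i + 1]], "forward", 0.2)
        bridges.append(rid)
    detour = None
    if include_detour:
        add("R_SRC_D", ["S"], ["D"], "forward", 0.9)
        # written D -> B, but only the reverse direction is permitted
        add("R_WRONGWAY", ["D"], ["B"], "backward", 0.2)
        detour = "R_WRONGWAY"

    manifest = {
        "sources": ["S"],
        "target": "R_TARGET",
        "bridges": bridges,
        "detour": detour,
        "scores": scores,
    }
    db = ReactionDatabase(compounds, reactions, {})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        db.to_dir(out_dir / "db")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return db, manifest
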