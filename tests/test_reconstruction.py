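"""Connectivity graphs, gap-filling, orphans, dead-end metrics."""

from __future__ import annotations

import itertools
import random
from collections import OrderedDict
from fractions import Fraction

import networkx as nx
import pytest

from gapless.chem_core import CompoundRecord, ReactionEquation, parse_formula
from gapless.fixtures import make_gap_fixture, valine_database
from gapless.reaction_db import ReactionDatabase, UnifiedReaction
from gapless.reconstruction import (
    ConnectivityGraph,
    ModelDraft,
    ReconstructionParams,
    build_connectivity_graph,
    dead_end_metrics,
    reachable_compounds,
    reconstruct,
)


def _db_from_edges(edges, directions=None):
    """Isomerase database: every reaction converts one compound to one."""
    directions = directions or {}
    compounds = {}
    reactions = OrderedDict()
    for i, (u, v) in enumerate(edges):
        for c in (u, v):
            compounds.setdefault(
                c, CompoundRecord(c, parse_formula("C6H12O6"), 0)
            )
        rid = f"R{i:03d}"
        reactions[rid] = UnifiedReaction(
            id=rid,
            equation=ReactionEquation({u: Fraction(1)}, {v: Fraction(1)}),
            representative_source="TEST",
            direction=directions.get(rid, "forward"),
        )
    return ReactionDatabase(compounds, reactions, {})


class TestConnectivityGraph:
    def test_direction_respected_on_chain(self):
        db = _db_from_edges([("A", "B"), ("B", "C")])
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        assert "C" in reachable_compounds(graph, db.reactions, ["A"])
        assert "A" not in reachable_compounds(graph, db.reactions, ["C"])

    def test_bidirectional_gives_both_edges(self):
        db = _db_from_edges([("A", "B")], {"R000": "bidirectional"})
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        assert "A" in reachable_compounds(graph, db.reactions, ["B"])

    def test_currency_metabolites_carry_no_edges(self):
        db = _db_from_edges([("A", "ATP"), ("ATP", "B")])
        graph = build_connectivity_graph(
            db, currency_exclusions=frozenset({"ATP"})
        )
        assert "B" not in reachable_compounds(graph, db.reactions, ["A"])

    def test_atom_mode_requires_maps(self):
        db = _db_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            build_connectivity_graph(db, mode="atom")

    def test_atom_mode_drops_unmapped_pairs(self):
        # a transferase moving only phosphate: no carbon edge A -> B
        compounds = {
            c: CompoundRecord(c, parse_formula("C3H7O6P"), 0)
            for c in ("A", "B", "C", "D")
        }
        rxn = UnifiedReaction(
            id="R0",
            equation=ReactionEquation(
                {"A": Fraction(1), "B": Fraction(1)},
                {"C": Fraction(1), "D": Fraction(1)},
            ),
            representative_source="TEST",
            direction="forward",
        )
        db = ReactionDatabase(compounds, OrderedDict([("R0", rxn)]), {})
        # carbon skeleton of A ends up in C; B's carbon goes to D
        graph = build_connectivity_graph(
            db, mode="atom", atom_maps={"R0": [("A", "C"), ("B", "D")]}
        )
        assert ("A", "D") not in graph.edges["R0"]
        assert ("A", "C") in graph.edges["R0"]

    @pytest.mark.parametrize("seed", range(5))
    def test_reachability_matches_networkx_bfs(self, seed):
        rng = random.Random(seed)
        nodes = [f"N{i}" for i in range(20)]
        edges = [
            (rng.choice(nodes), rng.choice(nodes)) for _ in range(30)
        ]
        edges = [(u, v) for u, v in edges if u != v]
        db = _db_from_edges(edges)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        got = reachable_compounds(graph, db.reactions, ["N0"])
        dg = nx.DiGraph(edges)
        dg.add_nodes_from(["N0"])
        expected = {"N0"} | nx.descendants(dg, "N0")
        assert got == expected


class TestReconstruct:
    def test_all_connected_means_no_gap_fill(self):
        db = _db_from_edges([("S", "A"), ("A", "B")])
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct({"R000": 0.9, "R001": 0.8}, db, graph, params)
        assert set(draft.ids_with_status("scored")) == {"R000", "R001"}
        assert not draft.ids_with_status("gap-fill")

    def test_single_bridge_within_budget(self):
        db, manifest = make_gap_fixture(1)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        assert draft.status["R_TARGET"] == "scored"
        assert draft.ids_with_status("gap-fill") == manifest["bridges"]

    def test_budget_exceeded_orphans_target(self):
        db, manifest = make_gap_fixture(3)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        assert draft.status["R_TARGET"] == "orphan"
        assert not draft.ids_with_status("gap-fill")

    def test_wrong_way_irreversible_detour_never_selected(self):
        db, manifest = make_gap_fixture(1, include_detour=True)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        assert manifest["detour"] not in draft.status
        assert draft.status["R_TARGET"] == "scored"
        assert draft.ids_with_status("gap-fill") == manifest["bridges"]

    def test_detour_only_instance_orphans_target(self):
        """With the real bridges over budget, the wrong-way shortcut must
        still not rescue the target."""
        db, manifest = make_gap_fixture(3, include_detour=True)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        assert draft.status["R_TARGET"] == "orphan"
        assert manifest["detour"] not in draft.status

    def test_beta_zero_is_pure_thresholding(self):
        db, manifest = make_gap_fixture(1)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=0, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        assert all(
            manifest["scores"][rid] >= 0.5 for rid in draft.status
        )
        assert not draft.ids_with_status("gap-fill")

    def test_gaplessness_invariant(self):
        db, manifest = make_gap_fixture(2)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        non_orphans = [r for r, s in draft.status.items() if s != "orphan"]
        reached = reachable_compounds(graph, non_orphans, ["S"])
        for rid in non_orphans:
            rxn = db.reactions[rid]
            subs = (
                rxn.equation.substrates
                if draft.directions[rid] != "backward"
                else rxn.equation.products
            )
            assert all(s in reached for s in subs)

    def test_alpha_monotonicity(self):
        db, manifest = make_gap_fixture(1)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        high = reconstruct(
            manifest["scores"], db, graph,
            ReconstructionParams(alpha=0.7, beta=2, sources=("S",)),
        )
        low = reconstruct(
            manifest["scores"], db, graph,
            ReconstructionParams(alpha=0.5, beta=2, sources=("S",)),
        )
        assert set(high.status) <= set(low.status)

    def test_determinism(self):
        db, manifest = make_gap_fixture(2, include_detour=True)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        drafts = [
            reconstruct(manifest["scores"], db, graph, params) for _ in range(3)
        ]
        assert drafts[0].status == drafts[1].status == drafts[2].status

    def test_empty_candidates_empty_draft(self):
        db = _db_from_edges([("A", "B")])
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("A",))
        draft = reconstruct({}, db, graph, params)
        assert not draft.status

    def test_draft_json_roundtrip(self, tmp_path):
        db, manifest = make_gap_fixture(1)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        draft.to_json(tmp_path / "d.json")
        back = ModelDraft.from_json(tmp_path / "d.json")
        assert back.status == draft.status
        assert back.directions == draft.directions


def _oracle_min_gap_cost(db, graph, scores, target_id, alpha, beta, sources):
    """Exhaustive enumeration over all direction-feasible gap subsets."""
    target = db.reactions[target_id]
    others = [rid for rid in db.reactions if rid != target_id]
    best = None
    for k in range(len(others) + 1):
        for combo in itertools.combinations(others, k):
            sub = [r for r in combo if scores.get(r, 0.0) < alpha]
            if len(sub) > beta:
                continue
            reached = reachable_compounds(graph, combo, sources)
            need = target.equation.substrates
            if all(s in reached for s in need):
                # the episode cost counts only sub-threshold additions;
                # above-threshold reactions enter on their own merit
                gap_cost = sum(1.0 - scores.get(r, 0.0) for r in sub)
                if best is None or gap_cost < best:
                    best = gap_cost
    return best


class TestGapSetOptimality:
    @pytest.mark.parametrize("n_bridges,beta", [(1, 2), (2, 2), (2, 3)])
    def test_cost_matches_exhaustive_enumeration(self, n_bridges, beta):
        db, manifest = make_gap_fixture(n_bridges)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=beta, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        got_cost = sum(
            1.0 - manifest["scores"][r] for r in draft.ids_with_status("gap-fill")
        )
        oracle = _oracle_min_gap_cost(
            db, graph, manifest["scores"], "R_TARGET", 0.5, beta, ("S",)
        )
        assert oracle is not None
        assert got_cost == pytest.approx(oracle)

    def test_cheaper_of_two_bridges_chosen(self):
        """Two alternative sub-threshold bridges: the higher-scoring wins."""
        compounds = {
            c: CompoundRecord(c, parse_formula("C6H12O6"), 0)
            for c in ("S", "B", "P")
        }
        reactions = OrderedDict()

        def add(rid, u, v, direction="forward"):
            reactions[rid] = UnifiedReaction(
                id=rid,
                equation=ReactionEquation({u: Fraction(1)}, {v: Fraction(1)}),
                representative_source="TEST",
                direction=direction,
            )

        add("CHEAP", "S", "B")
        add("DEAR", "S", "B")
        add("TARGET", "B", "P")
        db = ReactionDatabase(compounds, reactions, {})
        scores = {"CHEAP": 0.4, "DEAR": 0.1, "TARGET": 0.9}
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=1, sources=("S",))
        draft = reconstruct(scores, db, graph, params)
        assert draft.ids_with_status("gap-fill") == ["CHEAP"]
        assert "DEAR" not in draft.status


class TestDeadEndMetrics:
    def _draft_for(self, db):
        return ModelDraft(
            status={rid: "scored" for rid in db.reactions},
            directions={rid: r.direction for rid, r in db.reactions.items()},
        )

    def test_linear_chain_dead_end(self):
        db = _db_from_edges([("A", "B"), ("B", "C")])
        draft = self._draft_for(db)
        metrics = dead_end_metrics(draft, db, exchanges=["A"])
        # C is never consumed; A is exchanged, B is produced and consumed
        assert metrics["dead_end_metabolite_pct"] == pytest.approx(100 / 3)
        assert metrics["dead_end_reaction_pct"] == pytest.approx(50.0)

    def test_exchange_for_terminal_clears_dead_ends(self):
        db = _db_from_edges([("A", "B"), ("B", "C")])
        draft = self._draft_for(db)
        metrics = dead_end_metrics(draft, db, exchanges=["A", "C"])
        assert metrics["dead_end_metabolite_pct"] == 0.0
        assert metrics["dead_end_reaction_pct"] == 0.0

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_brute_force(self, seed):
        rng = random.Random(seed)
        nodes = [f"M{i}" for i in range(12)]
        edges = []
        for _ in range(15):
            u, v = rng.sample(nodes, 2)
            edges.append((u, v))
        directions = {
            f"R{i:03d}": rng.choice(["forward", "bidirectional"])
            for i in range(len(edges))
        }
        db = _db_from_edges(edges, directions)
        draft = self._draft_for(db)
        exchanges = set(rng.sample(nodes, 3))
        metrics = dead_end_metrics(draft, db, exchanges=exchanges)

        # brute force: scan every reaction orientation independently
        producible, consumable = set(exchanges), set(exchanges)
        for rid, rxn in db.reactions.items():
            (u,) = rxn.equation.substrates
            (v,) = rxn.equation.products
            pairs = [(u, v)]
            if rxn.direction == "bidirectional":
                pairs.append((v, u))
            for a, b in pairs:
                consumable.add(a)
                producible.add(b)
        mets = {m for r in db.reactions.values() for m in r.equation.compound_ids}
        dead = {m for m in mets if m not in producible or m not in consumable}
        dead_rxns = sum(
            1
            for r in db.reactions.values()
            if r.equation.compound_ids & dead
        )
        assert metrics["dead_end_metabolite_pct"] == pytest.approx(
            100.0 * len(dead) / len(mets)
        )
        assert metrics["dead_end_reaction_pct"] == pytest.approx(
            100.0 * dead_rxns / len(db.reactions)
        )

    def test_gap_fill_fraction(self):
        db, manifest = make_gap_fixture(1)
        graph = build_connectivity_graph(db, currency_exclusions=frozenset())
        params = ReconstructionParams(alpha=0.5, beta=2, sources=("S",))
        draft = reconstruct(manifest["scores"], db, graph, params)
        metrics = dead_end_metrics(draft, db, exchanges=["S", "P"])
        assert metrics["gap_fill_pct"] == pytest.approx(100.0 / 3)


class TestValineNetworkReconstruction:
    def test_fully_connected_no_orphans(self):
        db, manifest = valine_database()
        graph = build_connectivity_graph(db)
        params = ReconstructionParams(
            alpha=0.5, beta=2, sources=tuple(manifest["sources"])
        )
        draft = reconstruct(manifest["scores"], db, graph, params)
        assert set(draft.ids_with_status("scored")) == set(manifest["reactions"])
        metrics = dead_end_metrics(
            draft, db, exchanges=[e.removeprefix("EX_") for e in manifest["exchanges"]]
        )
        assert metrics["dead_end_metabolite_pct"] == 0.0
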