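"""Direction-aware gapless network reconstruction.

Reactions whose evidence score reaches the acceptance threshold alpha
are added greedily, best score first.  A reaction may only enter the
network if every substrate (of some permitted orientation) is reachable
from the declared source metabolites through already-included reactions,
respecting reaction directions.  When a candidate is unreachable, a
gap-filling search looks for the cheapest set of database reactions
(cost of reaction r = 1 - score(r)) that connects it, with at most beta
reactions scoring below alpha per episode.  Candidates that cannot be
connected within the budget stay in the model as *orphans*: retained for
their evidence, flagged as unconnected.

Connectivity is evaluated on a directed compound graph.  In compound
mode, each permitted orientation of a reaction contributes
substrate -> product edges, with ubiquitous currency metabolites (ATP,
water, NADH, ...) excluded to avoid spurious shortcuts.  In atom mode,
an edge exists only where a carbon atom of the substrate is actually
mapped to the product, which is the higher-fidelity surrogate.
"""

from __future__ import annotations

import heapq
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from gapless.reaction_db import ReactionDatabase, UnifiedReaction

__all__ = [
    "ReconstructionParams",
    "ConnectivityGraph",
    "ModelDraft",
    "DEFAULT_CURRENCY",
    "build_connectivity_graph",
    "reachable_compounds",
    "reconstruct",
    "gap_fill",
    "dead_end_metrics",
]

#: Crude currency-metabolite surrogate for atom maps (compound mode).
DEFAULT_CURRENCY = frozenset(
    {
        "C00001",  # water
        "C00080",  # proton
        "C00002",  # ATP
        "C00008",  # ADP
        "C00020",  # AMP
        "C00003",  # NAD+
        "C00004",  # NADH
        "C00005",  # NADPH
        "C00006",  # NADP+
        "C00011",  # CO2
        "C00009",  # phosphate
    }
)


@dataclass
class ReconstructionParams:
    """Tunables of the greedy reconstruction.

    ``alpha`` is the probability-scale acceptance threshold; ``beta``
    budgets gap-filling.  With ``beta_mode="count"`` (default) beta caps
    the number of sub-threshold reactions added per gap-filling episode;
    with ``beta_mode="cost"`` it caps the total cost (sum of 1 - score)
    of the episode's gap set.
    """

    alpha: float = 0.5
    beta: int = 2
    sources: tuple[str, ...] = ()
    beta_mode: str = "count"
    #: exact subset search is used while the candidate pool is at most
    #: this large; beyond it a per-substrate shortest-path heuristic.
    exact_gap_limit: int = 14

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.beta_mode not in ("count", "cost"):
            raise ValueError("beta_mode must be 'count' or 'cost'")
        self.sources = tuple(self.sources)


def _orientations(direction: str) -> list[bool]:
    """Permitted orientations as flags: True = as written, False = reversed."""
    if direction == "forward":
        return [True]
    if direction == "backward":
        return [False]
    return [True, False]


@dataclass
class ConnectivityGraph:
    """Directed reaction-mediated compound graph.

    ``edges[rid]`` holds the (u, v) compound pairs reaction ``rid``
    contributes in its permitted directions.
    """

    mode: str
    edges: dict[str, list[tuple[str, str]]]
    currency_exclusions: frozenset[str] = frozenset()

    def adjacency(self, reaction_ids: Iterable[str]) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {}
        for rid in reaction_ids:
            for u, v in self.edges.get(rid, ()):
                adj.setdefault(u, []).append(v)
        return adj


def build_connectivity_graph(
    database: ReactionDatabase,
    mode: str = "compound",
    currency_exclusions: frozenset[str] = DEFAULT_CURRENCY,
    atom_maps: Mapping[str, Iterable[tuple[str, str]]] | None = None,
) -> ConnectivityGraph:
    """Build the compound- or atom-mode connectivity graph.

    Compound mode links every substrate to every product of each
    permitted orientation, skipping currency metabolites.  Atom mode
    links only pairs listed in ``atom_maps[rid]`` (substrate, product)
    carbon correspondences, again respecting directions.
    """
    if mode not in ("compound", "atom"):
        raise ValueError("mode must be 'compound' or 'atom'")
    if mode == "atom" and atom_maps is None:
        raise ValueError("atom mode requires atom_maps")
    edges: dict[str, list[tuple[str, str]]] = {}
    for rid, rxn in database.reactions.items():
        pairs: list[tuple[str, str]] = []
        for forward in _orientations(rxn.direction):
            subs = rxn.equation.substrates if forward else rxn.equation.products
            prods = rxn.equation.products if forward else rxn.equation.substrates
            for u in subs:
                for v in prods:
                    if mode == "compound":
                        if u in currency_exclusions or v in currency_exclusions:
                            continue
                        pairs.append((u, v))
                    else:
                        if (u, v) in set(map(tuple, atom_maps.get(rid, ()))):
                            pairs.append((u, v))
        edges[rid] = sorted(set(pairs))
    return ConnectivityGraph(
        mode=mode,
        edges=edges,
        currency_exclusions=currency_exclusions if mode == "compound" else frozenset(),
    )


def reachable_compounds(
    graph: ConnectivityGraph,
    included: Iterable[str],
    sources: Sequence[str],
) -> set[str]:
    """BFS closure of the sources over the included reactions' edges."""
    adj = graph.adjacency(included)
    seen = set(sources)
    frontier = list(sources)
    while frontier:
        u = frontier.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                frontier.append(v)
    return seen


@dataclass
class ModelDraft:
    """Reconstruction result: per-reaction inclusion status and direction.

    Status is ``scored`` (above-threshold, connected), ``gap-fill``
    (below-threshold, added to connect a scored reaction) or ``orphan``
    (above-threshold, retained but unconnected).
    """

    status: dict[str, str] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    sources: tuple[str, ...] = ()
    params: ReconstructionParams | None = None

    @property
    def included(self) -> list[str]:
        return sorted(self.status)

    def ids_with_status(self, status: str) -> list[str]:
        return sorted(r for r, s in self.status.items() if s == status)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sources": list(self.sources),
            "params": {
                "alpha": self.params.alpha if self.params else None,
                "beta": self.params.beta if self.params else None,
                "beta_mode": self.params.beta_mode if self.params else None,
            },
            "reactions": {
                rid: {
                    "status": self.status[rid],
                    "direction": self.directions.get(rid, "bidirectional"),
                    "score": self.scores.get(rid),
                }
                for rid in self.included
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelDraft":
        payload = json.loads(Path(path).read_text())
        draft = cls(sources=tuple(payload.get("sources", ())))
        for rid, info in payload["reactions"].items():
            draft.status[rid] = info["status"]
            draft.directions[rid] = info.get("direction", "bidirectional")
            if info.get("score") is not None:
                draft.scores[rid] = info["score"]
        return draft


def _connection_sides(rxn: UnifiedReaction) -> list[frozenset[str]]:
    """Substrate sets whose reachability would connect the reaction."""
    sides = []
    for forward in _orientations(rxn.direction):
        side = rxn.equation.substrates if forward else rxn.equation.products
        sides.append(frozenset(side))
    return sides


def _needed_substrates(
    rxn: UnifiedReaction, graph: ConnectivityGraph, reached: set[str]
) -> frozenset[str] | None:
    """Unreached substrates of the easiest permitted orientation.

    Returns an empty set when already connected, or ``None``-like best
    side otherwise.  Currency metabolites never need connecting.
    """
    best: frozenset[str] | None = None
    for side in _connection_sides(rxn):
        need = frozenset(
            s for s in side if s not in reached and s not in graph.currency_exclusions
        )
        if not need:
            return frozenset()
        if best is None or len(need) < len(best):
            best = need
    return best if best is not None else frozenset()


def gap_fill(
    target: UnifiedReaction,
    included: set[str],
    reached: set[str],
    graph: ConnectivityGraph,
    params: ReconstructionParams,
    database: ReactionDatabase,
    scores: Mapping[str, float],
) -> list[str] | None:
    """Cheapest reaction set connecting ``target``, or None on failure.

    Cost of a candidate reaction is ``1 - score``; at most ``beta``
    sub-threshold reactions may be used (``beta_mode="count"``), or the
    gap set's total cost is capped by beta (``beta_mode="cost"``).

    While the candidate pool is small the search enumerates subsets in
    ascending cost order and is exact; larger pools fall back to a
    per-substrate uniform-cost search over (compound, budget-used)
    states, which is exact for single-substrate gaps.
    """
    need = _needed_substrates(target, graph, reached)
    if not need:
        return []
    candidates = sorted(
        rid
        for rid in database.reactions
        if rid not in included and rid != target.id and graph.edges.get(rid)
    )
    if len(candidates) <= params.exact_gap_limit:
        return _gap_fill_exact(
            target, need, included, graph, params, scores, candidates
        )
    return _gap_fill_dijkstra(
        target, need, included, reached, graph, params, scores
    )


def _episode_ok(
    gap_set: Sequence[str], params: ReconstructionParams, scores: Mapping[str, float]
) -> bool:
    sub = [r for r in gap_set if scores.get(r, 0.0) < params.alpha]
    if params.beta_mode == "count":
        return len(sub) <= params.beta
    return sum(1.0 - scores.get(r, 0.0) for r in gap_set) <= params.beta + 1e-12


def _gap_fill_exact(
    target: UnifiedReaction,
    need: frozenset[str],
    included: set[str],
    graph: ConnectivityGraph,
    params: ReconstructionParams,
    scores: Mapping[str, float],
    candidates: list[str],
) -> list[str] | None:
    cost = {rid: 1.0 - scores.get(rid, 0.0) for rid in candidates}
    best: tuple[float, int, tuple[str, ...]] | None = None
    base = list(included)
    for k in range(0, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            total = sum(cost[r] for r in combo)
            if best is not None and (total, len(combo), combo) >= best:
                continue
            if not _episode_ok(combo, params, scores):
                continue
            reached = reachable_compounds(graph, base + list(combo), params.sources)
            if all(s in reached for s in need):
                best = (total, len(combo), combo)
    if best is None:
        return None
    return list(best[2])


def _gap_fill_dijkstra(
    target: UnifiedReaction,
    need: frozenset[str],
    included: set[str],
    reached: set[str],
    graph: ConnectivityGraph,
    params: ReconstructionParams,
    scores: Mapping[str, float],
) -> list[str] | None:
    """Per-substrate uniform-cost search over (compound, #sub-threshold)."""
    # reaction-labelled in-edges: v -> [(u, rid)]
    in_edges: dict[str, list[tuple[str, str]]] = {}
    for rid, pairs in graph.edges.items():
        if rid == target.id:
            continue
        for u, v in pairs:
            in_edges.setdefault(v, []).append((u, rid))

    union: set[str] = set()
    for goal in sorted(need):
        # Dijkstra from the reached frontier towards goal (search reversed).
        start = [(0.0, 0, goal, ())]
        seen: dict[tuple[str, int], float] = {}
        found: tuple | None = None
        while start:
            cost, used, node, path = heapq.heappop(start)
            if node in reached:
                found = (cost, path)
                break
            key = (node, used)
            if seen.get(key, float("inf")) <= cost:
                continue
            seen[key] = cost
            for u, rid in in_edges.get(node, ()):
                if rid in included or rid in union:
                    step_cost, step_used = 0.0, 0
                else:
                    step_cost = 1.0 - scores.get(rid, 0.0)
                    step_used = 1 if scores.get(rid, 0.0) < params.alpha else 0
                nxt_used = used + step_used
                if params.beta_mode == "count" and nxt_used > params.beta:
                    continue
                nxt_cost = cost + (0.0 if rid in path else step_cost)
                if params.beta_mode == "cost" and nxt_cost > params.beta + 1e-12:
                    continue
                heapq.heappush(
                    start,
                    (nxt_cost, nxt_used, u, path + ((rid,) if rid not in path else ())),
                )
        if found is None:
            return None
        union.update(r for r in found[1] if r not in included)
    if not _episode_ok(sorted(union), params, scores):
        return None
    return sorted(union)


def reconstruct(
    scored: Mapping[str, float],
    database: ReactionDatabase,
    graph: ConnectivityGraph,
    params: ReconstructionParams,
) -> ModelDraft:
    """Greedy gapless reconstruction.

    Candidates with score >= alpha are processed best-first (ties break
    lexicographically on reaction id).  Each is connected directly, via
    gap-filling, or retained as an orphan; no reaction below alpha ever
    enters except with gap-fill status.  Identical inputs always yield
    identical drafts.
    """
    if not params.sources and scored:
        raise ValueError("sources must be non-empty")
    for rid, s in scored.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score out of [0, 1] for {rid}: {s}")

    draft = ModelDraft(sources=params.sources, params=params)
    candidates = sorted(
        (rid for rid, s in scored.items() if s >= params.alpha and rid in database.reactions),
        key=lambda rid: (-scored[rid], rid),
    )
    included: set[str] = set()
    reached = reachable_compounds(graph, included, params.sources)

    def admit(rid: str, status: str) -> None:
        rxn = database.reactions[rid]
        draft.status[rid] = status
        draft.directions[rid] = rxn.direction
        draft.scores[rid] = scored.get(rid, 0.0)
        included.add(rid)

    for rid in candidates:
        rxn = database.reactions[rid]
        need = _needed_substrates(rxn, graph, reached)
        if not need:
            admit(rid, "scored")
        else:
            gap = gap_fill(rxn, included, reached, graph, params, database, scored)
            if gap is None:
                admit(rid, "orphan")
                # orphan edges must not extend reachability
                included.discard(rid)
                continue
            for gid in gap:
                admit(gid, "gap-fill" if scored.get(gid, 0.0) < params.alpha else "scored")
            admit(rid, "scored")
        reached = reachable_compounds(graph, included, params.sources)

    return draft


def dead_end_metrics(
    draft: ModelDraft,
    database: ReactionDatabase,
    exchanges: Iterable[str] = (),
) -> dict[str, float]:
    """Dead-end and gap-filling statistics of a finalized draft.

    A metabolite is dead-end when it cannot be both produced and
    consumed by the model's reactions in their permitted directions
    (an exchange for it counts as both).  A reaction is dead-end when it
    involves a dead-end metabolite.  All three metrics are percentages.
    """
    exchanges = set(exchanges)
    producible: set[str] = set(exchanges)
    consumable: set[str] = set(exchanges)
    mets: set[str] = set()
    for rid in draft.status:
        rxn = database.reactions[rid]
        mets |= rxn.equation.compound_ids
        for forward in _orientations(draft.directions.get(rid, rxn.direction)):
            subs = rxn.equation.substrates if forward else rxn.equation.products
            prods = rxn.equation.products if forward else rxn.equation.substrates
            consumable |= set(subs)
            producible |= set(prods)
    dead_mets = {m for m in mets if not (m in producible and m in consumable)}
    dead_rxns = {
        rid
        for rid in draft.status
        if database.reactions[rid].equation.compound_ids & dead_mets
    }
    n_rxn = len(draft.status)
    n_met = len(mets)
    n_gap = sum(1 for s in draft.status.values() if s == "gap-fill")
    return {
        "dead_end_reaction_pct": 100.0 * len(dead_rxns) / n_rxn if n_rxn else 0.0,
        "dead_end_metabolite_pct": 100.0 * len(dead_mets) / n_met if n_met else 0.0,
        "gap_fill_pct": 100.0 * n_gap / n_rxn if n_rxn else 0.0,
    }
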