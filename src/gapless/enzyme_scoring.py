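"""Max-rule combination of homology evidence into reaction scores.

Each enzyme (E.C. number) carries two probability-scale evidence values
per species, one from BLAST sequence similarity and one from GTG
domain-context similarity.  The combined enzyme score is the maximum of
the two: either line of evidence alone suffices to keep an enzyme (a
mean rule would reject enzymes whose closest GTG match is merely
phylogenetically distant).  A reaction annotated with several enzymes
takes the highest enzyme score.

Reactions coupled to gene evidence but lacking a real E.C. class get a
deterministic pseudo-E.C. in the reserved ``7.x.x.x`` format so that the
gene-to-reaction coupling survives the scoring step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "EvidenceRecord",
    "ScoredReaction",
    "combine_evidence",
    "ec_score_table",
    "score_reaction",
    "PseudoEcAssigner",
    "load_evidence_table",
    "write_scores",
    "load_scores",
    "smooth_scores_along_tree",
]


def _check_prob(value: float, label: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{label} out of [0, 1]: {value}")
    return float(value)


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-species, per-E.C. evidence probabilities (missing = 0)."""

    species: str
    ec: str
    blast_score: float
    gtg_score: float

    def __post_init__(self) -> None:
        _check_prob(self.blast_score, "blast_score")
        _check_prob(self.gtg_score, "gtg_score")


@dataclass(frozen=True)
class ScoredReaction:
    reaction_id: str
    species: str
    score: float
    supporting_ec: str | None

    def __post_init__(self) -> None:
        _check_prob(self.score, "score")


def combine_evidence(record: EvidenceRecord) -> float:
    """Combined enzyme score: max of the BLAST and GTG probabilities."""
    return max(record.blast_score, record.gtg_score)


def ec_score_table(
    records: Iterable[EvidenceRecord], species: str
) -> dict[str, float]:
    """Per-E.C. combined scores for one species.

    Duplicate rows for the same E.C. are merged by max, so the result is
    invariant to the ordering of evidence rows.
    """
    out: dict[str, float] = {}
    for rec in records:
        if rec.species != species:
            continue
        score = combine_evidence(rec)
        out[rec.ec] = max(out.get(rec.ec, 0.0), score)
    return out


def score_reaction(
    reaction_id: str,
    ec_numbers: Sequence[str],
    ec_scores: Mapping[str, float],
    species: str = "",
) -> ScoredReaction:
    """Score a reaction as the maximum over its annotated enzymes.

    E.C. numbers absent from the score table contribute 0 (missing
    evidence); ties break on the lexicographically first E.C. so the
    supporting enzyme is deterministic.
    """
    if not ec_numbers:
        raise ValueError(f"reaction {reaction_id} has no E.C. annotations")
    best_score, best_ec = 0.0, None
    for ec in sorted(ec_numbers):
        score = _check_prob(ec_scores.get(ec, 0.0), f"score for {ec}")
        if score > best_score:
            best_score, best_ec = score, ec
    return ScoredReaction(reaction_id, species, best_score, best_ec)


class PseudoEcAssigner:
    """Deterministic pseudo-E.C. ids (``7.a.b.c``) for gene-only reactions.

    Identifiers are assigned in first-come order and are stable across
    runs for the same input sequence; the same reaction id always
    receives the same pseudo-E.C. within one assigner.
    """

    def __init__(self, start: tuple[int, int, int] = (1, 1, 1), base: int = 100):
        self._assigned: dict[str, str] = {}
        self._counter = 0
        self._start = start
        self._base = base

    def assign(self, reaction_id: str) -> str:
        if reaction_id in self._assigned:
            return self._assigned[reaction_id]
        n = self._counter
        self._counter += 1
        a0, b0, c0 = self._start
        c = c0 + n % self._base
        b = b0 + (n // self._base) % self._base
        a = a0 + n // (self._base * self._base)
        ec = f"7.{a}.{b}.{c}"
        self._assigned[reaction_id] = ec
        return ec

    @property
    def assignments(self) -> dict[str, str]:
        return dict(self._assigned)


def load_evidence_table(path: str | Path) -> list[EvidenceRecord]:
    """Read an evidence TSV (species, ec, blast_score, gtg_score)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                EvidenceRecord(
                    species=row["species"],
                    ec=row["ec"],
                    blast_score=float(row.get("blast_score") or 0.0),
                    gtg_score=float(row.get("gtg_score") or 0.0),
                )
            )
    return out


def write_scores(scores: Iterable[ScoredReaction], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["species", "reaction_id", "score", "supporting_ec"])
        for s in scores:
            w.writerow([s.species, s.reaction_id, repr(s.score), s.supporting_ec or ""])


def load_scores(path: str | Path) -> list[ScoredReaction]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ScoredReaction(
                    reaction_id=row["reaction_id"],
                    species=row["species"],
                    score=float(row["score"]),
                    supporting_ec=row.get("supporting_ec") or None,
                )
            )
    return out


def smooth_scores_along_tree(
    species_scores: Mapping[str, Mapping[str, float]],
    parent: Mapping[str, str],
    weight: float = 0.25,
) -> dict[str, dict[str, float]]:
    """Optional linear blending of per-species E.C. scores along a tree.

    Each species' score for an enzyme is blended with its parent's:
    ``(1 - weight) * own + weight * parent``.  This is a simple
    experimental smoother for synthetic-fixture studies; it is NOT part
    of the production scoring path, which consumes pre-calibrated
    probabilities as-is.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    out: dict[str, dict[str, float]] = {}
    for species, scores in species_scores.items():
        if species not in parent:  # roots keep their own scores
            out[species] = dict(scores)
            continue
        parent_scores = species_scores.get(parent[species], {})
        ecs = set(scores) | set(parent_scores)
        out[species] = {
            ec: (1 - weight) * scores.get(ec, 0.0)
            + weight * parent_scores.get(ec, 0.0)
            for ec in ecs
        }
    return out
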