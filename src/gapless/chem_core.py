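"""Molecular-formula arithmetic, electron accounting and reaction balancing.

Charge imbalance in reaction databases is handled by the
electron-replacement convention: instead of balancing hydrogen atoms and
charge separately, hydrogen is excluded from the per-element check and
each compound is assigned its total electron count
(``sum(atomic_number * count) - charge``).  A reaction is *balanced* when
every element other than hydrogen and the total electron count are
conserved exactly.  Protons are zero-electron, zero-element species under
this convention and therefore never unbalance anything.

All balance arithmetic uses exact rationals (:class:`fractions.Fraction`);
floats appear only at serialization boundaries.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping

from rdkit import Chem

__all__ = [
    "FormulaError",
    "UnresolvableFormulaError",
    "RebalanceError",
    "Formula",
    "CompoundRecord",
    "ReactionEquation",
    "BalanceStatus",
    "BalanceReport",
    "parse_formula",
    "electron_count",
    "molar_mass",
    "check_balance",
    "rebalance",
    "parse_equation",
    "format_equation",
]

_PERIODIC = Chem.GetPeriodicTable()

#: Symbols that denote an undefined group of atoms.  Formulas containing
#: them are flagged unresolvable and excluded from balance checking.
GENERIC_SYMBOLS = frozenset({"R", "*", "X"})

_TOKEN = re.compile(r"([A-Z][a-z]?|\*)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


class UnresolvableFormulaError(FormulaError):
    """Raised when an operation needs atom counts a generic formula lacks."""


class RebalanceError(ValueError):
    """Raised when no coefficient/water repair balances a reaction."""


def atomic_number(symbol: str) -> int:
    """Atomic number of an element symbol, via the periodic table."""
    try:
        z = _PERIODIC.GetAtomicNumber(symbol)
    except Exception:
        raise FormulaError(f"unknown element symbol: {symbol!r}") from None
    if z <= 0:
        raise FormulaError(f"unknown element symbol: {symbol!r}")
    return z


@dataclass(frozen=True)
class Formula:
    """An elemental formula as a map element-symbol -> atom count.

    ``generic`` lists undefined-group symbols ("R", "*") found in the
    source formula; a formula with generic groups is *unresolvable* and
    must never silently enter balance arithmetic.
    """

    element_counts: Mapping[str, int]
    generic: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for sym, n in self.element_counts.items():
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
            atomic_number(sym)  # rejects unknown symbols
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    @property
    def resolvable(self) -> bool:
        return not self.generic

    def __getitem__(self, symbol: str) -> int:
        return self.element_counts.get(symbol, 0)

    def __iter__(self):
        return iter(self.element_counts)

    def merged(self, other: "Formula") -> "Formula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return Formula(counts, self.generic | other.generic)

    def to_hill(self) -> str:
        """Serialize in Hill order (C, H, then alphabetical)."""
        counts = self.element_counts
        order: list[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
            order.extend(sorted(s for s in counts if s not in ("C", "H")))
        else:
            order.extend(sorted(counts))
        parts = []
        for sym in order:
            n = counts[sym]
            if n == 0:
                continue
            parts.append(sym if n == 1 else f"{sym}{n}")
        parts.extend(sorted(self.generic))
        return "".join(parts) or ""


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style elemental formula without nesting.

    Generic group symbols ("R", "*") are accepted but mark the formula
    unresolvable.  Any other unparsable token raises
    :class:`FormulaError` carrying the offending token.

    >>> parse_formula("C5H11NO2").element_counts
    {'C': 5, 'H': 11, 'N': 1, 'O': 2}
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    generic: set[str] = set()
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise FormulaError(f"unparsable token at {text[pos:]!r} in {text!r}")
        sym, digits = m.groups()
        n = int(digits) if digits else 1
        if sym in GENERIC_SYMBOLS:
            generic.add(sym)
        else:
            try:
                atomic_number(sym)
            except FormulaError:
                # "Co" vs "CO": retry as single-letter element + rest
                if len(sym) == 2 and sym[1].islower():
                    raise FormulaError(
                        f"unparsable token {sym!r} in {text!r}"
                    ) from None
                raise
            counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return Formula(counts, frozenset(generic))


def electron_count(formula: Formula, charge: int = 0) -> int:
    """Total electrons of a species: sum(Z * count) - charge.

    A bare proton (formula H, charge +1) counts zero electrons, which is
    what makes the electron-replacement convention proton-safe.
    """
    if not formula.resolvable:
        raise UnresolvableFormulaError(
            f"generic groups {sorted(formula.generic)} have no electron count"
        )
    total = sum(atomic_number(sym) * n for sym, n in formula.element_counts.items())
    return total - charge


def molar_mass(formula: Formula) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    if not formula.resolvable:
        raise UnresolvableFormulaError("generic formula has no molar mass")
    return sum(
        _PERIODIC.GetAtomicWeight(sym) * n
        for sym, n in formula.element_counts.items()
    )


@dataclass
class CompoundRecord:
    """A metabolite with unified identifier and (optional) composition.

    A compound without a resolvable formula cannot take part in balance
    checking; reactions touching it are reported unresolvable rather
    than crashed on.
    """

    id: str
    formula: Formula | None = None
    charge: int = 0
    names: list[str] = field(default_factory=list)
    xrefs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")

    @property
    def balanceable(self) -> bool:
        return self.formula is not None and self.formula.resolvable


Coefficients = Mapping[str, Fraction]


def _as_fractions(side: Mapping) -> dict[str, Fraction]:
    out = {}
    for cid, coeff in side.items():
        f = Fraction(coeff)
        if f <= 0:
            raise ValueError(f"non-positive coefficient {coeff} for {cid}")
        out[cid] = f
    return out


@dataclass(frozen=True)
class ReactionEquation:
    """Stoichiometry as positive rational coefficients per side."""

    substrates: Coefficients
    products: Coefficients

    def __post_init__(self) -> None:
        subs = _as_fractions(self.substrates)
        prods = _as_fractions(self.products)
        overlap = set(subs) & set(prods)
        if overlap:
            raise ValueError(f"compounds on both sides: {sorted(overlap)}")
        object.__setattr__(self, "substrates", subs)
        object.__setattr__(self, "products", prods)

    @property
    def compound_ids(self) -> frozenset[str]:
        return frozenset(self.substrates) | frozenset(self.products)

    def reversed(self) -> "ReactionEquation":
        return ReactionEquation(self.products, self.substrates)

    def signed_coefficients(self) -> dict[str, Fraction]:
        """Products positive, substrates negative."""
        out = {cid: -c for cid, c in self.substrates.items()}
        for cid, c in self.products.items():
            out[cid] = out.get(cid, Fraction(0)) + c
        return out

    def __str__(self) -> str:
        return format_equation(self)


class BalanceStatus(str, Enum):
    BALANCED = "balanced"
    ELEMENT_IMBALANCED = "element_imbalanced"
    ELECTRON_IMBALANCED = "electron_imbalanced"
    UNRESOLVABLE = "unresolvable"


@dataclass(frozen=True)
class BalanceReport:
    """Products-minus-substrates deltas; hydrogen folded into electrons."""

    per_element_delta: Mapping[str, Fraction]
    electron_delta: Fraction
    status: BalanceStatus
    unresolvable_compounds: tuple[str, ...] = ()

    @property
    def balanced(self) -> bool:
        return self.status is BalanceStatus.BALANCED


def _reaction_deltas(
    reaction: ReactionEquation, compounds: Mapping[str, CompoundRecord]
) -> tuple[dict[str, Fraction], Fraction]:
    """(per-element delta excluding H, electron delta), exact rationals."""
    element_delta: dict[str, Fraction] = {}
    electron_delta = Fraction(0)
    for cid, coeff in reaction.signed_coefficients().items():
        rec = compounds[cid]
        assert rec.formula is not None
        for sym, n in rec.formula.element_counts.items():
            if sym == "H":
                continue
            element_delta[sym] = element_delta.get(sym, Fraction(0)) + coeff * n
        electron_delta += coeff * electron_count(rec.formula, rec.charge)
    return {s: d for s, d in element_delta.items() if d != 0}, electron_delta


def check_balance(
    reaction: ReactionEquation, compounds: Mapping[str, CompoundRecord]
) -> BalanceReport:
    """Check element (ex-hydrogen) and electron conservation exactly.

    Compounds lacking a resolvable formula make the report
    ``unresolvable`` and are listed; they never raise.
    """
    missing = [cid for cid in sorted(reaction.compound_ids) if cid not in compounds]
    if missing:
        raise KeyError(f"compounds absent from index: {missing}")
    bad = [
        cid
        for cid in sorted(reaction.compound_ids)
        if not compounds[cid].balanceable
    ]
    if bad:
        return BalanceReport(
            {}, Fraction(0), BalanceStatus.UNRESOLVABLE, tuple(bad)
        )
    element_delta, electron_delta = _reaction_deltas(reaction, compounds)
    if element_delta:
        status = BalanceStatus.ELEMENT_IMBALANCED
    elif electron_delta != 0:
        status = BalanceStatus.ELECTRON_IMBALANCED
    else:
        status = BalanceStatus.BALANCED
    return BalanceReport(element_delta, electron_delta, status)


def _multipliers(max_coeff: int) -> list[Fraction]:
    vals = {
        Fraction(p, q)
        for p in range(1, max_coeff + 1)
        for q in range(1, max_coeff + 1)
    }
    return sorted(vals)


def rebalance(
    reaction: ReactionEquation,
    compounds: Mapping[str, CompoundRecord],
    max_coeff: int = 6,
    water_id: str = "C00001",
) -> ReactionEquation:
    """Repair an imbalanced reaction by rescaling coefficients and water.

    The only permitted edits are (i) rescaling each coefficient by a
    positive rational p/q with p, q <= ``max_coeff`` and (ii) adding
    water to either side.  Among feasible repairs the one minimizing the
    total coefficient change is returned; ties break on fewest water
    molecules added, then lexicographically on the coefficient vector.

    Water is never searched: once multipliers are fixed, the oxygen
    delta dictates the signed water amount and the electron delta must
    agree with it (10 electrons per water), so each multiplier
    assignment is feasible or not in O(1).

    Raises :class:`RebalanceError` when no repair exists within
    ``max_coeff`` — such reactions are rejected from the database.
    """
    if max_coeff < 1:
        raise ValueError("max_coeff must be >= 1")
    report = check_balance(reaction, compounds)
    if report.status is BalanceStatus.UNRESOLVABLE:
        raise RebalanceError(
            f"unresolvable compounds: {report.unresolvable_compounds}"
        )
    if report.balanced:
        return reaction
    if water_id not in compounds:
        raise KeyError(f"water compound {water_id!r} absent from index")

    # Signed original coefficients with water split out as a free variable.
    orig = reaction.signed_coefficients()
    w0 = orig.pop(water_id, Fraction(0))
    items = sorted(orig.items())  # deterministic order
    ids = [cid for cid, _ in items]
    coeffs = [c for _, c in items]

    # Per-compound element/electron contributions (signed by side).
    contribs: list[tuple[dict[str, Fraction], Fraction]] = []
    for cid, c in items:
        rec = compounds[cid]
        assert rec.formula is not None
        elems = {
            s: Fraction(n) * c
            for s, n in rec.formula.element_counts.items()
            if s != "H"
        }
        contribs.append((elems, Fraction(electron_count(rec.formula, rec.charge)) * c))

    mults = _multipliers(max_coeff)
    best: tuple | None = None  # (cost, water_added, coeff_vector, w_final)

    def candidate(multvec: tuple[Fraction, ...]) -> None:
        nonlocal best
        elem_delta: dict[str, Fraction] = {}
        e_delta = Fraction(0)
        for m, (elems, electrons) in zip(multvec, contribs):
            for s, d in elems.items():
                elem_delta[s] = elem_delta.get(s, Fraction(0)) + m * d
            e_delta += m * electrons
        d_o = elem_delta.get("O", Fraction(0))
        if any(d != 0 for s, d in elem_delta.items() if s != "O"):
            return
        if e_delta != 10 * d_o:
            return
        # the final signed water amount (product side positive) is fixed
        # by the oxygen deficit of the water-free equation
        w_final = -d_o
        water_added = abs(w_final - w0)
        if water_added > max_coeff:
            return
        new_coeffs = tuple(m * c for m, c in zip(multvec, coeffs))
        cost = sum(abs(n - o) for n, o in zip(new_coeffs, coeffs)) + water_added
        key = (cost, water_added, new_coeffs)
        if best is None or key < (best[0], best[1], best[2]):
            best = (cost, water_added, new_coeffs, w_final)

    n = len(items)
    # Branch and bound: multipliers tried in ascending per-position cost;
    # prune once the accumulated cost cannot beat the incumbent.
    order = [
        sorted(mults, key=lambda m: (abs(m - 1) * coeffs[i], m)) for i in range(n)
    ]

    def recurse(i: int, acc_cost: Fraction, multvec: list[Fraction]) -> None:
        if best is not None and acc_cost >= best[0] + 1:
            return
        if i == n:
            candidate(tuple(multvec))
            return
        for m in order[i]:
            step = abs(m - 1) * coeffs[i]
            if best is not None and acc_cost + step > best[0]:
                break  # ascending order: nothing cheaper follows
            multvec.append(m)
            recurse(i + 1, acc_cost + step, multvec)
            multvec.pop()

    recurse(0, Fraction(0), [])

    if best is None:
        raise RebalanceError(
            f"no balancing repair within max_coeff={max_coeff} for {reaction}"
        )
    _, _, new_coeffs, w_final = best
    subs: dict[str, Fraction] = {}
    prods: dict[str, Fraction] = {}
    for cid, c in zip(ids, new_coeffs):
        if cid in reaction.substrates:
            subs[cid] = -c  # signed coefficients carry the side
        else:
            prods[cid] = c
    if w_final > 0:
        prods[water_id] = w_final
    elif w_final < 0:
        subs[water_id] = -w_final
    repaired = ReactionEquation(subs, prods)
    assert check_balance(repaired, compounds).balanced
    return repaired


# -- textual equation dialect -------------------------------------------------

_ARROWS = {"<=>": "bidirectional", "=>": "forward", "<=": "backward"}


def parse_equation(text: str) -> tuple[ReactionEquation, str]:
    """Parse ``"2 C00031 + C00001 <=> C00095"`` into (equation, direction).

    Coefficients are optional and may be integers, fractions ("3/2") or
    decimals; direction markers are ``<=>``, ``=>`` and ``<=``.
    """
    arrow = None
    for marker in ("<=>", "=>", "<="):
        if marker in text:
            arrow = marker
            break
    if arrow is None:
        raise ValueError(f"no direction marker in equation: {text!r}")
    left_text, right_text = text.split(arrow, 1)

    def parse_side(side: str) -> dict[str, Fraction]:
        out: dict[str, Fraction] = {}
        side = side.strip()
        if not side:
            return out
        for term in side.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                coeff, cid = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, cid = Fraction(parts[0]), parts[1]
            else:
                raise ValueError(f"bad term {term!r} in {text!r}")
            out[cid] = out.get(cid, Fraction(0)) + coeff
        return out

    left, right = parse_side(left_text), parse_side(right_text)
    return ReactionEquation(left, right), _ARROWS[arrow]


def _coeff_str(c: Fraction) -> str:
    if c == 1:
        return ""
    if c.denominator == 1:
        return f"{c.numerator} "
    return f"{c} "


def format_equation(eq: ReactionEquation, direction: str = "bidirectional") -> str:
    marker = {v: k for k, v in _ARROWS.items()}[direction]
    left = " + ".join(f"{_coeff_str(c)}{cid}" for cid, c in sorted(eq.substrates.items()))
    right = " + ".join(f"{_coeff_str(c)}{cid}" for cid, c in sorted(eq.products.items()))
    return f"{left} {marker} {right}"
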