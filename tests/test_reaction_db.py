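"""Compound mapping, deduplication, representatives, directions, policies."""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest

from gapless.chem_core import CompoundRecord, ReactionEquation, parse_formula
from gapless.reaction_db import (
    DatabaseConfig,
    SourceReaction,
    UnifiedCompoundIndex,
    apply_lipid_policy,
    assign_direction,
    build_database,
    canonical_key,
    map_compound,
    mint_cluster_id,
    select_representative,
)


@pytest.fixture()
def unified_index():
    records = [
        CompoundRecord(
            "C00031",
            parse_formula("C6H12O6"),
            0,
            names=["D-glucose"],
            xrefs={"chebi": "CHEBI:4167", "inchi": "InChI=glc"},
        ),
        CompoundRecord(
            "C00022", parse_formula("C3H4O3"), 0, names=["pyruvate"]
        ),
        CompoundRecord("C00001", parse_formula("H2O"), 0, names=["water"]),
        CompoundRecord("C00080", parse_formula("H"), 1, names=["proton"]),
        CompoundRecord("AMBI1", parse_formula("CH4"), 0, names=["twin"]),
        CompoundRecord("AMBI2", parse_formula("CH4O"), 0, names=["twin"]),
    ]
    return UnifiedCompoundIndex(records)


class TestMapCompound:
    def test_xref_match_preferred(self, unified_index):
        src = CompoundRecord("glc_src", xrefs={"kegg": "C00031"}, names=["twin"])
        entry = map_compound(src, unified_index)
        assert entry.unified_id == "C00031" and entry.method == "xref"

    def test_structure_match(self, unified_index):
        src = CompoundRecord("s1", xrefs={"inchi": "InChI=glc"})
        entry = map_compound(src, unified_index)
        assert entry.unified_id == "C00031" and entry.method == "structure"

    def test_unique_name_match(self, unified_index):
        src = CompoundRecord("s2", names=["Pyruvate"])
        entry = map_compound(src, unified_index)
        assert entry.unified_id == "C00022" and entry.method == "name-unique"

    def test_ambiguous_name_unmapped(self, unified_index):
        src = CompoundRecord("s3", names=["twin"])
        entry = map_compound(src, unified_index)
        assert entry.unified_id is None and entry.method == "unmapped"

    def test_cluster_id_minting_is_deterministic(self):
        a = mint_cluster_id(["N-carbamoylglycine"])
        b = mint_cluster_id(["n-carbamoylglycine"])  # case-insensitive
        assert a == b and a.startswith("Cluster")
        assert mint_cluster_id(["N-carbamoylglycine"], taken=[a]) != a


class TestCanonicalKey:
    def test_protons_ignored(self):
        with_h = ReactionEquation({"A": 1, "C00080": 1}, {"B": 1})
        without = ReactionEquation({"A": 1}, {"B": 1})
        assert canonical_key(with_h) == canonical_key(without)

    def test_side_swap_symmetric(self):
        fwd = ReactionEquation({"A": 1}, {"B": 1})
        rev = ReactionEquation({"B": 1}, {"A": 1})
        assert canonical_key(fwd) == canonical_key(rev)

    def test_coefficients_excluded(self):
        one = ReactionEquation({"A": 1}, {"B": 1})
        two = ReactionEquation({"A": 2}, {"B": 3})
        assert canonical_key(one) == canonical_key(two)

    def test_different_metabolite_sets_distinct(self):
        a = ReactionEquation({"A": 1, "C": 1}, {"B": 1})
        b = ReactionEquation({"A": 1}, {"B": 1})
        assert canonical_key(a) != canonical_key(b)


def _member(source, native_id, direction="unknown", ecs=()):
    eq = ReactionEquation({"C00031": 1}, {"C00022": 2})
    return SourceReaction(source, native_id, eq, list(ecs), direction)


class TestRepresentatives:
    def test_yeast_model_with_kegg_composite_id(self):
        members = [
            _member("KEGG", "R00086"),
            _member("YCM606", "r_0226", direction="forward"),
        ]
        rep = select_representative(members)
        assert rep.id == "r0226-YCM606-R00086"
        assert rep.representative_source == "YCM606"

    def test_kegg_beats_metacyc(self):
        members = [_member("MetaCyc", "RXN-1"), _member("KEGG", "R01234")]
        rep = select_representative(members)
        assert rep.representative_source == "KEGG" and rep.id == "R01234"

    def test_single_member_is_itself(self):
        rep = select_representative([_member("MetaCyc", "RXN-9")])
        assert rep.representative_source == "MetaCyc"

    def test_ec_lists_unioned(self):
        members = [
            _member("KEGG", "R1", ecs=["1.1.1.1"]),
            _member("iMA871", "r9", ecs=["2.2.2.2", "1.1.1.1"]),
        ]
        rep = select_representative(members)
        assert rep.ec_numbers == ["1.1.1.1", "2.2.2.2"]

    def test_priority_total_under_permutation(self):
        members = [
            _member("MetaCyc", "RXN-1"),
            _member("KEGG", "R00001"),
            _member("iSS884", "r_1"),
            _member("YCM606", "r_2"),
        ]
        ids = {
            select_representative(list(p)).id
            for p in itertools.permutations(members)
        }
        assert ids == {"r2-YCM606-R00001"}


class TestDirections:
    def test_agreeing_models(self):
        members = [
            _member("YCM606", "a", "forward"),
            _member("iMA871", "b", "forward"),
        ]
        assert assign_direction(members) == "forward"

    def test_conflict_becomes_bidirectional(self):
        members = [
            _member("YCM606", "a", "forward"),
            _member("iMA871", "b", "backward"),
        ]
        assert assign_direction(members) == "bidirectional"

    def test_public_sources_always_bidirectional(self):
        assert assign_direction([_member("KEGG", "R1", "forward")]) == "bidirectional"
        assert assign_direction([_member("MetaCyc", "M1")]) == "bidirectional"

    def test_model_direction_wins_over_public(self):
        members = [
            _member("KEGG", "R1", "forward"),
            _member("YCM606", "a", "backward"),
        ]
        assert assign_direction(members) == "backward"


class TestLipidPolicy:
    def _rxn(self, source):
        members = [_member(source, "rl")]
        return select_representative(members)

    def test_policy(self):
        config = DatabaseConfig(lipid_compounds=frozenset({"C00022"}))
        from_niger = self._rxn("iMA871")
        from_kegg = self._rxn("KEGG")
        kept, removed = apply_lipid_policy([from_niger, from_kegg], config)
        assert removed == [from_niger] and kept == [from_kegg]

    def test_non_lipid_retained(self):
        config = DatabaseConfig(lipid_compounds=frozenset({"NOPE"}))
        rxn = self._rxn("iMA871")
        kept, removed = apply_lipid_policy([rxn], config)
        assert kept == [rxn] and not removed


def _universe():
    return [
        CompoundRecord("C00031", parse_formula("C6H12O6"), 0, ["glucose"]),
        CompoundRecord("C00022", parse_formula("C3H4O3"), 0, ["pyruvate"]),
        CompoundRecord("C00469", parse_formula("C2H6O"), 0, ["ethanol"]),
        CompoundRecord("C00011", parse_formula("CO2"), 0, ["co2"]),
        CompoundRecord("C00001", parse_formula("H2O"), 0, ["water"]),
        CompoundRecord("C00033", parse_formula("C2H4O2"), 0, ["acetate"]),
        CompoundRecord("C00186", parse_formula("C3H6O3"), 0, ["lactate"]),
        CompoundRecord("KETENE", parse_formula("C2H2O"), 0, ["ketene"]),
    ]


class TestBuildDatabase:
    def test_dedupe_and_rejection_accounting(self):
        fermentation = ReactionEquation({"C00031": 1}, {"C00469": 2, "C00011": 2})
        unbalanceable = ReactionEquation({"C00031": 1}, {"C00469": 2})
        rxns = [
            SourceReaction("YCM606", "r_1", fermentation, direction="forward"),
            SourceReaction("KEGG", "R00001", fermentation),
            SourceReaction("KEGG", "R00002", unbalanceable),
        ]
        db = build_database(rxns, _universe())
        assert len(db.reactions) == 1
        assert [r["reason"] for r in db.rejected] == ["unbalanceable"]
        (rep,) = db.reactions.values()
        assert rep.id == "r1-YCM606-R00001"
        assert rep.direction == "forward"

    def test_water_repair_counts_as_balanced_representative(self):
        needs_water = ReactionEquation({"C00033": 1}, {"KETENE": 1})
        db = build_database(
            [SourceReaction("KEGG", "R00003", needs_water)], _universe()
        )
        (rep,) = db.reactions.values()
        assert rep.equation.products.get("C00001") == 1
        acct = db.accounting["KEGG"]
        assert acct["Representatives that balance"] == 1
        assert acct["% of balanced reactions"] == 0.0  # raw input did not balance

    def test_every_entry_balances(self):
        from gapless.chem_core import check_balance

        rxns = [
            SourceReaction(
                "KEGG",
                "R1",
                ReactionEquation({"C00031": 1}, {"C00469": 2, "C00011": 2}),
            ),
            SourceReaction(
                "KEGG", "R2", ReactionEquation({"C00033": 1}, {"KETENE": 1})
            ),
        ]
        db = build_database(rxns, _universe())
        for rxn in db.reactions.values():
            assert check_balance(rxn.equation, db.compounds).balanced

    def test_empty_input(self):
        db = build_database([], _universe())
        assert not db.reactions and not db.rejected

    def test_rebuild_is_idempotent(self):
        rxns = [
            SourceReaction(
                "YCM606",
                "r_1",
                ReactionEquation({"C00031": 1}, {"C00469": 2, "C00011": 2}),
                direction="forward",
            ),
            SourceReaction(
                "KEGG", "R9", ReactionEquation({"C00033": 1}, {"KETENE": 1})
            ),
        ]
        db1 = build_database(rxns, _universe())
        rebuilt_inputs = [
            SourceReaction(r.representative_source, r.id, r.equation, r.ec_numbers, r.direction)
            for r in db1.reactions.values()
        ]
        db2 = build_database(rebuilt_inputs, _universe())
        assert len(db2.reactions) == len(db1.reactions)
        assert {
            canonical_key(r.equation) for r in db2.reactions.values()
        } == {canonical_key(r.equation) for r in db1.reactions.values()}

    def test_input_order_never_changes_representatives(self):
        fermentation = ReactionEquation({"C00031": 1}, {"C00469": 2, "C00011": 2})
        rxns = [
            SourceReaction("MetaCyc", "RXN-5", fermentation),
            SourceReaction("KEGG", "R5", fermentation),
            SourceReaction("iMA871", "r_5", fermentation, direction="forward"),
        ]
        ids = set()
        for perm in itertools.permutations(rxns):
            db = build_database(list(perm), _universe())
            ids.add(next(iter(db.reactions)))
        assert ids == {"r5-iMA871-R5"}

    def test_accounting_identity(self):
        rxns = [
            SourceReaction(
                "KEGG", "R1", ReactionEquation({"C00031": 1}, {"C00469": 2, "C00011": 2})
            ),
            SourceReaction(
                "KEGG", "R2", ReactionEquation({"C00031": 1}, {"C00469": 2})
            ),
        ]
        db = build_database(rxns, _universe())
        acct = db.accounting["KEGG"]
        assert acct["Selected as representative"] >= acct["Representatives that balance"]

    def test_curation_close_and_flip(self):
        fermentation = ReactionEquation({"C00031": 1}, {"C00469": 2, "C00011": 2})
        pyr = ReactionEquation({"C00031": 1}, {"C00186": 2})
        rxns = [
            SourceReaction("YCM606", "r_1", fermentation, direction="forward"),
            SourceReaction("YCM606", "r_2", pyr, direction="forward"),
        ]
        curation = {"r1-YCM606": "close", "r2-YCM606": "backward"}
        db = build_database(rxns, _universe(), curation=curation)
        assert "r1-YCM606" not in db.reactions
        assert db.reactions["r2-YCM606"].direction == "backward"

    def test_roundtrip_through_directory(self, tmp_path):
        rxns = [
            SourceReaction(
                "YCM606",
                "r_1",
                ReactionEquation({"C00031": 1}, {"C00469": 2, "C00011": 2}),
                ["1.1.1.1"],
                "forward",
            )
        ]
        db = build_database(rxns, _universe())
        db.to_dir(tmp_path / "db")
        from gapless.reaction_db import ReactionDatabase

        back = ReactionDatabase.from_dir(tmp_path / "db")
        assert set(back.reactions) == set(db.reactions)
        (rep,) = back.reactions.values()
        assert rep.direction == "forward" and rep.ec_numbers == ["1.1.1.1"]
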