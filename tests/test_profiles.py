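"""Composition, linearity, loop contributions, identity and redundancy."""

import pytest

from abcompare.binding_site_profiles import (
    SEVEN_CLASSES,
    epitope_identity,
    epitope_linearity,
    framework_position_frequency,
    loop_contributions,
    redundancy_filter,
    seven_class_composition,
)
from abcompare.interaction_engine import binding_site, find_contacts, summarize_pairs
from abcompare.structure_model import Atom, Residue
from abcompare.synthetic_data import ComplexPlan, ContactSpec, make_complex


def _residues(numbers, chain="G", aa="ALA"):
    return [Residue(chain, n, aa, []) for n in numbers]


class TestSevenClasses:
    def test_partition_covers_all_twenty(self):
        members = "".join(SEVEN_CLASSES.values())
        assert len(members) == 20 and len(set(members)) == 20
        sizes = sorted(len(v) for v in SEVEN_CLASSES.values())
        assert sizes == [2, 2, 2, 2, 3, 3, 6]

    def test_example_fractions(self):
        comp = seven_class_composition(list("FWSR"))
        assert comp["aromatic"] == 0.5
        assert comp["hydroxyl"] == 0.25
        assert comp["basic"] == 0.25
        assert comp["aliphatic"] == 0.0

    def test_all_alanine(self):
        assert seven_class_composition(list("AAAA"))["aliphatic"] == 1.0

    def test_one_of_each_amino_acid(self):
        comp = seven_class_composition(list("ACDEFGHIKLMNPQRSTVWY"))
        expected = {
            "aliphatic": 6 / 20, "aromatic": 3 / 20, "sulfur": 2 / 20,
            "hydroxyl": 2 / 20, "basic": 3 / 20, "acidic": 2 / 20,
            "amine": 2 / 20,
        }
        assert comp.fractions == pytest.approx(expected)

    def test_fractions_sum_to_one(self):
        comp = seven_class_composition(list("KDYGMQ"))
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            seven_class_composition([])


class TestLinearity:
    @pytest.mark.parametrize(
        "numbers,count,pct",
        [
            ([10, 11, 12, 40], 3, 75.0),
            ([1, 2, 3, 4, 5], 5, 100.0),
            ([2, 4, 6, 8], 0, 0.0),
            ([7], 0, 0.0),
        ],
    )
    def test_enumerated_sets(self, numbers, count, pct):
        c, p = epitope_linearity(_residues(numbers))
        assert (c, p) == (count, pytest.approx(pct))

    def test_contiguous_runs_any_size(self):
        for n in range(2, 7):
            c, p = epitope_linearity(_residues(range(100, 100 + n)))
            assert c == n and p == 100.0

    def test_chain_breaks_adjacency(self):
        res = _residues([10], chain="A") + _residues([11], chain="B")
        assert epitope_linearity(res)[0] == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            epitope_linearity([])


class TestLoopContributions:
    def test_worked_example_standins(self, worked_example_standins):
        (ab, _), (sd, _) = worked_example_standins
        for cx, total, h3 in ((ab, 26, 6), (sd, 15, 9)):
            site = binding_site(cx, "interactions")
            pairs = summarize_pairs(find_contacts(cx))
            prof = loop_contributions(cx, site, pairs)
            assert prof.size == total
            assert prof.per_loop_residues["CDR-H3"] == h3

    def test_counts_are_consistent(self, worked_example_standins):
        for cx, _ in worked_example_standins:
            site = binding_site(cx, "interactions")
            pairs = summarize_pairs(find_contacts(cx))
            prof = loop_contributions(cx, site, pairs)
            assert sum(prof.per_loop_residues.values()) == prof.size
            assert 0.0 <= prof.cdr_fraction <= 1.0

    def test_loop_without_contacts_contributes_zero(self):
        plan = ComplexPlan(
            pdb_id="H2ONLY",
            contacts=[ContactSpec(56, 10, "vdw"), ContactSpec(57, 11, "vdw")],
        )
        cx, _ = make_complex(plan)
        site = binding_site(cx, "interactions")
        pairs = summarize_pairs(find_contacts(cx))
        prof = loop_contributions(cx, site, pairs)
        assert prof.per_loop_interactions["CDR-H3"] == 0
        assert prof.per_loop_interactions["CDR-H2"] == 2

    def test_framework_positions_recorded(self, worked_example_standins):
        (_, _), (sd, _) = worked_example_standins
        site = binding_site(sd, "interactions")
        pairs = summarize_pairs(find_contacts(sd))
        prof = loop_contributions(sd, site, pairs)
        assert prof.framework_positions == {("H", 66), ("H", 69)}


class TestFrameworkFrequency:
    def _profile(self, positions):
        return type("P", (), {"framework_positions": {("H", p) for p in positions}})

    def test_threshold_and_ranking(self):
        dataset = [(None, self._profile([66])) for _ in range(6)]
        dataset += [(None, self._profile([52])) for _ in range(2)]
        dataset += [(None, self._profile([])) for _ in range(2)]
        ranked = framework_position_frequency(dataset, threshold=0.10)
        assert ranked[0] == (("H", 66), pytest.approx(0.6))
        assert (("H", 52), pytest.approx(0.2)) == ranked[1]

    def test_absent_positions_not_reported(self):
        dataset = [(None, self._profile([66]))] + [(None, self._profile([]))] * 9
        ranked = framework_position_frequency(dataset, threshold=0.10)
        assert [pos for pos, _ in ranked] == [("H", 66)]
        below, = [f for _, f in ranked]
        assert below >= 0.10


class TestEpitopeIdentity:
    def test_identical_antigens_identical_epitopes(self):
        seq = "MKTAYIAKQR"
        assert epitope_identity({1, 2, 3}, seq, {1, 2, 3}, seq) == 1.0

    def test_disjoint_epitopes(self):
        seq = "MKTAYIAKQR"
        assert epitope_identity({1, 2}, seq, {5, 6}, seq) == 0.0

    def test_min_denominator_and_symmetry(self):
        seq = "MKDLL"
        a, b = {1, 2}, {1}
        assert epitope_identity(a, seq, b, seq) == 1.0
        assert epitope_identity(b, seq, a, seq) == 1.0

    def test_union_denominator(self):
        seq = "MKDLL"
        assert epitope_identity({1, 2}, seq, {1}, seq, denominator="union") == 0.5

    def test_alignment_handles_gaps(self):
        # same epitope motif shifted by an insertion
        a_seq, b_seq = "AAKDEAA", "AAXKDEAA"
        score = epitope_identity({2, 3, 4}, a_seq, {3, 4, 5}, b_seq)
        assert score == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            epitope_identity(set(), "AAA", {0}, "AAA")


class TestRedundancyFilter:
    def _cx(self, pdb_id, cdr3_aa="LEU", ag_start=10):
        contacts = [ContactSpec(105 + i, ag_start + i, "vdw") for i in range(3)]
        plan = ComplexPlan(pdb_id=pdb_id, contacts=contacts)
        cx, _ = make_complex(plan)
        return cx

    def test_identical_cdrs_identical_epitopes_collapse(self):
        a, b = self._cx("A"), self._cx("B")
        kept = redundancy_filter([a, b])
        assert len(kept) == 1

    def test_identical_cdrs_different_epitopes_both_kept(self):
        a = self._cx("A", ag_start=10)
        b = self._cx("B", ag_start=200)
        # different antigen sequence composition at the epitope
        for r, aa in zip(b.antigen["G"], ("TRP", "TYR", "PHE")):
            r.aa = aa
        kept = redundancy_filter([a, b])
        assert len(kept) == 2

    def test_distinct_cdrs_all_kept(self):
        complexes = []
        for pdb_id, aas in (("A", "LKW"), ("B", "DDD"), ("C", "YYY")):
            cx = self._cx(pdb_id)
            from abcompare.structure_model import AA_1TO3

            for r, aa in zip(cx.cdr_residues("CDR3", "heavy"), aas):
                r.aa = AA_1TO3[aa]
            complexes.append(cx)
        assert len(redundancy_filter(complexes)) == 3

    def test_idempotent(self):
        complexes = [self._cx("A"), self._cx("B"), self._cx("C", ag_start=50)]
        once = redundancy_filter(complexes)
        twice = redundancy_filter(once)
        assert [c.pdb_id for c in once] == [c.pdb_id for c in twice]
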