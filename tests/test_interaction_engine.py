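"""Contact detection, fingerprint typing and binding-site construction."""

import numpy as np
import pytest

from abcompare.interaction_engine import (
    INTERACTION_TYPES,
    binding_site,
    count_interactions,
    find_contacts,
    interactions_per_residue,
    subsample_interaction_stats,
    summarize_pairs,
    type_contact,
)
from abcompare.structure_model import Atom, Residue
from abcompare.synthetic_data import (
    BOND_MOTIFS,
    ComplexPlan,
    ContactSpec,
    make_complex,
    random_rotation,
    rigid_transform,
)
from conftest import random_atom_complex


def _pair(ab_aa, ab_atom, ab_el, ag_aa, ag_atom, ag_el, d):
    ab_res = Residue("H", 1, ab_aa, [Atom(ab_atom, ab_el, [0, 0, 0])])
    ag_res = Residue("G", 1, ag_aa, [Atom(ag_atom, ag_el, [d, 0, 0])])
    return ab_res.atoms[0], ag_res.atoms[0], d, ab_res, ag_res


class TestTypeContact:
    @pytest.mark.parametrize(
        "args,expected",
        [
            # apolar C-C at 3.30 <= 3.40 + 0.1: van der Waals and hydrophobic
            (("LEU", "CD1", "C", "LEU", "CD1", "C", 3.30), {"vdw", "hydrophobic"}),
            # backbone N donor to backbone O acceptor at 2.9 A
            (("GLY", "N", "N", "GLY", "O", "O", 2.90), {"vdw", "hbond"}),
            # opposite formal charges within 4.0 A
            (("LYS", "NZ", "N", "GLU", "OE1", "O", 3.50), {"proximal", "ionic", "hbond"}),
            (("LYS", "NZ", "N", "GLU", "OE1", "O", 3.80), {"proximal", "ionic"}),
            # deep overlap is a steric clash
            (("LEU", "CD1", "C", "ASN", "OD1", "O", 2.50), {"clash"}),
            # near-bonding distance is covalent
            (("CYS", "SG", "S", "CYS", "SG", "S", 2.05), {"covalent"}),
            # within cutoff but nothing structural or specific
            (("ALA", "CB", "C", "ASN", "OD1", "O", 4.00), {"proximal"}),
        ],
    )
    def test_fingerprints(self, args, expected):
        assert type_contact(*_pair(*args)) == frozenset(expected)

    def test_exactly_one_structural_type(self):
        rng = np.random.default_rng(0)
        structural = {"covalent", "clash", "vdw", "proximal"}
        for _ in range(50):
            d = float(rng.uniform(1.0, 4.5))
            fp = type_contact(*_pair("LEU", "CD1", "C", "SER", "OG", "O", d))
            assert len(fp & structural) == 1

    def test_unknown_element_fatal(self):
        with pytest.raises(ValueError, match="XX"):
            type_contact(Atom("Q", "XX", [0, 0, 0]), Atom("O", "O", [3, 0, 0]), 3.0)

    def test_bond_motif_vocabulary_types_as_designed(self):
        """Every synthetic bond motif realises its designed fingerprint."""
        for name, motif in BOND_MOTIFS.items():
            ab = Residue("H", 1, motif.ab_aa, [Atom(*motif.ab_tip, [0, 0, 0])])
            ag = Residue("G", 1, motif.ag_aa,
                         [Atom(*motif.ag_tip, [motif.distance, 0, 0])])
            fp = type_contact(ab.atoms[0], ag.atoms[0], motif.distance, ab, ag)
            assert fp == motif.fingerprint, name


class TestFindContacts:
    def test_cutoff_edges(self):
        for d, n in ((4.4, 1), (4.6, 0)):
            ab = Residue("H", 1, "ALA", [Atom("CB", "C", [0, 0, 0])])
            ab.imgt_position = 1
            ag = Residue("G", 1, "ALA", [Atom("CB", "C", [d, 0, 0])])
            from abcompare.structure_model import AntibodyComplex, annotate_regions

            cx = annotate_regions(AntibodyComplex("E", [ab], {"G": [ag]}))
            assert len(find_contacts(cx)) == n

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        cx = random_atom_complex(n_ab=50, n_ag=50, seed=seed)
        found = {
            (c.ab_residue.number, c.ag_residue.number, round(c.distance, 6))
            for c in find_contacts(cx)
        }
        brute = set()
        for ab in cx.antibody_residues():
            for ag in cx.antigen_residues():
                d = float(np.linalg.norm(ab.atoms[0].position - ag.atoms[0].position))
                if d <= 4.5:
                    brute.add((ab.number, ag.number, round(d, 6)))
        assert found == brute

    def test_rigid_motion_invariance(self, simple_complex):
        cx, _ = simple_complex
        base = find_contacts(cx)
        rng = np.random.default_rng(3)
        moved_h = rigid_transform(cx.heavy, random_rotation(rng), [5.0, -3.0, 9.0])
        # apply the same motion to the antigen
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        from abcompare.structure_model import AntibodyComplex, annotate_regions

        moved = AntibodyComplex(
            "M",
            rigid_transform(cx.heavy, rot, [5.0, -3.0, 9.0]),
            {"G": rigid_transform(cx.antigen["G"], rot, [5.0, -3.0, 9.0])},
        )
        annotate_regions(moved)
        after = find_contacts(moved)
        assert len(base) == len(after)
        for c0, c1 in zip(base, after):
            assert abs(c0.distance - c1.distance) < 1e-6
            assert c0.fingerprint == c1.fingerprint

    def test_cutoff_monotonicity(self, simple_complex):
        cx, _ = simple_complex
        small = binding_site(cx, "distance", contacts=find_contacts(cx, cutoff=4.0))
        large = binding_site(cx, "distance", contacts=find_contacts(cx, cutoff=5.5))
        assert {r.key for r in small.paratope} <= {r.key for r in large.paratope}


class TestSummarizeAndSites:
    def test_type_counts_and_classification(self, simple_complex):
        cx, gt = simple_complex
        pairs = summarize_pairs(find_contacts(cx))
        by_key = {(p.ab_residue.imgt_position, p.ag_residue.number): p for p in pairs}
        assert by_key[(106, 11)].type_counts == {"vdw": 1, "hbond": 1}
        assert by_key[(106, 11)].classification == "interaction"
        assert by_key[(108, 40)].type_counts == {"proximal": 1}
        assert by_key[(108, 40)].classification == "contact"

    def test_empty_input(self):
        assert summarize_pairs([]) == []

    def test_sites_match_ground_truth(self, simple_complex):
        cx, gt = simple_complex
        dist = binding_site(cx, "distance")
        inter = binding_site(cx, "interactions")
        assert {r.key for r in dist.paratope} == gt.distance_paratope
        assert {r.key for r in inter.paratope} == gt.interactions_paratope
        assert len(dist.paratope) == 4 and len(inter.paratope) == 3

    def test_interactions_nested_in_distance(self, worked_example_standins):
        for cx, _ in worked_example_standins:
            dist = binding_site(cx, "distance")
            inter = binding_site(cx, "interactions")
            assert {r.key for r in inter.paratope} <= {r.key for r in dist.paratope}
            assert {r.key for r in inter.epitope} <= {r.key for r in dist.epitope}

    def test_unknown_definition(self, simple_complex):
        with pytest.raises(ValueError, match="definition"):
            binding_site(simple_complex[0], "magic")

    def test_no_contact_complex_has_empty_sites(self):
        cx = random_atom_complex(n_ab=3, n_ag=3, seed=9)
        for r in cx.antigen_residues():
            for a in r.atoms:
                a.position = a.position + 100.0
        assert binding_site(cx, "distance").paratope == []


class TestCounting:
    def test_totals_match_atom_level_recount(self, worked_example_standins):
        for cx, gt in worked_example_standins:
            contacts = find_contacts(cx)
            pairs = summarize_pairs(contacts)
            total, per_type = count_interactions(pairs)
            brute = sum(
                1
                for c in contacts
                for t in c.fingerprint
                if t in INTERACTION_TYPES
            )
            assert total == brute == gt.n_interactions

    def test_example_arithmetic(self):
        r1 = Residue("H", 1, "ALA", [])
        g1 = Residue("G", 1, "ALA", [])
        from abcompare.interaction_engine import ResiduePairInteraction

        pairs = [
            ResiduePairInteraction(r1, g1, {"vdw": 2}, "interaction"),
            ResiduePairInteraction(r1, g1, {"vdw": 1, "hbond": 1}, "interaction"),
        ]
        total, per_type = count_interactions(pairs)
        assert total == 4 and per_type == {"vdw": 3, "hbond": 1}
        assert count_interactions([])[0] == 0

    def test_interactions_per_residue(self, worked_example_standins):
        (ab, _), (sd, _) = worked_example_standins
        for cx, expected in ((ab, 31 / 26), (sd, 29 / 15)):
            site = binding_site(cx, "interactions")
            pairs = [
                p for p in summarize_pairs(find_contacts(cx))
                if p.classification == "interaction"
            ]
            assert interactions_per_residue(site, pairs) == pytest.approx(expected)

    def test_empty_paratope_errors(self):
        from abcompare.interaction_engine import BindingSite

        with pytest.raises(ValueError, match="paratope"):
            interactions_per_residue(BindingSite("interactions", [], []), [])


class TestSubsampling:
    def _pairs(self, counts):
        from abcompare.interaction_engine import ResiduePairInteraction

        r = Residue("H", 1, "ALA", [])
        g = Residue("G", 1, "ALA", [])
        return [ResiduePairInteraction(r, g, counts, "interaction")]

    def test_single_type_has_zero_sd(self):
        stats = subsample_interaction_stats(self._pairs({"vdw": 50}), seed=0)
        mean, sd = stats["vdw"]
        assert mean == 1.0 and sd == 0.0

    def test_seeded_determinism(self):
        pairs = self._pairs({"vdw": 30, "hbond": 30})
        assert subsample_interaction_stats(pairs, seed=7) == subsample_interaction_stats(
            pairs, seed=7
        )

    def test_balanced_mix_matches_binomial(self):
        pairs = self._pairs({"vdw": 500, "hbond": 500})
        reps = 1000
        stats = subsample_interaction_stats(pairs, reps=reps, seed=1)
        mean, sd = stats["vdw"]
        # k=100 draws without replacement from a 50/50 pool of 1000
        k, n = 100, 1000
        per_rep_sd = np.sqrt(0.25 / k * (n - k) / (n - 1))
        assert abs(mean - 0.5) < 3 * per_rep_sd / np.sqrt(reps)
        assert sd == pytest.approx(per_rep_sd, rel=0.15)

    def test_too_few_interactions(self):
        with pytest.raises(ValueError, match=">= 10"):
            subsample_interaction_stats(self._pairs({"vdw": 5}))
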