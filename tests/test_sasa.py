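"""Shrake-Rupley SASA, relative SASA and epitope accessibility."""

import numpy as np
import pytest

from abcompare.sasa_accessibility import (
    compute_sasa,
    delta_sasa_site,
    epitope_accessibility,
    relative_sasa,
)
from abcompare.structure_model import Atom, Residue
from abcompare.synthetic_data import (
    _make_residue,
    make_burial_cage,
    random_rotation,
    rigid_transform,
)
from abcompare.interaction_engine import binding_site


def _carbon(pos, chain="A", num=1):
    return Residue(chain, num, "ALA", [Atom("CB", "C", pos)])


class TestComputeSasa:
    def test_single_atom_matches_analytic_sphere(self):
        prof = compute_sasa([_carbon([0, 0, 0])])
        analytic = 4 * np.pi * (1.70 + 1.4) ** 2
        assert prof.per_residue[("A", 1, "")] == pytest.approx(analytic, rel=0.02)

    def test_far_apart_atoms_are_additive(self):
        a, b = _carbon([0, 0, 0], num=1), _carbon([50, 0, 0], num=2)
        together = compute_sasa([a, b])
        alone = compute_sasa([a]).per_residue[("A", 1, "")]
        assert together.per_residue[("A", 1, "")] == pytest.approx(alone, abs=1e-9)
        assert together.per_residue[("A", 2, "")] == pytest.approx(alone, abs=1e-9)

    def test_caged_atom_has_zero_sasa(self):
        target = _carbon([0, 0, 0])
        cage = make_burial_cage([target], chain_id="A", number=2)
        prof = compute_sasa([target, cage])
        assert prof.per_residue[("A", 1, "")] == pytest.approx(0.0, abs=1e-6)

    def test_rotation_translation_invariance(self):
        """Invariance up to point-lattice discretisation, tightening as the
        lattice is refined (the lattice is fixed in space, not body-fixed)."""
        residues = [
            _make_residue("A", i, "", "GLY", np.array([i * 3.8, 0.0, 0.0]))
            for i in range(4)
        ]
        rng = np.random.default_rng(5)
        rot, shift = random_rotation(rng), np.array([12.0, -4.0, 7.0])
        moved = rigid_transform(residues, rot, shift)
        errors = {}
        for n in (960, 15360):
            base = compute_sasa(residues, n_points=n)
            after = compute_sasa(moved, n_points=n)
            errors[n] = max(
                abs(after.per_residue[k] - base.per_residue[k])
                for k in base.per_residue
            )
        assert errors[960] < 1.5  # ~1% of a residue's area at 960 points
        assert errors[15360] < 0.3
        assert errors[15360] < errors[960]

    def test_translation_invariance_exact_to_numerics(self):
        residues = [
            _make_residue("A", i, "", "GLY", np.array([i * 3.8, 0.0, 0.0]))
            for i in range(4)
        ]
        moved = rigid_transform(residues, np.eye(3), [12.0, -4.0, 7.0])
        base, after = compute_sasa(residues), compute_sasa(moved)
        for key in base.per_residue:
            assert after.per_residue[key] == pytest.approx(
                base.per_residue[key], abs=1e-6
            )

    def test_unknown_element_fatal(self):
        bad = Residue("A", 1, "ALA", [Atom("X", "XX", [0, 0, 0])])
        with pytest.raises(ValueError, match="XX"):
            compute_sasa([bad])

    def test_matches_independent_implementation(self):
        """Cross-check against biotite's Shrake-Rupley on a random cluster."""
        import biotite.structure as struc

        rng = np.random.default_rng(1)
        n = 40
        coords = rng.uniform(0, 12, size=(n, 3))
        elements = [["C", "N", "O"][i] for i in rng.integers(0, 3, size=n)]
        res = Residue(
            "A", 1, "ALA",
            [Atom(f"X{i}", el, c) for i, (el, c) in enumerate(zip(elements, coords))],
        )
        mine = sum(compute_sasa([res]).per_atom.values())
        arr = struc.AtomArray(n)
        arr.coord = coords
        arr.element = np.array(elements)
        arr.res_id = np.ones(n, dtype=int)
        arr.res_name = np.array(["ALA"] * n)
        arr.atom_name = np.array([f"X{i}" for i in range(n)])
        arr.chain_id = np.array(["A"] * n)
        theirs = float(np.nansum(struc.sasa(arr, vdw_radii="Single", point_number=960)))
        assert mine == pytest.approx(theirs, rel=1e-4)


class TestRelativeSasa:
    def test_tripeptide_centre_near_full_exposure(self):
        strand = [
            _make_residue("A", i, "", "GLY", np.array([i * 3.8, 0.0, 0.0]))
            for i in range(3)
        ]
        rel = relative_sasa(compute_sasa(strand))
        assert rel[("A", 1, "")] == pytest.approx(1.0, abs=0.15)

    def test_buried_residue_near_zero(self):
        target = _make_residue("A", 1, "", "GLY", np.zeros(3))
        cage = make_burial_cage([target], chain_id="A", number=2)
        rel = relative_sasa(compute_sasa([target, cage]))
        assert rel[("A", 1, "")] == pytest.approx(0.0, abs=0.01)

    def test_empty_structure(self):
        assert relative_sasa(compute_sasa([])) == {}


class TestDeltaSasaSite:
    def test_overlaps_distance_site(self, simple_complex):
        cx, _ = simple_complex
        sasa_site = delta_sasa_site(cx)
        dist = binding_site(cx, "distance")
        assert {r.key for r in sasa_site.paratope} & {r.key for r in dist.paratope}
        assert {r.key for r in sasa_site.epitope} & {r.key for r in dist.epitope}

    def test_distant_residues_excluded(self, simple_complex):
        cx, _ = simple_complex
        site = delta_sasa_site(cx)
        paratope_keys = {r.key for r in site.paratope}
        far = [r for r in cx.heavy if r.atoms[0].position[1] < -20]
        assert far and not ({r.key for r in far} & paratope_keys)

    def test_threshold_robust_on_clean_fixture(self, simple_complex):
        cx, _ = simple_complex
        a = {r.key for r in delta_sasa_site(cx, threshold=0.1).paratope}
        b = {r.key for r in delta_sasa_site(cx, threshold=1.0).paratope}
        assert a == b


class TestEpitopeAccessibility:
    def test_arithmetic_on_relative_values(self):
        # two residues with designed relative SASA ~0.5 vs direct mean
        strand = [
            _make_residue("G", i, "", "GLY", np.array([i * 3.8, 0.0, 0.0]))
            for i in range(5)
        ]
        rel = relative_sasa(compute_sasa(strand))
        epitope = [strand[1], strand[2]]
        expected = np.mean([rel[r.key] for r in epitope])
        assert epitope_accessibility(strand, epitope) == pytest.approx(expected)

    def test_exposed_and_buried_limits(self):
        strand = [
            _make_residue("G", i, "", "GLY", np.array([i * 3.8, 0.0, 0.0]))
            for i in range(12)
        ]
        mid = strand[4:8]
        exposed = epitope_accessibility(strand, mid)
        cage = make_burial_cage(mid)
        buried = epitope_accessibility(strand + [cage], mid)
        assert exposed > 0.85
        assert buried < 0.05

    def test_knob_more_accessible_than_pocket(self):
        strand = [
            _make_residue("G", i, "", "GLY", np.array([i * 3.8, 0.0, 0.0]))
            for i in range(6)
        ]
        knob = epitope_accessibility(strand, strand[2:4])
        cage = make_burial_cage(strand[2:4], clearance=6.0)
        pocket = epitope_accessibility(strand + [cage], strand[2:4])
        assert knob > pocket

    def test_empty_epitope_errors(self):
        with pytest.raises(ValueError, match="empty"):
            epitope_accessibility([_carbon([0, 0, 0])], [])
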