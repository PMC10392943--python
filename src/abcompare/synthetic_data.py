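"""Synthetic inputs with known ground truth for every pipeline stage.

Stands in for curated structural and repertoire datasets.  Realism is not
the goal; controllability is:

* :func:`make_complex` builds an antibody-antigen complex from an explicit
  contact plan.  Each planned residue pair is realised by a single designed
  atom pair at an exact distance, drawn from a small vocabulary of bond
  motifs (pure van der Waals, vdW+hydrogen bond, hydrophobic, ionic,
  proximal-only, clash-only ...), so the paratope/epitope membership under
  every binding-site definition and the exact interaction counts are known
  by construction.  Residues are idealised: a rigid backbone plate plus one
  side-chain tip atom on a stalk facing the interface; plan slots are
  spaced so no unplanned atom pair falls within the contact cutoff (this is
  validated by brute force, and violations name the offending pair).
* :func:`make_loop_scaffold` emits a VH-like chain whose CDR-H3 backbone
  centre of geometry sits exactly at requested spherical coordinates
  (rho, theta, phi) in the frame the geometry module constructs — the
  generator and the descriptor are mutual inverses.
* :func:`make_repertoire` draws CDR sequence sets with controlled length
  distributions, per-position compositions and pinned (conserved)
  positions; :func:`make_repertoire_pair` adds a specified mean CDR-H3
  length difference between two populations.
* :func:`make_worked_example_standins` builds a synthetic Ab/sdAb pair of
  complexes whose designed site sizes, CDR-H3 lengths and interaction
  counts mirror the published worked example's printed values.  These are
  synthetic stand-ins, not the real structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_model import (
    AA_1TO3,
    AntibodyComplex,
    Atom,
    CDR_RANGES,
    Residue,
    annotate_regions,
    write_complex,
)

TIP_LEN = 5.5  # A, side-chain tip stalk length
SLOT = 20.0  # A, spacing between contact slots along the interface
FORK_HALF = 1.6  # A, half-separation of twinned residues in a fork motif
FORK_ANGLE = math.radians(25.0)

# rigid backbone plate: offsets from CA in the xz-plane so the +-y tip
# direction is free of backbone atoms
_BACKBONE_OFFSETS = {
    "N": np.array([-1.458, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.551, 0.0, 1.420]),
    "O": np.array([1.181, 0.0, 2.480]),
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


@dataclass(frozen=True)
class BondMotif:
    """A designed single-atom-pair contact with a known fingerprint."""

    ab_aa: str
    ab_tip: tuple[str, str]  # (atom name, element)
    ag_aa: str
    ag_tip: tuple[str, str]
    distance: float
    fingerprint: frozenset[str]
    n_interactions: int


BOND_MOTIFS: dict[str, BondMotif] = {
    "vdw": BondMotif("LEU", ("CD1", "C"), "ASN", ("OD1", "O"), 3.25,
                     frozenset({"vdw"}), 1),
    "vdw2": BondMotif("SER", ("OG", "O"), "LEU", ("CD1", "C"), 3.25,
                      frozenset({"vdw"}), 1),
    "hydrophobic": BondMotif("LEU", ("CD1", "C"), "LEU", ("CD1", "C"), 3.45,
                             frozenset({"vdw", "hydrophobic"}), 2),
    "vdw_hbond": BondMotif("SER", ("OG", "O"), "ASN", ("OD1", "O"), 2.90,
                           frozenset({"vdw", "hbond"}), 2),
    "hbond": BondMotif("ASN", ("ND2", "N"), "ASN", ("OD1", "O"), 3.40,
                       frozenset({"proximal", "hbond"}), 1),
    "ionic": BondMotif("LYS", ("NZ", "N"), "GLU", ("OE1", "O"), 3.80,
                       frozenset({"proximal", "ionic"}), 1),
    "ionic_hbond": BondMotif("LYS", ("NZ", "N"), "GLU", ("OE1", "O"), 3.30,
                             frozenset({"proximal", "ionic", "hbond"}), 2),
    "proximal": BondMotif("ALA", ("CB", "C"), "ASN", ("OD1", "O"), 4.00,
                          frozenset({"proximal"}), 0),
    "clash": BondMotif("LEU", ("CD1", "C"), "ASN", ("OD1", "O"), 2.50,
                       frozenset({"clash"}), 0),
}


@dataclass
class ContactSpec:
    """One planned residue-pair contact."""

    ab_position: int  # IMGT position on the antibody chain
    ag_number: int  # author number on the antigen chain
    bond: str = "vdw"
    ab_icode: str = ""
    ab_chain: str = "H"  # "H" | "L"


@dataclass
class ComplexPlan:
    pdb_id: str = "SYN1"
    is_sdab: bool = True
    contacts: list[ContactSpec] = field(default_factory=list)
    cdr_lengths: tuple[int, int, int] = (8, 7, 12)  # heavy CDR1/2/3
    light_cdr_lengths: tuple[int, int, int] = (6, 3, 9)
    antigen_extra: list[int] = field(default_factory=list)  # far, non-epitope
    resolution: float = 2.0
    method: str = "X-RAY DIFFRACTION"


@dataclass
class GroundTruth:
    """Planned binding-site membership and interaction counts, by residue key."""

    distance_paratope: set[tuple[str, int, str]]
    distance_epitope: set[tuple[str, int, str]]
    interactions_paratope: set[tuple[str, int, str]]
    interactions_epitope: set[tuple[str, int, str]]
    pair_fingerprints: dict[tuple, frozenset[str]]
    n_interactions: int


class PlanError(ValueError):
    """The contact plan is not geometrically realisable."""


def imgt_cdr3_positions(length: int) -> list[tuple[int, str]]:
    """IMGT-style CDR3 numbering for a loop of given length.

    Up to 13 residues fill 105.. and ..117 from both ends inward; longer
    loops add lettered insertions after position 111.
    """
    if length < 1:
        raise ValueError("CDR3 length must be >= 1")
    if length <= 13:
        left = math.ceil(length / 2)
        right = length - left
        return [(p, "") for p in range(105, 105 + left)] + [
            (p, "") for p in range(118 - right, 118)
        ]
    extra = length - 13
    out = [(p, "") for p in range(105, 112)]
    out += [(111, chr(ord("A") + i)) for i in range(extra)]
    out += [(p, "") for p in range(112, 118)]
    return out


def _chain_positions(cdr_lengths: tuple[int, int, int]) -> list[tuple[int, str]]:
    len1, len2, len3 = cdr_lengths
    lo1, hi1 = CDR_RANGES["CDR1"]
    lo2, hi2 = CDR_RANGES["CDR2"]
    if len1 > hi1 - lo1 + 1 or len2 > hi2 - lo2 + 1:
        raise ValueError("CDR1/CDR2 length exceeds the IMGT range")
    positions = [(p, "") for p in (1, 2, 3)]
    positions += [(lo1 + i, "") for i in range(len1)]
    positions += [(p, "") for p in (39, 42, 49, 50, 52, 55)]
    positions += [(lo2 + i, "") for i in range(len2)]
    positions += [(p, "") for p in (66, 67, 68, 69, 77, 84, 102, 103, 104)]
    positions += imgt_cdr3_positions(len3)
    positions += [(p, "") for p in (118, 119, 120, 123)]
    return sorted(set(positions))


def _make_residue(
    chain_id: str,
    number: int,
    icode: str,
    aa: str,
    ca: np.ndarray,
    tip: tuple[str, str, np.ndarray] | None = None,
    imgt: tuple[int, str] | None = None,
) -> Residue:
    atoms = [
        Atom(name=name, element=_ELEMENT[name], position=ca + off)
        for name, off in _BACKBONE_OFFSETS.items()
    ]
    if tip is not None:
        name, element, pos = tip
        atoms.append(Atom(name=name, element=element, position=np.asarray(pos, float)))
    res = Residue(chain_id=chain_id, number=number, icode=icode, aa=aa, atoms=atoms)
    if imgt is not None:
        res.imgt_position, res.imgt_icode = imgt
    return res


def _group_motifs(contacts: list[ContactSpec]) -> list[list[ContactSpec]]:
    # union-find over shared antibody residues / antigen residues
    parent = list(range(len(contacts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_ab: dict[tuple, list[int]] = {}
    by_ag: dict[int, list[int]] = {}
    for i, c in enumerate(contacts):
        by_ab.setdefault((c.ab_chain, c.ab_position, c.ab_icode), []).append(i)
        by_ag.setdefault(c.ag_number, []).append(i)
    for group in list(by_ab.values()) + list(by_ag.values()):
        for i in group[1:]:
            parent[find(i)] = find(group[0])
    comps: dict[int, list[ContactSpec]] = {}
    for i, c in enumerate(contacts):
        comps.setdefault(find(i), []).append(c)
    return [comps[k] for k in sorted(comps)]


def make_complex(plan: ComplexPlan) -> tuple[AntibodyComplex, GroundTruth]:
    """Build a complex realising the contact plan exactly; see module docstring."""
    motifs = _group_motifs(plan.contacts)

    ab_specs: dict[tuple, dict] = {}  # (chain,pos,icode) -> {"aa":..,"tip":..}
    ag_specs: dict[int, dict] = {}
    pair_fp: dict[tuple, frozenset[str]] = {}
    n_interactions = 0

    def _assign(store, key, aa, tip_name, tip_el, tip_pos):
        entry = store.setdefault(key, {"aa": aa, "tips": {}})
        if entry["aa"] != aa:
            raise PlanError(
                f"conflicting amino-acid requirements for residue {key}: "
                f"{entry['aa']} vs {aa}"
            )
        if tip_name in entry["tips"] and not np.allclose(
            entry["tips"][tip_name][1], tip_pos
        ):
            raise PlanError(f"conflicting tip placements for residue {key}")
        entry["tips"][tip_name] = (tip_el, np.asarray(tip_pos, float))

    for slot, motif in enumerate(motifs):
        x0 = SLOT * slot
        ab_keys = sorted({(c.ab_chain, c.ab_position, c.ab_icode) for c in motif})
        ag_nums = sorted({c.ag_number for c in motif})
        if len(ab_keys) > 2 or len(ag_nums) > 2 or (len(ab_keys) == 2 and len(ag_nums) == 2):
            raise PlanError(
                f"motif {ab_keys} x {ag_nums} too entangled: only 1-1, 1-2 and "
                "2-1 contact components are realisable"
            )
        bonds = {(  # one bond per (ab,ag) pair
            (c.ab_chain, c.ab_position, c.ab_icode), c.ag_number): BOND_MOTIFS[c.bond]
            for c in motif
        }
        if len(bonds) != len(motif):
            raise PlanError(f"duplicate contact specs in motif {ab_keys} x {ag_nums}")

        if len(ab_keys) == 1:
            ab_key = ab_keys[0]
            ab_tip_xy = np.array([x0, TIP_LEN, 0.0])
            dirs = (
                [np.array([0.0, 1.0, 0.0])]
                if len(ag_nums) == 1
                else [
                    np.array([math.sin(FORK_ANGLE), math.cos(FORK_ANGLE), 0.0]),
                    np.array([-math.sin(FORK_ANGLE), math.cos(FORK_ANGLE), 0.0]),
                ]
            )
            for u, ag_num in zip(dirs, ag_nums):
                bond = bonds[(ab_key, ag_num)]
                ag_tip = ab_tip_xy + bond.distance * u
                ag_ca = ag_tip + TIP_LEN * u
                _assign(ab_specs, ab_key, bond.ab_aa, *bond.ab_tip, ab_tip_xy)
                _assign(ag_specs, ag_num, bond.ag_aa, *bond.ag_tip, ag_tip)
                ag_specs[ag_num]["ca"] = ag_ca
            ab_specs[ab_key]["ca"] = np.array([x0, 0.0, 0.0])
        else:  # 2 antibody residues sharing one antigen residue
            ag_num = ag_nums[0]
            tips = []
            for sign, ab_key in zip((-1, 1), ab_keys):
                ca = np.array([x0 + sign * FORK_HALF, 0.0, 0.0])
                tip = ca + np.array([0.0, TIP_LEN, 0.0])
                bond = bonds[(ab_key, ag_num)]
                _assign(ab_specs, ab_key, bond.ab_aa, *bond.ab_tip, tip)
                ab_specs[ab_key]["ca"] = ca
                tips.append((tip, bond))
            (t1, b1), (t2, b2) = tips
            if b1.ag_aa != b2.ag_aa or b1.ag_tip != b2.ag_tip:
                raise PlanError(
                    f"fork onto antigen residue {ag_num} mixes antigen residue types"
                )
            d_base = 2 * FORK_HALF
            a = (b1.distance**2 - b2.distance**2 + d_base**2) / (2 * d_base)
            h2 = b1.distance**2 - a**2
            if h2 <= 0:
                raise PlanError(
                    f"fork onto antigen residue {ag_num}: distances "
                    f"{b1.distance}/{b2.distance} unreachable from twin tips"
                )
            ag_tip = t1 + np.array([a, math.sqrt(h2), 0.0])
            _assign(ag_specs, ag_num, b1.ag_aa, *b1.ag_tip, ag_tip)
            ag_specs[ag_num]["ca"] = ag_tip + np.array([0.0, TIP_LEN, 0.0])

        for c in motif:
            key = ((c.ab_chain, c.ab_position, c.ab_icode), c.ag_number)
            bond = BOND_MOTIFS[c.bond]
            pair_fp[key] = bond.fingerprint
            n_interactions += bond.n_interactions

    # --- assemble the antibody chains
    filler_x = SLOT * (len(motifs) + 1)
    chains: dict[str, list[Residue]] = {"H": []}
    layouts = {"H": _chain_positions(plan.cdr_lengths)}
    if not plan.is_sdab:
        chains["L"] = []
        layouts["L"] = _chain_positions(plan.light_cdr_lengths)
    for chain_id, layout in layouts.items():
        have = {(pos, ic) for pos, ic in layout}
        for c in plan.contacts:
            if c.ab_chain == chain_id and (c.ab_position, c.ab_icode) not in have:
                raise PlanError(
                    f"planned contact position {chain_id}{c.ab_position}{c.ab_icode} "
                    "absent from the chain layout"
                )
        for pos, ic in layout:
            key = (chain_id, pos, ic)
            if key in ab_specs:
                spec = ab_specs[key]
                (tip_name, (tip_el, tip_pos)) = next(iter(spec["tips"].items()))
                res = _make_residue(
                    chain_id, pos, ic, spec["aa"], spec["ca"],
                    (tip_name, tip_el, tip_pos), imgt=(pos, ic),
                )
            else:
                ca = np.array([filler_x, -30.0, 0.0])
                filler_x += 6.0
                res = _make_residue(chain_id, pos, ic, "GLY", ca, imgt=(pos, ic))
            chains[chain_id].append(res)

    # --- assemble the antigen chain
    antigen: list[Residue] = []
    extra_x = SLOT * (len(motifs) + 1)
    for num in sorted(set(list(ag_specs) + list(plan.antigen_extra))):
        if num in ag_specs:
            spec = ag_specs[num]
            (tip_name, (tip_el, tip_pos)) = next(iter(spec["tips"].items()))
            res = _make_residue("G", num, "", spec["aa"], spec["ca"],
                                (tip_name, tip_el, tip_pos))
        else:
            ca = np.array([extra_x, 40.0, 0.0])
            extra_x += 6.0
            res = _make_residue("G", num, "", "GLY", ca)
        antigen.append(res)

    cx = AntibodyComplex(
        pdb_id=plan.pdb_id,
        heavy=chains["H"],
        light=chains.get("L"),
        antigen={"G": antigen},
        resolution=plan.resolution,
        method=plan.method,
    )
    annotate_regions(cx)
    _validate_geometry(cx, pair_fp, plan)

    planned_pairs = pair_fp
    dist_para = {k[0] for k in planned_pairs}
    dist_epi = {("G", k[1], "") for k in planned_pairs}
    int_para = {
        k[0] for k, fp in planned_pairs.items()
        if fp & {"vdw", "hbond", "ionic", "hydrophobic"}
    }
    int_epi = {
        ("G", k[1], "") for k, fp in planned_pairs.items()
        if fp & {"vdw", "hbond", "ionic", "hydrophobic"}
    }
    gt = GroundTruth(
        distance_paratope={(c, p, i) for (c, p, i) in dist_para},
        distance_epitope=dist_epi,
        interactions_paratope={(c, p, i) for (c, p, i) in int_para},
        interactions_epitope=int_epi,
        pair_fingerprints=planned_pairs,
        n_interactions=n_interactions,
    )
    return cx, gt


def _validate_geometry(
    cx: AntibodyComplex, planned: dict[tuple, frozenset[str]], plan: ComplexPlan
) -> None:
    """Brute-force check: only the designed atom pairs fall within the cutoff."""
    cutoff = 4.5
    designed = {((c, p, i), num) for ((c, p, i), num) in planned}
    for ab_res in cx.antibody_residues():
        ab_key = (ab_res.chain_id, ab_res.number, ab_res.icode)
        for ag_res in cx.antigen_residues():
            close = [
                (a.name, b.name, float(np.linalg.norm(a.position - b.position)))
                for a in ab_res.atoms
                for b in ag_res.atoms
                if np.linalg.norm(a.position - b.position) <= cutoff
            ]
            key = (ab_key, ag_res.number)
            if key in designed:
                if len(close) != 1:
                    raise PlanError(
                        f"{plan.pdb_id}: designed pair {key} realises {len(close)} "
                        f"atom contacts instead of 1: {close}"
                    )
            elif close:
                raise PlanError(
                    f"{plan.pdb_id}: unplanned contact between {ab_key} and antigen "
                    f"residue {ag_res.number}: {close}"
                )


def emit_complex(plan: ComplexPlan, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the planned complex as PDB plus a ground-truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cx, gt = make_complex(plan)
    pdb_path = out_dir / f"{plan.pdb_id}.pdb"
    write_complex(cx, pdb_path)
    gt_path = out_dir / f"{plan.pdb_id}.ground_truth.tsv"
    lines = ["ab_chain\tab_position\tab_icode\tag_number\tfingerprint\tinteracting"]
    for (ab_key, ag_num), fp in sorted(gt.pair_fingerprints.items()):
        interacting = bool(fp & {"vdw", "hbond", "ionic", "hydrophobic"})
        lines.append(
            f"{ab_key[0]}\t{ab_key[1]}\t{ab_key[2]}\t{ag_num}\t"
            f"{','.join(sorted(fp))}\t{int(interacting)}"
        )
    gt_path.write_text("\n".join(lines) + "\n")
    return pdb_path, gt_path


# ---------------------------------------------------------------------------
# burial cages for accessibility fixtures

def make_burial_cage(
    residues: list[Residue],
    chain_id: str = "G",
    number: int = 990,
    clearance: float = 3.5,
    spacing: float = 1.2,
) -> Residue:
    """An inert shell of carbon blocker atoms enclosing the given residues.

    Blocker carbons fill a solid slab of grid points hugging the caged
    atoms (between ``clearance`` and ``clearance + 2.5`` A away, grid step
    ``spacing``), so every probe position touching a caged atom intersects a
    blocker; a hollow shell would not do, since interior cavity surface
    still counts as accessible.  Returned as one pseudo-residue for the
    antigen chain.
    """
    from scipy.spatial import cKDTree

    coords = np.concatenate([r.coords for r in residues])
    lo = coords.min(axis=0) - (clearance + 3.0)
    hi = coords.max(axis=0) + (clearance + 3.0)
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = cKDTree(coords).query(grid, k=1)
    keep = grid[(d >= clearance) & (d <= clearance + 2.5)]
    atoms = [Atom(name="C", element="C", position=p) for p in keep]
    blocker = Residue(chain_id=chain_id, number=number, aa="GLY", atoms=atoms)
    blocker.region = "antigen"
    return blocker


# ---------------------------------------------------------------------------
# loop scaffolds (inverse of the orientation descriptors)

def make_loop_scaffold(
    length: int, rho: float, theta: float, phi: float
) -> list[Residue]:
    """VH-like chain whose CDR-H3 backbone centre sits at (rho, theta, phi).

    The frame the geometry module builds from this chain is the identity
    frame at the origin, so the descriptors recover the construction
    parameters exactly.
    """
    if rho < 1:
        raise ValueError("rho must be >= 1 A")
    residues: list[Residue] = []

    def add(pos: int, icode: str, ca: np.ndarray) -> None:
        residues.append(
            _make_residue("H", pos, icode, "GLY", np.asarray(ca, float),
                          imgt=(pos, icode))
        )

    # framework slab: 4x4 grid at z=-8, symmetric about the z axis
    grid = [(x, y) for y in (3.0, 1.0, -1.0, -3.0) for x in (-3.0, -1.0, 1.0, 3.0)]
    fr2_interface = (42, 49, 50, 52)  # the y=+3 row: sets the azimuth reference
    fr_positions = list(fr2_interface) + [1, 2, 3, 4, 5, 6, 66, 67, 68, 69, 70, 71]
    for pos, (x, y) in zip(fr_positions, grid):
        add(pos, "", np.array([x, y, -8.0]))
    # six CDR-H3 anchors on a circle of radius 3 at z=0 (centroid = origin)
    for pos, ang in zip((102, 103, 104, 118, 119, 120), range(0, 360, 60)):
        a = math.radians(ang)
        add(pos, "", np.array([3 * math.cos(a), 3 * math.sin(a), 0.0]))

    # loop residues on a small ring, then shifted so the backbone centre of
    # geometry lands exactly on the requested point
    th, ph = math.radians(theta), math.radians(phi)
    target = rho * np.array(
        [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
    )
    loop_positions = imgt_cdr3_positions(length)
    ring: list[np.ndarray] = []
    for i in range(length):
        a = 2 * math.pi * i / max(length, 2)
        ring.append(np.array([2 * math.cos(a), 2 * math.sin(a), 0.2 * (i % 2)]))
    loop_res = []
    for (pos, icode), ca in zip(loop_positions, ring):
        loop_res.append(
            _make_residue("H", pos, icode, "GLY", ca, imgt=(pos, icode))
        )
    bb = np.array([a.position for r in loop_res for a in r.atoms])
    shift = target - bb.mean(axis=0)
    for r in loop_res:
        for a in r.atoms:
            a.position = a.position + shift
    residues.extend(loop_res)
    residues.sort(key=lambda r: (r.imgt_position, r.imgt_icode))
    for r in residues:
        from .structure_model import region_of

        r.region = region_of(r.imgt_position)
    return residues


def rigid_transform(
    residues: list[Residue], rotation: np.ndarray, translation: np.ndarray
) -> list[Residue]:
    """A rigidly moved deep copy of a chain (for invariance checks)."""
    import copy

    moved = copy.deepcopy(residues)
    for r in moved:
        for a in r.atoms:
            a.position = rotation @ a.position + np.asarray(translation, float)
    return moved


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# repertoires

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_repertoire(
    n: int,
    seed: int | None = None,
    base_length: int = 5,
    poisson_mean: float = 9.0,
    alphabet: str = AMINO_ALPHABET,
    per_position: dict[int, dict[str, float]] | None = None,
    pinned: dict[int, str] | None = None,
) -> list[str]:
    """Draw n CDR-like sequences i.i.d. with controlled length/composition.

    Lengths are ``base_length + Poisson(poisson_mean)``; positions draw
    uniformly from ``alphabet`` unless ``per_position`` specifies a
    distribution or ``pinned`` fixes the letter (a conserved position).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = base_length + int(rng.poisson(poisson_mean))
        letters = []
        for pos in range(length):
            if pinned and pos in pinned:
                letters.append(pinned[pos])
            elif per_position and pos in per_position:
                dist = per_position[pos]
                aas = sorted(dist)
                probs = np.array([dist[a] for a in aas], dtype=float)
                letters.append(rng.choice(aas, p=probs / probs.sum()))
            else:
                letters.append(alphabet[rng.integers(len(alphabet))])
        out.append("".join(letters))
    return out


def make_repertoire_pair(
    n_each: int,
    delta: float = 1.4,
    seed: int | None = None,
    poisson_mean: float = 9.0,
    **kwargs,
) -> tuple[list[str], list[str]]:
    """Two populations whose mean loop lengths differ by ``delta`` residues.

    Returns (longer set, shorter set) — e.g. an sdAb-like and an Ab-like
    CDR-H3 repertoire with the default 1.4-residue shift.
    """
    rng = np.random.default_rng(seed)
    long_set = make_repertoire(
        n_each, seed=int(rng.integers(2**31)), poisson_mean=poisson_mean + delta,
        **kwargs,
    )
    short_set = make_repertoire(
        n_each, seed=int(rng.integers(2**31)), poisson_mean=poisson_mean, **kwargs
    )
    return long_set, short_set


def write_fasta(sequences: list[str], path: str | Path, prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sequences):
            fh.write(f">{prefix}{i}\n{s}\n")


def read_fasta(path: str | Path) -> list[str]:
    seqs, current = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if current:
                seqs.append("".join(current))
                current = []
        elif line.strip():
            current.append(line.strip())
    if current:
        seqs.append("".join(current))
    return seqs


# ---------------------------------------------------------------------------
# synthetic worked-example stand-ins

def worked_example_plans() -> tuple[ComplexPlan, ComplexPlan]:
    """Plans for a synthetic Ab / sdAb pair mirroring the published worked
    example's printed characteristics (CDR-H3 lengths 12 / 18,
    interactions-defined paratopes 26 / 15, epitopes 15 / 18, interaction
    totals 31 / 29, CDR-H3 paratope contributions 6 / 9).

    These are synthetic stand-ins built from the contact-plan vocabulary,
    not the real structures.
    """
    C = ContactSpec
    sdab = ComplexPlan(
        pdb_id="SYNSDAB",
        is_sdab=True,
        cdr_lengths=(8, 7, 18),
        contacts=[
            # three forked CDR-H3 residues, each touching two antigen residues
            C(105, 372, "hydrophobic"), C(105, 373, "vdw"),
            C(106, 374, "hydrophobic"), C(106, 375, "vdw"),
            C(107, 376, "vdw_hbond"), C(107, 377, "vdw2"),
            # single contacts from the rest of the CDR-H3
            C(108, 378, "hydrophobic"), C(109, 404, "hydrophobic"),
            C(110, 405, "hydrophobic"), C(111, 406, "vdw_hbond"),
            C(112, 408, "vdw_hbond"), C(113, 437, "vdw_hbond"),
            # CDR-H1, CDR-H2 and framework contributions
            C(27, 438, "vdw_hbond"), C(28, 439, "vdw"),
            C(56, 500, "vdw"), C(57, 501, "ionic"),
            C(66, 503, "ionic"), C(69, 505, "hydrophobic"),
        ],
        antigen_extra=[300, 301, 302, 303, 304, 305],
    )
    ab = ComplexPlan(
        pdb_id="SYNAB",
        is_sdab=False,
        cdr_lengths=(8, 7, 12),
        light_cdr_lengths=(6, 3, 9),
        contacts=[
            # twinned paratope residues sharing one antigen residue each
            C(105, 460, "hydrophobic"), C(106, 460, "vdw2"),
            C(107, 461, "vdw_hbond"), C(108, 461, "vdw"),
            C(109, 462, "hydrophobic"), C(110, 462, "vdw2"),
            C(27, 463, "vdw"), C(28, 463, "vdw"),
            C(29, 464, "vdw"), C(56, 464, "vdw"),
            C(57, 465, "vdw"), C(58, 465, "vdw"),
            C(27, 466, "vdw_hbond", ab_chain="L"), C(28, 466, "vdw", ab_chain="L"),
            C(29, 467, "vdw", ab_chain="L"), C(30, 467, "vdw", ab_chain="L"),
            C(31, 468, "vdw", ab_chain="L"), C(56, 468, "vdw", ab_chain="L"),
            C(57, 469, "vdw", ab_chain="L"), C(58, 469, "vdw", ab_chain="L"),
            C(105, 470, "hydrophobic", ab_chain="L"), C(106, 470, "vdw2", ab_chain="L"),
            # single contacts, including the framework positions
            C(1, 472, "ionic"),
            C(68, 473, "ionic", ab_chain="L"),
            C(107, 475, "vdw", ab_chain="L"),
            C(108, 476, "vdw", ab_chain="L"),
        ],
        antigen_extra=[300, 301, 302, 303, 304, 305],
    )
    return ab, sdab


def make_benchmark(
    n_per_group: int = 10,
    seed: int = 0,
    sdab_paratope: tuple[int, int] = (7, 10),
    ab_paratope: tuple[int, int] = (11, 15),
) -> list[tuple[AntibodyComplex, str]]:
    """Two-group benchmark with a designed paratope-size difference.

    Each complex draws its paratope size uniformly from the group's range
    (ranges emulate the direction of the published size gap: sdAb paratopes
    smaller), distributes contacts over CDR and framework positions, and
    draws bond motifs at random from the interaction-bearing vocabulary.
    Returns (complex, label) pairs, labels ``sdAb`` / ``Ab``.
    """
    rng = np.random.default_rng(seed)
    interacting_bonds = ["vdw", "vdw_hbond", "hydrophobic", "ionic", "hbond"]
    h_positions = [105, 106, 107, 108, 109, 110, 112, 113, 27, 28, 29, 30,
                   56, 57, 58, 59, 66, 69, 2, 114, 115]
    out: list[tuple[AntibodyComplex, str]] = []
    for label, (lo, hi), is_sdab in (
        ("sdAb", sdab_paratope, True),
        ("Ab", ab_paratope, False),
    ):
        for i in range(n_per_group):
            k = int(rng.integers(lo, hi + 1))
            positions = h_positions[:k]
            start = int(rng.integers(200, 400))
            # mostly contiguous epitope with a scattered tail
            ag_numbers = [start + j for j in range(max(1, k - 3))]
            ag_numbers += [start + 50 + 7 * j for j in range(k - len(ag_numbers))]
            contacts = [
                ContactSpec(pos, num, str(rng.choice(interacting_bonds)))
                for pos, num in zip(positions, ag_numbers)
            ]
            plan = ComplexPlan(
                pdb_id=f"{label.upper()}{i:03d}",
                is_sdab=is_sdab,
                contacts=contacts,
                antigen_extra=[start + 120 + j for j in range(4)],
            )
            cx, _ = make_complex(plan)
            out.append((cx, label))
    return out


def make_worked_example_standins() -> tuple[
    tuple[AntibodyComplex, GroundTruth], tuple[AntibodyComplex, GroundTruth]
]:
    """Synthetic (Ab, sdAb) stand-in complexes for the worked example."""
    ab_plan, sdab_plan = worked_example_plans()
    return make_complex(ab_plan), make_complex(sdab_plan)
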