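"""Typed interatomic contacts across the antibody-antigen interface.

Every antibody-atom / antigen-atom pair within a cutoff (default 4.5 A)
receives a fingerprint of contact types.  The structural component of the
fingerprint is exactly one of {covalent, clash, vdw, proximal}, decided by a
distance ladder over covalent and van der Waals radii; specific types
(hydrogen bond, ionic, hydrophobic) are added independently when their
geometric and chemical criteria hold.  Atom contacts are summarised per
residue pair: a pair *interacts* when at least one of its atom pairs forms a
van der Waals or specific interaction, otherwise it is a mere *contact*
(only clash/proximal observed).  Binding sites are derived under three
definitions: distance, typed interactions, or buried surface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import AntibodyComplex, Atom, Residue

# Bondi van der Waals radii (A)
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
# single-bond covalent radii (A)
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
}

STRUCTURAL_TYPES = ("covalent", "clash", "vdw", "proximal")
SPECIFIC_TYPES = ("hbond", "ionic", "hydrophobic")
#: types that qualify a residue pair as interacting
INTERACTION_TYPES = ("vdw", "hbond", "ionic", "hydrophobic")

# hydrogen-bond capable heavy atoms, by residue and atom name
_DONORS_SIDECHAIN: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",), "ASN": ("ND2",), "GLN": ("NE2",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
}
_ACCEPTORS_SIDECHAIN: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}
# formal-charge carriers at physiological pH
_POSITIVE: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
}
_NEGATIVE: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
}
# side-chain carbons bonded to neither N nor O (hydrophobic candidates)
APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "CYS": ("CB",),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "GLY": (),
    "HIS": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG"),
    "SER": (),
    "THR": ("CG2",),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "VAL": ("CB", "CG1", "CG2"),
}


@dataclass
class InteractionConfig:
    """Distance thresholds of the contact-typing ladder (A).

    Structural ladder: covalent if d <= r_cov_i + r_cov_j + covalent_tol;
    else clash if d < r_vdw_i + r_vdw_j - clash_tol; else vdw if
    d <= r_vdw_i + r_vdw_j + vdw_tol; else proximal (within ``cutoff``).
    """

    cutoff: float = 4.5
    covalent_tol: float = 0.4
    clash_tol: float = 0.4
    vdw_tol: float = 0.1
    hbond_max: float = 3.5
    ionic_max: float = 4.0
    hydrophobic_max: float = 4.5


DEFAULT_CONFIG = InteractionConfig()


@dataclass
class AtomContact:
    """A typed contact between one antibody atom and one antigen atom."""

    ab_atom: Atom
    ag_atom: Atom
    ab_residue: Residue
    ag_residue: Residue
    distance: float
    fingerprint: frozenset[str]


@dataclass
class ResiduePairInteraction:
    """Atom-level fingerprints of one residue pair, summarised as type counts."""

    ab_residue: Residue
    ag_residue: Residue
    type_counts: dict[str, int] = field(default_factory=dict)
    classification: str = "contact"  # "interaction" | "contact"

    @property
    def n_interactions(self) -> int:
        return sum(self.type_counts.get(t, 0) for t in INTERACTION_TYPES)


@dataclass
class BindingSite:
    """Paratope and epitope residue sets under one binding-site definition."""

    definition: str  # "distance" | "sasa" | "interactions"
    paratope: list[Residue]
    epitope: list[Residue]


def _is_donor(res: Residue, atom: Atom) -> bool:
    if atom.name == "N" and res.aa != "PRO":
        return True
    return atom.name in _DONORS_SIDECHAIN.get(res.aa, ())


def _is_acceptor(res: Residue, atom: Atom) -> bool:
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in _ACCEPTORS_SIDECHAIN.get(res.aa, ())


def _is_positive(res: Residue, atom: Atom) -> bool:
    return atom.name in _POSITIVE.get(res.aa, ())


def _is_negative(res: Residue, atom: Atom) -> bool:
    if atom.name == "OXT":
        return True
    return atom.name in _NEGATIVE.get(res.aa, ())


def _is_apolar_carbon(res: Residue, atom: Atom) -> bool:
    return atom.element == "C" and atom.name in APOLAR_CARBONS.get(res.aa, ())


def type_contact(
    ab_atom: Atom,
    ag_atom: Atom,
    distance: float,
    ab_residue: Residue | None = None,
    ag_residue: Residue | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> frozenset[str]:
    """Fingerprint one interatomic contact.

    The structural type is decided by the distance ladder; specific types
    need residue context (donor/acceptor and formal-charge assignment come
    from residue+atom-name templates) and are skipped when the residues are
    not given.
    """
    try:
        rv = VDW_RADII[ab_atom.element] + VDW_RADII[ag_atom.element]
        rc = COVALENT_RADII[ab_atom.element] + COVALENT_RADII[ag_atom.element]
    except KeyError as exc:
        raise ValueError(f"no tabulated radius for element {exc.args[0]!r}") from exc

    fp: set[str] = set()
    if distance <= rc + config.covalent_tol:
        fp.add("covalent")
    elif distance < rv - config.clash_tol:
        fp.add("clash")
    elif distance <= rv + config.vdw_tol:
        fp.add("vdw")
    else:
        fp.add("proximal")

    if ab_residue is not None and ag_residue is not None and "covalent" not in fp:
        if distance <= config.hbond_max and (
            (_is_donor(ab_residue, ab_atom) and _is_acceptor(ag_residue, ag_atom))
            or (_is_donor(ag_residue, ag_atom) and _is_acceptor(ab_residue, ab_atom))
        ):
            fp.add("hbond")
        if distance <= config.ionic_max and (
            (_is_positive(ab_residue, ab_atom) and _is_negative(ag_residue, ag_atom))
            or (_is_positive(ag_residue, ag_atom) and _is_negative(ab_residue, ab_atom))
        ):
            fp.add("ionic")
        if (
            distance <= config.hydrophobic_max
            and _is_apolar_carbon(ab_residue, ab_atom)
            and _is_apolar_carbon(ag_residue, ag_atom)
        ):
            fp.add("hydrophobic")
    return frozenset(fp)


def find_contacts(
    complex: AntibodyComplex,
    cutoff: float | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> list[AtomContact]:
    """All antibody/antigen atom pairs within the cutoff, fingerprinted.

    Neighbour search via a k-d tree; equivalent to the all-pairs computation.
    """
    if cutoff is None:
        cutoff = config.cutoff
    ab_residues = complex.antibody_residues()
    ag_residues = complex.antigen_residues()
    ab_atoms = [(r, a) for r in ab_residues for a in r.atoms]
    ag_atoms = [(r, a) for r in ag_residues for a in r.atoms]
    if not ab_atoms or not ag_atoms:
        return []
    ab_xyz = np.array([a.position for _, a in ab_atoms])
    ag_xyz = np.array([a.position for _, a in ag_atoms])
    tree = cKDTree(ag_xyz)
    neighbours = tree.query_ball_point(ab_xyz, r=cutoff)
    contacts: list[AtomContact] = []
    for i, hits in enumerate(neighbours):
        ab_res, ab_atom = ab_atoms[i]
        for j in sorted(hits):
            ag_res, ag_atom = ag_atoms[j]
            d = float(np.linalg.norm(ab_xyz[i] - ag_xyz[j]))
            fp = type_contact(ab_atom, ag_atom, d, ab_res, ag_res, config)
            contacts.append(AtomContact(ab_atom, ag_atom, ab_res, ag_res, d, fp))
    return contacts


def summarize_pairs(contacts: list[AtomContact]) -> list[ResiduePairInteraction]:
    """Aggregate atom-level fingerprints per residue pair.

    Each type on an atom pair is counted once per (atom pair, type).  A pair
    is classified ``interaction`` iff at least one non-covalent atom contact
    carries a vdw / hbond / ionic / hydrophobic type; otherwise ``contact``.
    """
    pairs: dict[tuple, ResiduePairInteraction] = {}
    interacting: set[tuple] = set()
    for c in contacts:
        key = (c.ab_residue.key, c.ag_residue.key)
        if key not in pairs:
            pairs[key] = ResiduePairInteraction(c.ab_residue, c.ag_residue)
        p = pairs[key]
        for t in c.fingerprint:
            p.type_counts[t] = p.type_counts.get(t, 0) + 1
        if "covalent" not in c.fingerprint and any(
            t in c.fingerprint for t in INTERACTION_TYPES
        ):
            interacting.add(key)
    for key, p in pairs.items():
        p.classification = "interaction" if key in interacting else "contact"
    return list(pairs.values())


def binding_site(
    complex: AntibodyComplex,
    definition: str = "interactions",
    config: InteractionConfig = DEFAULT_CONFIG,
    contacts: list[AtomContact] | None = None,
) -> BindingSite:
    """Paratope/epitope under one of the three definitions.

    distance: every residue with >= 1 atom contact; interactions: residues in
    >= 1 residue pair classified as interaction; sasa: residues buried on
    complex formation (delegated to the SASA module).
    """
    if definition == "sasa":
        from .sasa_accessibility import delta_sasa_site

        return delta_sasa_site(complex)
    if definition not in ("distance", "interactions"):
        raise ValueError(f"unknown binding-site definition {definition!r}")
    if contacts is None:
        contacts = find_contacts(complex, config=config)
    pairs = summarize_pairs(contacts)
    if definition == "interactions":
        pairs = [p for p in pairs if p.classification == "interaction"]
    para: dict[tuple, Residue] = {}
    epi: dict[tuple, Residue] = {}
    for p in pairs:
        para.setdefault(p.ab_residue.key, p.ab_residue)
        epi.setdefault(p.ag_residue.key, p.ag_residue)
    return BindingSite(definition, list(para.values()), list(epi.values()))


def count_interactions(
    pairs: list[ResiduePairInteraction],
) -> tuple[int, dict[str, int]]:
    """Total number of interaction instances and per-type marginals.

    Multiple types on one atom pair are counted individually.  ``total``
    sums the interaction types (vdw, hbond, ionic, hydrophobic); the
    per-type map additionally reports the non-interaction types observed.
    """
    per_type: dict[str, int] = {}
    for p in pairs:
        for t, n in p.type_counts.items():
            per_type[t] = per_type.get(t, 0) + n
    total = sum(per_type.get(t, 0) for t in INTERACTION_TYPES)
    return total, per_type


def interactions_per_residue(
    site: BindingSite, pairs: list[ResiduePairInteraction]
) -> float:
    """Total interactions normalised by paratope size."""
    if not site.paratope:
        raise ValueError("empty paratope: interactions per residue undefined")
    total, _ = count_interactions(pairs)
    return total / len(site.paratope)


def subsample_interaction_stats(
    pairs: list[ResiduePairInteraction],
    fraction: float = 0.10,
    reps: int = 1000,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Subsampled composition of interaction types.

    Draws ``floor(fraction * N)`` of the N interaction instances uniformly
    without replacement, ``reps`` times, and reports the mean and standard
    deviation of each type's proportion across replicates.
    """
    instances: list[str] = []
    for p in pairs:
        for t in INTERACTION_TYPES:
            instances.extend([t] * p.type_counts.get(t, 0))
    n = len(instances)
    if n < 10:
        raise ValueError(f"need >= 10 interaction instances, got {n}")
    k = int(np.floor(fraction * n))
    labels = np.array(instances)
    types = sorted(set(instances))
    rng = np.random.default_rng(seed)
    props = np.empty((reps, len(types)))
    for r in range(reps):
        pick = labels[rng.choice(n, size=k, replace=False)]
        for j, t in enumerate(types):
            props[r, j] = np.mean(pick == t)
    return {
        t: (float(props[:, j].mean()), float(props[:, j].std(ddof=0)))
        for j, t in enumerate(types)
    }


def contacts_table(contacts: list[AtomContact]) -> "pandas.DataFrame":  # noqa: F821
    """Per-contact table (TSV-ready) with residue identifiers and fingerprints."""
    import pandas as pd

    rows = []
    for c in contacts:
        rows.append(
            {
                "ab_chain": c.ab_residue.chain_id,
                "ab_resnum": c.ab_residue.number,
                "ab_imgt": c.ab_residue.imgt_position,
                "ab_atom": c.ab_atom.name,
                "ag_chain": c.ag_residue.chain_id,
                "ag_resnum": c.ag_residue.number,
                "ag_atom": c.ag_atom.name,
                "distance": round(c.distance, 3),
                "fingerprint": ",".join(sorted(c.fingerprint)),
            }
        )
    return pd.DataFrame(rows)
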