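"""Parsing and representation of antibody-antigen complexes.

A complex is one antibody (heavy chain, optional light chain) bound to one
or more antigen chains.  Antibody residues carry IMGT numbering, either read
from a sidecar table or taken from pre-renumbered coordinate files, and are
annotated with the IMGT region they fall in (FR1-FR4, CDR1-CDR3).  All
downstream analyses consume the types defined here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: IMGT position ranges of the three CDR loops (inclusive).
CDR_RANGES: dict[str, tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}

#: Framework regions as the complement of the CDR ranges within 1..128.
FR_RANGES: dict[str, tuple[int, int]] = {
    "FR1": (1, 26),
    "FR2": (39, 55),
    "FR3": (66, 104),
    "FR4": (118, 128),
}

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A single atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """One amino-acid residue with author numbering and optional IMGT annotation."""

    chain_id: str
    number: int
    aa: str  # three-letter code
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    imgt_position: int | None = None
    imgt_icode: str = ""
    region: str | None = None

    @property
    def aa1(self) -> str:
        return AA_3TO1[self.aa]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)


@dataclass
class AntibodyComplex:
    """One antibody (H +- L) bound to one or more antigen chains."""

    pdb_id: str
    heavy: list[Residue]
    antigen: dict[str, list[Residue]]
    light: list[Residue] | None = None
    resolution: float = float("nan")
    method: str = ""

    @property
    def is_sdab(self) -> bool:
        return self.light is None

    def antibody_residues(self) -> list[Residue]:
        res = list(self.heavy)
        if self.light is not None:
            res.extend(self.light)
        return res

    def antigen_residues(self) -> list[Residue]:
        return [r for chain in self.antigen.values() for r in chain]

    def all_residues(self) -> list[Residue]:
        return self.antibody_residues() + self.antigen_residues()

    def cdr_residues(self, loop: str | None = None, chain: str = "heavy") -> list[Residue]:
        """Residues of a CDR loop (``CDR1``/``CDR2``/``CDR3``) on one antibody chain."""
        source = self.heavy if chain == "heavy" else (self.light or [])
        if loop is None:
            return [r for r in source if r.region in CDR_RANGES]
        return [r for r in source if r.region == loop]


def region_of(imgt_position: int) -> str:
    """Map an IMGT position to its region under the IMGT CDR definitions."""
    for name, (lo, hi) in CDR_RANGES.items():
        if lo <= imgt_position <= hi:
            return name
    for name, (lo, hi) in FR_RANGES.items():
        if lo <= imgt_position <= hi:
            return name
    raise ValueError(f"IMGT position {imgt_position} outside 1..128")


def annotate_regions(complex: AntibodyComplex) -> AntibodyComplex:
    """Assign FR/CDR regions to antibody residues from their IMGT positions.

    Idempotent; antigen residues are tagged ``antigen``.  A numbered antibody
    residue outside 1..128 or an unnumbered one is an error.
    """
    for res in complex.antibody_residues():
        if res.imgt_position is None:
            raise ValueError(
                f"{complex.pdb_id}: antibody residue {res.chain_id}{res.number}{res.icode} "
                "has no IMGT position"
            )
        res.region = region_of(res.imgt_position)
    for res in complex.antigen_residues():
        res.region = "antigen"
    return complex


def read_numbering_table(path: str | Path) -> dict[tuple[str, int, str], tuple[int, str]]:
    """Read a sidecar IMGT numbering table.

    TSV columns: chain_id, author_number, insertion, imgt_position.  The IMGT
    column may carry an insertion letter (e.g. ``111A``).
    """
    table: dict[tuple[str, int, str], tuple[int, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chain_id"):
                continue
            chain_id, author_number, insertion, imgt = line.split("\t")[:4]
            imgt = imgt.strip()
            if imgt[-1].isalpha():
                pos, ic = int(imgt[:-1]), imgt[-1]
            else:
                pos, ic = int(imgt), ""
            table[(chain_id, int(author_number), insertion.strip())] = (pos, ic)
    return table


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy; ties broken by file order
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_complex(
    pdb_path: str | Path,
    chain_map: dict[str, str],
    numbering: str | Path | dict | None = None,
    pdb_id: str | None = None,
) -> AntibodyComplex:
    """Read a PDB file into an :class:`AntibodyComplex`.

    Parameters
    ----------
    chain_map
        Maps chain identifiers to roles ``heavy`` / ``light`` / ``antigen``.
        Chains not in the map are ignored; waters and heterogens are dropped.
    numbering
        Sidecar IMGT table (path or pre-parsed dict).  When absent, antibody
        chains are assumed pre-renumbered: IMGT position = author number and
        IMGT insertion = author insertion code.
    """
    roles = set(chain_map.values())
    if "heavy" not in roles:
        raise ValueError("chain_map must assign a heavy chain")
    if "antigen" not in roles:
        raise ValueError("chain_map must assign at least one antigen chain")

    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    model = st[0]
    present = {ch.name for ch in model}
    missing = set(chain_map) - present
    if missing:
        raise ValueError(f"chains {sorted(missing)} in chain_map absent from {pdb_path}")

    if isinstance(numbering, (str, Path)):
        numbering = read_numbering_table(numbering)

    chains: dict[str, list[Residue]] = {cid: [] for cid in chain_map}
    for ch in model:
        if ch.name not in chain_map:
            continue
        role = chain_map[ch.name]
        for gres in ch:
            rname = gres.name.strip()
            if rname == "HOH" or gres.is_water():
                continue
            if rname not in AA_3TO1:
                # heterogens silently removed; non-standard amino acids differ by role
                if gres.het_flag == "A" or rname in ("MSE", "SEC", "PYL"):
                    if role == "antigen":
                        warnings.warn(
                            f"{pdb_path}: dropping non-standard antigen residue "
                            f"{rname} {ch.name}{gres.seqid.num}"
                        )
                    else:
                        warnings.warn(
                            f"{pdb_path}: skipping unknown residue {rname} in antibody "
                            f"chain {ch.name}"
                        )
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for a in gres:
                by_name.setdefault(a.name, []).append(a)
            atoms = []
            for name, group in by_name.items():
                a = _best_altloc(group)
                atoms.append(
                    Atom(
                        name=name,
                        element=a.element.name.upper(),
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        altloc=a.altloc if a.altloc != "\x00" else "",
                        occupancy=a.occ,
                    )
                )
            icode = gres.seqid.icode.strip()
            res = Residue(
                chain_id=ch.name, number=gres.seqid.num, icode=icode, aa=rname, atoms=atoms
            )
            if role in ("heavy", "light"):
                if numbering is not None:
                    key = (ch.name, res.number, icode)
                    if key in numbering:
                        res.imgt_position, res.imgt_icode = numbering[key]
                else:
                    res.imgt_position, res.imgt_icode = res.number, icode
            chains[ch.name].append(res)

    heavy = [r for cid, role in chain_map.items() if role == "heavy" for r in chains[cid]]
    if not heavy:
        raise ValueError(f"{pdb_path}: heavy chain is empty after cleaning")
    light_res = [r for cid, role in chain_map.items() if role == "light" for r in chains[cid]]
    antigen = {cid: chains[cid] for cid, role in chain_map.items() if role == "antigen"}

    resolution = st.resolution if st.resolution else float("nan")
    cx = AntibodyComplex(
        pdb_id=pdb_id or (st.name or Path(pdb_path).stem),
        heavy=heavy,
        light=light_res or None,
        antigen=antigen,
        resolution=resolution,
        method=(st.info["_exptl.method"] if "_exptl.method" in st.info else ""),
    )
    return cx


def write_complex(complex: AntibodyComplex, path: str | Path) -> None:
    """Write the cleaned complex back out as a PDB coordinate file."""
    lines = []
    serial = 1
    chains: list[tuple[str, list[Residue]]] = [("heavy", complex.heavy)]
    if complex.light is not None:
        chains.append(("light", complex.light))
    for cid, residues in complex.antigen.items():
        chains.append((cid, residues))
    for _, residues in chains:
        for res in residues:
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.position
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.aa:>3s} {res.chain_id[:1]}"
                    f"{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CurationRules:
    """Dataset curation thresholds.

    ``antigen_mode='protein'`` keeps antigens with at least
    ``antigen_size_threshold`` residues (the database convention separating
    protein from peptide antigens); ``'peptide'`` inverts the rule.
    """

    max_resolution: float = 3.0
    contact_cutoff: float = 4.5
    antigen_size_threshold: int = 50
    antigen_mode: str = "protein"
    allowed_methods: tuple[str, ...] = ("X-RAY DIFFRACTION",)


def _min_cdr_antigen_distance(complex: AntibodyComplex) -> float:
    from scipy.spatial import cKDTree

    cdr_atoms = [a.position for r in complex.antibody_residues() if r.region in CDR_RANGES
                 for a in r.atoms]
    ag_atoms = [a.position for r in complex.antigen_residues() for a in r.atoms]
    if not cdr_atoms or not ag_atoms:
        return float("inf")
    tree = cKDTree(np.asarray(ag_atoms))
    d, _ = tree.query(np.asarray(cdr_atoms), k=1)
    return float(np.min(d))


def filter_dataset(
    complexes: list[AntibodyComplex],
    rules: CurationRules | None = None,
) -> tuple[list[AntibodyComplex], list[tuple[str, str]]]:
    """Apply the curation rules; returns (kept, rejection log).

    A complex is kept iff it is X-ray at <= 3.0 A resolution, its antigen
    passes the size rule, and at least one CDR atom lies within 4.5 A of the
    antigen.  Order-preserving; the log lists ``(pdb_id, reason)`` pairs.
    """
    rules = rules or CurationRules()
    kept: list[AntibodyComplex] = []
    log: list[tuple[str, str]] = []
    for cx in complexes:
        if cx.method and cx.method.upper() not in rules.allowed_methods:
            log.append((cx.pdb_id, f"method {cx.method!r} not allowed"))
            continue
        if not np.isnan(cx.resolution) and cx.resolution > rules.max_resolution:
            log.append((cx.pdb_id, f"resolution {cx.resolution:.2f} > {rules.max_resolution}"))
            continue
        n_ag = len(cx.antigen_residues())
        if rules.antigen_mode == "protein" and n_ag < rules.antigen_size_threshold:
            log.append((cx.pdb_id, f"antigen size {n_ag} < {rules.antigen_size_threshold}"))
            continue
        if rules.antigen_mode == "peptide" and n_ag >= rules.antigen_size_threshold:
            log.append((cx.pdb_id, f"antigen size {n_ag} >= {rules.antigen_size_threshold}"))
            continue
        d = _min_cdr_antigen_distance(cx)
        if d > rules.contact_cutoff:
            log.append((cx.pdb_id, f"nearest CDR-antigen distance {d:.2f} > {rules.contact_cutoff}"))
            continue
        kept.append(cx)
    return kept, log
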