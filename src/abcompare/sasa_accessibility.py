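"""Solvent-accessible surface area and the epitope-accessibility metric.

SASA is computed with the Shrake-Rupley rolling-probe method on a
deterministic golden-section spiral point lattice, so results are exactly
reproducible for a fixed point count.  Per-residue SASA divided by the
residue type's theoretical maximum exposure (Tien et al. 2013 values,
bundled) gives relative SASA in [0, ~1.2].  Epitope accessibility is the
mean relative SASA over the epitope residues, computed on the antigen with
the antibody removed: 1 means a fully exposed surface patch, 0 fully
buried.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .interaction_engine import VDW_RADII
from .structure_model import AntibodyComplex, Residue

ResKey = tuple[str, int, str]


def load_max_sasa_table(path: str | Path | None = None) -> dict[str, float]:
    """Reference maximal per-residue SASA; swappable via ``path``."""
    if path is None:
        ref = resources.files("abcompare").joinpath("data/max_sasa_tien2013.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        table[aa] = float(value)
    return table


MAX_SASA = load_max_sasa_table()


@dataclass
class SasaProfile:
    """Per-atom and per-residue SASA of one structure (or sub-structure)."""

    per_atom: dict[tuple[ResKey, str], float]
    per_residue: dict[ResKey, float]
    residues: dict[ResKey, Residue]
    probe_radius: float
    n_points: int

    def relative(self) -> dict[ResKey, float]:
        return relative_sasa(self)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k  # golden angle increments
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    residues: list[Residue],
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaProfile:
    """Shrake-Rupley SASA over a set of residues (one or more chains)."""
    atoms = [(res, a) for res in residues for a in res.atoms]
    profile = SasaProfile({}, {}, {res.key: res for res in residues}, probe, n_points)
    if not atoms:
        return profile
    xyz = np.array([a.position for _, a in atoms])
    try:
        radii = np.array([VDW_RADII[a.element] for _, a in atoms]) + probe
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from exc

    sphere = _sphere_points(n_points)
    tree = cKDTree(xyz)
    rmax = radii.max()
    for i, (res, atom) in enumerate(atoms):
        pts = xyz[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 >= radii[j] ** 2
        area = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
        profile.per_atom[(res.key, atom.name)] = float(area)
        profile.per_residue[res.key] = profile.per_residue.get(res.key, 0.0) + float(area)
    for res in residues:
        profile.per_residue.setdefault(res.key, 0.0)
    return profile


def relative_sasa(
    profile: SasaProfile, reference: dict[str, float] | None = None
) -> dict[ResKey, float]:
    """Per-residue SASA divided by the residue type's reference maximum."""
    reference = reference or MAX_SASA
    out = {}
    for key, area in profile.per_residue.items():
        aa = profile.residues[key].aa
        if aa not in reference:
            raise ValueError(f"residue type {aa} absent from the reference SASA table")
        out[key] = area / reference[aa]
    return out


def delta_sasa_site(complex: AntibodyComplex, threshold: float = 0.1):
    """SASA-defined binding site: residues burying > threshold A^2 on binding."""
    from .interaction_engine import BindingSite

    ab = complex.antibody_residues()
    ag = complex.antigen_residues()
    bound = compute_sasa(ab + ag)
    free_ab = compute_sasa(ab)
    free_ag = compute_sasa(ag)
    paratope = [
        r for r in ab if free_ab.per_residue[r.key] - bound.per_residue[r.key] > threshold
    ]
    epitope = [
        r for r in ag if free_ag.per_residue[r.key] - bound.per_residue[r.key] > threshold
    ]
    return BindingSite("sasa", paratope, epitope)


def epitope_accessibility(
    antigen_residues: list[Residue],
    epitope: list[Residue],
    n_points: int = 960,
) -> float:
    """Mean relative SASA of the epitope residues on the unbound antigen.

    Equals the epitope's surface area relative to the summed exposure the
    same residues would have in isolation (that sum is one per residue by
    construction of relative SASA), so the value lies in [0, ~1].
    """
    if not epitope:
        raise ValueError("empty epitope")
    profile = compute_sasa(antigen_residues, n_points=n_points)
    rel = relative_sasa(profile)
    missing = [r.key for r in epitope if r.key not in rel]
    if missing:
        raise ValueError(f"epitope residues not in antigen: {missing}")
    return float(np.mean([rel[r.key] for r in epitope]))


def sasa_report(profile: SasaProfile) -> "pandas.DataFrame":  # noqa: F821
    """Per-residue SASA table (chain, resnum, aa, sasa, relative_sasa)."""
    import pandas as pd

    rel = relative_sasa(profile)
    rows = []
    for key, res in profile.residues.items():
        rows.append(
            {
                "chain": res.chain_id,
                "resnum": res.number,
                "icode": res.icode,
                "aa": res.aa,
                "sasa": round(profile.per_residue[key], 3),
                "relative_sasa": round(rel[key], 4),
            }
        )
    return pd.DataFrame(rows)
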