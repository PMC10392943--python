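"""Per-complex descriptive statistics of paratopes and epitopes.

Covers the seven-class amino-acid composition, epitope linearity
(sequence-contiguity), CDR/framework contributions to the paratope,
framework-position frequency across a dataset, the epitope-identity score
used for redundancy control, and the greedy CDR-identity redundancy filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align

from .interaction_engine import (
    BindingSite,
    ResiduePairInteraction,
    binding_site,
    INTERACTION_TYPES,
)
from .structure_model import AntibodyComplex, CDR_RANGES, Residue

#: the seven-class partition of the 20 standard amino acids
SEVEN_CLASSES: dict[str, str] = {
    "aliphatic": "AGILPV",
    "aromatic": "FWY",
    "sulfur": "CM",
    "hydroxyl": "ST",
    "basic": "RHK",
    "acidic": "DE",
    "amine": "NQ",
}
_CLASS_OF = {aa: cls for cls, aas in SEVEN_CLASSES.items() for aa in aas}


@dataclass
class CompositionVector:
    """Fractions of the seven amino-acid classes; sums to 1."""

    fractions: dict[str, float]

    def __getitem__(self, cls: str) -> float:
        return self.fractions[cls]


@dataclass
class ParatopeProfile:
    size: int
    composition: CompositionVector
    cdr_fraction: float
    per_loop_residues: dict[str, int]
    per_loop_interactions: dict[str, int]
    per_loop_interactions_per_residue: dict[str, float]
    framework_positions: set[tuple[str, int]]


@dataclass
class EpitopeProfile:
    size: int
    linear_count: int
    linear_pct: float
    composition: CompositionVector
    accessibility: float | None = None


def seven_class_composition(residues: list[Residue] | list[str]) -> CompositionVector:
    """Class fractions of a residue set (Residue objects or one-letter codes)."""
    letters = [r if isinstance(r, str) else r.aa1 for r in residues]
    if not letters:
        raise ValueError("empty residue set")
    counts = {cls: 0 for cls in SEVEN_CLASSES}
    for aa in letters:
        counts[_CLASS_OF[aa]] += 1
    n = len(letters)
    return CompositionVector({cls: c / n for cls, c in counts.items()})


def _icode_rank(icode: str) -> int:
    return 0 if icode == "" else ord(icode.upper()) - ord("A") + 1


def _adjacent(a: Residue, b: Residue) -> bool:
    if a.chain_id != b.chain_id:
        return False
    if a.number == b.number:
        return abs(_icode_rank(a.icode) - _icode_rank(b.icode)) == 1
    return abs(a.number - b.number) == 1


def epitope_linearity(epitope: list[Residue]) -> tuple[int, float]:
    """Count and percentage of epitope residues with a sequence-adjacent
    epitope neighbour (author numbering; insertion codes ordered
    lexicographically)."""
    if not epitope:
        raise ValueError("empty epitope")
    linear = 0
    for r in epitope:
        if any(other is not r and _adjacent(r, other) for other in epitope):
            linear += 1
    return linear, 100.0 * linear / len(epitope)


def _loop_tag(complex: AntibodyComplex, res: Residue) -> str:
    chain = "H" if any(res is h for h in complex.heavy) else "L"
    if res.region in CDR_RANGES:
        return f"CDR-{chain}{res.region[-1]}"
    return "framework"


def loop_contributions(
    complex: AntibodyComplex,
    site: BindingSite,
    pairs: list[ResiduePairInteraction],
) -> ParatopeProfile:
    """Attribute paratope residues and interaction counts to CDR loops.

    Loops are CDR-H1/H2/H3 (and CDR-L1/L2/L3 when a light chain is present);
    everything else is framework.  Interaction counts per loop are also
    normalised by the loop's residue count in the structure.
    """
    loops = ["CDR-H1", "CDR-H2", "CDR-H3"]
    if complex.light is not None:
        loops += ["CDR-L1", "CDR-L2", "CDR-L3"]
    loops.append("framework")

    per_loop_res = {lp: 0 for lp in loops}
    fw_positions: set[tuple[str, int]] = set()
    for r in site.paratope:
        tag = _loop_tag(complex, r)
        per_loop_res[tag] += 1
        if tag == "framework" and r.imgt_position is not None:
            chain = "H" if any(r is h for h in complex.heavy) else "L"
            fw_positions.add((chain, r.imgt_position))

    paratope_keys = {r.key for r in site.paratope}
    per_loop_int = {lp: 0 for lp in loops}
    for p in pairs:
        if p.classification != "interaction" or p.ab_residue.key not in paratope_keys:
            continue
        tag = _loop_tag(complex, p.ab_residue)
        per_loop_int[tag] += sum(p.type_counts.get(t, 0) for t in INTERACTION_TYPES)

    loop_len = {
        f"CDR-{chain}{n}": len(complex.cdr_residues(f"CDR{n}", "heavy" if chain == "H" else "light"))
        for chain in (["H", "L"] if complex.light is not None else ["H"])
        for n in (1, 2, 3)
    }
    per_loop_norm = {
        lp: (per_loop_int[lp] / loop_len[lp]) if loop_len.get(lp) else 0.0
        for lp in loops
        if lp != "framework"
    }

    size = len(site.paratope)
    n_cdr = size - per_loop_res["framework"]
    return ParatopeProfile(
        size=size,
        composition=seven_class_composition(site.paratope),
        cdr_fraction=(n_cdr / size) if size else 0.0,
        per_loop_residues=per_loop_res,
        per_loop_interactions=per_loop_int,
        per_loop_interactions_per_residue=per_loop_norm,
        framework_positions=fw_positions,
    )


def epitope_profile(
    complex: AntibodyComplex,
    site: BindingSite,
    accessibility: float | None = None,
) -> EpitopeProfile:
    linear_count, linear_pct = epitope_linearity(site.epitope)
    return EpitopeProfile(
        size=len(site.epitope),
        linear_count=linear_count,
        linear_pct=linear_pct,
        composition=seven_class_composition(site.epitope),
        accessibility=accessibility,
    )


def framework_position_frequency(
    dataset: list[tuple[AntibodyComplex, ParatopeProfile]],
    threshold: float = 0.10,
) -> list[tuple[tuple[str, int], float]]:
    """Framework IMGT positions appearing in at least ``threshold`` of the
    complexes' paratopes, sorted by descending frequency."""
    if not dataset:
        raise ValueError("empty dataset")
    counts: dict[tuple[str, int], int] = {}
    for _, profile in dataset:
        for pos in profile.framework_positions:
            counts[pos] = counts.get(pos, 0) + 1
    n = len(dataset)
    ranked = [(pos, c / n) for pos, c in counts.items() if c / n >= threshold]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def epitope_identity(
    epitope_a: set[int],
    seq_a: str,
    epitope_b: set[int],
    seq_b: str,
    denominator: str = "min",
) -> float:
    """Fraction of matching epitope residues between two complexes.

    The antigen sequences are globally aligned (match +1, mismatch 0, gap
    -1); a match is an epitope position of A aligned to an epitope position
    of B carrying the same amino acid.  The default denominator is the
    smaller epitope (symmetric); ``denominator='union'`` is stricter.
    """
    if not epitope_a or not epitope_b:
        raise ValueError("empty epitope")
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for off in range(a_end - a_start):
            i, j = a_start + off, b_start + off
            if i in epitope_a and j in epitope_b and seq_a[i] == seq_b[j]:
                matches += 1
    if denominator == "min":
        denom = min(len(epitope_a), len(epitope_b))
    elif denominator == "union":
        denom = len(epitope_a) + len(epitope_b) - matches
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return matches / denom


def concatenated_cdr_sequence(complex: AntibodyComplex) -> str:
    """One-letter CDR1+CDR2+CDR3 sequence, heavy then light chain."""
    parts = []
    for chain in ("heavy", "light"):
        for loop in ("CDR1", "CDR2", "CDR3"):
            parts.extend(r.aa1 for r in complex.cdr_residues(loop, chain))
    return "".join(parts)


def _sequence_identity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _antigen_seq_and_epitope(complex: AntibodyComplex) -> tuple[str, set[int]]:
    residues = complex.antigen_residues()
    seq = "".join(r.aa1 for r in residues)
    site = binding_site(complex, "distance")
    epi_keys = {r.key for r in site.epitope}
    idx = {i for i, r in enumerate(residues) if r.key in epi_keys}
    return seq, idx


def redundancy_filter(
    complexes: list[AntibodyComplex],
    cdr_identity_cutoff: float = 0.95,
    epitope_cutoff: float = 0.75,
) -> list[AntibodyComplex]:
    """Greedy CDR-identity redundancy removal with epitope-based rescue.

    Complexes are greedily clustered on concatenated IMGT CDR sequences at
    >= 95% identity; the representative of each cluster is the member with
    the longest CDR-H3 (ties: first in input order).  Discarded members are
    reintroduced when their epitope identity to every kept complex is below
    the epitope cutoff, so similar CDRs binding different epitopes survive.
    Output preserves input order; the filter is idempotent.
    """
    if not complexes:
        return []
    order = sorted(
        range(len(complexes)),
        key=lambda i: (-len(complexes[i].cdr_residues("CDR3", "heavy")), i),
    )
    cdr_seqs = [concatenated_cdr_sequence(cx) for cx in complexes]
    reps: list[int] = []
    members: dict[int, list[int]] = {}
    for i in order:
        for rep in reps:
            if _sequence_identity(cdr_seqs[i], cdr_seqs[rep]) >= cdr_identity_cutoff:
                members[rep].append(i)
                break
        else:
            reps.append(i)
            members[i] = []

    kept = set(reps)
    epitopes = {i: _antigen_seq_and_epitope(complexes[i]) for i in range(len(complexes))}
    discarded = [i for rep in reps for i in members[rep]]
    for i in discarded:
        seq_i, epi_i = epitopes[i]
        if not epi_i:
            continue
        rescued = all(
            epitope_identity(epi_i, seq_i, epitopes[k][1], epitopes[k][0]) < epitope_cutoff
            for k in sorted(kept)
            if epitopes[k][1]
        )
        if rescued:
            kept.add(i)
    return [complexes[i] for i in sorted(kept)]
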