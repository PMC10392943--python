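"""Greedy length+RMSD clustering of CDR loops and the random-overlap null.

Loops are comparable only at identical residue count; within a length
stratum the similarity measure is the minimal backbone RMSD over rigid
superpositions (Kabsch).  Greedy clustering processes loops in a pinned
deterministic order (length descending, then source id) and assigns each
loop to the first cluster whose representative is within the cutoff, else
it founds a new cluster.  The expected number of clusters containing both
Ab and sdAb members under random assignment is estimated by permuting the
labels into the observed cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_model import AntibodyComplex, BACKBONE_ATOMS, CDR_RANGES


@dataclass
class LoopRecord:
    source_id: str
    label: str  # "Ab" | "sdAb"
    loop: str  # "CDR-H1" | "CDR-H2" | "CDR-H3"
    length: int
    backbone_coords: np.ndarray  # (4 * length, 3): N, CA, C, O per residue

    def __post_init__(self) -> None:
        self.backbone_coords = np.asarray(self.backbone_coords, dtype=float)
        if self.backbone_coords.shape != (4 * self.length, 3):
            raise ValueError(
                f"{self.source_id}/{self.loop}: expected {4 * self.length} backbone "
                f"atoms, got {self.backbone_coords.shape[0]}"
            )


@dataclass
class ClusterSet:
    clusters: list[list[LoopRecord]]
    representatives: list[LoopRecord]

    @property
    def overlap_count(self) -> int:
        return sum(
            1
            for members in self.clusters
            if {m.label for m in members} >= {"Ab", "sdAb"}
        )

    @property
    def singletons(self) -> int:
        return sum(1 for members in self.clusters if len(members) == 1)

    def label_only_count(self, label: str) -> int:
        return sum(1 for members in self.clusters if {m.label for m in members} == {label})


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between two equal-size coordinate sets over rigid motions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    # proper rotation: flip the smallest singular direction if det < 0
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = s.copy()
    s[-1] *= d
    e0 = np.sum(ac**2) + np.sum(bc**2)
    msd = max(0.0, (e0 - 2.0 * np.sum(s)) / a.shape[0])
    return float(np.sqrt(msd))


def extract_loop_records(
    complex: AntibodyComplex, label: str | None = None
) -> list[LoopRecord]:
    """Backbone loop records (CDR-H1/H2/H3) of one antibody; loops with
    incomplete backbone are skipped."""
    if label is None:
        label = "sdAb" if complex.is_sdab else "Ab"
    records = []
    for n in (1, 2, 3):
        loop = complex.cdr_residues(f"CDR{n}", "heavy")
        if not loop or not all(r.has_backbone for r in loop):
            continue
        coords = np.array(
            [r.atom(name).position for r in loop for name in BACKBONE_ATOMS]
        )
        records.append(
            LoopRecord(complex.pdb_id, label, f"CDR-H{n}", len(loop), coords)
        )
    return records


def greedy_cluster(loops: list[LoopRecord], cutoff: float = 1.5) -> ClusterSet:
    """Greedy single-pass clustering by length and Kabsch RMSD."""
    ordered = sorted(loops, key=lambda r: (-r.length, r.source_id))
    reps: list[LoopRecord] = []
    clusters: list[list[LoopRecord]] = []
    for rec in ordered:
        for i, rep in enumerate(reps):
            if rep.length == rec.length and kabsch_rmsd(
                rec.backbone_coords, rep.backbone_coords
            ) <= cutoff:
                clusters[i].append(rec)
                break
        else:
            reps.append(rec)
            clusters.append([rec])
    return ClusterSet(clusters=clusters, representatives=reps)


def random_overlap_null(
    cluster_sizes: list[int],
    labels: list[str],
    reps: int = 20,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean and sd of the overlap-cluster count under random label assignment.

    Labels are permuted into slots of the observed cluster sizes; a cluster
    overlaps when it receives both an ``Ab`` and an ``sdAb`` label.
    """
    if sum(cluster_sizes) != len(labels):
        raise ValueError(
            f"cluster sizes sum to {sum(cluster_sizes)} but {len(labels)} labels given"
        )
    rng = np.random.default_rng(seed)
    labels_arr = np.array(labels)
    bounds = np.cumsum([0] + list(cluster_sizes))
    counts = np.empty(reps)
    for r in range(reps):
        perm = labels_arr[rng.permutation(len(labels_arr))]
        overlap = 0
        for i in range(len(cluster_sizes)):
            slot = perm[bounds[i]: bounds[i + 1]]
            if "Ab" in slot and "sdAb" in slot:
                overlap += 1
        counts[r] = overlap
    return float(counts.mean()), float(counts.std(ddof=0))


def cluster_report(cluster_set: ClusterSet) -> "pandas.DataFrame":  # noqa: F821
    """Per-cluster table: representative, members, and per-label counts."""
    import pandas as pd

    rows = []
    for i, (rep, members) in enumerate(
        zip(cluster_set.representatives, cluster_set.clusters)
    ):
        rows.append(
            {
                "cluster_id": i,
                "loop": rep.loop,
                "length": rep.length,
                "representative_id": rep.source_id,
                "member_ids": ";".join(m.source_id for m in members),
                "n_Ab": sum(1 for m in members if m.label == "Ab"),
                "n_sdAb": sum(1 for m in members if m.label == "sdAb"),
            }
        )
    return pd.DataFrame(rows)


def cluster_summary(cluster_set: ClusterSet) -> dict[str, int]:
    """Summary in the layout of the headline cluster table: per-label-only
    counts (with single-occupancy in brackets in the printed form), overlap,
    and total."""
    ab_only = [c for c in cluster_set.clusters if {m.label for m in c} == {"Ab"}]
    sd_only = [c for c in cluster_set.clusters if {m.label for m in c} == {"sdAb"}]
    return {
        "abs_only": len(ab_only),
        "abs_only_singletons": sum(1 for c in ab_only if len(c) == 1),
        "sdabs_only": len(sd_only),
        "sdabs_only_singletons": sum(1 for c in sd_only if len(c) == 1),
        "overlap": cluster_set.overlap_count,
        "total": len(cluster_set.clusters),
    }
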