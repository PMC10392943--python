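"""Repertoire-scale sequence statistics.

Works on plain CDR sequence sets (optionally with explicit IMGT position
labels): loop-length distributions, per-position amino-acid composition
with an occupancy floor, conservation scoring of framework positions, and
the expected probability that a random cross-repertoire pair of loop
sequences is identical under a per-position independence model.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

Sequence = str
#: a sequence either as a string (positions = 0-based indices) or as an
#: explicit mapping from position label to amino acid
Record = str | dict[str, str]


@dataclass
class PositionComposition:
    """Per-position amino-acid frequencies of an aligned sequence set."""

    per_position: dict[str, dict[str, float]]
    occupancy: dict[str, float]
    n_sequences: int
    occupancy_floor: float


def _positions_of(record: Record) -> dict[str, str]:
    if isinstance(record, dict):
        return record
    return {str(i): aa for i, aa in enumerate(record)}


def length_distribution(sequences: list[Sequence]) -> tuple[dict[int, int], float]:
    """Histogram of loop lengths and their mean."""
    if not sequences:
        raise ValueError("empty sequence set")
    lengths = [len(s) for s in sequences]
    return dict(sorted(Counter(lengths).items())), float(np.mean(lengths))


def mean_length_difference(a: list[Sequence], b: list[Sequence]) -> float:
    """Difference of mean loop lengths, set A minus set B."""
    _, mean_a = length_distribution(a)
    _, mean_b = length_distribution(b)
    return mean_a - mean_b


def position_composition(
    sequences: list[Record],
    positions: list[str] | None = None,
    occupancy_floor: float = 0.05,
) -> PositionComposition:
    """Per-position amino-acid frequencies with occupancy filtering.

    Positions where fewer than ``occupancy_floor`` of the sequences carry a
    residue are omitted; frequencies are over the sequences observed at the
    position (they renormalise to 1 after filtering).
    """
    n = len(sequences)
    counts: dict[str, Counter] = {}
    for record in sequences:
        for pos, aa in _positions_of(record).items():
            counts.setdefault(pos, Counter())[aa] += 1
    per_position: dict[str, dict[str, float]] = {}
    occupancy: dict[str, float] = {}
    wanted = positions if positions is not None else sorted(counts, key=_pos_sort_key)
    for pos in wanted:
        c = counts.get(pos, Counter())
        occ = sum(c.values()) / n if n else 0.0
        if occ < occupancy_floor:
            continue
        total = sum(c.values())
        per_position[pos] = {aa: k / total for aa, k in sorted(c.items())}
        occupancy[pos] = occ
    return PositionComposition(per_position, occupancy, n, occupancy_floor)


def _pos_sort_key(label: str):
    try:
        return (float(label), "")
    except ValueError:
        return (float("inf"), label)


def expected_identical_overlap(
    set_a: list[Sequence], set_b: list[Sequence]
) -> tuple[float, float, float]:
    """Expected vs observed identity probability between two sequence sets.

    expected: probability that independent draws from A and B are identical
    under a length- and position-independent composition model,
    sum over L of P_A(L) P_B(L) prod over positions of sum over aa of
    f_A(aa|pos,L) f_B(aa|pos,L).

    observed: the empirical cross-set identity probability,
    sum over distinct sequences s of f_A(s) f_B(s).

    Also returned: the fraction of A's distinct sequences present in B (an
    alternative overlap statistic).
    """
    if not set_a or not set_b:
        raise ValueError("empty sequence set")
    by_len_a = _group_by_length(set_a)
    by_len_b = _group_by_length(set_b)
    expected = 0.0
    for length in set(by_len_a) & set(by_len_b):
        pa = len(by_len_a[length]) / len(set_a)
        pb = len(by_len_b[length]) / len(set_b)
        prod = 1.0
        for pos in range(length):
            fa = Counter(s[pos] for s in by_len_a[length])
            fb = Counter(s[pos] for s in by_len_b[length])
            na, nb = len(by_len_a[length]), len(by_len_b[length])
            prod *= sum(fa[aa] / na * fb.get(aa, 0) / nb for aa in fa)
        expected += pa * pb * prod

    freq_a = Counter(set_a)
    freq_b = Counter(set_b)
    observed = sum(
        (ka / len(set_a)) * (freq_b[s] / len(set_b)) for s, ka in freq_a.items() if s in freq_b
    )
    shared = sum(1 for s in set(set_a) if s in freq_b) / len(set(set_a))
    return expected, observed, shared


def _group_by_length(seqs: list[Sequence]) -> dict[int, list[Sequence]]:
    out: dict[int, list[Sequence]] = {}
    for s in seqs:
        out.setdefault(len(s), []).append(s)
    return out


def shannon_entropy(freqs: dict[str, float]) -> float:
    """Shannon entropy in bits over the observed amino-acid frequencies."""
    return -sum(f * math.log2(f) for f in freqs.values() if f > 0)


def framework_conservation(
    background: PositionComposition,
    positions: list[str],
) -> tuple[dict[str, tuple[str, float, float]], list[str]]:
    """Conservation of queried framework positions against a sequence background.

    Returns per-position (modal amino acid, modal frequency, entropy in
    bits) plus the list of positions flagged because they fall below the
    background's occupancy floor (these are not scored).
    """
    scores: dict[str, tuple[str, float, float]] = {}
    flagged: list[str] = []
    for pos in positions:
        pos = str(pos)
        if pos not in background.per_position:
            flagged.append(pos)
            continue
        freqs = background.per_position[pos]
        modal_aa = max(freqs, key=lambda aa: (freqs[aa], aa))
        scores[pos] = (modal_aa, freqs[modal_aa], shannon_entropy(freqs))
    return scores, flagged


def composition_matrix(comp: PositionComposition) -> "pandas.DataFrame":  # noqa: F821
    """Logo-ready position x amino-acid frequency matrix."""
    import pandas as pd

    return pd.DataFrame(comp.per_position).T.fillna(0.0)
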