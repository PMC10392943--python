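"""Resampling statistics for group comparisons.

Group differences between sdAb and Ab metrics are summarised by the
unpaired mean difference with a bootstrap percentile confidence interval
(5000 resamples of size 300 by default) and a two-sided permutation test on
the difference of means.  All routines are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats


@dataclass
class ResamplingResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    boot_size: tuple[int, int]
    n_perm: int
    seed: int | None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def permutation_pvalue(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation test on the difference of means.

    Labels are shuffled over the pooled raw data; the p-value uses +1
    smoothing in numerator and denominator so it is never exactly 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    total = pooled.sum()
    # vectorised label shuffles: each row is one permutation's group-A index set
    hits = 0
    chunk = max(1, min(n_perm, int(2e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)[:, :n_a]
        sums_a = pooled[order].sum(axis=1)
        diffs = np.abs(sums_a / n_a - (total - sums_a) / (n - n_a))
        hits += int(np.sum(diffs >= observed - 1e-12))
        done += m
    return (hits + 1) / (n_perm + 1)


def bootstrap_mean_diff(
    group_a: list[float] | np.ndarray,
    group_b: list[float] | np.ndarray,
    n_boot: int = 5000,
    boot_size: int | None = 300,
    n_perm: int = 5000,
    seed: int | None = None,
) -> ResamplingResult:
    """Unpaired mean difference (A minus B) with bootstrap CI and permutation p.

    ``boot_size`` resamples are drawn with replacement from each group
    (``boot_size=None`` uses each group's own size); the CI is the
    2.5/97.5 percentile interval of the bootstrap differences.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    size_a = boot_size or a.size
    size_b = boot_size or b.size
    boot_a = a[rng.integers(0, a.size, size=(n_boot, size_a))].mean(axis=1)
    boot_b = b[rng.integers(0, b.size, size=(n_boot, size_b))].mean(axis=1)
    diffs = boot_a - boot_b
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    p = permutation_pvalue(a, b, n_perm=n_perm, rng=rng)
    return ResamplingResult(
        mean_diff=float(a.mean() - b.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        n_boot=n_boot,
        boot_size=(size_a, size_b),
        n_perm=n_perm,
        seed=seed,
    )


def pearson_r(x: list[float] | np.ndarray, y: list[float] | np.ndarray) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    return float(_scipy_stats.pearsonr(x, y).statistic)
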