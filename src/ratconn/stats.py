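"""Permutation tests for group contrasts and Pearson correlations.

This is the inferential layer behind every "class A vs class B" contrast in
the pipeline (wiring cost, edge module diversity, strength by edge class,
perturbation impact, hub vs peripheral participation).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    observed_diff: float      # mean(A) − mean(B)
    mean_a: float
    mean_b: float
    ratio: float              # mean(A) / mean(B); NaN when mean(B) == 0
    n_perm: int
    p: float                  # add-one rule, in (0, 1]
    side: str
    seed: int


def permutation_test(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    side: str = "two",
) -> PermutationResult:
    """Label-shuffling test for a difference in group means.

    Group labels are permuted ``n_perm`` times; the p-value follows the
    add-one rule (1 + #{|null diff| ≥ |observed|}) / (1 + n_perm) for the
    two-sided default, with directional variants via ``side="greater"`` /
    ``"less"`` (A vs B).  If the pooled sample has zero variance the test is
    degenerate and p = 1 is returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if side not in ("two", "greater", "less"):
        raise ValueError(f"side must be two/greater/less, got {side!r}")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    observed = mean_a - mean_b
    ratio = mean_a / mean_b if mean_b != 0 else float("nan")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return PermutationResult(observed, mean_a, mean_b, ratio, n_perm, 1.0, side, seed)

    rng = np.random.default_rng(seed)
    n_tot = pooled.size
    # canonical resampling: draw subsets of the *smaller* group's size from
    # the *sorted* pool, so swapping the two groups reproduces the identical
    # null distribution (up to sign) and the two-sided p is exactly symmetric
    n_small = min(a.size, b.size)
    sign = 1.0 if a.size <= b.size else -1.0
    pool_sorted = np.sort(pooled)
    total = pool_sorted.sum()
    null_diffs = np.empty(n_perm)
    block = max(1, min(n_perm, int(2e7 // max(n_tot, 1))))
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        u = rng.random((k, n_tot))
        take = np.argpartition(u, n_small - 1, axis=1)[:, :n_small]
        sum_s = pool_sorted[take].sum(axis=1)
        diff = sum_s / n_small - (total - sum_s) / (n_tot - n_small)
        null_diffs[done:done + k] = sign * diff
        done += k

    if side == "two":
        count = int(np.sum(np.abs(null_diffs) >= abs(observed)))
    elif side == "greater":
        count = int(np.sum(null_diffs >= observed))
    else:
        count = int(np.sum(null_diffs <= observed))
    p = (1 + count) / (1 + n_perm)
    return PermutationResult(observed, mean_a, mean_b, ratio, n_perm, p, side, seed)


def pearson_r(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Product-moment correlation with the t-transform p-value (df = n − 2).

    Pairs with a NaN in either variable are dropped; zero variance in either
    variable yields (nan, nan) — flagged undefined rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
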