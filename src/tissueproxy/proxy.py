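"""Ranking candidate proxy tissues and testing the stability of the winner.

Given an expression matrix, a tissue of interest (TI) and candidate
accessible tissues of analysis (TAs), :func:`rank_tas` orders the TAs by
Pearson correlation with the TI over a phenotype gene list.  Because that
ranking depends on the particular genes in the list,
:func:`randomization_test` repeats the correlation contest on random gene
lists of the same size and counts, per TA, how often it correlates best.
Whether the overall winner is significantly better than the exchangeable
"every TA equally likely to win each round" null is then assessed exactly.

Two p-values are reported for the winner:

``top_ta_tail_p``
    The plain one-sided binomial tail P(X >= k) for the winning TA's win
    count at p0 = 1/|TAs|.  This is the textbook binomial test applied to
    the top tissue, but it ignores that the tissue was *selected* for
    having the most wins and is therefore anti-conservative.
``binomial_p``
    The selection-aware significance call used by this package: the exact
    probability, under a uniform multinomial over the TAs, that the
    *largest* win count reaches the observed maximum,
    P(max_j X_j >= k).  Computed by inclusion-exclusion, no approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_THRESHOLD,
    CorrelationResult,
    ExpressionMatrix,
    ExpressionThreshold,
    GeneSet,
    _selection_mask,
    correlate_tissues,
    pearson_r,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RandomizationResult",
    "rank_tas",
    "randomization_test",
    "binomial_tail_p",
    "multinomial_max_tail_p",
]


def binomial_tail_p(k: int, n: int, p0: float) -> float:
    """Exact one-sided upper tail P(X >= k) for X ~ Binomial(n, p0).

    Computed by direct summation of the probability mass function (no
    normal approximation).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"require 0 <= p0 <= 1, got {p0}")
    if k == 0:
        return 1.0
    if p0 == 1.0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1.0 - p0) ** (n - i)
    return min(total, 1.0)


@lru_cache(maxsize=None)
def _joint_tail(j: int, k: int, n: int, m: int) -> float:
    """P(X_1 >= k, ..., X_j >= k) for (X_1..X_m) ~ Multinomial(n, uniform)."""
    if j == 0:
        return 1.0
    if j * k > n:
        return 0.0
    p = 1.0 / m
    total = 0.0
    # condition on X_1 = a; the rest is multinomial(n - a, uniform over m - 1)
    for a in range(k, n - (j - 1) * k + 1):
        total += (
            math.comb(n, a) * p**a * (1.0 - p) ** (n - a) * _joint_tail(j - 1, k, n - a, m - 1)
        )
    return total


def multinomial_max_tail_p(k: int, n: int, m: int) -> float:
    """Exact P(max_j X_j >= k) for (X_1..X_m) ~ Multinomial(n, uniform over m).

    Inclusion-exclusion over which cells exceed k; terms with j*k > n
    vanish, so the sum is finite and exact up to floating point.
    """
    if m < 1:
        raise ValueError("need at least one category")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    total = 0.0
    for j in range(1, m + 1):
        if j * k > n:
            break
        total += (-1) ** (j + 1) * math.comb(m, j) * _joint_tail(j, k, n, m)
    return float(min(max(total, 0.0), 1.0))


@dataclass(frozen=True)
class RandomizationResult:
    """Outcome of the random-gene-list contest between candidate TAs.

    ``wins`` maps each TA to the number of iterations in which it had the
    highest correlation with the TI; ``binomial_p`` is the selection-aware
    exact p-value for the top TA (see module docstring) and
    ``top_ta_tail_p`` the plain binomial tail at ``null_probability``.
    """

    ti: str
    n_iterations: int
    list_size: int
    wins: Mapping[str, int]
    top_ta: str
    binomial_p: float
    top_ta_tail_p: float
    null_probability: float
    seed: int
    n_ties: int = 0
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if sum(self.wins.values()) != self.n_iterations:
            raise ValueError("wins must sum to n_iterations")


def _as_labels(x) -> list[str]:
    if isinstance(x, str):
        return [x]
    return list(x)


def rank_tas(
    matrix: ExpressionMatrix,
    ti,
    tas: Sequence[str],
    genes: GeneSet,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
    rule: str = "either_tissue",
    log_transform: bool = False,
) -> list[CorrelationResult]:
    """One CorrelationResult per (TI, TA) pair, best correlation first.

    ``ti`` may be a single label or a list of TI tissues; results are
    sorted descending by r within each TI, undefined correlations last.
    """
    tis = _as_labels(ti)
    tas = list(tas)
    if not tas:
        raise ValueError("need at least one candidate TA")
    overlap = set(tis) & set(tas)
    if overlap:
        raise ValueError(f"tissues cannot be both TI and TA: {sorted(overlap)}")
    results: list[CorrelationResult] = []
    for t in tis:
        per_ti = [
            correlate_tissues(matrix, t, ta, genes, threshold, rule, log_transform)
            for ta in tas
        ]
        per_ti.sort(key=lambda c: (not c.defined, -(c.r if c.defined else 0.0), c.ta))
        results.extend(per_ti)
    return results


def _masked_pearson(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() < 3:
        return math.nan
    return pearson_r(x[mask], y[mask])


def randomization_test(
    matrix: ExpressionMatrix,
    ti: str,
    tas: Sequence[str],
    list_size: int,
    n_iterations: int = 100,
    seed: int = 0,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
    rule: str = "either_tissue",
    universe: str = "all",
    log_transform: bool = False,
    max_redraws: int = 1000,
) -> RandomizationResult:
    """Contest the TAs on random gene lists of a fixed size.

    Each iteration samples ``list_size`` genes uniformly without
    replacement from the sampling universe (default: all genes in the
    matrix; ``universe="expressed_in_ti"`` restricts to genes expressed in
    the TI), recomputes the TI correlation of every TA on that list with
    the same threshold/rule as the real analysis, and awards one win to
    the best TA.  Ties for the best correlation are broken toward the
    lexicographically smallest tissue label and counted in ``n_ties``.  A
    TA whose correlation is undefined in an iteration cannot win it; if
    every TA is undefined the iteration is redrawn (at most
    ``max_redraws`` times in total) and counted in ``n_redrawn``.
    """
    tas = sorted(set(tas))
    if not tas:
        raise ValueError("need at least one candidate TA")
    if ti in tas:
        raise ValueError(f"TI {ti!r} cannot also be a TA")
    if list_size < 3:
        raise ValueError(f"list_size must be >= 3, got {list_size}")
    x_all = matrix.tissue_values(ti)
    cols = {ta: matrix.tissue_values(ta) for ta in tas}
    if universe == "all":
        pool = np.arange(len(matrix.feature_ids))
    elif universe == "expressed_in_ti":
        pool = np.flatnonzero(threshold.passes(x_all))
    else:
        raise ValueError(f"universe must be 'all' or 'expressed_in_ti', got {universe!r}")
    if pool.size < list_size:
        raise ValueError(
            f"sampling universe has {pool.size} genes, fewer than list_size={list_size}"
        )
    rng = np.random.default_rng(seed)
    wins = {ta: 0 for ta in tas}
    n_ties = 0
    n_redrawn = 0
    for _ in range(n_iterations):
        while True:
            idx = rng.choice(pool, size=list_size, replace=False)
            x = x_all[idx]
            if log_transform:
                xl = np.log2(x + 1.0)
            best_ta = None
            best_r = -math.inf
            tied = False
            for ta in tas:  # sorted, so ties resolve lexicographically
                y = cols[ta][idx]
                mask = _selection_mask(x, y, threshold, rule)
                if log_transform:
                    r = _masked_pearson(xl, np.log2(y + 1.0), mask)
                else:
                    r = _masked_pearson(x, y, mask)
                if math.isnan(r):
                    continue
                if r > best_r:
                    best_ta, best_r, tied = ta, r, False
                elif r == best_r:
                    tied = True
            if best_ta is not None:
                break
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"all TA correlations undefined in {max_redraws} consecutive redraws"
                )
        wins[best_ta] += 1
        if tied:
            n_ties += 1
    if n_redrawn:
        logger.info("randomization test: redrew %d iterations with no defined r", n_redrawn)
    top_ta = min(wins, key=lambda t: (-wins[t], t))
    k = wins[top_ta]
    p0 = 1.0 / len(tas)
    return RandomizationResult(
        ti=ti,
        n_iterations=n_iterations,
        list_size=list_size,
        wins=wins,
        top_ta=top_ta,
        binomial_p=multinomial_max_tail_p(k, n_iterations, len(tas)),
        top_ta_tail_p=binomial_tail_p(k, n_iterations, p0),
        null_probability=p0,
        seed=seed,
        n_ties=n_ties,
        n_redrawn=n_redrawn,
    )
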