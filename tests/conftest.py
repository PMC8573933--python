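"""Shared fixtures: small hand-set matrices and networks, built in memory."""

import numpy as np
import pandas as pd
import pytest

from tissueproxy.core import ExpressionMatrix, GeneSet, SampleMatrix
from tissueproxy.enrichment import PpiNetwork


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """5 genes x 3 tissues with hand-set values spanning the 1.5 cutoff."""
    df = pd.DataFrame(
        {
            "heart": [10.0, 2.0, 0.2, 5.0, 1.5],
            "muscle": [8.0, 3.0, 0.1, 4.0, 2.5],
            "blood": [0.5, 0.2, 0.3, 0.1, 0.4],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def toy_samples() -> SampleMatrix:
    """3 genes, two tissues with 3 and 2 samples."""
    df = pd.DataFrame(
        {
            "a1": [1.0, 5.0, 0.0],
            "a2": [2.0, 5.0, 0.0],
            "a3": [9.0, 5.0, 0.0],
            "b1": [1.0, 4.0, 2.0],
            "b2": [3.0, 6.0, 2.0],
        },
        index=["g1", "g2", "g3"],
    )
    mapping = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
    return SampleMatrix(df, mapping)


@pytest.fixture
def all_genes() -> GeneSet:
    return GeneSet.from_iterable("all", ["g1", "g2", "g3", "g4", "g5"])


@pytest.fixture
def toy_network() -> PpiNetwork:
    """6-node graph: hub a-(b,c,d); chain d-e; isolated f."""
    return PpiNetwork(
        edges=[("a", "b"), ("a", "c"), ("a", "d"), ("d", "e")],
        nodes=["a", "b", "c", "d", "e", "f"],
    )


def enumerate_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Brute-force oracle: fraction of all C(N, n) draws with >= k successes.

    The population is materialised as K success labels and N-K failure
    labels and every draw is enumerated, so this shares no code path with
    the closed-form implementation.
    """
    from itertools import combinations

    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        hits += sum(population[i] for i in draw) >= k
    return hits / total
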