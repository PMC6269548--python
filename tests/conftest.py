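"""Shared fixtures: a small fast cohort for unit tests and brute-force oracles."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from straintrace.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A miniature cohort used by unit tests that only need structure."""
    return CohortConfig(
        n_pairs_per_group={"VD": 2, "CSD": 2, "CSD_SGA": 1},
        genome_length=40_000,
        n_kos=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


# ----------------------------------------------------------- oracle functions

def pi_enumeration(counts: np.ndarray, mode: str) -> float:
    """Exhaustive read-pair enumeration of per-column diversity.

    ``plugin`` draws ordered pairs with replacement; ``unbiased`` ordered
    pairs without replacement.  Returns the probability that the two drawn
    reads differ.
    """
    counts = np.asarray(counts, dtype=np.int64)
    reads = [allele for allele, c in enumerate(counts) for _ in range(c)]
    n = len(reads)
    pairs = ((itertools.product(range(n), repeat=2)) if mode == "plugin"
             else itertools.permutations(range(n), 2))
    total = diff = 0
    for i, j in pairs:
        total += 1
        diff += reads[i] != reads[j]
    return diff / total


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by summing hypergeometric probabilities
    <= the observed table's probability, over all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x: int) -> Fraction:
        return (Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                         math.comb(n, c1)))

    observed = table_prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((p for x in range(lo, hi + 1)
                 if (p := table_prob(x)) <= observed), Fraction(0))
    return float(total)


def hypergeom_upper_tail_enumeration(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric(M, K, n) by direct summation."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(M - K, n - x),
                          math.comb(M, n))
    return float(total)


def brute_force_best_modularity(graph) -> float:
    """Optimal weighted modularity over all partitions of the node set."""
    import networkx as nx

    nodes = list(graph.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best = -math.inf
    for part in partitions(nodes):
        q = nx.community.modularity(graph, [set(p) for p in part], weight="weight")
        best = max(best, q)
    return best
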