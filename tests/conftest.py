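import math
from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from comorbnet.catalog import GeneSet
from comorbnet.enrichment import AnnotationCollection, AnnotationTerm

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def enumeration_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Independent oracle: exact upper-tail hypergeometric probability by
    direct summation of binomial-coefficient counts (big-integer exact)."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    )
    return Fraction(hits, total)


def stepup_bh(pvalues):
    """Independent oracle: literal BH step-up definition — sort ascending,
    q_(i) = min_{j>=i} p_(j) * m / j capped at 1, back to input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order):
        q = min(
            pvalues[order[j]] * m / (j + 1)
            for j in range(rank_pos, m)
        )
        adjusted[idx] = min(q, 1.0)
    return adjusted


@pytest.fixture
def small_collection() -> AnnotationCollection:
    """Three disjoint-ish terms over a 12-gene universe."""
    terms = [
        AnnotationTerm("T1", "alpha pathway", frozenset({"A1", "A2", "A3", "A4"})),
        AnnotationTerm("T2", "beta pathway", frozenset({"B1", "B2", "B3"})),
        AnnotationTerm("T3", "gamma pathway", frozenset({"A4", "C1", "C2", "C3", "C4"})),
    ]
    return AnnotationCollection("pathway", terms)


@pytest.fixture
def set_a() -> GeneSet:
    return GeneSet(name="a", members=frozenset({"A1", "A2", "A3", "B1"}))


@pytest.fixture
def set_b() -> GeneSet:
    return GeneSet(name="b", members=frozenset({"B1", "B2", "C1"}))
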