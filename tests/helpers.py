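"""Independent brute-force oracles for the belief-function algebra.

These deliberately use frozenset arithmetic and exhaustive enumeration so
they share no code or representation with the bitmask implementation they
check.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np


def powerset(classes):
    s = list(classes)
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))


def brute_belief(focal: dict, A) -> float:
    A = frozenset(A)
    return sum(m for B, m in focal.items() if frozenset(B) and frozenset(B) <= A)


def brute_plausibility(focal: dict, A) -> float:
    A = frozenset(A)
    return sum(m for B, m in focal.items() if frozenset(B) & A)


def brute_conflict(f1: dict, f2: dict) -> float:
    return sum(m1 * m2 for B, m1 in f1.items() for C, m2 in f2.items()
               if not frozenset(B) & frozenset(C))


def brute_combine(f1: dict, f2: dict) -> dict:
    acc = {}
    k = 0.0
    for B, m1 in f1.items():
        for C, m2 in f2.items():
            inter = frozenset(B) & frozenset(C)
            if inter:
                acc[inter] = acc.get(inter, 0.0) + m1 * m2
            else:
                k += m1 * m2
    return {A: m / (1.0 - k) for A, m in acc.items()}


def brute_combine3(f1: dict, f2: dict, f3: dict) -> dict:
    """Direct triple-sum orthogonal combination (no pairwise folding)."""
    acc = {}
    k = 0.0
    for B, m1 in f1.items():
        for C, m2 in f2.items():
            for D, m3 in f3.items():
                inter = frozenset(B) & frozenset(C) & frozenset(D)
                w = m1 * m2 * m3
                if inter:
                    acc[inter] = acc.get(inter, 0.0) + w
                else:
                    k += w
    return {A: m / (1.0 - k) for A, m in acc.items()}


def brute_pignistic(focal: dict, classes) -> dict:
    out = {c: 0.0 for c in classes}
    for A, m in focal.items():
        for c in A:
            out[c] += m / len(A)
    return out


def brute_kappa(correct) -> float:
    """Reference inter-rater agreement computed sample-by-sample in loops."""
    correct = [list(map(bool, row)) for row in correct]
    L = len(correct)
    N = len(correct[0])
    total = sum(sum(row) for row in correct)
    pbar = total / (L * N)
    num = 0.0
    for j in range(N):
        lj = sum(correct[i][j] for i in range(L))
        num += lj * (L - lj)
    return 1.0 - num / (N * L * (L - 1) * pbar * (1.0 - pbar))


def random_normal_bba(rng: np.random.Generator, classes, max_focals: int = 6) -> dict:
    """Random normal BBA as a frozenset->mass dict (for oracle comparisons)."""
    subsets = [s for s in powerset(classes) if s]
    n = rng.integers(1, min(max_focals, len(subsets)) + 1)
    chosen = rng.choice(len(subsets), size=n, replace=False)
    masses = rng.dirichlet(np.ones(n))
    return {frozenset(subsets[i]): float(m) for i, m in zip(chosen, masses)}
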