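"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (subset enumeration, closed-form
combinatorics, triple loops) and never call the implementation paths they
check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from mirweave.expression import CONTROL, TREATED, ExpressionMatrix
from mirweave.sim import SimConfig, generate_dataset


# ---------------------------------------------------------------- oracles

def hypergeom_tail_comb(k: int, N: int, K: int, n: int) -> float:
    """Closed-form upper tail P(X >= k) via exact binomial coefficients."""
    denom = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / denom


def hypergeom_tail_enumerate(k: int, N: int, K: int, n: int) -> float:
    """Upper tail by brute-force enumeration of all n-subsets of [N]."""
    successes = set(range(K))
    hits = total = 0
    for subset in combinations(range(N), n):
        total += 1
        if len(successes.intersection(subset)) >= k:
            hits += 1
    return hits / total


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, independent of the matrix route."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (2000 genes x 32 samples), one fixed seed."""
    return generate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A light dataset for stages where full size is unnecessary."""
    cfg = SimConfig(
        seed=7, n_genes=400, n_mirnas=60,
        module_specs=(("M1", 60, 0.6), ("M2", 50, -0.5)),
    )
    return generate_dataset(cfg)


def make_matrix(values, groups=None, prefix="f"):
    """Small ExpressionMatrix helper for hand-built fixtures."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    sample_ids = [f"s{i}" for i in range(n_samp)]
    if groups is None:
        half = n_samp // 2
        groups = {s: (TREATED if i < half else CONTROL)
                  for i, s in enumerate(sample_ids)}
    return ExpressionMatrix(
        feature_ids=[f"{prefix}{i}" for i in range(n_feat)],
        sample_ids=sample_ids,
        values=values,
        sample_groups=groups,
    )
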