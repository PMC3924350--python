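"""Shared hypergeometric upper-tail kernel.

Every over-representation statistic in the package -- miRNA/mRNA
over-targeting, gene-set enrichment, DE-in-module enrichment, and the
module-overlap contingency tests -- calls the single function below, so
all of them are numerically identical by construction.
"""

from __future__ import annotations

from scipy.stats import hypergeom


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Parameters
    ----------
    k : observed overlap (successes among the draws)
    N : population size
    K : number of success states in the population
    n : number of draws (without replacement)

    Returns the upper tail including ``k`` itself; ``k == 0`` gives 1.0.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"invalid overlap k={k} for K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))
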