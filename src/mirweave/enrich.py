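"""Hypergeometric gene-set enrichment with Benjamini-Hochberg correction.

Used for cell-type marker sets, functional categories, and the enrichment
of differentially expressed genes within coexpression modules. All counts
are restricted to the stated gene universe (by default, all expressed
genes after the presence filter).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd

from .expression import bh_adjust
from .hyper import hypergeom_upper_tail
from .wgcna import GREY


def hypergeom_enrich(query: set[str], collection: Mapping[str, set[str]],
                     universe: set[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set in each gene set.

    Query members outside the universe are dropped with a warning; set
    members are intersected with the universe before counting. Returns one
    row per set with k, K, n, N, p and BH-adjusted p.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped")
    q = query & universe
    N, n = len(universe), len(q)
    rows = []
    for name, members in collection.items():
        K = len(members & universe)
        k = len(members & q)
        p = hypergeom_upper_tail(k, N, K, n) if K else 1.0
        rows.append((name, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"]) \
        .set_index("set_name")
    if len(df):
        df["adj_p"] = bh_adjust(df["p"])
    else:
        df["adj_p"] = []
    return df


def de_in_module_enrichment(labels: Mapping[str, str], de_genes: set[str],
                            universe: set[str]) -> pd.DataFrame:
    """Enrichment of DE genes in each coexpression module (grey included)."""
    unlabeled = universe - set(labels)
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} universe genes lack a module label")
    modules: dict[str, set[str]] = {GREY: set()}
    for g in universe:
        modules.setdefault(labels[g], set()).add(g)
    return hypergeom_enrich(de_genes & universe, modules, universe)
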