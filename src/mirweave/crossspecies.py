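"""Cross-species overlap of differentially expressed miRNA families and genes.

Significance of an observed overlap is assessed empirically: random sets of
the same size are drawn from a shared universe and the add-one Monte Carlo
p-value (1 + #{replicate >= observed}) / (R + 1) reported, so the smallest
attainable p is 1/(R+1). Gene lists are matched across species through
homology groups; direction concordance classifies each common gene by
whether its sign of change agrees between the two species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .universe import map_homologs


@dataclass(frozen=True)
class OverlapResult:
    observed_overlap: int
    size_a: int
    size_b: int
    universe_size: int
    mc_p: float
    R: int
    seed: int

    def __post_init__(self) -> None:
        if self.observed_overlap > min(self.size_a, self.size_b):
            raise ValueError("observed overlap exceeds the smaller set")
        if not 0 < self.mc_p <= 1:
            raise ValueError("mc_p must be in (0, 1]")


def family_overlap(families_a: set[str], families_b: set[str]) -> tuple[set[str], int]:
    common = set(families_a) & set(families_b)
    return common, len(common)


def montecarlo_overlap_p(observed: int, size_a: int, size_b: int,
                         universe_size: int, R: int, seed: int) -> OverlapResult:
    """Empirical p for an overlap of two sets drawn from a common universe.

    Set A is re-drawn uniformly without replacement R times against a fixed
    set B; the add-one estimator never returns 0.
    """
    if max(size_a, size_b) > universe_size:
        raise ValueError("set sizes must not exceed the universe")
    if observed > min(size_a, size_b):
        raise ValueError("observed overlap exceeds the smaller set")
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6d63]))
    hits = 0
    for _ in range(R):
        draw = rng.choice(universe_size, size=size_a, replace=False)
        if int((draw < size_b).sum()) >= observed:
            hits += 1
    mc_p = (1 + hits) / (R + 1)
    return OverlapResult(observed, size_a, size_b, universe_size, mc_p, R, seed)


def gene_overlap_crossspecies(de_a: set[str], de_b: set[str],
                              homology: pd.DataFrame, taxon_a: str, taxon_b: str,
                              universe_a: set[str], R: int = 10_000,
                              seed: int = 0) -> tuple[set[str], OverlapResult]:
    """Overlap of two DE gene lists after homology conversion of list B.

    ``de_b`` symbols (taxon_b) are converted into taxon_a symbols and
    intersected with ``de_a``; Monte Carlo significance is evaluated over
    ``universe_a`` (all taxon_a genes eligible for list A).
    """
    mapped, _ = map_homologs(sorted(de_b), homology, from_taxon=taxon_b,
                             to_taxon=taxon_a)
    mapped_cf = {m.casefold() for m in mapped}
    common = {g for g in de_a if g.casefold() in mapped_cf}
    universe_cf = {u.casefold() for u in universe_a}
    size_b = len(mapped_cf & universe_cf)
    size_a = len({g.casefold() for g in de_a} & universe_cf)
    result = montecarlo_overlap_p(len(common), size_a, size_b,
                                  len(universe_cf), R=R, seed=seed)
    return common, result


def direction_concordance(common: Iterable[str], dirs_a: Mapping[str, str],
                          dirs_b: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene direction agreement between two species.

    Returns one row per common gene with both directions and a concordant
    flag; summary percentages live in ``df.attrs`` (NaN when empty).
    """
    rows = []
    for g in sorted(common):
        if g not in dirs_a or g not in dirs_b:
            raise ValueError(f"direction undefined for gene {g!r}")
        rows.append((g, dirs_a[g], dirs_b[g], dirs_a[g] == dirs_b[g]))
    df = pd.DataFrame(rows, columns=["gene", "direction_a", "direction_b",
                                     "concordant"])
    if len(df):
        pct_concordant = 100.0 * df["concordant"].mean()
        df.attrs.update(
            pct_concordant=pct_concordant,
            pct_opposite=100.0 - pct_concordant,
            pct_up_a=100.0 * (df["direction_a"] == "up").mean(),
            pct_up_b=100.0 * (df["direction_b"] == "up").mean(),
        )
    else:
        df.attrs.update(pct_concordant=np.nan, pct_opposite=np.nan,
                        pct_up_a=np.nan, pct_up_b=np.nan)
    return df
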