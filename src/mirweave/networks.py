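"""Correlated bipartite targeting networks, randomized nulls, and over-targeting.

The positively correlated network joins upregulated miRNAs to their
upregulated targets; the negatively correlated network joins upregulated
miRNAs to downregulated targets. Interconnectedness is summarized as the
average number of neighbors (mean degree over connected nodes) and compared
against randomized control networks in which the gene set is resampled
uniformly from the expressed-and-targetable gene universe.

Over-targeting asks, per miRNA, whether its targets are over-represented in
a differentially expressed gene set under hypergeometric sampling; the
symmetric per-mRNA test asks whether a gene is targeted by more
differentially expressed miRNAs than expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import networkx as nx

from .expression import bh_adjust
from .hyper import hypergeom_upper_tail
from .universe import InteractionUniverse, targets_of


@dataclass
class BipartiteNetwork:
    """miRNA-gene bipartite network; only nodes of degree >= 1 are members."""

    mirna_nodes: set[str]
    gene_nodes: set[str]
    edges: set[tuple[str, str]]
    label: str = "positive"

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if m not in self.mirna_nodes or g not in self.gene_nodes:
                raise ValueError(f"edge ({m}, {g}) has endpoint outside node sets")

    @property
    def n_nodes(self) -> int:
        return len(self.mirna_nodes) + len(self.gene_nodes)

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.mirna_nodes, bipartite="mirna")
        g.add_nodes_from(self.gene_nodes, bipartite="gene")
        g.add_edges_from(self.edges)
        return g

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(sorted(self.edges), columns=["mirna_id", "gene_symbol"])
        df["label"] = self.label
        df.to_csv(path, sep="\t", index=False)
        return path


@dataclass
class NullSummary:
    """Per-replicate statistics of randomized control networks."""

    mean_degrees: np.ndarray
    overtarget_proportions: np.ndarray
    R: int
    seed: int

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")

    @property
    def mean_degree(self) -> float:
        return float(np.mean(self.mean_degrees))

    @property
    def sd_degree(self) -> float:
        return float(np.std(self.mean_degrees, ddof=1)) if self.R > 1 else 0.0

    @property
    def overtarget_proportion(self) -> float:
        return float(np.nanmean(self.overtarget_proportions))


def build_bipartite(universe: InteractionUniverse, mirna_set: set[str],
                    gene_set: set[str], label: str = "positive") -> BipartiteNetwork:
    """Restrict the universe to the given node candidates; drop isolated nodes."""
    if not mirna_set or not gene_set:
        raise ValueError("mirna_set and gene_set must be nonempty")
    edges = set()
    for m in mirna_set:
        for g in targets_of(universe, m, gene_set):
            edges.add((m, g))
    return BipartiteNetwork(
        mirna_nodes={m for m, _ in edges},
        gene_nodes={g for _, g in edges},
        edges=edges,
        label=label,
    )


def average_neighbors(network: BipartiteNetwork) -> float:
    """Mean degree 2|E|/|V| over the connected (degree >= 1) nodes."""
    if network.n_nodes == 0:
        raise ValueError("network has no connected nodes")
    return 2.0 * len(network.edges) / network.n_nodes


def mirna_overtargeting(universe: InteractionUniverse, mirna_set: set[str],
                        de_set: set[str], expressed: set[str],
                        fdr: float = 0.10) -> pd.DataFrame:
    """Per-miRNA hypergeometric over-representation of targets in a DE gene set.

    The sampling population is the set of expressed genes that are a target
    of at least one universe miRNA (genes outside the universe can never be
    drawn as targets). miRNAs with no expressed target are excluded and
    flagged in the ``tested`` column.
    """
    if not de_set <= expressed:
        raise ValueError("de_set must be a subset of expressed")
    universe_genes_cf = {g.casefold() for g in universe.genes}
    targetable = {g for g in expressed if g.casefold() in universe_genes_cf}
    n_success = len(de_set & targetable)
    N = len(targetable)
    rows = []
    for m in sorted(mirna_set):
        targ = targets_of(universe, m, targetable)
        K = len(targ)
        k = len(targ & de_set)
        if K == 0:
            rows.append((m, 0, 0, np.nan, False))
        else:
            p = hypergeom_upper_tail(k, N, n_success, K)
            rows.append((m, K, k, p, True))
    df = pd.DataFrame(rows, columns=["mirna_id", "K", "k", "p", "tested"])
    df = df.set_index("mirna_id")
    df["adj_p"] = np.nan
    tested = df["tested"]
    if tested.any():
        df.loc[tested, "adj_p"] = bh_adjust(df.loc[tested, "p"])
    df["overtargeting"] = df["adj_p"] < fdr
    df.attrs.update(N=N, n_de=n_success, fdr=fdr)
    return df


def mrna_overtargeting(universe: InteractionUniverse, mirna_de_set: set[str],
                       expressed_mirnas: set[str], gene_set: set[str],
                       fdr: float = 0.10) -> pd.DataFrame:
    """Per-mRNA over-targeting by DE miRNAs (roles of the test swapped).

    Only genes targeted by more than one expressed miRNA are tested;
    the population is the expressed miRNAs present in the universe.
    """
    pop = expressed_mirnas & universe.mirnas
    n_success = len(mirna_de_set & pop)
    N = len(pop)
    gene_cf = {g.casefold(): g for g in gene_set}
    targeting: dict[str, set[str]] = {g: set() for g in gene_cf.values()}
    for m in pop:
        for t in universe.targets(m):
            g = gene_cf.get(t.casefold())
            if g is not None:
                targeting[g].add(m)
    rows = []
    for g in sorted(targeting):
        mirnas = targeting[g]
        K = len(mirnas)
        if K <= 1:
            rows.append((g, K, len(mirnas & mirna_de_set), np.nan, False))
        else:
            k = len(mirnas & mirna_de_set)
            p = hypergeom_upper_tail(k, N, n_success, K)
            rows.append((g, K, k, p, True))
    df = pd.DataFrame(rows, columns=["gene_symbol", "K", "k", "p", "tested"])
    df = df.set_index("gene_symbol")
    df["adj_p"] = np.nan
    tested = df["tested"]
    if tested.any():
        df.loc[tested, "adj_p"] = bh_adjust(df.loc[tested, "p"])
    df["overtargeting"] = df["adj_p"] < fdr
    df.attrs.update(N=N, n_de=n_success, fdr=fdr)
    return df


def randomize_networks(universe: InteractionUniverse, mirna_set: set[str],
                       gene_universe: set[str], gene_set_size: int,
                       R: int, seed: int, fdr: float = 0.10) -> NullSummary:
    """Randomized control networks: resample the gene set, keep the miRNAs fixed.

    For each replicate a gene set of the observed cardinality is drawn
    uniformly without replacement from the expressed-and-targetable gene
    universe; the bipartite network is rebuilt and its mean degree and
    over-targeting proportion recorded.
    """
    if gene_set_size > len(gene_universe):
        raise ValueError("gene_set_size exceeds the gene universe")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6e65]))
    genes = np.array(sorted(gene_universe))
    # precompute per-miRNA target membership over the ordered gene universe
    mirnas = sorted(mirna_set)
    masks = []
    for m in mirnas:
        targ = targets_of(universe, m, gene_universe)
        masks.append(np.isin(genes, np.array(sorted(targ)) if targ else []))
    masks = np.array(masks) if masks else np.zeros((0, len(genes)), dtype=bool)
    targetable = masks.any(axis=0)
    N = int(targetable.sum())
    mean_degrees = np.empty(R)
    props = np.empty(R)
    for r in range(R):
        pick = rng.choice(len(genes), size=gene_set_size, replace=False)
        sel = np.zeros(len(genes), dtype=bool)
        sel[pick] = True
        K_per = masks.sum(axis=1)            # expressed targets per miRNA
        k_per = masks[:, sel].sum(axis=1)    # targets within the sampled set
        n_edges = int(k_per.sum())
        n_mirna_nodes = int((k_per > 0).sum())
        n_gene_nodes = int(masks[:, sel].any(axis=0).sum())
        n_nodes = n_mirna_nodes + n_gene_nodes
        mean_degrees[r] = 2.0 * n_edges / n_nodes if n_nodes else np.nan
        tested = K_per > 0
        if tested.any():
            n_success = int((sel & targetable).sum())
            p = stats.hypergeom.sf(k_per[tested] - 1, N, n_success, K_per[tested])
            adj = bh_adjust(p)
            props[r] = float(np.mean(adj < fdr))
        else:
            props[r] = np.nan
    return NullSummary(mean_degrees=mean_degrees, overtarget_proportions=props,
                       R=R, seed=seed)


def proportion_gof_test(k: int, n: int, p0: float) -> tuple[float, float]:
    """Pearson chi-squared goodness of fit of k/n against proportion p0.

    One degree of freedom, no continuity correction, two-sided p.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    observed = np.array([k, n - k], dtype=float)
    expected = np.array([n * p0, n * (1 - p0)])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def network_contrast_report(positive: BipartiteNetwork, negative: BipartiteNetwork,
                            positive_null: NullSummary, negative_null: NullSummary,
                            positive_overtarget: pd.DataFrame,
                            negative_overtarget: pd.DataFrame) -> pd.DataFrame:
    """Observed-vs-null summary for the two correlated networks.

    One row per network with mean degree, null mean degree +/- SD, the
    over-targeting proportion, the null expectation, and the chi-squared
    comparison of the two; ``enrichment`` flags whether the observed mean
    degree exceeds the null by more than 3 null SD (or falls below it).
    """
    rows = []
    for net, null, ot in ((positive, positive_null, positive_overtarget),
                          (negative, negative_null, negative_overtarget)):
        obs_deg = average_neighbors(net)
        tested = ot["tested"]
        n_tested = int(tested.sum())
        n_over = int(ot.loc[tested, "overtargeting"].sum())
        prop = n_over / n_tested if n_tested else np.nan
        p0 = null.overtarget_proportion
        if n_tested and 0 < p0 < 1:
            chi2, gof_p = proportion_gof_test(n_over, n_tested, p0)
        else:
            chi2, gof_p = np.nan, np.nan
        z = ((obs_deg - null.mean_degree) / null.sd_degree
             if null.sd_degree > 0 else np.nan)
        flag = "none"
        if np.isfinite(z):
            flag = "enriched" if z > 3 else ("depleted" if z < -3 else "none")
        rows.append({
            "network": net.label,
            "n_mirnas": len(net.mirna_nodes),
            "n_genes": len(net.gene_nodes),
            "n_edges": len(net.edges),
            "mean_degree": obs_deg,
            "null_mean_degree": null.mean_degree,
            "null_sd_degree": null.sd_degree,
            "null_R": null.R,
            "degree_z": z,
            "overtarget_n": n_over,
            "overtarget_tested": n_tested,
            "overtarget_proportion": prop,
            "null_overtarget_proportion": p0,
            "proportion_chi2": chi2,
            "proportion_p": gof_p,
            "connectivity": flag,
        })
    return pd.DataFrame(rows).set_index("network")


def write_contrast_tsv(report: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    report.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_contrast_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
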