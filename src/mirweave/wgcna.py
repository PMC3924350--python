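"""Signed weighted gene coexpression network analysis.

Pipeline: signed similarity S_ij = (1 + cor(x_i, x_j)) / 2, soft-threshold
adjacency a_ij = S_ij^beta (beta chosen for approximate scale-free
connectivity), topological overlap TOM, average-linkage clustering of
1 - TOM, static-height tree cut with a minimum module size, module
eigengenes (first principal component of the standardized module
submatrix), and the derived per-gene statistics: module membership
MM = cor(gene, eigengene) and gene significance GS = |cor(gene, trait)|.

The signed similarity maps anti-correlated pairs to 0, so modules group
genes whose profiles move together in the same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, bh_adjust
from .hyper import hypergeom_upper_tail

GREY = "grey"

# size-ordered module color convention (largest module first)
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class SimilarityMatrix:
    genes: list[str]
    values: np.ndarray  # (g, g) in [0, 1], unit diagonal

    def __post_init__(self) -> None:
        _check_square(self.values, len(self.genes))


@dataclass
class AdjacencyMatrix:
    genes: list[str]
    values: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        _check_square(self.values, len(self.genes))


@dataclass
class TOMMatrix:
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square(self.values, len(self.genes))

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


def _check_square(m: np.ndarray, n: int) -> None:
    if m.shape != (n, n):
        raise ValueError(f"matrix shape {m.shape} does not match {n} genes")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("matrix is not symmetric")


def signed_similarity(matrix: ExpressionMatrix) -> SimilarityMatrix:
    """S = (1 + Pearson r) / 2; zero-variance genes are dropped with a warning."""
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = matrix.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(matrix.feature_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance genes: "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    genes = [g for g, k in zip(matrix.feature_ids, keep) if k]
    r = np.atleast_2d(np.corrcoef(matrix.values[keep]))
    r = np.clip(r, -1.0, 1.0)
    s = (1.0 + r) / 2.0
    np.fill_diagonal(s, 1.0)
    s = (s + s.T) / 2.0
    return SimilarityMatrix(genes=genes, values=s)


def soft_adjacency(similarity: SimilarityMatrix, beta: float = 12.0) -> AdjacencyMatrix:
    """Elementwise power a_ij = S_ij^beta, emphasizing strong correlations."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    return AdjacencyMatrix(genes=list(similarity.genes),
                           values=similarity.values ** beta, beta=beta)


def scale_free_fit(adjacency: AdjacencyMatrix, n_bins: int = 10) -> tuple[float, float, float]:
    """Scale-free topology fit of the connectivity distribution.

    Connectivities k_i = sum_{j != i} a_ij are binned into ``n_bins``
    equal-width bins; log10 frequency is regressed on log10 mean-k per bin.
    Returns (r_squared, slope, mean_k); degenerate distributions give R2=0.
    """
    a = adjacency.values.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    mean_k = float(k.mean())
    if np.ptp(k) == 0:
        return 0.0, 0.0, mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, centers = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0:
            freqs.append(mask.mean())
            centers.append(k[mask].mean())
    freqs, centers = np.array(freqs), np.array(centers)
    ok = (freqs > 0) & (centers > 0)
    if ok.sum() < 2:
        return 0.0, 0.0, mean_k
    res = stats.linregress(np.log10(centers[ok]), np.log10(freqs[ok]))
    return float(res.rvalue ** 2), float(res.slope), mean_k


def pick_soft_threshold(similarity: SimilarityMatrix,
                        beta_grid: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
                        r2_target: float = 0.85) -> pd.DataFrame:
    """Scan soft-threshold powers and choose the scale-free-fitting one.

    Chooses the smallest beta whose fit R^2 reaches ``r2_target``; if none
    does, the beta with the highest R^2. The chosen power is stored in
    ``df.attrs['beta']``.
    """
    if not beta_grid:
        raise ValueError("beta_grid must be nonempty")
    rows = []
    for beta in beta_grid:
        r2, slope, mean_k = scale_free_fit(soft_adjacency(similarity, beta))
        rows.append((beta, r2, slope, mean_k))
    df = pd.DataFrame(rows, columns=["beta", "r_squared", "slope", "mean_k"])
    reaching = df[df["r_squared"] >= r2_target]
    chosen = float(reaching["beta"].iloc[0]) if len(reaching) else \
        float(df.loc[df["r_squared"].idxmax(), "beta"])
    df.attrs["beta"] = chosen
    df.attrs["r2_target"] = r2_target
    return df


def topological_overlap(adjacency: AdjacencyMatrix) -> TOMMatrix:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), unit diagonal.

    l_ij sums shared neighbor strength over u != i, j; k_i is the
    connectivity excluding the diagonal.
    """
    a = adjacency.values.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l_ij = sum_u a_iu a_uj over u != i, j (diag of a is 0)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(genes=list(adjacency.genes), values=tom)


def detect_modules(dissimilarity: np.ndarray, genes: list[str],
                   min_module_size: int = 100,
                   cut_height: float = 0.99,
                   expression: "ExpressionMatrix | None" = None,
                   kme_min: float = 0.5) -> dict[str, str]:
    """Static-height tree cut of average-linkage clustering into color modules.

    Branches merging below ``cut_height`` x the maximum merge height form
    candidate clusters; clusters smaller than ``min_module_size`` fall into
    "grey". When an expression matrix is supplied, final assignments are
    refined by module membership: genes whose |kME| to their candidate
    module eigengene is below ``kme_min`` are returned to grey (with few
    samples, tree branches recruit low-connectivity satellite genes whose
    chance correlation to a module profile inflates topological overlap;
    the membership filter removes them). Surviving modules are named by
    decreasing size following the conventional color order (ties broken by
    first gene index).
    """
    n = len(genes)
    if dissimilarity.shape != (n, n):
        raise ValueError("dissimilarity shape does not match gene list")
    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count; all genes unassigned")
        return {g: GREY for g in genes}
    d = (dissimilarity + dissimilarity.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    max_height = link[:, 2].max() if len(link) else 0.0
    if max_height == 0:
        clusters = np.ones(n, dtype=int)
    else:
        clusters = hierarchy.fcluster(link, t=cut_height * max_height,
                                      criterion="distance")
    members: dict[int, list[int]] = {}
    for i, c in enumerate(clusters):
        members.setdefault(int(c), []).append(i)
    kept = {c: idx for c, idx in members.items() if len(idx) >= min_module_size}
    if expression is not None and kept:
        kept = _membership_cleanup(expression, genes, kept, kme_min,
                                   min_module_size)
    order = sorted(kept, key=lambda c: (-len(kept[c]), min(kept[c])))
    labels = {g: GREY for g in genes}
    for rank, c in enumerate(order):
        name = COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE) \
            else f"module{rank + 1}"
        for i in kept[c]:
            labels[genes[i]] = name
    return labels


def _membership_cleanup(expression: "ExpressionMatrix", genes: list[str],
                        modules: dict[int, list[int]], kme_min: float,
                        min_module_size: int) -> dict[int, list[int]]:
    """Drop genes with |kME| below threshold from their candidate module."""
    gi = {g: i for i, g in enumerate(expression.feature_ids)}
    missing = [g for g in genes if g not in gi]
    if missing:
        raise ValueError(f"expression matrix lacks genes: {missing[:5]}")
    z = _standardize(expression.values)
    cleaned: dict[int, list[int]] = {}
    for c, idx in modules.items():
        sub = z[[gi[genes[i]] for i in idx]]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        me = vt[0]
        if np.dot(me, sub.mean(axis=0)) < 0:
            me = -me
        kme = _cor_with(sub, me)
        keep = [i for i, r in zip(idx, kme) if abs(r) >= kme_min]
        if len(keep) >= min_module_size:
            cleaned[c] = keep
    return cleaned


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def module_eigengenes(matrix: ExpressionMatrix, labels: dict[str, str],
                      include_grey: bool = False) -> pd.DataFrame:
    """First principal component per module, oriented along the mean profile.

    Returns a (module x sample) DataFrame; each eigengene has unit norm
    across samples and non-negative correlation with the module's average
    standardized profile.
    """
    idx = {g: i for i, g in enumerate(matrix.feature_ids)}
    modules = sorted({m for m in labels.values() if include_grey or m != GREY})
    rows = []
    for mod in modules:
        members = [idx[g] for g in matrix.feature_ids if labels.get(g) == mod]
        if len(members) < 1:
            raise ValueError(f"module {mod!r} has no genes in the matrix")
        z = _standardize(matrix.values[members])
        # first right singular vector = profile over samples
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        rows.append(me)
    return pd.DataFrame(rows, index=pd.Index(modules, name="module"),
                        columns=matrix.sample_ids)


def cor_pvalue_student(r: float, n: int) -> float:
    """Two-sided Student-t p-value for a Pearson correlation of r over n samples."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _cor_with(profiles: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of ``profiles`` with a single target vector."""
    pz = _standardize(profiles)
    tz = _standardize(target[None, :])[0]
    return np.clip(pz @ tz / pz.shape[1], -1.0, 1.0)


def relate_to_traits(matrix: ExpressionMatrix, eigengenes: pd.DataFrame,
                     trait: pd.Series, mirna_profiles: pd.DataFrame | None = None,
                     labels: dict[str, str] | None = None,
                     corr_fdr: float = 0.10) -> dict[str, pd.DataFrame]:
    """Gene- and module-level trait statistics.

    Returns:
      gene_stats    per gene: module, signed GS, |GS| and p, MM to own module and p
      module_trait  per module eigengene: r vs trait, Student-t p
      module_mirna  eigengene x miRNA grid: r, p, BH-adjusted p over the whole
                    grid, and a significance flag at ``corr_fdr`` (empty when
                    no miRNA profiles are given)
    """
    missing = [s for s in matrix.sample_ids if s not in trait.index]
    if missing:
        raise ValueError(f"trait missing samples: {missing}")
    if mirna_profiles is not None:
        missing = [s for s in matrix.sample_ids if s not in mirna_profiles.columns]
        if missing:
            raise ValueError(f"miRNA profiles missing samples: {missing}")
    t = trait.loc[matrix.sample_ids].to_numpy(dtype=float)
    n = matrix.n_samples
    gs_signed = _cor_with(matrix.values, t)
    gene_rows = {
        "module": [labels.get(g, GREY) if labels else GREY
                   for g in matrix.feature_ids],
        "GS_signed": gs_signed,
        "GS": np.abs(gs_signed),
        "GS_p": [cor_pvalue_student(r, n) for r in gs_signed],
    }
    me_mat = eigengenes.to_numpy()
    me_index = {m: i for i, m in enumerate(eigengenes.index)}
    mm = np.full(matrix.n_features, np.nan)
    mm_p = np.full(matrix.n_features, np.nan)
    z = _standardize(matrix.values)
    for i, g in enumerate(matrix.feature_ids):
        mod = gene_rows["module"][i]
        if mod in me_index:
            r = float(_cor_with(z[i][None, :], me_mat[me_index[mod]])[0])
            mm[i] = r
            mm_p[i] = cor_pvalue_student(r, n)
    gene_rows["MM"] = mm
    gene_rows["MM_p"] = mm_p
    gene_stats = pd.DataFrame(gene_rows,
                              index=pd.Index(matrix.feature_ids, name="gene"))
    mt_rows = []
    for m in eigengenes.index:
        r = float(_cor_with(me_mat[me_index[m]][None, :], t)[0])
        mt_rows.append((m, r, cor_pvalue_student(r, n)))
    module_trait = pd.DataFrame(mt_rows, columns=["module", "r", "p"]) \
        .set_index("module")
    if mirna_profiles is not None and len(mirna_profiles):
        mp = mirna_profiles[matrix.sample_ids].to_numpy(dtype=float)
        grid = []
        for m in eigengenes.index:
            rs = _cor_with(mp, me_mat[me_index[m]])
            for mid, r in zip(mirna_profiles.index, rs):
                grid.append((m, mid, float(r), cor_pvalue_student(float(r), n)))
        module_mirna = pd.DataFrame(grid, columns=["module", "mirna_id", "r", "p"])
        module_mirna["adj_p"] = bh_adjust(module_mirna["p"])
        module_mirna["significant"] = module_mirna["adj_p"] < corr_fdr
    else:
        module_mirna = pd.DataFrame(columns=["module", "mirna_id", "r", "p",
                                             "adj_p", "significant"])
    return {"gene_stats": gene_stats, "module_trait": module_trait,
            "module_mirna": module_mirna}


def module_overlap(labels_a: dict[str, str],
                   labels_b: dict[str, str]) -> pd.DataFrame:
    """Module correspondence between two decompositions of the same genes.

    Returns one row per (module_a, module_b) cell with the overlap count and
    an upper-tail hypergeometric p (BH-adjusted across cells). Gene sets
    are restricted to the intersection with a warning if they differ.
    """
    common = set(labels_a) & set(labels_b)
    if common != set(labels_a) or common != set(labels_b):
        warnings.warn("gene sets differ; restricting to the intersection")
    if not common:
        raise ValueError("no genes in common")
    N = len(common)
    by_a: dict[str, set[str]] = {}
    by_b: dict[str, set[str]] = {}
    for g in common:
        by_a.setdefault(labels_a[g], set()).add(g)
        by_b.setdefault(labels_b[g], set()).add(g)
    rows = []
    for ma in sorted(by_a):
        for mb in sorted(by_b):
            k = len(by_a[ma] & by_b[mb])
            p = hypergeom_upper_tail(k, N, len(by_a[ma]), len(by_b[mb]))
            rows.append((ma, mb, len(by_a[ma]), len(by_b[mb]), k, p))
    df = pd.DataFrame(rows, columns=["module_a", "module_b", "size_a", "size_b",
                                     "overlap", "p"])
    df["adj_p"] = bh_adjust(df["p"])
    return df


def extract_hub_network(gene_stats: pd.DataFrame, adjacency: AdjacencyMatrix,
                        module: str, mm_min: float = 0.5,
                        gs_min: float = 0.5) -> dict[str, object]:
    """Weighted within-module network of high-MM, high-GS genes.

    Inclusion is strict: |MM| > mm_min and GS > gs_min. Edges are weighted
    by adjacency; connectivity is the within-subnetwork adjacency row sum,
    and the hub is the gene with maximal connectivity.
    """
    if module not in set(gene_stats["module"]):
        raise ValueError(f"module {module!r} not present")
    members = gene_stats[(gene_stats["module"] == module)
                         & (gene_stats["MM"].abs() > mm_min)
                         & (gene_stats["GS"] > gs_min)].index.tolist()
    members = [g for g in members if g in adjacency.genes]
    if not members:
        warnings.warn(f"no gene in module {module!r} passes MM > {mm_min}, "
                      f"GS > {gs_min}")
        return {"genes": [], "edges": pd.DataFrame(columns=["gene_a", "gene_b",
                                                            "weight"]),
                "connectivity": pd.Series(dtype=float), "hub": None}
    gi = {g: i for i, g in enumerate(adjacency.genes)}
    sub = adjacency.values[np.ix_([gi[g] for g in members],
                                  [gi[g] for g in members])].copy()
    np.fill_diagonal(sub, 0.0)
    edges = []
    for i, ga in enumerate(members):
        for j in range(i + 1, len(members)):
            edges.append((ga, members[j], float(sub[i, j])))
    connectivity = pd.Series(sub.sum(axis=1), index=members, name="connectivity")
    return {
        "genes": members,
        "edges": pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]),
        "connectivity": connectivity,
        "hub": connectivity.idxmax(),
    }
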