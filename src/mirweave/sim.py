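"""Synthetic paired miRNA/mRNA expression with known ground truth.

The generator emulates the statistical structure of a two-group (20
ethanol-treated vs 12 control mice) paired microarray study on the log2
scale: small group-mean shifts (|logFC| in [0.15, 0.7]), coexpression
modules driven by shared latent profiles that correlate with an ethanol
consumption trait (g/kg per 3-h session; treated mean 4.92, SD 0.52;
controls drink none), a predominance of upregulation among differentially
expressed miRNAs, and a miRNA->gene interaction universe in which
upregulated miRNAs preferentially target upregulated genes (the
``overtarget_enrichment`` odds multiplier).

Module latents are built with their stated sample correlation to the trait
*exactly* and mutually orthogonal (Gram-Schmidt in the residual space), so
distinct modules stay distinguishable; because the consumption trait
separates the groups, a trait-correlated module latent also shifts its
genes between groups -- exactly the situation in which trait-correlated
coexpression modules are enriched in differentially expressed genes. The
ground-truth log-fold-change of each gene therefore combines any planted
shift with the realized latent-induced shift, and DE labels follow the
total.

One pseudo-random stream per dataset, split into named substreams
(expression, trait, edges, ...), keeps existing draws stable when new
features are added.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CONTROL, TREATED, ExpressionMatrix
from .universe import PREDICTION_TOOLS, Edge, InteractionUniverse

CONSUMPTION_MEAN = 4.92  # g/kg/3h, treated group
CONSUMPTION_SD = 0.52


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic dataset."""

    n_treated: int = 20
    n_control: int = 12
    n_genes: int = 2000
    n_mirnas: int = 300
    module_specs: tuple[tuple[str, int, float], ...] = (
        ("M1", 160, 0.60),
        ("M2", 140, -0.50),
        ("M3", 120, 0.45),
        ("M4", 100, -0.40),
    )
    de_fraction_genes: float = 0.075
    de_fraction_mirnas: float = 0.25
    gene_up_fraction: float = 0.58   # 413 of 709 DE genes upregulated
    mirna_up_fraction: float = 0.85  # miRNA upregulation predominant
    logfc_range: tuple[float, float] = (0.15, 0.7)
    module_amplitude: float = 0.6    # log2 units per unit latent
    noise_sd: float = 0.2            # per-gene residual SD, log2 units
    overtarget_enrichment: float = 4.0
    baseline_edge_prob: float = 0.02
    validated_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_treated", "n_control", "n_genes", "n_mirnas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("de_fraction_genes", "de_fraction_mirnas", "gene_up_fraction",
                     "mirna_up_fraction", "baseline_edge_prob", "validated_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.logfc_range[0] > self.logfc_range[1]:
            raise ValueError("logfc_range low must be <= high")
        if self.noise_sd < 0 or self.module_amplitude < 0:
            raise ValueError("noise_sd and module_amplitude must be >= 0")
        if self.overtarget_enrichment < 1:
            raise ValueError("overtarget_enrichment must be >= 1")
        if sum(size for _, size, _ in self.module_specs) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for mid, size, rho in self.module_specs:
            if size <= 0:
                raise ValueError(f"module {mid}: size must be > 0")
            if not -1 <= rho <= 1:
                raise ValueError(f"module {mid}: trait correlation outside [-1, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_treated + self.n_control


@dataclass
class SyntheticTruth:
    """Planted labels used by recovery tests."""

    gene_de_labels: dict[str, str]    # gene -> up | down | null
    mirna_de_labels: dict[str, str]
    module_labels: dict[str, str]     # gene -> module_id or "noise"
    gene_logfc: dict[str, float]      # total expected treated-minus-control shift
    mirna_logfc: dict[str, float]
    trait: pd.Series                  # sample -> consumption (g/kg/3h)
    planted_edges: set[tuple[str, str]]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, stream name)."""
    tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _module_latents(rhos: list[float], trait: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-variance latents with exact trait correlations, mutually orthogonal.

    Each latent u_m satisfies sample cor(u_m, trait) = rho_m exactly. The
    residual directions are chosen with the negative inner products that
    cancel the shared trait component, so cor(u_i, u_j) = 0 whenever the
    correlation pattern permits (sum of rho^2 <= 1); otherwise residuals
    fall back to mutually orthogonal directions and cor(u_i, u_j) = rho_i*rho_j.
    """
    n = len(trait)
    k = len(rhos)
    tz = _unit(trait)
    # orthonormal residual basis perpendicular to the trait
    basis = []
    while len(basis) < k:
        e = rng.standard_normal(n)
        e = e - e.mean()  # keep the latent space centered
        e = e - np.dot(e, tz) * tz
        for b in basis:
            e = e - np.dot(e, b) * b
        norm = np.linalg.norm(e)
        if norm > 1e-8:
            basis.append(e / norm)
    basis = np.array(basis)
    scale = np.sqrt([max(0.0, 1.0 - r * r) for r in rhos])
    gram = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i != j and scale[i] > 0 and scale[j] > 0:
                gram[i, j] = -rhos[i] * rhos[j] / (scale[i] * scale[j])
    try:
        chol = np.linalg.cholesky(gram + 1e-12 * np.eye(k))
        resid = chol @ basis
    except np.linalg.LinAlgError:
        resid = basis  # rho pattern infeasible for exact orthogonality
    units = np.array([r * tz + s * f for r, s, f in zip(rhos, scale, resid)])
    return units * np.sqrt(n)  # unit sample variance


def plant_modules(n_genes: int, module_specs, n_samples: int, noise_sd: float,
                  seed: int, trait: np.ndarray | None = None,
                  amplitude: float = 0.6
                  ) -> tuple[np.ndarray, dict[int, str], np.ndarray]:
    """Eigengene-driven module profiles plus independent noise genes.

    Genes in a module share ``amplitude`` times a latent profile whose
    sample correlation with the trait equals the module's
    trait_correlation exactly; remaining genes are independent noise.
    Returns (values, gene index -> module label, trait).
    """
    total = sum(size for _, size, _ in module_specs)
    if total > n_genes:
        raise ValueError("module sizes exceed n_genes")
    rng = _rng(seed, "modules")
    if trait is None:
        trait = _rng(seed, "trait").standard_normal(n_samples)
    values = np.empty((n_genes, n_samples))
    labels: dict[int, str] = {}
    if module_specs:
        latents = _module_latents([rho for _, _, rho in module_specs], trait, rng)
    row = 0
    for m, (mid, size, _rho) in enumerate(module_specs):
        noise = rng.standard_normal((size, n_samples)) * noise_sd
        values[row:row + size] = amplitude * latents[m][None, :] + noise
        for i in range(row, row + size):
            labels[i] = str(mid)
        row += size
    n_noise = n_genes - row
    if n_noise:
        values[row:] = rng.standard_normal((n_noise, n_samples)) * noise_sd
        for i in range(row, n_genes):
            labels[i] = "noise"
    return values, labels, trait


def generate_dataset(config: SimConfig) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                                 pd.DataFrame, InteractionUniverse,
                                                 SyntheticTruth]:
    """Full synthetic study: miRNA matrix, mRNA matrix, traits, universe, truth."""
    n = config.n_samples
    sample_ids = ([f"treated_{i + 1:02d}" for i in range(config.n_treated)]
                  + [f"control_{i + 1:02d}" for i in range(config.n_control)])
    groups = {s: (TREATED if s.startswith("treated") else CONTROL)
              for s in sample_ids}
    treated_mask = np.array([groups[s] == TREATED for s in sample_ids])

    trait_rng = _rng(config.seed, "trait")
    consumption = np.zeros(n)
    consumption[treated_mask] = (CONSUMPTION_MEAN
                                 + CONSUMPTION_SD * trait_rng.standard_normal(
                                     config.n_treated))
    traits = pd.DataFrame({
        "group": [groups[s] for s in sample_ids],
        "consumption": consumption,
    }, index=pd.Index(sample_ids, name="sample_id"))

    gene_ids = [f"Gene{i + 1:04d}" for i in range(config.n_genes)]
    values, idx_labels, _ = plant_modules(
        config.n_genes, config.module_specs, n, config.noise_sd,
        config.seed, trait=consumption, amplitude=config.module_amplitude)
    # latent-induced group shift, realized per gene (shared within a module)
    n_t, n_c = int(treated_mask.sum()), int((~treated_mask).sum())
    induced = values.copy()  # before baseline/planted shifts
    induced_shift = (induced[:, treated_mask].mean(axis=1)
                     - induced[:, ~treated_mask].mean(axis=1))
    expr_rng = _rng(config.seed, "expression")
    baseline = expr_rng.normal(8.0, 1.5, size=config.n_genes)
    values = values + baseline[:, None]
    module_labels = {gene_ids[i]: lab for i, lab in idx_labels.items()}

    de_rng = _rng(config.seed, "de_genes")
    n_de = round(config.de_fraction_genes * config.n_genes)
    noise_idx = [i for i, lab in idx_labels.items() if lab == "noise"]
    module_idx = [i for i, lab in idx_labels.items() if lab != "noise"]
    # planted shifts go to noise genes first; module genes already carry the
    # latent-induced shift and are only drawn on when noise genes run out
    pool = (list(de_rng.permutation(noise_idx)) if noise_idx else []) \
        + (list(de_rng.permutation(module_idx)) if module_idx else [])
    de_idx = pool[:n_de]
    planted_lfc = np.zeros(config.n_genes)
    for i in de_idx:
        up = de_rng.random() < config.gene_up_fraction
        lfc = de_rng.uniform(*config.logfc_range) * (1 if up else -1)
        planted_lfc[i] = lfc
        values[i, treated_mask] += lfc
    total_lfc = planted_lfc + np.where(
        [idx_labels[i] != "noise" for i in range(config.n_genes)],
        induced_shift, 0.0)
    min_call = config.logfc_range[0]
    gene_logfc = {g: float(total_lfc[i]) for i, g in enumerate(gene_ids)}
    gene_de_labels = {
        g: ("up" if total_lfc[i] > 0 else "down") if abs(total_lfc[i]) >= min_call
        else "null"
        for i, g in enumerate(gene_ids)
    }
    mrna = ExpressionMatrix(gene_ids, list(sample_ids), values, dict(groups))

    mirna_ids = [f"mmu-sim-miR-{i + 1}" for i in range(config.n_mirnas)]
    mi_rng = _rng(config.seed, "mirna_expression")
    mi_base = mi_rng.normal(9.0, 1.8, size=config.n_mirnas)
    mi_values = (mi_base[:, None]
                 + mi_rng.standard_normal((config.n_mirnas, n)) * config.noise_sd)
    de_mi_rng = _rng(config.seed, "de_mirnas")
    n_de_mi = round(config.de_fraction_mirnas * config.n_mirnas)
    de_mi_idx = de_mi_rng.choice(config.n_mirnas, size=n_de_mi, replace=False)
    mirna_de_labels = {m: "null" for m in mirna_ids}
    mirna_logfc = {m: 0.0 for m in mirna_ids}
    for i in de_mi_idx:
        up = de_mi_rng.random() < config.mirna_up_fraction
        lfc = de_mi_rng.uniform(*config.logfc_range) * (1 if up else -1)
        mirna_de_labels[mirna_ids[i]] = "up" if up else "down"
        mirna_logfc[mirna_ids[i]] = lfc
        mi_values[i, treated_mask] += lfc
    mirna = ExpressionMatrix(mirna_ids, list(sample_ids), mi_values, dict(groups))

    edge_rng = _rng(config.seed, "edges")
    up_mi = np.array([mirna_de_labels[m] == "up" for m in mirna_ids])
    up_g = np.array([gene_de_labels[g] == "up" for g in gene_ids])
    prob = np.full((config.n_mirnas, config.n_genes), config.baseline_edge_prob)
    prob[np.ix_(up_mi, up_g)] = min(1.0, config.baseline_edge_prob
                                    * config.overtarget_enrichment)
    drawn = edge_rng.random(prob.shape) < prob
    edges = []
    planted: set[tuple[str, str]] = set()
    mi_idx, g_idx = np.nonzero(drawn)
    validated_draw = edge_rng.random(len(mi_idx)) < config.validated_fraction
    tools_validated = edge_rng.integers(0, 12, size=len(mi_idx))
    tools_predicted = edge_rng.integers(4, 12, size=len(mi_idx))
    for j, (a, b) in enumerate(zip(mi_idx, g_idx)):
        m, g = mirna_ids[a], gene_ids[b]
        planted.add((m, g))
        if validated_draw[j]:
            edges.append(Edge(m, g, "validated", int(tools_validated[j])))
        else:
            edges.append(Edge(m, g, "predicted", int(tools_predicted[j])))
    universe = InteractionUniverse(edges=edges)

    truth = SyntheticTruth(
        gene_de_labels=gene_de_labels,
        mirna_de_labels=mirna_de_labels,
        module_labels=module_labels,
        gene_logfc=gene_logfc,
        mirna_logfc=mirna_logfc,
        trait=traits["consumption"].copy(),
        planted_edges=planted,
    )
    return mirna, mrna, traits, universe, truth


def write_fixture_bundle(dataset, directory: str | Path,
                         tool_names: tuple[str, ...] = PREDICTION_TOOLS,
                         seed: int = 0) -> dict[str, Path]:
    """Write the dataset as the plain-text bundle the readers consume.

    Emits expression and trait TSVs, one prediction TSV per tool (each
    predicted universe edge distributed over ``n_tools`` distinct tools so
    the consensus filter round-trips), a validated-interaction TSV, a
    family map covering every simulated miRNA, and a toy homology table.
    """
    from . import io as mio

    mirna, mrna, traits, universe, truth = dataset
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc
    paths: dict[str, Path] = {}
    paths["mirna_expression"] = mio.write_expression_tsv(
        mirna, directory / "mirna_expression.tsv")
    paths["mrna_expression"] = mio.write_expression_tsv(
        mrna, directory / "mrna_expression.tsv")
    paths["traits"] = mio.write_traits_tsv(traits, directory / "traits.tsv")

    rng = _rng(seed, "fixture_tools")
    per_tool: dict[str, list[tuple[str, str]]] = {t: [] for t in tool_names}
    validated_rows: list[tuple[str, str, str]] = []
    for e in universe.edges:
        if e.status == "validated":
            validated_rows.append((e.mirna_id, e.gene_symbol, "tarbase"))
        if e.n_tools > 0:
            chosen = rng.choice(len(tool_names), size=min(e.n_tools, len(tool_names)),
                                replace=False)
            for c in chosen:
                per_tool[tool_names[c]].append((e.mirna_id, e.gene_symbol))
    for tool, rows in per_tool.items():
        p = directory / f"predicted_{tool.replace('/', '_')}.tsv"
        pd.DataFrame(rows, columns=["mirna_id", "gene_symbol"]).to_csv(
            p, sep="\t", index=False)
        paths[f"predicted_{tool}"] = p
    p = directory / "validated.tsv"
    pd.DataFrame(validated_rows,
                 columns=["mirna_id", "gene_symbol", "source"]).to_csv(
        p, sep="\t", index=False)
    paths["validated"] = p

    fam_rows = [(m, f"fam-{i // 2 + 1}") for i, m in enumerate(mirna.feature_ids)]
    p = directory / "families.tsv"
    pd.DataFrame(fam_rows, columns=["mirna_id", "family_id"]).to_csv(
        p, sep="\t", index=False)
    paths["families"] = p

    hom_rows = []
    for i, g in enumerate(mrna.feature_ids):
        hom_rows.append((f"hg-{i + 1}", "mouse", g))
        hom_rows.append((f"hg-{i + 1}", "human", g.upper()))
    p = directory / "homology.tsv"
    pd.DataFrame(hom_rows, columns=["homology_group_id", "taxon_id",
                                    "gene_symbol"]).to_csv(p, sep="\t", index=False)
    paths["homology"] = p

    paths["universe"] = universe.write_tsv(directory / "universe.tsv")
    return paths
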