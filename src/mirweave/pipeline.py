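"""End-to-end orchestration: DE -> universe -> networks -> coexpression -> enrichment.

A single :class:`PipelineConfig` (YAML-loadable) drives the full analysis,
either from a bundle of input TSVs or from the synthetic-data generator.
Every stage writes its intermediate table into the output directory and
contributes to one structured JSON report; the report is a pure function
of (config, seed), so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .crossspecies import montecarlo_overlap_p
from .enrich import de_in_module_enrichment
from .expression import (ExpressionMatrix, call_de, fit_moderated_t,
                         quantile_normalize, scale_normalize)
from .networks import (build_bipartite, mirna_overtargeting,
                       network_contrast_report, randomize_networks,
                       write_contrast_tsv)
from .sim import SimConfig, generate_dataset, write_fixture_bundle
from .universe import InteractionUniverse, build_universe, map_to_families
from .wgcna import (detect_modules, extract_hub_network, module_eigengenes,
                    relate_to_traits, signed_similarity, soft_adjacency,
                    topological_overlap)

log = logging.getLogger("mirweave")


@dataclass
class PipelineConfig:
    """Thresholds and inputs for a full run.

    Either ``simulate`` holds a :class:`SimConfig` (synthetic mode) or the
    four path fields point at input TSVs produced elsewhere.
    """

    simulate: SimConfig | None = field(default_factory=SimConfig)
    mirna_expression: str | None = None
    mrna_expression: str | None = None
    traits: str | None = None
    universe: str | None = None
    mirna_fdr: float = 0.10
    gene_fdr: float = 0.01
    overtarget_fdr: float = 0.10
    corr_fdr: float = 0.10
    min_tools: int = 4
    beta: float = 12.0
    min_module_size: int = 100
    cut_height: float = 0.99
    null_reps: int = 1000
    mc_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mirna_fdr", "gene_fdr", "overtarget_fdr", "corr_fdr"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.simulate is None:
            missing = [n for n in ("mirna_expression", "mrna_expression",
                                   "traits", "universe")
                       if getattr(self, n) is None]
            if missing:
                raise ValueError(f"file mode requires paths for: {missing}")
            for n in ("mirna_expression", "mrna_expression", "traits", "universe"):
                p = Path(getattr(self, n))
                if not p.exists():
                    raise FileNotFoundError(f"input path for {n} not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulate", None)
        if isinstance(sim, dict):
            if "module_specs" in sim:
                sim["module_specs"] = tuple(tuple(m) for m in sim["module_specs"])
            if "logfc_range" in sim:
                sim["logfc_range"] = tuple(sim["logfc_range"])
            sim = SimConfig(**sim)
        return cls(simulate=sim, **raw)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage, write intermediates, return the structured report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": _config_dict(config),
        "stages": [],
    }

    def stage(name: str):
        t0 = time.time()
        log.info("stage %s started", name)
        report["stages"].append(name)
        return t0

    try:
        t0 = stage("inputs")
        if config.simulate is not None:
            dataset = generate_dataset(config.simulate)
            mirna, mrna, traits, universe, truth = dataset
            write_fixture_bundle(dataset, outdir / "inputs",
                                 seed=config.simulate.seed)
        else:
            traits = mio.read_traits_tsv(config.traits)
            groups = traits["group"].to_dict()
            mirna = mio.read_expression_tsv(config.mirna_expression, groups)
            mrna = mio.read_expression_tsv(config.mrna_expression, groups)
            universe = InteractionUniverse.read_tsv(config.universe)
            truth = None
        log.info("inputs ready in %.1fs", time.time() - t0)

        t0 = stage("differential_expression")
        mrna_n = quantile_normalize(mrna)
        mirna_n = scale_normalize(mirna)
        de_genes = fit_moderated_t(mrna_n)
        de_mirnas = fit_moderated_t(mirna_n)
        de_genes.to_csv(outdir / "de_genes.tsv", sep="\t", float_format="%.10g")
        de_mirnas.to_csv(outdir / "de_mirnas.tsv", sep="\t", float_format="%.10g")
        up_genes, down_genes = call_de(de_genes, config.gene_fdr)
        up_mirnas, down_mirnas = call_de(de_mirnas, config.mirna_fdr)
        report["de"] = {
            "genes_up": len(up_genes), "genes_down": len(down_genes),
            "mirnas_up": len(up_mirnas), "mirnas_down": len(down_mirnas),
            "gene_fdr": config.gene_fdr, "mirna_fdr": config.mirna_fdr,
        }
        log.info("DE done in %.1fs: %d/%d genes, %d/%d miRNAs up/down",
                 time.time() - t0, len(up_genes), len(down_genes),
                 len(up_mirnas), len(down_mirnas))

        t0 = stage("targeting_networks")
        expressed = set(mrna.feature_ids)
        universe.write_tsv(outdir / "universe.tsv")
        report["universe"] = {
            "edges": len(universe.edges),
            "mirnas": len(universe.mirnas),
            "genes": len(universe.genes),
        }
        report["networks"] = _network_stage(
            universe, up_mirnas, up_genes, down_genes, expressed, config, outdir)
        log.info("networks done in %.1fs", time.time() - t0)

        t0 = stage("cross_species")
        report["cross_species"] = _crossspecies_stage(
            universe, up_mirnas, truth, config)
        log.info("cross-species done in %.1fs", time.time() - t0)

        t0 = stage("coexpression")
        report["coexpression"] = _coexpression_stage(
            mrna_n, mirna_n, traits, de_mirnas, up_genes | down_genes,
            config, outdir)
        log.info("coexpression done in %.1fs", time.time() - t0)

        report["seed"] = config.seed
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                          default=_json_default) + "\n")
        log.info("report written to %s", report_path)
        return report
    except Exception as exc:
        failed = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc


def _network_stage(universe, up_mirnas, up_genes, down_genes, expressed,
                   config, outdir) -> dict[str, Any]:
    out: dict[str, Any] = {}
    if not up_mirnas or not (up_genes or down_genes):
        out["built"] = False
        return out
    out["built"] = True
    nets = {}
    for label, gene_set in (("positive", up_genes), ("negative", down_genes)):
        if not gene_set:
            continue
        net = build_bipartite(universe, up_mirnas, gene_set, label=label)
        if not net.edges:
            continue
        net.write_tsv(outdir / f"network_{label}.tsv")
        ot = mirna_overtargeting(universe, up_mirnas, gene_set, expressed,
                                 fdr=config.overtarget_fdr)
        ot.to_csv(outdir / f"overtargeting_{label}.tsv", sep="\t",
                  float_format="%.10g")
        null = randomize_networks(
            universe, up_mirnas, _targetable(universe, expressed),
            gene_set_size=len(gene_set & _targetable(universe, expressed)),
            R=config.null_reps, seed=config.seed,
            fdr=config.overtarget_fdr)
        nets[label] = (net, null, ot)
    if {"positive", "negative"} <= set(nets):
        contrast = network_contrast_report(
            nets["positive"][0], nets["negative"][0],
            nets["positive"][1], nets["negative"][1],
            nets["positive"][2], nets["negative"][2])
        write_contrast_tsv(contrast, outdir / "network_contrast.tsv")
        out["contrast"] = json.loads(
            contrast.reset_index().to_json(orient="records"))
    for label, (net, null, ot) in nets.items():
        tested = ot["tested"]
        out[label] = {
            "mean_degree": round(2.0 * len(net.edges) / net.n_nodes, 6),
            "null_mean_degree": round(null.mean_degree, 6),
            "null_sd_degree": round(null.sd_degree, 6),
            "n_edges": len(net.edges),
            "overtargeting": int(ot.loc[tested, "overtargeting"].sum()),
            "tested_mirnas": int(tested.sum()),
        }
    return out


def _targetable(universe, expressed) -> set[str]:
    cf = {g.casefold() for g in universe.genes}
    return {g for g in expressed if g.casefold() in cf}


def _crossspecies_stage(universe, up_mirnas, truth, config) -> dict[str, Any]:
    """Self-consistency overlap: detected vs planted upregulated miRNA families.

    In synthetic mode every pair of simulated miRNAs shares a family; the
    detected upregulated set is compared against the planted truth over the
    universe of all simulated families. Without truth the stage is skipped.
    """
    if truth is None:
        return {"skipped": "no ground truth available in file mode"}
    fam_map = {m: f"fam-{i // 2 + 1}"
               for i, m in enumerate(sorted(truth.mirna_de_labels,
                                            key=_sim_index))}
    detected, _ = map_to_families(sorted(up_mirnas), fam_map)
    planted, _ = map_to_families(
        sorted(m for m, l in truth.mirna_de_labels.items() if l == "up"), fam_map)
    all_fams = set(fam_map.values())
    common = detected & planted
    if not detected or not planted:
        return {"detected_families": len(detected),
                "planted_families": len(planted), "overlap": len(common)}
    result = montecarlo_overlap_p(
        observed=len(common), size_a=len(detected), size_b=len(planted),
        universe_size=len(all_fams), R=config.mc_reps, seed=config.seed)
    return {
        "detected_families": len(detected),
        "planted_families": len(planted),
        "overlap": len(common),
        "universe_size": len(all_fams),
        "mc_p": result.mc_p,
        "mc_reps": result.R,
    }


def _sim_index(mirna_id: str) -> tuple:
    tail = mirna_id.rsplit("-", 1)[-1]
    return (0, int(tail)) if tail.isdigit() else (1, mirna_id)


def _coexpression_stage(mrna, mirna, traits, de_mirnas, de_genes,
                        config, outdir) -> dict[str, Any]:
    S = signed_similarity(mrna)
    A = soft_adjacency(S, config.beta)
    tom = topological_overlap(A)
    labels = detect_modules(tom.dissimilarity, tom.genes,
                            min_module_size=config.min_module_size,
                            cut_height=config.cut_height, expression=mrna)
    pd.Series(labels, name="module").rename_axis("gene").to_csv(
        outdir / "module_labels.tsv", sep="\t")
    modules = sorted({m for m in labels.values() if m != "grey"})
    out: dict[str, Any] = {
        "beta": config.beta,
        "n_modules": len(modules),
        "module_sizes": {m: sum(v == m for v in labels.values())
                         for m in modules},
        "grey": sum(v == "grey" for v in labels.values()),
    }
    if not modules:
        return out
    eig = module_eigengenes(mrna, labels)
    eig.to_csv(outdir / "eigengenes.tsv", sep="\t", float_format="%.10g")
    top_de = de_mirnas.sort_values("adj_p").head(20)
    mirna_prof = pd.DataFrame(
        {s: mirna.values[:, i] for i, s in enumerate(mirna.sample_ids)},
        index=mirna.feature_ids).loc[list(top_de.index)]
    rel = relate_to_traits(mrna, eig, traits["consumption"], mirna_prof,
                           labels=labels, corr_fdr=config.corr_fdr)
    rel["gene_stats"].to_csv(outdir / "gene_stats.tsv", sep="\t",
                             float_format="%.10g")
    rel["module_trait"].to_csv(outdir / "module_trait.tsv", sep="\t",
                               float_format="%.10g")
    rel["module_mirna"].to_csv(outdir / "module_mirna.tsv", sep="\t",
                               index=False, float_format="%.10g")
    mt = rel["module_trait"].sort_values("r", key=np.abs, ascending=False)
    out["module_trait"] = [
        {"module": m, "r": round(float(row["r"]), 6),
         "p": float(f'{row["p"]:.6g}')}
        for m, row in mt.iterrows()
    ]
    universe_genes = set(labels)  # genes in the network (zero-variance dropped)
    enr = de_in_module_enrichment(labels, de_genes & universe_genes,
                                  universe_genes)
    enr.to_csv(outdir / "de_in_module.tsv", sep="\t", float_format="%.10g")
    out["de_in_module"] = {
        m: {"k": int(r["k"]), "K": int(r["K"]), "p": float(f'{r["p"]:.6g}')}
        for m, r in enr.iterrows()
    }
    out["mirna_module_significant"] = int(rel["module_mirna"]["significant"].sum())
    top_module = mt.index[0]
    hub = extract_hub_network(rel["gene_stats"], A, top_module)
    hub["edges"].to_csv(outdir / f"hub_{top_module}.tsv", sep="\t", index=False,
                        float_format="%.10g")
    out["hub"] = {"module": top_module, "hub_gene": hub["hub"],
                  "n_genes": len(hub["genes"])}
    return out


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _fmt(x, spec: str = ".3g") -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "n/a"
    return format(x, spec)


def summarize_report(report: dict[str, Any]) -> str:
    """Human-readable digest; every number is read straight from the report."""
    lines = []
    de = report.get("de", {})
    lines.append(f"Differential expression: {de.get('genes_up', 0)} genes up, "
                 f"{de.get('genes_down', 0)} down (FDR < {de.get('gene_fdr')}); "
                 f"{de.get('mirnas_up', 0)} miRNAs up, {de.get('mirnas_down', 0)} "
                 f"down (FDR < {de.get('mirna_fdr')})")
    uni = report.get("universe", {})
    lines.append(f"Interaction universe: {uni.get('edges', 0)} edges, "
                 f"{uni.get('mirnas', 0)} miRNAs, {uni.get('genes', 0)} genes")
    nets = report.get("networks", {})
    if not nets.get("built"):
        lines.append("Targeting networks: zero networks built (no DE sets)")
    else:
        for label in ("positive", "negative"):
            n = nets.get(label)
            if n:
                lines.append(
                    f"{label.capitalize()} network: mean degree "
                    f"{n['mean_degree']} vs null {n['null_mean_degree']} "
                    f"(SD {n['null_sd_degree']}); over-targeting "
                    f"{n['overtargeting']}/{n['tested_mirnas']} miRNAs")
        for row in nets.get("contrast", []):
            lines.append(
                f"{str(row['network']).capitalize()} vs null proportion "
                f"{_fmt(row['null_overtarget_proportion'], '.3f')}: chi2 p = "
                f"{_fmt(row['proportion_p'])} ({row['connectivity']})")
    cs = report.get("cross_species", {})
    if "mc_p" in cs:
        lines.append(f"Cross-set family overlap: {cs['overlap']} of "
                     f"{cs['detected_families']} detected vs "
                     f"{cs['planted_families']} reference families "
                     f"(Monte Carlo p = {_fmt(cs['mc_p'])}, R = {cs['mc_reps']})")
    co = report.get("coexpression", {})
    if co:
        lines.append(f"Coexpression: {co.get('n_modules', 0)} modules "
                     f"(grey: {co.get('grey', 0)} genes) at beta = "
                     f"{co.get('beta')}")
        for row in co.get("module_trait", []):
            dem = co.get("de_in_module", {}).get(row["module"], {})
            lines.append(
                f"  module {row['module']}: trait r = {row['r']:+.3f} "
                f"(p = {row['p']:.3g}), DE genes {dem.get('k', 0)}/"
                f"{dem.get('K', 0)} (enrichment p = {dem.get('p', 1):.3g})")
        hub = co.get("hub")
        if hub:
            lines.append(f"  hub of {hub['module']}: {hub['hub_gene']} "
                         f"({hub['n_genes']} genes pass MM/GS thresholds)")
    return "\n".join(lines)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
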