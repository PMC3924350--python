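"""miRNA -> mRNA interaction universe and cross-species identifier mapping.

The universe is a composite of experimentally validated interactions and
predicted interactions supported by a consensus of target-prediction tools
(default: at least 4 of the 11 programs whose tables are consumed).
Validated interactions always enter the universe and take precedence when
an interaction is both validated and predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

PREDICTION_TOOLS = (
    "DIANA-microT", "MicroInspector", "miRanda", "MirTarget2", "miTarget",
    "NBmiRTar", "PicTar", "PITA", "RNA22", "RNAhybrid", "TargetScan",
)


@dataclass(frozen=True)
class Edge:
    mirna_id: str
    gene_symbol: str
    status: str  # "validated" | "predicted"
    n_tools: int


@dataclass
class InteractionUniverse:
    """Deduplicated miRNA->gene edges with provenance."""

    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = {(e.mirna_id, _casefold(e.gene_symbol)) for e in self.edges}
        if len(pairs) != len(self.edges):
            raise ValueError("duplicate (mirna, gene) pairs in universe")
        self._targets: dict[str, set[str]] = {}
        self._genes_cf: dict[str, str] = {}
        for e in self.edges:
            self._targets.setdefault(e.mirna_id, set()).add(e.gene_symbol)
            self._genes_cf.setdefault(_casefold(e.gene_symbol), e.gene_symbol)

    @property
    def mirnas(self) -> set[str]:
        return set(self._targets)

    @property
    def genes(self) -> set[str]:
        return {g for t in self._targets.values() for g in t}

    def targets(self, mirna_id: str) -> set[str]:
        return set(self._targets.get(mirna_id, set()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.mirna_id, e.gene_symbol, e.status, e.n_tools) for e in self.edges],
            columns=["mirna_id", "gene_symbol", "status", "n_tools"],
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionUniverse":
        df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_symbol": str,
                                                "status": str})
        edges = [Edge(r.mirna_id, r.gene_symbol, r.status, int(r.n_tools))
                 for r in df.itertuples(index=False)]
        return cls(edges=edges)


def _casefold(symbol: str) -> str:
    return symbol.casefold()


def build_universe(predicted_tables: Sequence[tuple[str, Iterable[tuple[str, str]]]],
                   validated_table: Iterable[tuple[str, str]],
                   min_tools: int = 4) -> InteractionUniverse:
    """Composite universe from per-tool predictions plus validated interactions.

    A predicted pair is kept iff it is reported by at least ``min_tools``
    distinct tools. Validated pairs are always kept; when a pair is both,
    the single record carries status="validated" with its tool count.
    Gene symbols are matched case-insensitively (first-seen casing wins).
    """
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    names = [t for t, _ in predicted_tables]
    if len(set(names)) != len(names):
        raise ValueError("tool names must be unique")
    support: dict[tuple[str, str], set[str]] = {}
    casing: dict[tuple[str, str], tuple[str, str]] = {}
    for tool, rows in predicted_tables:
        for lineno, row in enumerate(rows, start=1):
            mirna, gene = _check_row(tool, lineno, row)
            key = (mirna, _casefold(gene))
            support.setdefault(key, set()).add(tool)
            casing.setdefault(key, (mirna, gene))
    validated: set[tuple[str, str]] = set()
    for lineno, row in enumerate(validated_table, start=1):
        mirna, gene = _check_row("validated", lineno, row)
        key = (mirna, _casefold(gene))
        validated.add(key)
        casing.setdefault(key, (mirna, gene))
    edges = []
    for key in sorted(validated | {k for k, s in support.items() if len(s) >= min_tools}):
        mirna, gene = casing[key]
        edges.append(Edge(
            mirna_id=mirna,
            gene_symbol=gene,
            status="validated" if key in validated else "predicted",
            n_tools=len(support.get(key, ())),
        ))
    return InteractionUniverse(edges=edges)


def _check_row(source: str, lineno: int, row: tuple[str, str]) -> tuple[str, str]:
    try:
        mirna, gene = row[0], row[1]
    except (TypeError, IndexError):
        raise ValueError(f"{source}: malformed edge row at line {lineno}: {row!r}")
    if not mirna or not gene or not isinstance(mirna, str) or not isinstance(gene, str):
        raise ValueError(f"{source}: malformed edge row at line {lineno}: {row!r}")
    return mirna, gene


def normalize_family_name(mirna_id: str) -> str:
    """Fallback family-style name: strip species prefix and arm suffix.

    "mmu-miR-152-3p" -> "mir-152"; used for cross-species name matching when
    an explicit family map entry is missing.
    """
    name = mirna_id
    for prefix in ("mmu-", "hsa-", "rno-"):
        if name.startswith(prefix):
            name = name[len(prefix):]
            break
    for suffix in ("-3p", "-5p"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return name.lower()


def map_to_families(mirna_ids: Iterable[str], family_map: Mapping[str, str],
                    fallback: bool = False) -> tuple[set[str], list[str]]:
    """Convert species-specific miRNA IDs to cross-species family IDs.

    IDs absent from the map are returned in the unmapped list (never
    silently dropped); with ``fallback=True`` they are instead converted by
    name normalization (prefix/arm stripping).
    """
    families: set[str] = set()
    unmapped: list[str] = []
    for mid in mirna_ids:
        if mid in family_map:
            families.add(family_map[mid])
        elif fallback:
            families.add(normalize_family_name(mid))
        else:
            unmapped.append(mid)
    return families, unmapped


def count_unique_families(rows: Iterable[tuple[str, str]]) -> int:
    """Number of distinct family IDs among (mirna_id, family_id) rows."""
    return len({fam for _, fam in rows})


def map_homologs(symbols: Iterable[str], homology: pd.DataFrame,
                 from_taxon: str, to_taxon: str) -> tuple[list[str], list[str]]:
    """Convert gene symbols between taxa via homology groups.

    Matching is case-insensitive; every target-taxon member of the source
    symbol's group is returned. Symbols without a group, or whose group has
    no member in the target taxon, are reported unmapped.
    """
    taxa = set(homology["taxon_id"])
    for t in (from_taxon, to_taxon):
        if str(t) not in taxa:
            raise ValueError(f"taxon {t!r} absent from homology table")
    src = homology[homology["taxon_id"] == str(from_taxon)]
    dst = homology[homology["taxon_id"] == str(to_taxon)]
    sym_to_group = {s.casefold(): g for g, s in
                    zip(src["homology_group_id"], src["gene_symbol"])}
    group_to_dst: dict[str, list[str]] = {}
    for g, s in zip(dst["homology_group_id"], dst["gene_symbol"]):
        group_to_dst.setdefault(g, []).append(s)
    mapped: list[str] = []
    unmapped: list[str] = []
    for sym in symbols:
        group = sym_to_group.get(sym.casefold())
        if group is None or group not in group_to_dst:
            unmapped.append(sym)
        else:
            mapped.extend(group_to_dst[group])
    return mapped, unmapped


def targets_of(universe: InteractionUniverse, mirna_id: str,
               expressed_genes: set[str]) -> set[str]:
    """Universe targets of a miRNA restricted to the expressed gene set."""
    expressed_cf = {_casefold(g): g for g in expressed_genes}
    return {expressed_cf[_casefold(g)] for g in universe.targets(mirna_id)
            if _casefold(g) in expressed_cf}
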