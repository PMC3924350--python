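"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated with a header row. Expression tables carry the
feature ID in the first column and one column per sample; traits, target
predictions, validated interactions, miRNA families, homology groups and
GMT gene sets follow the column layouts documented per function.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from .expression import ExpressionMatrix


def read_expression_tsv(path: str | Path,
                        sample_groups: dict[str, str] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        sample_groups=dict(sample_groups or {}),
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_frame().rename_axis("feature_id").to_csv(path, sep="\t",
                                                       float_format="%.10g")
    return path


def read_traits_tsv(path: str | Path) -> pd.DataFrame:
    """Columns: sample_id, group in {treated, control}, consumption (g/kg/3h)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group", "consumption"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trait table needs columns {sorted(required)}")
    return df.set_index("sample_id")


def write_traits_tsv(traits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    traits.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_edge_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column edge table: mirna_id, gene_symbol (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = df.index[df.iloc[:, :2].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed edge rows at lines {[i + 2 for i in bad]}")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def read_validated_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Columns: mirna_id, gene_symbol, source; the source column is optional."""
    return read_edge_tsv(path)


def read_family_tsv(path: str | Path) -> dict[str, str]:
    """Columns: mirna_id, family_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: family map needs columns mirna_id, family_id")
    out: dict[str, str] = {}
    for mirna, fam in df.iloc[:, :2].itertuples(index=False, name=None):
        if not fam:
            raise ValueError(f"{path}: empty family_id for {mirna}")
        out[str(mirna)] = str(fam)
    return out


def read_homology_tsv(path: str | Path) -> pd.DataFrame:
    """Columns: homology_group_id, taxon_id, gene_symbol (Homologene layout)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"homology_group_id", "taxon_id", "gene_symbol"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: homology table needs columns {sorted(required)}")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "") -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
    return path


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def packaged_table(name: str) -> pd.DataFrame:
    """Load a TSV shipped under mirweave/data (e.g. the printed DE-miRNA table)."""
    ref = importlib.resources.files("mirweave").joinpath("data", name)
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"mirna_id": str, "family_id": str})
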