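"""Plain-text readers and writers: TSV tables and GMT gene sets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from coexnet.enrichment import GeneSetCollection


def read_counts(path) -> pd.DataFrame:
    """Gene x sample count TSV (first column = gene ids, header = samples)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][:5]
        raise ValueError(f"duplicate gene ids: {list(dup)}")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count header")
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with sample_id, population, temperature, replicate."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"population", "temperature"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("module").rename_axis("gene").to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["module"].astype(int)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """GMT format: one set per line, name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(name=name or Path(path).stem, sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or collection.name, *sorted(genes)])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_homolog_map(path) -> pd.DataFrame:
    """Two-column TSV (source gene, target gene); one-to-many allowed."""
    table = pd.read_csv(path, sep="\t", header=None, names=["source", "target"],
                        dtype=str, comment="#")
    if table.isna().any().any():
        raise ValueError("homolog map has missing entries")
    return table.drop_duplicates()
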