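"""Reading expression tables, layout configs and GMT gene sets.

Expression input is a plain TSV with a header row of sample names plus one
gene-symbol column; a layout config (YAML mapping) assigns sample columns
to conditions.  Gene sets use the standard GMT format (name, description,
member symbols, tab-separated).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from .expression import DesignError, FormatError, GeneSet, ProbeTable

__all__ = [
    "read_layout",
    "read_expression_table",
    "read_gene_sets",
    "write_gene_sets",
    "write_tsv",
]


def read_layout(path: str | Path) -> dict:
    """Load a layout config: {gene_column: str, conditions: {label: [cols]}}."""
    with open(path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, dict) or "conditions" not in layout:
        raise FormatError(f"{path}: layout config needs a 'conditions' mapping")
    layout.setdefault("gene_column", "gene")
    return layout


def read_expression_table(path: str | Path, layout: dict | str | Path) -> ProbeTable:
    """Parse a TSV of spot intensities into a :class:`ProbeTable`.

    Rows with a non-numeric or missing value in any assigned sample column
    are dropped; the drop count is recorded in ``table.log["rows_dropped"]``.
    """
    if not isinstance(layout, dict):
        layout = read_layout(layout)
    gene_col = layout.get("gene_column", "gene")
    conditions: dict[str, list[str]] = {
        str(c): [str(s) for s in cols] for c, cols in layout["conditions"].items()
    }

    df = pd.read_csv(path, sep="\t", dtype=str)
    if gene_col not in df.columns:
        raise FormatError(f"{path}: gene column {gene_col!r} not found")
    for cond, cols in conditions.items():
        if len(cols) < 2:
            raise DesignError(f"condition {cond!r} has <2 replicate columns")
        absent = [c for c in cols if c not in df.columns]
        if absent:
            raise FormatError(f"{path}: condition {cond!r} columns {absent} missing")

    sample_cols = [c for cols in conditions.values() for c in cols]
    spot_col = layout.get("spot_column")
    if spot_col is not None and spot_col in df.columns:
        spots = df[spot_col].astype(str)
    else:
        spots = pd.Series([f"spot{i:06d}" for i in range(len(df))], index=df.index)

    numeric = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1) & df[gene_col].notna()
    dropped = int((~keep).sum())
    numeric = numeric.loc[keep]
    if (numeric.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative intensity encountered")

    values = numeric.copy()
    values.index = pd.Index(spots.loc[keep], name="spot")
    gene_of_spot = pd.Series(
        df.loc[keep, gene_col].to_numpy(), index=values.index, name="gene"
    )
    table = ProbeTable(
        values=values,
        gene_of_spot=gene_of_spot,
        replicate_columns=conditions,
        log={"rows_in": len(df), "rows_dropped": dropped, "rows_kept": int(keep.sum())},
    )
    return table


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of gene sets (duplicates de-duplicated)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gene_sets(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    """Write a results table with a comment header recording provenance."""
    from . import __version__

    with open(path, "w") as fh:
        meta = dict(header_meta or {})
        meta.setdefault("genefabric_version", __version__)
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
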