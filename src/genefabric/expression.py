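"""Data model for replicated, redundantly probed expression tables.

A microarray (or any probe-based platform) may interrogate one gene with
several spots.  Spots are technical replicates *within* each biological
replicate: the biological signal is shared by all spots of a gene on one
array, while spot-level noise is technical.  The containers here keep the
spot level explicit so that downstream variability estimates can pool over
a gene's spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeTable",
    "GeneSet",
    "GeneProfile",
    "DesignError",
    "FormatError",
    "DegenerateInputError",
    "normalize_to_median",
    "gene_profiles",
]


class FormatError(ValueError):
    """Malformed input file (missing columns, short GMT lines ...)."""


class DesignError(ValueError):
    """Experimental design violates requirements (e.g. <2 replicates)."""


class DegenerateInputError(ValueError):
    """Numerically degenerate input (zero median, zero mean ...)."""


@dataclass
class GeneSet:
    """A named set of gene symbols (one GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")

    def members_upper(self) -> frozenset[str]:
        return frozenset(m.upper() for m in self.members)


@dataclass
class ProbeTable:
    """Spot-level intensities for all samples of a multi-condition design.

    Parameters
    ----------
    values
        DataFrame of non-negative intensities, index = spot ids,
        columns = sample names.  NaN marks a missing measurement.
    gene_of_spot
        Series mapping each spot id to one gene symbol.
    replicate_columns
        Ordered mapping condition label -> list of sample columns
        (biological replicates).  Every condition needs >= 2 replicates.
    """

    values: pd.DataFrame
    gene_of_spot: pd.Series
    replicate_columns: dict[str, list[str]]
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.gene_of_spot.index)
        if missing:
            raise FormatError(f"{len(missing)} spots lack a gene symbol")
        for cond, cols in self.replicate_columns.items():
            if len(cols) < 2:
                raise DesignError(
                    f"condition {cond!r} has {len(cols)} replicate(s); need >= 2"
                )
            absent = [c for c in cols if c not in self.values.columns]
            if absent:
                raise FormatError(f"condition {cond!r}: columns {absent} not in table")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("negative intensity in probe table")

    @property
    def conditions(self) -> list[str]:
        return list(self.replicate_columns)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.gene_of_spot.loc[self.values.index]:
            seen.setdefault(g, None)
        return list(seen)

    def n_replicates(self, condition: str) -> int:
        return len(self.replicate_columns[condition])

    def spots_of_gene(self, gene: str) -> list[str]:
        """Spots probing `gene` (case-insensitive symbol match)."""
        key = gene.upper()
        mask = self.gene_of_spot.loc[self.values.index].str.upper() == key
        return list(self.values.index[mask.to_numpy()])

    def condition_values(self, condition: str) -> pd.DataFrame:
        if condition not in self.replicate_columns:
            raise DesignError(f"unknown condition {condition!r}")
        return self.values[self.replicate_columns[condition]]


@dataclass
class GeneProfile:
    """One gene's expression in one condition, at spot resolution.

    `spot_values` is the (R_i, n_c) matrix of intensities; `spot_means` /
    `spot_sds` are its row-wise replicate mean and sample SD (n-1
    denominator); `replicate_values` averages the gene's spots within each
    biological replicate, giving the gene-level per-replicate signal.
    """

    gene: str
    condition: str
    spot_ids: list[str]
    spot_values: np.ndarray

    def __post_init__(self) -> None:
        self.spot_values = np.asarray(self.spot_values, dtype=float)
        if self.spot_values.ndim != 2 or self.spot_values.shape[0] == 0:
            raise ValueError("spot_values must be a non-empty 2-D array")

    @property
    def n_spots(self) -> int:
        return self.spot_values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.spot_values.shape[1]

    @property
    def spot_means(self) -> np.ndarray:
        return self.spot_values.mean(axis=1)

    @property
    def spot_sds(self) -> np.ndarray:
        return self.spot_values.std(axis=1, ddof=1)

    @property
    def replicate_values(self) -> np.ndarray:
        return self.spot_values.mean(axis=0)


def normalize_to_median(table: ProbeTable) -> ProbeTable:
    """Divide each condition's values by that condition's overall median.

    The median is taken over all (spot, replicate) cells of the condition,
    so after normalization the per-condition median intensity is exactly 1
    and expression is in "median units".  Idempotent and scale-invariant.
    """
    out = table.values.copy()
    for cond, cols in table.replicate_columns.items():
        block = out[cols]
        med = float(np.nanmedian(block.to_numpy()))
        if med <= 0 or not np.isfinite(med):
            raise DegenerateInputError(f"condition {cond!r}: median {med} is not positive")
        out[cols] = block / med
    return ProbeTable(
        values=out,
        gene_of_spot=table.gene_of_spot,
        replicate_columns=dict(table.replicate_columns),
        log=dict(table.log),
    )


def gene_profiles(table: ProbeTable, condition: str) -> dict[str, GeneProfile]:
    """Per-gene spot-resolved profiles for one condition.

    A spot with any missing value in the condition's columns is excluded
    from that condition; a gene whose spots are all excluded is absent
    from the result.
    """
    block = table.condition_values(condition)
    ok = ~block.isna().any(axis=1)
    block = block.loc[ok]
    genes = table.gene_of_spot.loc[block.index]

    profiles: dict[str, GeneProfile] = {}
    by_gene: dict[str, list[str]] = {}
    canonical: dict[str, str] = {}
    for spot, g in genes.items():
        key = g.upper()
        canonical.setdefault(key, g)
        by_gene.setdefault(key, []).append(spot)
    for key, spots in by_gene.items():
        g = canonical[key]
        profiles[g] = GeneProfile(
            gene=g,
            condition=condition,
            spot_ids=spots,
            spot_values=block.loc[spots].to_numpy(dtype=float),
        )
    return profiles
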