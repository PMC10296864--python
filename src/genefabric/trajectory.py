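"""Individual transcriptomic trajectories and the transcriptomic distance.

Each gene's move from a reference to a case condition is a 3-vector of
orthogonal, dimensionless components: the change of its average
expression (AVE), of its expression variability (REV) and of its
expression correlation with the other genes (COR), each normalized by the
reference-condition scale of the corresponding characteristic over a gene
universe.  The transcriptomic distance TD is the Euclidean norm of the
vector — zero iff the gene's whole expression character is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import DegenerateInputError

__all__ = ["TrajectoryRecord", "compute_itt", "trajectory_table", "pathway_td_summary"]


@dataclass(frozen=True)
class TrajectoryRecord:
    gene: str
    reference: str
    case: str
    d_ave: float
    d_rev: float
    d_cor: float

    @property
    def td(self) -> float:
        return math.sqrt(self.d_ave**2 + self.d_rev**2 + self.d_cor**2)


def compute_itt(
    gene: str,
    fabric_ref: pd.DataFrame,
    fabric_case: pd.DataFrame,
    cor_ref: pd.DataFrame,
    cor_case: pd.DataFrame,
    universe: list[str] | None = None,
    reference: str = "ref",
    case: str = "case",
) -> TrajectoryRecord:
    """Trajectory components for one gene.

    ``fabric_ref`` / ``fabric_case`` are gene-indexed frames with columns
    ``ave`` and ``rev``; ``cor_ref`` / ``cor_case`` are symmetric gene x
    gene correlation frames.  ``universe`` (default: all genes shared by
    both fabric frames) defines both the AVE/REV normalizers and the COR
    partner set (minus the focal gene).  Partner pairs whose correlation
    is undefined in either condition are excluded from numerator and
    denominator alike.
    """
    if universe is None:
        universe = [g for g in fabric_ref.index if g in fabric_case.index]
    if gene not in fabric_ref.index or gene not in fabric_case.index:
        raise KeyError(f"gene {gene!r} absent from a condition")

    ave_norm = float(fabric_ref.loc[universe, "ave"].mean())
    rev_norm = float(fabric_ref.loc[universe, "rev"].mean())
    if ave_norm == 0 or rev_norm == 0:
        raise DegenerateInputError("zero AVE or REV normalizer over the universe")

    d_ave = (fabric_case.loc[gene, "ave"] - fabric_ref.loc[gene, "ave"]) / ave_norm
    d_rev = (fabric_case.loc[gene, "rev"] - fabric_ref.loc[gene, "rev"]) / rev_norm

    partners = [g for g in universe if g != gene]
    cr = cor_ref.loc[gene, partners].to_numpy(dtype=float)
    cc = cor_case.loc[gene, partners].to_numpy(dtype=float)
    ok = ~(np.isnan(cr) | np.isnan(cc))
    cr, cc = cr[ok], cc[ok]
    if cr.size == 0 or np.all(cr == 0):
        raise DegenerateInputError(
            f"gene {gene!r}: no usable reference correlations for the COR component"
        )
    d_cor = math.sqrt(np.mean((cc - cr) ** 2)) / math.sqrt(np.mean(cr**2))

    return TrajectoryRecord(
        gene=gene,
        reference=reference,
        case=case,
        d_ave=float(d_ave),
        d_rev=float(d_rev),
        d_cor=float(d_cor),
    )


def trajectory_table(
    fabric_ref: pd.DataFrame,
    fabric_case: pd.DataFrame,
    cor_ref: pd.DataFrame,
    cor_case: pd.DataFrame,
    reference: str,
    case: str,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """TD components for every gene of the universe, as a DataFrame."""
    if universe is None:
        universe = [g for g in fabric_ref.index if g in fabric_case.index]
    rows = []
    for g in universe:
        try:
            rec = compute_itt(
                g, fabric_ref, fabric_case, cor_ref, cor_case,
                universe=universe, reference=reference, case=case,
            )
        except DegenerateInputError:
            continue
        rows.append(
            {
                "gene": g,
                "reference": reference,
                "case": case,
                "d_ave": rec.d_ave,
                "d_rev": rec.d_rev,
                "d_cor": rec.d_cor,
                "td": rec.td,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "reference", "case", "d_ave", "d_rev", "d_cor", "td"]
    )


def pathway_td_summary(members: set[str], trajectories: pd.DataFrame) -> dict:
    """Mean TD over a gene set plus the member ranking by TD (descending)."""
    keys = {m.upper() for m in members}
    sub = trajectories[trajectories["gene"].str.upper().isin(keys)]
    if sub.empty:
        raise DegenerateInputError("no gene-set member has a trajectory record")
    ranked = sub.sort_values("td", ascending=False)
    return {
        "mean_td": float(sub["td"].mean()),
        "n": int(len(sub)),
        "ranking": list(ranked["gene"]),
        "td_ranked": ranked[["gene", "td"]].reset_index(drop=True),
    }
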