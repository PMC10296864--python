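"""Regulation calling between a reference and a case condition.

A gene is significantly regulated when the Welch t-test on its gene-level
replicate values gives p < alpha *and* its absolute expression ratio
exceeds a gene- and contrast-specific cutoff CUT derived from the two
conditions' REVs.  Unlike a fixed 1.5x/2x rule, CUT adapts to each gene's
own variability: stably expressed genes face a low bar, noisy genes a
high one.

Conventions: the expression ratio x is signed with |x| >= 1 (negative for
down-regulation); WIR = AVE_ref * (|x| - 1) * sign(x) * (1 - p) weights a
gene's regulation by its normal expression level, its net fold departure
and the confidence of the call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DegenerateInputError, GeneProfile
from .fabric import compute_ave, compute_rev

__all__ = [
    "RegulationRecord",
    "expression_ratio",
    "welch_p",
    "compute_cut",
    "call_regulation",
    "compute_wir",
    "psr",
    "regulation_table",
]


@dataclass(frozen=True)
class RegulationRecord:
    gene: str
    reference: str
    case: str
    ave_ref: float
    ave_case: float
    x: float
    p: float
    cut: float
    significant: bool
    wir: float

    @property
    def direction(self) -> int:
        """Uniform contribution: +1 / -1 if significant, else 0."""
        if not self.significant:
            return 0
        return 1 if self.x > 0 else -1


def expression_ratio(ave_ref: float, ave_case: float) -> float:
    """Signed expression ratio: case/ref if up, -ref/case if down; |x| >= 1."""
    if ave_ref <= 0 or ave_case <= 0:
        raise DegenerateInputError("expression ratio needs positive AVEs")
    if ave_case >= ave_ref:
        return ave_case / ave_ref
    return -ave_ref / ave_case


def welch_p(profile_ref: GeneProfile, profile_case: GeneProfile) -> float:
    """Two-tailed heteroscedastic (Welch) t-test on gene-level replicate values."""
    a = profile_ref.replicate_values
    b = profile_case.replicate_values
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per side")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p)


def compute_cut(rev_ref: float, rev_case: float, pooling: str = "rms") -> float:
    """Gene-specific fold-change cutoff from the two conditions' REVs (percent).

    ``rms`` (default): 1 + sqrt((rev_ref^2 + rev_case^2) / 2) / 100 — the
    root-mean-square of the two REVs, which degenerates to 1 + REV/100
    when they agree.  ``sum2``: 1 + sqrt(2 * (rev_ref^2 + rev_case^2)) / 100.
    """
    if rev_ref < 0 or rev_case < 0:
        raise ValueError("REV must be >= 0")
    s2 = rev_ref**2 + rev_case**2
    if pooling == "rms":
        return 1.0 + math.sqrt(s2 / 2.0) / 100.0
    if pooling == "sum2":
        return 1.0 + math.sqrt(2.0 * s2) / 100.0
    raise ValueError(f"unknown pooling {pooling!r}")


def call_regulation(x: float, p: float, cut: float, alpha: float = 0.05) -> bool:
    """Significant iff p < alpha and |x| > cut (both strict)."""
    return bool(p < alpha and abs(x) > cut)


def compute_wir(ave_ref: float, x: float, p: float) -> float:
    """Weighted individual regulation: AVE_ref * (|x|-1) * sign(x) * (1-p)."""
    if abs(x) < 1:
        raise ValueError("|x| must be >= 1")
    return ave_ref * (abs(x) - 1.0) * math.copysign(1.0, x) * (1.0 - p)


def psr(members: set[str], records: list[RegulationRecord]) -> dict:
    """Percentage of significantly regulated genes in a gene set.

    Returns the percentage plus up/down/total counts over the set members
    that have a regulation record (case-insensitive symbol match).
    """
    keys = {m.upper() for m in members}
    hits = [r for r in records if r.gene.upper() in keys]
    if not hits:
        raise DegenerateInputError("no gene-set member has a regulation record")
    up = sum(1 for r in hits if r.significant and r.x > 0)
    down = sum(1 for r in hits if r.significant and r.x < 0)
    n = len(hits)
    return {
        "psr": 100.0 * (up + down) / n,
        "n": n,
        "n_significant": up + down,
        "n_up": up,
        "n_down": down,
    }


def regulation_table(
    profiles_ref: dict[str, GeneProfile],
    profiles_case: dict[str, GeneProfile],
    reference: str,
    case: str,
    alpha: float = 0.05,
    cut_pooling: str = "rms",
    rev_variant: str = "sqrt",
) -> pd.DataFrame:
    """Full per-gene regulation analysis for one reference -> case contrast."""
    rows = []
    shared = [g for g in profiles_ref if g in profiles_case]
    for g in shared:
        pr, pc = profiles_ref[g], profiles_case[g]
        ave_r, ave_c = compute_ave(pr), compute_ave(pc)
        x = expression_ratio(ave_r, ave_c)
        p = welch_p(pr, pc)
        cut = compute_cut(compute_rev(pr, rev_variant), compute_rev(pc, rev_variant), cut_pooling)
        sig = call_regulation(x, p, cut, alpha)
        wir = compute_wir(ave_r, x, p)
        rows.append(
            {
                "gene": g,
                "reference": reference,
                "case": case,
                "ave_ref": ave_r,
                "ave_case": ave_c,
                "x": x,
                "p": p,
                "cut": cut,
                "significant": sig,
                "direction": (1 if x > 0 else -1) if sig else 0,
                "wir": wir,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "reference", "case", "ave_ref", "ave_case",
            "x", "p", "cut", "significant", "direction", "wir",
        ],
    )
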