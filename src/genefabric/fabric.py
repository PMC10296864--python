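"""Per-condition transcriptomic characteristics: AVE, REV and COR.

Three mutually independent characteristics are attached to every gene in
every condition:

* **AVE** — average expression level: the mean over a gene's redundant
  spots of the per-spot replicate means.
* **REV** — relative expression variability: the pooled coefficient of
  variation over the gene's spots, corrected by a chi-square mid-interval
  factor so that small replicate numbers do not understate variability.
  REV is an inverse proxy for the strength of transcription control.
* **COR** — Pearson correlation of two genes' expression across the
  biological replicates of one condition.  Pairs with |COR| at or above a
  significance threshold are *synergistic* (positive) or *antagonistic*
  (negative); pairs with |COR| at or below an independence threshold are
  *independent*; everything between is not significant.

The pathway coordination score aggregates pair classes over a gene set:
COORD = SYN% + ANT% − IND%.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DegenerateInputError, GeneProfile

__all__ = [
    "FabricSummary",
    "CorPair",
    "CoordScore",
    "compute_ave",
    "compute_pooled_cv",
    "chi2_midinterval_factor",
    "compute_rev",
    "compute_cor",
    "classify_pair",
    "classify_pairs",
    "cor_matrix",
    "pairs_from_matrix",
    "coordination_score",
    "fabric_summary",
    "SYNERGISTIC",
    "ANTAGONISTIC",
    "INDEPENDENT",
    "NOT_SIGNIFICANT",
]

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"
INDEPENDENT = "independent"
NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class FabricSummary:
    gene: str
    condition: str
    ave: float
    pooled_cv: float
    rev: float  # percent


@dataclass(frozen=True)
class CorPair:
    gene_a: str
    gene_b: str
    condition: str
    cor: float  # NaN when undefined (a constant profile)
    klass: str


@dataclass(frozen=True)
class CoordScore:
    gene_set: str
    condition: str
    syn_pct: float
    ant_pct: float
    ind_pct: float
    n_pairs: int

    @property
    def coord(self) -> float:
        return self.syn_pct + self.ant_pct - self.ind_pct


def compute_ave(profile: GeneProfile) -> float:
    """Average expression: mean over spots of per-spot replicate means."""
    return float(profile.spot_means.mean())


def compute_pooled_cv(profile: GeneProfile) -> float:
    """Pooled CV over a gene's spots: sqrt(mean_k (s_k / mu_k)^2).

    For a single spot this is the ordinary coefficient of variation.
    """
    mu = profile.spot_means
    if np.any(mu <= 0):
        raise DegenerateInputError(
            f"gene {profile.gene!r}: spot mean <= 0, CV undefined"
        )
    return float(np.sqrt(np.mean((profile.spot_sds / mu) ** 2)))


def chi2_midinterval_factor(r: int, variant: str = "sqrt") -> float:
    """Chi-square mid-interval correction for a CV estimated on r d.f.

    The 95% confidence interval of a variance estimated on r degrees of
    freedom has endpoints r*s^2/chi2(r; 0.975) and r*s^2/chi2(r; 0.025)
    (upper/lower tail quantiles).  The factor is the midpoint of the
    interval endpoints, mapped onto the CV scale:

    * ``sqrt`` (default): 0.5 * (sqrt(r/chi2_hi) + sqrt(r/chi2_lo)) —
      endpoints square-rooted so they live on the SD/CV scale;
    * ``linear``: 0.5 * (r/chi2_hi + r/chi2_lo), the uncorrected
      variance-scale midpoint.

    The factor is > 1, strictly decreasing in r, and tends to 1 as the
    replication grows.
    """
    if r < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {r}")
    hi = stats.chi2.ppf(0.975, r)
    lo = stats.chi2.ppf(0.025, r)
    if variant == "sqrt":
        return float(0.5 * (math.sqrt(r / hi) + math.sqrt(r / lo)))
    if variant == "linear":
        return float(0.5 * (r / hi + r / lo))
    raise ValueError(f"unknown variant {variant!r}")


def compute_rev(profile: GeneProfile, variant: str = "sqrt") -> float:
    """Relative expression variability, in percent.

    REV = chi-square mid-interval factor at r = n_c * R_i - 1 degrees of
    freedom, times the pooled CV, times 100.
    """
    r = profile.n_replicates * profile.n_spots - 1
    return chi2_midinterval_factor(r, variant) * compute_pooled_cv(profile) * 100.0


def compute_cor(
    profile_i: GeneProfile,
    profile_g: GeneProfile,
    mode: str = "gene_means",
    log2: bool = True,
) -> float:
    """Expression correlation of two genes across biological replicates.

    ``gene_means`` (default) averages each gene's spots within every
    replicate and takes the Pearson correlation of the two per-replicate
    vectors (optionally after log2).  ``pooled_spots`` evaluates the
    spot-pooled double sum over all spot pairs; that form is not bounded
    by [-1, 1] when the two genes have different spot counts, so values
    outside the interval are clamped.

    Returns NaN when either profile has zero variance (correlation
    undefined; distinct from 0).
    """
    if profile_i.n_replicates != profile_g.n_replicates:
        raise ValueError("profiles must have the same replicate count")
    if mode == "gene_means":
        a = profile_i.replicate_values
        b = profile_g.replicate_values
        if log2:
            a, b = np.log2(a), np.log2(b)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])
    if mode == "pooled_spots":
        va = np.log2(profile_i.spot_values) if log2 else profile_i.spot_values
        vb = np.log2(profile_g.spot_values) if log2 else profile_g.spot_values
        da = va - va.mean()
        db = vb - vb.mean()
        denom = math.sqrt((da**2).sum() * (db**2).sum())
        if denom == 0:
            return float("nan")
        # all spot pairs (k_i, k_g), replicate-matched
        num = float(da.sum(axis=0) @ db.sum(axis=0))
        return float(np.clip(num / denom, -1.0, 1.0))
    raise ValueError(f"unknown mode {mode!r}")


def classify_pair(
    cor: float, sig_threshold: float = 0.95, ind_threshold: float = 0.05
) -> str:
    """Classify a correlation: synergistic / antagonistic / independent.

    |cor| >= sig_threshold (boundary inclusive) is significant, signed;
    |cor| <= ind_threshold is independent; NaN (undefined) and everything
    in between is not significant.
    """
    if not ind_threshold < sig_threshold:
        raise ValueError("ind_threshold must be < sig_threshold")
    if math.isnan(cor):
        return NOT_SIGNIFICANT
    if abs(cor) >= sig_threshold:
        return SYNERGISTIC if cor > 0 else ANTAGONISTIC
    if abs(cor) <= ind_threshold:
        return INDEPENDENT
    return NOT_SIGNIFICANT


def classify_pairs(
    profiles: dict[str, GeneProfile],
    condition: str,
    genes: list[str] | None = None,
    mode: str = "gene_means",
    log2: bool = True,
    sig_threshold: float = 0.95,
    ind_threshold: float = 0.05,
) -> list[CorPair]:
    """All-pairs COR and classification over a gene list.

    ``genes`` defaults to every profiled gene; symbols are matched
    case-insensitively against the profile keys.
    """
    lookup = {g.upper(): g for g in profiles}
    if genes is None:
        present = list(profiles)
    else:
        present = [lookup[g.upper()] for g in genes if g.upper() in lookup]
    pairs = []
    for a, b in itertools.combinations(present, 2):
        c = compute_cor(profiles[a], profiles[b], mode=mode, log2=log2)
        pairs.append(
            CorPair(a, b, condition, c, classify_pair(c, sig_threshold, ind_threshold))
        )
    return pairs


def coordination_score(
    gene_set_name: str, condition: str, pairs: list[CorPair]
) -> CoordScore:
    """COORD = SYN% + ANT% − IND% over all classified within-set pairs."""
    if not pairs:
        raise DegenerateInputError(
            f"gene set {gene_set_name!r}: fewer than 2 members present"
        )
    n = len(pairs)
    counts = {SYNERGISTIC: 0, ANTAGONISTIC: 0, INDEPENDENT: 0, NOT_SIGNIFICANT: 0}
    for p in pairs:
        counts[p.klass] += 1
    return CoordScore(
        gene_set=gene_set_name,
        condition=condition,
        syn_pct=100.0 * counts[SYNERGISTIC] / n,
        ant_pct=100.0 * counts[ANTAGONISTIC] / n,
        ind_pct=100.0 * counts[INDEPENDENT] / n,
        n_pairs=n,
    )


def cor_matrix(
    profiles: dict[str, GeneProfile],
    log2: bool = True,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs COR (gene_means mode) as a symmetric gene x gene frame.

    Vectorized equivalent of calling :func:`compute_cor` on every pair;
    rows/columns of zero-variance genes are NaN (undefined), diagonal 1
    otherwise.
    """
    if genes is None:
        genes = list(profiles)
    mat = np.vstack([profiles[g].replicate_values for g in genes])
    if log2:
        mat = np.log2(mat)
    constant = np.ptp(mat, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(mat)
    c = np.atleast_2d(c)
    c[constant, :] = np.nan
    c[:, constant] = np.nan
    np.fill_diagonal(c, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(c, index=genes, columns=genes)


def pairs_from_matrix(
    matrix: pd.DataFrame,
    condition: str,
    sig_threshold: float = 0.95,
    ind_threshold: float = 0.05,
) -> list[CorPair]:
    """Classified pair list from a correlation matrix (upper triangle)."""
    genes = list(matrix.index)
    vals = matrix.to_numpy()
    pairs = []
    for i, a in enumerate(genes):
        for j in range(i + 1, len(genes)):
            c = float(vals[i, j])
            pairs.append(
                CorPair(a, genes[j], condition, c,
                        classify_pair(c, sig_threshold, ind_threshold))
            )
    return pairs


def fabric_summary(
    profiles: dict[str, GeneProfile], variant: str = "sqrt"
) -> pd.DataFrame:
    """AVE / pooled CV / REV for every profiled gene, as a DataFrame."""
    rows = []
    for g, prof in profiles.items():
        cv = compute_pooled_cv(prof)
        rows.append(
            {
                "gene": g,
                "condition": prof.condition,
                "ave": compute_ave(prof),
                "pooled_cv": cv,
                "rev": compute_rev(prof, variant),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "condition", "ave", "pooled_cv", "rev"])
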