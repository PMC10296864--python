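"""Synthetic replicated expression data with known ground truth.

The generator emulates a multi-condition microarray study — by default 4
conditions (CO reference plus HO, CM, HM) x 4 biological replicates,
redundant spots per gene — with every quantity the pipeline estimates
planted by construction:

* log-normal expression: a gene's log2 value in replicate j of condition
  c is baseline + condition effect + shared latent factors + biological
  noise; each spot then adds independent technical noise;
* a latent-factor block structure gives synergistic (co-loaded),
  antagonistic (anti-loaded) and independent (zero-loading) gene pairs;
* per-gene biological CVs span roughly 3%-160% and baselines are spread
  so average expression covers ~0.2-300 median units, the ranges a whole-
  genome array exhibits;
* condition-specific fold-changes up to a few hundred-fold are applied
  before median normalization (strong regulation shifts the condition
  median slightly, as on real arrays); ground-truth fold-changes are
  recorded post-normalization.

Everything is deterministic for a fixed spec + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ProbeTable, normalize_to_median
from .fabric import CorPair, classify_pair

__all__ = [
    "CorrBlock",
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "recovery_report",
    "null_pair_rate",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CorrBlock:
    """A latent-factor block: `size` genes sharing one factor.

    `rho` is the loading share (pairwise |correlation| within the block on
    the log scale); the last `n_antagonistic` members load negatively, so
    their pairs with positive loaders have correlation -rho.
    """

    size: int
    rho: float = 0.99
    n_antagonistic: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.n_antagonistic >= self.size < 2:
            raise ValueError("block needs >= 2 genes")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study."""

    n_genes: int = 200
    conditions: tuple[str, ...] = ("CO", "HO", "CM", "HM")
    reference: str = "CO"
    n_replicates: int = 4
    spot_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 3.0
    cv_range: tuple[float, float] = (0.03, 1.6)
    tech_cv: float = 0.05
    corr_blocks: tuple[CorrBlock, ...] = (
        CorrBlock(10, 0.99, 0),
        CorrBlock(10, 0.99, 0),
        CorrBlock(10, 0.99, 5),
    )
    # (gene, condition, signed fold with |fold| >= 1; negative = down).
    # None -> plant a default pattern: ~10% of genes per case condition,
    # |fold| log-uniform in [1.5, 250], mixed sign.
    regulation_effects: tuple[tuple[str, str, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in self.conditions:
            raise ValueError("reference condition missing from condition list")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if sum(b.size for b in self.corr_blocks) > self.n_genes:
            raise ValueError("correlation blocks exceed the gene count")
        tot = sum(self.spot_distribution.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError("spot_distribution probabilities must sum to 1")
        if any(r < 1 for r in self.spot_distribution):
            raise ValueError("spot counts must be >= 1")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted values behind one generated dataset."""

    true_mean: pd.DataFrame        # gene x condition, post-normalization units
    true_cv: pd.DataFrame          # gene x condition biological CV (fraction)
    true_fold: pd.DataFrame        # gene x case condition, signed x convention
    # gene x gene correlation of the observed gene-level log2 expression:
    # loading-implied block structure, attenuated by spot-level technical noise
    true_correlation: pd.DataFrame
    pathways: dict[str, list[str]]
    regulated: dict[str, set[str]] # condition -> genes with planted |fold| > 1

    def pair_class(
        self, a: str, b: str, sig_threshold: float = 0.95, ind_threshold: float = 0.05
    ) -> str:
        return classify_pair(
            float(self.true_correlation.loc[a, b]), sig_threshold, ind_threshold
        )


def _default_regulation(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[tuple[str, str, float]]:
    genes = spec.gene_names()
    cases = [c for c in spec.conditions if c != spec.reference]
    n_reg = max(1, spec.n_genes // 10)
    effects = []
    for cond in cases:
        idx = rng.choice(spec.n_genes, size=n_reg, replace=False)
        mags = np.exp(rng.uniform(math.log(1.5), math.log(250.0), size=n_reg))
        signs = rng.choice([-1.0, 1.0], size=n_reg)
        for i, m, s in zip(idx, mags, signs):
            effects.append((genes[i], cond, float(s * m)))
    return effects


def generate_dataset(spec: SyntheticSpec) -> tuple[ProbeTable, GroundTruth]:
    """Draw one dataset and its ground truth from a spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    n, nrep = spec.n_genes, spec.n_replicates

    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=n)
    lo, hi = spec.cv_range
    if lo == hi:  # degenerate spec (incl. noise-free, cv = 0)
        cv = np.full(n, float(lo))
    elif lo <= 0:
        raise ValueError("cv_range lower bound must be > 0 (or equal to the upper)")
    else:
        cv = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    sigma_ln = np.sqrt(np.log1p(cv**2))      # natural-log SD of the bio effect
    sigma_l2 = sigma_ln / LN2                # same, in log2 units

    # latent-factor loadings: block members share one factor
    block_of = np.full(n, -1)
    sign = np.ones(n)
    pos = 0
    for bi, blk in enumerate(spec.corr_blocks):
        block_of[pos : pos + blk.size] = bi
        if blk.n_antagonistic:
            sign[pos + blk.size - blk.n_antagonistic : pos + blk.size] = -1.0
        pos += blk.size
    rho = np.array([spec.corr_blocks[b].rho if b >= 0 else 0.0 for b in block_of])
    loading = sign * np.sqrt(rho) * sigma_l2
    resid_sd = np.sqrt(1.0 - rho) * sigma_l2

    # spot counts and technical noise
    spot_counts = rng.choice(
        list(spec.spot_distribution), size=n, p=list(spec.spot_distribution.values())
    )
    tech_sd_l2 = math.sqrt(np.log1p(spec.tech_cv**2)) / LN2

    effects = (
        list(spec.regulation_effects)
        if spec.regulation_effects is not None
        else _default_regulation(spec, rng)
    )
    reg_l2 = pd.DataFrame(0.0, index=genes, columns=list(spec.conditions))
    for g, cond, fold in effects:
        if abs(fold) < 1:
            raise ValueError(f"planted fold for {g} must satisfy |fold| >= 1")
        reg_l2.loc[g, cond] = math.copysign(math.log2(abs(fold)), fold)

    spot_ids, spot_genes, blocks = [], [], {}
    for c in spec.conditions:
        nblk = len(spec.corr_blocks)
        z = rng.normal(size=(nblk, nrep))                     # factor scores
        eps = rng.normal(size=(n, nrep)) * resid_sd[:, None]  # gene-level noise
        bio = baseline[:, None] + reg_l2[c].to_numpy()[:, None] + eps
        bio[block_of >= 0] += (
            loading[block_of >= 0, None] * z[block_of[block_of >= 0]]
        )
        cond_rows = []
        for i, g in enumerate(genes):
            for k in range(spot_counts[i]):
                tech = rng.normal(0.0, tech_sd_l2, size=nrep)
                cond_rows.append(2.0 ** (bio[i] + tech))
                if c == spec.conditions[0]:
                    spot_ids.append(f"{g}_s{k + 1}")
                    spot_genes.append(g)
        blocks[c] = np.vstack(cond_rows)

    columns, data = [], []
    for c in spec.conditions:
        for j in range(nrep):
            columns.append(f"{c}_r{j + 1}")
        data.append(blocks[c])
    values = pd.DataFrame(
        np.hstack(data), index=pd.Index(spot_ids, name="spot"), columns=columns
    )
    table = ProbeTable(
        values=values,
        gene_of_spot=pd.Series(spot_genes, index=values.index, name="gene"),
        replicate_columns={
            c: [f"{c}_r{j + 1}" for j in range(nrep)] for c in spec.conditions
        },
    )
    normalized = normalize_to_median(table)
    medians = {
        c: float(np.nanmedian(table.condition_values(c).to_numpy()))
        for c in spec.conditions
    }

    # ground truth, in post-normalization units
    ln_var_total = sigma_ln**2 + (tech_sd_l2 * LN2) ** 2
    mean_raw = {
        c: 2.0 ** (baseline + reg_l2[c].to_numpy()) * np.exp(0.5 * ln_var_total)
        for c in spec.conditions
    }
    true_mean = pd.DataFrame(
        {c: mean_raw[c] / medians[c] for c in spec.conditions}, index=genes
    )
    cases = [c for c in spec.conditions if c != spec.reference]
    fold = {}
    for c in cases:
        ratio = (
            2.0 ** (reg_l2[c] - reg_l2[spec.reference]).to_numpy()
            * medians[spec.reference]
            / medians[c]
        )
        fold[c] = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    true_fold = pd.DataFrame(fold, index=genes)

    # Correlation of the *observed* gene-level log2 expression: averaging a
    # gene's spots leaves technical variance ~ tech_sd^2 / R_i, which
    # attenuates the loading-implied correlation by lambda_i * lambda_j.
    tau2 = tech_sd_l2**2 / spot_counts.astype(float)
    denom = np.sqrt(sigma_l2**2 + tau2)
    lam = np.divide(sigma_l2, denom, out=np.zeros_like(denom), where=denom > 0)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if block_of[i] >= 0 and block_of[i] == block_of[j]:
                corr[i, j] = corr[j, i] = sign[i] * sign[j] * rho[i] * lam[i] * lam[j]
    true_correlation = pd.DataFrame(corr, index=genes, columns=genes)

    pathways: dict[str, list[str]] = {}
    pos = 0
    for bi, blk in enumerate(spec.corr_blocks):
        pathways[f"block{bi + 1}"] = genes[pos : pos + blk.size]
        pos += blk.size
    if pos < n:
        pathways["background"] = genes[pos : min(n, pos + 30)]

    truth = GroundTruth(
        true_mean=true_mean,
        true_cv=pd.DataFrame({c: cv for c in spec.conditions}, index=genes),
        true_fold=true_fold,
        true_correlation=true_correlation,
        pathways=pathways,
        regulated={
            c: {g for g, cc, f in effects if cc == c and abs(f) > 1} for c in cases
        },
    )
    return normalized, truth


def recovery_report(
    truth: GroundTruth,
    ave: pd.DataFrame | None = None,
    fold: pd.DataFrame | None = None,
    rev: pd.DataFrame | None = None,
    pairs: list[CorPair] | None = None,
    regulation: pd.DataFrame | None = None,
    sig_threshold: float = 0.95,
    ind_threshold: float = 0.05,
) -> dict:
    """Compare pipeline estimates against the planted ground truth.

    Every argument is optional; each adds its own block of metrics:
    relative bias / RMSE for AVE, bias / RMSE for signed fold-changes,
    Spearman rank correlation of estimated REV against planted CVs, a
    pair-class confusion matrix, and a regulation-call confusion matrix.
    """
    out: dict = {}
    if ave is not None:
        genes = [g for g in ave.index if g in truth.true_mean.index]
        conds = [c for c in ave.columns if c in truth.true_mean.columns]
        est = ave.loc[genes, conds].to_numpy()
        tru = truth.true_mean.loc[genes, conds].to_numpy()
        rel = (est - tru) / tru
        out["ave_rel_bias"] = float(rel.mean())
        out["ave_rel_rmse"] = float(np.sqrt((rel**2).mean()))
    if fold is not None:
        genes = [g for g in fold.index if g in truth.true_fold.index]
        conds = [c for c in fold.columns if c in truth.true_fold.columns]
        err = fold.loc[genes, conds].to_numpy() - truth.true_fold.loc[genes, conds].to_numpy()
        out["fold_bias"] = float(err.mean())
        out["fold_rmse"] = float(np.sqrt((err**2).mean()))
    if rev is not None:
        out["rev_cv_spearman"] = {}
        for c in rev.columns:
            if c not in truth.true_cv.columns:
                continue
            genes = [g for g in rev.index if g in truth.true_cv.index]
            rho_s = stats.spearmanr(
                rev.loc[genes, c], truth.true_cv.loc[genes, c]
            ).statistic
            out["rev_cv_spearman"][c] = float(rho_s)
    if pairs is not None:
        classes = ["synergistic", "antagonistic", "independent", "not_significant"]
        conf = pd.DataFrame(0, index=classes, columns=classes)
        for p in pairs:
            t = truth.pair_class(p.gene_a, p.gene_b, sig_threshold, ind_threshold)
            conf.loc[t, p.klass] += 1
        out["pair_confusion"] = conf
    if regulation is not None:
        conf = pd.DataFrame(
            0, index=["regulated", "unregulated"], columns=["called", "not_called"]
        )
        for _, row in regulation.iterrows():
            reg_set = truth.regulated.get(row["case"], set())
            t = "regulated" if row["gene"] in reg_set else "unregulated"
            conf.loc[t, "called" if row["significant"] else "not_called"] += 1
        out["regulation_confusion"] = conf
    return out


def null_pair_rate(
    n_pairs: int,
    n_replicates: int = 4,
    sig_threshold: float = 0.95,
    seed: int = 0,
) -> float:
    """Monte-Carlo false-call rate of |r| >= threshold on independent genes.

    For n = 4 replicates the null density of the Pearson coefficient is
    proportional to (1 - r^2)^((n-4)/2), i.e. uniform on [-1, 1], so the
    analytic rate at threshold 0.95 is exactly 0.05.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_pairs, n_replicates))
    b = rng.normal(size=(n_pairs, n_replicates))
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    r = (a * b).sum(axis=1) / np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    return float(np.mean(np.abs(r) >= sig_threshold))
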