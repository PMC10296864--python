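# Methods

## Data model

The unit of input is a spot-level expression table: rows are array spots
(several spots may probe the same gene; `R_i` denotes gene *i*'s spot
count), columns are samples grouped into named conditions with at least
two biological replicates each. Spots are treated as technical
replicates *within* each biological replicate: the biological signal of
a gene is shared by all of its spots on one array, while spot-to-spot
scatter is technical. This is what makes redundant probing informative —
the pooled CV over a gene's spots accumulates degrees of freedom
(`r = n·R_i − 1`) without adding biological samples.

Intensities are normalized per condition to the median over all
(spot, replicate) cells, so expression is in "median units" and the
per-condition median is exactly 1. Normalization is idempotent and
scale-invariant. Missing or non-numeric cells cause the spot to be
excluded from the affected condition (and the whole row at parse time if
any assigned column is bad); the drop count is logged. No imputation is
attempted. Gene symbols are matched case-insensitively between
expression tables and GMT gene sets.

## The three characteristics

**AVE** is the mean over spots of per-spot replicate means.

**REV** corrects the pooled CV for small-sample underestimation using
the chi-square mid-interval of the variance confidence interval. The 95%
CI of a variance on *r* degrees of freedom is
`[r·s²/χ²_{r;0.975}, r·s²/χ²_{r;0.025}]`; the factor is the midpoint of
the interval endpoints mapped to the CV scale. Two variants exist:

- `sqrt` (default): `½(√(r/χ²_hi) + √(r/χ²_lo))` — endpoints
  square-rooted so they live on the SD/CV scale. At r = 3 the factor is
  2.148; it decreases strictly in *r* and tends to 1.
- `linear`: `½(r/χ²_hi + r/χ²_lo)` (7.11 at r = 3) — the variance-scale
  midpoint, kept for sensitivity analysis.

The `sqrt` variant is the default because a confidence interval for a
variance must be square-rooted endpoint-wise to bound a CV; the linear
form overcorrects by roughly the square of the factor.

**COR** defaults to `gene_means` mode: average a gene's spots within
each replicate, then Pearson across replicates. The spot-pooled
double-sum form (`pooled_spots`) is available behind a flag; it is not
bounded by [−1, 1] when the two genes have different spot counts, so
out-of-range values are clamped and logged. Correlation is computed on
log₂ expression by default (`cor_log2=True`); the linear scale is a
switch because the four-gene worked example's printed correlations are
linear-scale. Constant profiles give an *undefined* correlation (NaN),
which is distinct from 0 and classified `not_significant`.

Classification: `|COR| ≥ 0.95` (boundary inclusive) → synergistic or
antagonistic by sign; `|COR| ≤ 0.05` → independent; otherwise not
significant. The independence threshold 0.05 is a convention chosen to
mirror the 0.95 significance bound, since "independently expressed" has
no canonical numeric definition; both thresholds are configurable. At
n = 4 replicates the null density of Pearson *r* is `(1 − r²)^((n−4)/2)`
— uniform on [−1, 1] — so the 0.95 rule has an exact 5% false-call rate
on truly independent pairs; this is verified by Monte-Carlo in the test
suite. No multiple-testing correction is applied across pairs (a
Benjamini–Hochberg option exists for the regulation p-values but is off
by default).

## Regulation calling

The signed ratio `x` is case/ref AVE if the case is higher, else
−ref/case, so `|x| ≥ 1` always and the sign carries direction. The
Welch (heteroscedastic) t-test runs on gene-level per-replicate means —
spots of one gene are technical, not biological, replicates; a per-spot
variant would overstate the degrees of freedom. A gene is called
regulated when `p < α` (default 0.05) and `|x| > CUT` strictly.

`CUT = 1 + √((REV_ref² + REV_case²)/2)/100` (`rms` pooling, default)
degenerates to the interpretable `1 + REV/100` when the two REVs agree;
a `sum2` variant `1 + √(2(REV_ref² + REV_case²))/100` is kept for
sensitivity analysis. WIR resolves to
`AVE_ref · (|x| − 1) · sign(x) · (1 − p)`: zero at `|x| = 1` ("no
departure from the normal level"), signed by direction, damped by the
p-value ("confidence of regulation").

## Trajectories

Each gene's move from reference to case is the 3-vector
`(ΔAVE/⟨AVE_ref⟩, ΔREV/⟨REV_ref⟩, rms_j(ΔCOR_ij)/rms_j(COR_ref,ij))`
with ⟨·⟩ averaged over a gene universe; TD is its Euclidean norm. The
universe defaults to all quantified genes and is overridable to a
pathway-restricted set — published per-pathway TD values depend on this
choice, so they are not promised as reproducible without knowing the
original universe. Partner pairs with an undefined correlation in either
condition are excluded from numerator and denominator alike, keeping
both mean-square sums on the same support. TD is invariant under common
rescaling of all reference AVEs and strictly increasing in each
component's magnitude.

## Networks and remodeling

A gene set's coordination network has one node per member present in the
data (absent members are dropped with a warning) and one edge per pair
classified synergistic, antagonistic or independent; not-significant
pairs are blank. Edge classes come from the fabric stage with its
configured thresholds — networks never re-derive correlations.
Remodeling between conditions is the per-class count/percentage pair
plus the 4×4 class-transition table over all C(n, 2) pairs; row/column
sums reproduce the per-condition counts by construction.

## Synthetic data

The generator emulates a 4-condition (CO reference, HO, CM, HM) ×
4-replicate probe-redundant array study. Replicate *j* of gene *i* in
condition *c* is, on the log₂ scale,

```
baseline_i + regulation_{i,c} + loading_i · z_{block(i),j,c} + ε_{i,j,c}
```

with spot values adding independent technical noise before
exponentiation and per-condition median normalization. Defaults and
their rationale:

- `baseline_log2_mean = 3, sd = 3`: after normalization, AVE spans
  roughly 0.2–300 median units, the range a whole-genome array shows.
- `cv_range = (0.03, 1.6)`, log-uniform: per-gene biological CVs span
  the observed 3%–160% variability range.
- `spot_distribution = {1: 0.7, 2: 0.2, 3: 0.1}`: most genes probed
  once, a minority redundantly, as on the emulated platform.
- `tech_cv = 0.05`: spot-level technical scatter well below biological.
- Correlation blocks: genes in a block share one latent factor with
  loading share ρ (default 0.99); anti-loaded members make antagonistic
  pairs; unassigned genes are independent. The implied correlation
  matrix is positive semi-definite by construction.
- Planted fold-changes are signed with `|fold|` up to a few hundred;
  the default pattern regulates ~10% of genes per case condition with
  log-uniform magnitudes in [1.5, 250].

The log-normal model is used because intensities are positive and
right-skewed and correlation is defined on log₂ expression. Condition
effects are applied *before* normalization, so strong unbalanced
regulation slightly shifts the condition median as on real arrays;
ground-truth means and fold-changes are recorded post-normalization.
Ground-truth correlations are recorded on the observed scale: averaging
a gene's spots leaves technical variance `≈ σ_tech²/R_i`, which
attenuates the loading-implied correlation by
`λ_i = σ_bio/√(σ_bio² + σ_tech²/R_i)` (delta method). Empirical
correlations converge to these attenuated values, and for genes whose
biological CV is comparable to the technical CV the attenuation is
substantial — a feature of redundant-probe designs, not an artifact.

What the generator does *not* emulate: scanner background, dye effects,
probe-affinity biases, inter-array batch structure, and count-based
noise (for RNA-seq). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated stochastic model, not
robustness to platform artifacts.

## Recovery experiments and problem sizes

- Null calibration: 10,000 independent replicate-quadruple pairs; the
  `|COR| ≥ 0.95` rule fires at 5% ± Monte-Carlo error.
- Fold recovery: one 2.0× effect planted in a 400-gene universe at 1000
  replicates, the regulated gene carrying an ordinary 10–40% biological
  CV. Two deliberate design points: (i) at the extreme 160% CV the
  sampling sd of x at n = 1000 is ~0.15, so a ±0.1 recovery window would
  test noise, not consistency; (ii) a small universe makes the pooled
  per-condition median depend on a single middle gene, so the
  normalizer itself genuinely shifts between conditions — with ~400+
  genes it is stable, as on real arrays.
- REV ranking: 200 genes × 50 replicates; Spearman(REV, planted CV)
  exceeds 0.9.
- Coupling sensitivity: planted ρ = 0.99 blocks at the study's n = 4;
  the 0.95 rule recovers well over half of the truly coupled pairs
  (observed ≈ 0.92 over 200 Monte-Carlo seeds), which the suite asserts
  as a > 0.5 regression floor.

## Numerical conventions and degenerate inputs

Sample SDs use the n−1 denominator (required to reproduce the worked
example's CVs). Spot means of 0 make the CV undefined (error); a zero
per-condition median aborts normalization; a zero AVE aborts the ratio;
equal constant groups give Welch p = 1. Thresholds are applied to
machine values, boundary inclusive for `|COR| ≥ 0.95` and strict for
`|x| > CUT` and `p < α`. All randomness flows from a single integer seed
through `numpy.random.default_rng`; identical spec + seed reproduces a
dataset bit-identically, and the pipeline manifest (config, input
checksums, versions) makes file-level runs reproducible bit-for-bit.

## Known limitations

- The fixed |COR| threshold ignores replicate count: at n > 4 the 0.95
  rule becomes conservative on the null and the analytic-uniform
  argument no longer applies.
- TD values depend on the normalizing gene universe; cross-study TD
  comparisons require the same universe.
- The `pooled_spots` correlation mode is kept only for fidelity
  experiments; its clamping makes it a biased estimator when spot counts
  differ.
- PSR inherits every weakness of thresholded counting; WIR and TD are
  the recommended quantifiers.
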