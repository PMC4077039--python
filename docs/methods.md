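# Methods

## Data model

A screen is a long-format table of measurements `(pert_a, pert_b, score,
rep1, rep2)` with a non-negative, finite fitness score — the abundance of
a DNA barcode after exponential growth. `rep1` groups multiple
perturbations toward the same outcome (e.g. several hairpins targeting
one gene); `rep2` indexes repeat measurements of the same combination and
must form `1..n` without gaps within each `(A, B, rep1)` group. Importers
renumber `rep2` automatically, so duplicated identifier rows become
successive replicates. Downstream normalization estimates one effect per
perturbation level, hence at least two distinct levels per axis are
required.

All methods assume interactions are **rare**: marginal (row/column)
effects are estimated from the whole screen, so a screen in which most
pairs interact would normalize its own signal away.

### Importers

* **Canonical CSV** (3–5 semicolon-separated columns, comma/tab
  accepted): positional mapping; an optional header is detected as a
  first row whose score field is not numeric.
* **Luminex xMAP bead exports** (`cell line; drug; bead value`): the bead
  values of each pair are reduced to a symmetric trimmed mean —
  `floor(k · trim_fraction)` values dropped per tail, default 0.25,
  which interpolates between the mean (0) and the median (→ 0.5) and is
  robust to aggregated or dropped-out beads. All rows of a pair are
  beads of one measurement, so each pair yields one score; an optional
  fourth column names a replicate and splits the bead groups.
* **Sequencing count tables** (`cell line; shRNA; number of reads`): the
  target gene is the shRNA-name prefix before the first `_`
  (configurable); the full shRNA name is kept as `rep1`. Zero counts are
  retained and handled by the pseudocount at log-transform time, not
  dropped — a zero count is informative (complete dropout).

The analysis output is a nine-column semicolon-separated file (`pertA;
pertB; rel_mag_a; rel_mag_b; abs_mag_a; abs_mag_b; p_a; p_b;
p_combined`), written at full float precision so a read/write round trip
is exact to more than 12 significant digits; externally produced files in
the same layout can be read back for filtering and plotting.

## Pre-analysis filtering

Because true interactions are rare, the profile of replicate-mean log
scores of any perturbation across the other axis should correlate with
its peers'. For each axis all pairwise Spearman correlations between
profiles are computed (pairs sharing fewer than 3 positions contribute
nothing) and each perturbation is summarized by the **median** of its
correlations with all others — robust to a few genuinely interacting
cells and to other noisy perturbations. Cutoffs are applied per axis;
profiles are built on log scores for symmetry with the linear model's
transform. Correlating raw instead of log signals changes nothing for
Spearman within a profile (ranks are log-invariant) but the
replicate-mean aggregation is done on the log scale.

## Two-stage robust linear model

Stage 1 fits `ln(score + pseudocount) ~ intercept + A + B` (dummy coding,
first sorted level as reference) by Huber IRLS. The pseudocount defaults
to 1 when zeros are present (count data) and 0 otherwise; the natural-log
base is irrelevant to p-values (coefficients rescale). Because the model
is additive in log space, its coefficients describe multiplicative
fitness effects, and multiplying all scores by a constant changes no
residual and no p-value (checked to 1e-8 in the tests).

Stage 2 takes the stage-1 residuals and, per level of the fixed factor,
fits a no-intercept one-way robust regression on the other factor, so
every target level gets a directly estimable coefficient that pools the
pair's replicates; the variance is pooled across the context (one fit per
fixed level). Contexts with no spare residual degree of freedom report
coefficients with missing p-values.

### Huber fit

Iteratively reweighted least squares with weights
`w = min(1, k·ŝ/|r|)`, `k = 1.345` (95% Gaussian efficiency), scale
`ŝ = median(|r|)/0.6745` re-estimated each iteration, at most 50
iterations, convergence when no coefficient moves by more than 1e-6.
The design matrices are sparse dummy codings, so the normal equations
are assembled sparsely; a rank-deficient design raises an error naming
the aliased columns. With `k → ∞` the fit converges to ordinary least
squares (verified against the closed form).

Standard errors use Huber's asymptotic M-estimator covariance,

    se² = K² · [ŝ² Σψ(u)² / (n−p)] / (mean ψ′)² · diag((XᵀX)⁻¹) ,
    u = r/ŝ,  K = 1 + (p/n) · var(ψ′)/mean(ψ′)² ,

rather than a naive `ŝ²(XᵀWX)⁻¹` plug-in: the plug-in ignores the spread
absorbed by the fitted parameters and the inefficiency of the MAD scale,
which leaves the conditional t statistics visibly anti-conservative
(null Kolmogorov–Smirnov distance ≈ 0.10 at 50×50×4); with the corrected
covariance the null p-values are uniform to within KS ≈ 0.015, the
sampling floor for 2500 values.

### P-value tails

The coefficient test is two-sided by default, `p = 2·P(T_{n−p} > |t|)`,
because interactions in both fitness directions are of interest and
because the combined score's null calibration (and Brown's χ² theory)
requires uniformly distributed inputs; a `tail="directed"` option halves
it for users who deliberately want the anti-conservative variant. The
mapping is `p_b` = test of the B-coefficient at fixed A, `p_a` = test of
the A-coefficient at fixed B.

### Split variant

`lm_split_analyze` partitions the sorted levels of each axis into
near-equal contiguous blocks of at most `group_size` (default 50; a
seeded shuffle is available, and a trailing single-level block is merged
into its neighbour since normalization needs two levels). The full
pipeline — normalization, testing, magnitudes and Brown calibration —
runs independently per A-block × B-block, so memory scales with the
block, not the screen. With `group_size` at least both axis sizes the
result is bitwise identical to the full model; at 100×100×4 with blocks
of 50 the Spearman correlation of −log10 combined p-values with the full
model is ≈ 0.96.

## Mann–Whitney model

Scores (plus pseudocount) are arranged in an A × B × replicate array
(sub-perturbations and replicate indices flattened per pair). Each value
is divided by the median of its row's non-missing values, then by its
column median recomputed on the row-normalized values — one pass per
axis, deliberately not a median polish iterated to convergence — and
log10-transformed. After the row step every row's median is exactly 1;
the column step leaves a small residual row deviation that is accepted.
A row or column with median zero raises an error naming the perturbation.

For each pair with at least 3 replicate values, a two-sided Mann–Whitney
U test compares the pair's values against the pooled normalized values of
all other pairs in the same column (`p_a`, the distribution over A) and
row (`p_b`), excluding the pair's own values. Pairs under the replicate
floor keep their magnitudes and propagate missing p-values. The U
statistic uses midranks; the p-value is exact by enumeration of all rank
assignments when the combined sample size is ≤ 12 with no ties (at most
924 arrangements), otherwise a normal approximation with tie-corrected
variance and continuity correction — the approximation agrees with the
exact tail to < 0.02 already at 6 + 6.

## Combining p-values

The two directional p-values derive from the same measurements and are
dependent. `X = −2(ln p_a + ln p_b)` has mean 4 under the null; Brown's
method refers `X/c` to χ²(f) with `c = var/(2·4)`, `f = 2·4²/var`,
`var = 8 + 2·cov`. The covariance is estimated from the screen's own
p-value cloud as `cov = 4·max(0, r)` where `r` is the Pearson correlation
of `−2 ln p_a` and `−2 ln p_b`: the variances are pinned at their
theoretical value 4 (like the mean, so a hit-rich screen does not deflate
its own significance, and so perfect dependence yields the exact identity
map rather than a sample variance fluctuating around it), and clipping to
`[0, 4]` keeps `f ∈ [2, 4]` and prevents anti-conservative behavior from
negative sample correlation. At independence the method reduces exactly
to Fisher's χ²₄; with fewer than 30 complete pairs it falls back to
Fisher with a warning. Mean and product combiners are provided for
comparison; on the jointly significant corner Brown sits between them
(mean ≥ brown ≥ product).

Computed p-values are floored at 1e-300 before combination so the log
transform stays finite.

## Magnitudes

`rel_mag_a` = a pair's mean raw score divided by the median of pair means
over all A at the same B (treatment vs median of all treatments);
`rel_mag_b` symmetric. `abs_mag_a` / `abs_mag_b` = the perturbation's
mean raw signal across the whole screen — the quantity used to filter
out low-abundance barcodes (removing the bottom 5–10% of signals is a
typical noise reduction).

## Filter language

Grammar: `expr := or; or := and ('|' and)*; and := unary ('&' unary)*;
unary := '!' unary | '(' expr ')' | atom; atom := column op number |
column '~' pattern` with `op ∈ {<, <=, >, >=, =}`; `&` binds tighter
than `|`, whitespace is insignificant, `~` is a case-insensitive plain
substring match (no regex, no anchoring), and syntax errors report a
0-based character position. Rows with a missing value in a referenced
column evaluate comparisons and substring tests as false — so
significance filters exclude the pairs whose p-value could not be
computed (e.g. under the 3-replicate floor), while the negated filter
keeps them.

## Circle plot

One radial axis per labeled perturbation, uniformly spaced (a bijection
from labels to angles); a pair's bubble sits on its label's axis at
radius `min(−log10 p, cap)/cap` (cap default 10, so everything at or
beyond p = 1e-10 touches the circumference and one extreme hit cannot
flatten the rest; p = 1 is the exact center). Bubble size encodes
`|log2 rel_mag|` so 2-fold up and 2-fold down are equal-sized — the
direction is already color-coded (reduced fitness red, increased black).
Rendering is deterministic (no jitter; overplotting is handled by
transparency), PNG or PDF; the geometry, including each bubble's partner
perturbation, can be exported as CSV in lieu of interactive hover.

## Synthetic screens and benchmarking

`generate_screen` draws `E[score_ij] = exp(μ + a_i + b_j)` with
`a_i ~ N(0, σ_A²)`, `b_j ~ N(0, σ_B²)`; a seeded sample of pairs without
replacement has its expectation multiplied by the spike-in fold; each
replicate is the expectation times mean-one log-normal noise with a given
coefficient of variation. Defaults: 100 × 100 × 4 with 100 spikes,
`μ = 7` (e⁷ ≈ 1100, a typical bead-intensity/read-count magnitude),
`σ_A = σ_B = 0.3` (≈ 35% marginal fitness spread between perturbations),
`cv = 0.15` (typical replicate noise for pooled barcode assays). Under
these conditions quadruplicate detection of fold 0.5 is essentially
saturated while fold 1.3 is genuinely hard, so the benchmark resolves the
ordering of effect sizes. All randomness derives from a single seed.

The generator emulates the multiplicative structure, positive skew and
replicate noise of real barcode data. It does **not** emulate several
features of real screens: heavy-tailed outliers from failed wells,
correlated replicate batches, abundance-dependent noise (low-count
barcodes are noisier), hairpin-level heterogeneity within a gene, or
spatial plate effects. Tests passing on these simulations therefore
demonstrate correctness and calibration of the statistics under the
stated model, not robustness to every real-data pathology — the
prefilter and the bottom-signal filter exist precisely for what the
generator leaves out. The default log-normal noise is symmetric in log
space, so decreased- and increased-fitness spikes of mirrored fold are
equally detectable up to seed noise; with the optional raw-scale Gaussian
noise model (`noise="raw"`) the log transform makes the low side
heavier-tailed and decreased-fitness spikes become easier to detect, the
asymmetry reported for real data.

`roc` sweeps every distinct value of a ranking statistic (ascending;
missing values rank worst), so tied scores share a threshold and the
trapezoidal AUC equals the two-sample U statistic divided by
`n_pos · n_neg` (asserted to 1e-9 in the tests). `benchmark` runs a
folds × methods grid on shared-seed screens; its desk-scale default is
30 × 30 × 4 with 25 spikes and block size 15 (so the split model is a
genuine split at that scale), which keeps a full 4-fold × 3-method grid
in the tens of seconds while reproducing the qualitative orderings —
AUC(0.5) > AUC(0.7), AUC(1.5) > AUC(1.3), all methods comparable.

## Numerical and testing notes

* Sparse normal equations make the 100×100×4 full linear model run in a
  few seconds; the null-calibration and concordance checks in the test
  suite therefore run at the scale they are stated for (50×50×4 and
  100×100×4).
* Kolmogorov–Smirnov uniformity assertions are made only at sample sizes
  where the bound discriminates: with n p-values the KS statistic of
  perfectly uniform samples concentrates around `0.8/√n`, so a 0.05
  bound is meaningful at n = 2500 (floor ≈ 0.017) but a coin flip at
  n = 400.
* Ties: Spearman uses average ranks; Mann–Whitney uses midranks with
  tie-corrected variance; the bottom-signal filter and sorting are
  stable, with missing values last.
* Degenerate inputs: empty files, single-level axes, all-removed
  prefilter cutoffs, zero medians, empty plot geometries and empty truth
  sets all raise descriptive errors rather than propagating NaN.
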