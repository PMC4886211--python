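# Methods

This note documents the models, algorithms and design choices behind
`fermlink`, in the order the pipeline runs them.

## Preprocessing

Counts are converted to relative abundance per sample; the top 100
genera per kingdom are kept, ranked by row sum of the *full* relative
table (ties broken lexicographically by genus id so selection is
platform-independent).  Flavour rows are min-max normalized to [0, 1];
constant rows become zeros, are flagged, and never enter correlation
edges.  Pearson correlation is invariant to per-row increasing affine
maps, so the network stage gives identical results on raw and
normalized flavours (tested).

For the two-block fit the default abundance transform is the centered
log-ratio (CLR) of the counts, `log(x + 0.5)` minus the per-sample mean
of logs.  Compositional counts arise (in the generator, and to first
order in reality) from a softmax of latent log-abundances; the CLR
inverts that map exactly up to the per-sample closure constant, so
linear latent structure is estimated linearly.  Relative abundance is
available instead via `x_transform: relative`; the association network
always uses relative abundance, which is what the thresholded-|ρ|
tradition expects.

## O2PLS

Given column-centered (optionally unit-variance scaled) blocks `X`
(n × p) and `Y` (n × q):

1. `W` (p × K) and `C` (q × K) are the leading left/right singular
   vectors of `X'Y`.  Sign convention: the largest-|entry| of each `W`
   column is positive, `C` flips jointly — predictions are invariant.
2. X-orthogonal filtering, `nx` rounds: with `T = XW`, the dominant
   left singular vector of `(X − TW')'T` is an orthogonal weight; its
   score `t_o = X w_o` and loading `p_o = X't_o / t_o't_o` are deflated
   from `X`.  Symmetric procedure on `Y` for `ny` rounds.  One pass, no
   iteration to convergence; X side first.
3. On the filtered blocks, `T = XW`, `U = YC`,
   `B = (T'T)⁻¹ T'U`, and the predicted flavour block is
   `Ŷ = T B C'`.

Diagnostics: `R²Y(cum) = 1 − ‖Y − Ŷ‖²/‖Y‖²` on the centered (scaled)
original `Y`, joint components only; `R²X(cum)` uses the X
reconstruction including the X-orthogonal part.  `VIP` over the
predictive components is

```
VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),
```

with `SSY_a = ‖t_a‖² ‖B_a C'‖²` the flavour sum of squares carried by
component a's rank-one contribution; `mean(VIP²) = 1` identically.

**Cross-validation.**  Seven-fold, deterministic interleaved assignment
(sample i → fold `i mod 7` in batch-then-day order), so folds stripe
the time series.  Each fold refits (including centering/scaling and
orthogonal filtering), predicts the held-out rows in raw units, and
`Q²(cum) = 1 − PRESS/SS` with `SS` the total centered sum of squares of
`Y`.  Per-component Q² is the increment `Q²(1..a) − Q²(1..a−1)` on
nested sub-models.  PRESS is accumulated in raw units; with min-max
normalized `Y` (the pipeline default) all columns are on comparable
scales, so this matches a scaled-workspace Q² up to column-range
ratios.  Component selection is greedy forward: grow K while the
incremental Q² exceeds the limit (0.05 by default), then grow nx and ny
while cumulative Q² improves by more than the limit; if even the first
component fails, K = 1 is returned with a warning.  One-sample test
folds are legal (leave-one-out works); an error is raised only when a
training split is too small to fit.

The estimator is a projection method, not least squares: for a generic
full-rank `X` and exact linear `Y = XB₀`, the SVD weights tilt with the
sampling covariance of `X` and Q² saturates a few percent below 1.  In
the noise-free limit of the latent model itself (`X` of exact rank K)
the estimator is exact and Q² = 1; tests exercise that limit.

## Association network and core selection

Pearson ρ for every genus–flavour pair across samples (Spearman behind
a flag); constant profiles are flagged and produce no edges.  Edges
require `|ρ|` strictly above the threshold — 0.7 for the network view,
0.8 for the "high" set used downstream — and strictness matters at the
boundary (a pair at exactly 0.8 is out).  No multiple-testing
correction by default, mirroring the thresholded-|ρ| convention.

Core criteria (all must hold): prevalence ≥ 0.9 (fraction of
fermentation samples with non-zero abundance — the operationalization of
"detected stably", which the tradition leaves qualitative; raw-material
reference samples, marked by negative day, are excluded), membership in
all three flavour sets {OA, AA, VF} at the high threshold (sugars are
tracked separately and excluded from the Venn logic), `VIP > 1.55`, and
strictly more than 25 highly correlated flavours.  The report stores
every intermediate so the core set is recomputable from it.

## Stage statistics

* **Hellinger distance** between samples:
  Euclidean distance of per-sample square-rooted relative abundances;
  bounded by √2.
* **PCA** via SVD of the centered matrix (flavour block); **PCoA**
  (double-centered Gram form) for distance input, since the distance
  matrix has no feature loadings.  Both use the positive-loading sign
  convention.  The correlation-scaled biplot reports
  `p(corr)_{j,a} = corr(feature_j, t_a)` and scores divided by the
  largest two-component observation radius, so features lie in the unit
  circle and observations in the unit disk.
* **Ward HCA** through SciPy's Lance–Williams implementation on the
  Euclidean (or precomputed) distances, heights on the distance scale;
  trees export to Newick.  Tie-breaking follows SciPy's deterministic
  nearest-neighbor-chain order.
* **AMOVA**: `SS_total = Σ_{i<j} d²_{ij}/n`, `SS_within` the per-group
  analogue, `Fs = (SS_among/(k−1))/(SS_within/(n−k))`.  The p-value
  permutes group labels — Monte-Carlo with the +1 correction
  `p = (1 + #{Fs* ≥ Fs})/(1 + B)` (default B = 10,000; p is never 0),
  or exhaustive enumeration over all distinct labelings when requested
  (identity included, no correction).  The statistic coincides with the
  PERMANOVA pseudo-F, which the tests exploit as an independent oracle.
* **Spearman drivers**: rank correlation (average ranks on ties) of the
  first ordination axis with titratable acidity, alcohol and
  temperature.

## Synthetic data: what it emulates, and what it does not

The generator plants a two-component joint structure shaped like a real
AAF run.  Joint score 1 is a late logistic rise (midpoint day 9.5,
slope 1.5 days) — the acidification-driven succession that separates
mid from late fermentation; joint score 2 is a mid-fermentation hump
(center ~day 7, width 3.5 days), orthogonalized against score 1.
Scores are shared across the three batches up to seeded batch-level
offsets (sd 0.05) and smaller per-sample jitter, then scaled to maximum
amplitudes (4.3, 3.6) — bounded amplitudes keep the softmax rendering
out of saturation.  The X-orthogonal component is a seeded Gaussian
draw orthogonalized against the joint scores.  The Y-orthogonal
component is a *raw-material signature*: an exponential decay after day
0 loading on the sugars (strongly) and on part of the flavour panel,
representing substrate compounds present before fermentation — flavour
variation deliberately not shared with the microbial block, which is
exactly the structured noise O2PLS's Y-orthogonal filter exists to
remove.

Loadings: the seven core rows of `W` carry one dominant entry each
(scale 5, split 4/3 across the two components); the other 193 rows are
sparse bounded-uniform.  Columns are constructed sum-to-zero — this
makes the softmax invertible by CLR — and unit-normalized, and the
generator *verifies* that core rows are the top rows by norm, raising a
planted-truth violation otherwise.  Every flavour category is split
~60/40 across the two joint components so each component's flavour set
spans organic acids, amino acids and volatiles (required for the
shared-membership criterion to be attainable by all cores).  Counts are
rendered softmax → multinomial at depth 50,000 — the simplest
compositional model preserving the latent correlation structure;
concentrations are shifted non-negative.  Metadata: titratable acidity
rises and alcohol falls as logistic functions of day plus noise;
temperature is uncorrelated by construction.  Stage truth is day 0 |
days 1–9 | days 10–18.

With these defaults (verified over 20 seeds): the fitted joint
X-subspace lies within 5° of truth, cross-validation selects K = 2,
every core genus exceeds 26 highly correlated flavours while core VIPs
(~3–4) and non-core VIPs (< 1.1) are cleanly separated, and the
four-criterion selector returns exactly the planted core.

**Limits of realism.**  No taxonomic structure beyond kingdom labels,
no mechanistic kinetics, no zero inflation or overdispersion beyond
multinomial sampling, uniform expected abundance across taxa (no
log-normal rank-abundance curve), Gaussian flavour noise.  Passing the
recovery tests shows the chain is correct and well-calibrated on data
satisfying its own model; it does not certify performance on real
amplicon data, where compositional effects, rare-taxon dropout and
nonlinear responses are harsher.

**Stage-recovery caveat.**  At the full defaults the flavour block's
hump component creates within-stage-II spread larger than the
separation of the three day-0 samples, and Ward's size-weighted merges
then cut at the hump walls rather than isolating day 0 (Rand ≈ 0.8
against the planted partition).  This is a property of the planted
geometry, not of the clustering code; the stage-recovery test therefore
uses a crisply staged configuration (`stage_sharpness=0.5`, secondary
amplitude 0.05), where Ward recovers the planted partition
(Rand ≥ 0.9), and the acidity-driver test weakens the hump
(`score_scales=(4.3, 1.2)`) so the first ordination axis is the
monotone succession; both configurations are exposed as ordinary
generator parameters.

## Numerical choices

* SVD-based estimation throughout; no iterative NIPALS, no missing-value
  handling (missing cells are an input error).
* Degenerate guards: zero cross-covariance ("no joint variation"),
  rank-deficient joint Gram matrix (advises smaller K), zero-sum
  samples, constant profiles (flagged, correlation treated as 0).
* Strict inequalities at every threshold, after the "greater than"
  convention of the criteria.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; the pipeline manifest records the seed, config
  hash and per-stage summaries, and rerunning a config byte-reproduces
  the manifest.
* Problem sizes in tests and in `scripts/acceptance.py` follow the
  study design (n = 57, p = 200, q = 88, 20 replicate seeds); the AMOVA
  calibration uses 1,000 null replicates at 199 permutations each,
  which gives the +1-corrected p-value exact resolution at α = 0.05.
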