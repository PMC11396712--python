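# Methods

`plexcompo` implements the statistical core of a multiplex-immunohistochemistry
(mIHC) cell-composition study: per-marker positivity gating by finite mixture
models, composite phenotyping, compositional summaries, and the
community-ecology style inference used to compare disease subtypes
(Bray–Curtis / NMDS / PERMANOVA / SIMPER / CLR-ANOVA / Fisher), plus a
simplified differential-expression screen for targeted count panels.
Because per-cell segmentation exports for such studies are typically only
available on request, the package ships a synthetic-cohort generator with
known ground truth; every stage is validated against that truth.

## Synthetic cohort generator

The generator emulates the output of nuclear/cytoplasm segmentation on
Opal-stained sections: one row per cell with mean intensities for each
marker of one of two antibody panels (T-cell panel: CD8, FoxP3, IL17A,
GranzymeB, PanCK, CD4; macrophage panel: pSTAT1, MPO, cMaf, PanCK, CD68).

* **Cell types and mixing proportions.** Eleven mutually exclusive cell
  types (CD4 T, CD8 T, Treg, Granzyme B+, IL17A+/Tc17, keratinocyte,
  CD68-only macrophage, M1, M2, neutrophil, other). Default per-subtype
  targets are the published dermal percentages for classical, genital and
  oral lichen planus, lichen planopilaris and non-diseased control skin;
  the total-macrophage pool is split into M1, M2 and a CD68-only remainder
  so every cell has exactly one type, and each column is renormalized to
  sum to 1 (printed columns sum to ~100.0–100.1).
* **Between-sample variability.** Each sample's true composition is a
  Dirichlet draw centered on its subtype target with concentration 200
  (per-category SD ≈ √(p(1−p)/201), e.g. ±3.2 pp for a 30% category) —
  visibly scattered replicates without degenerate zeros. Categories with a
  target of exactly 0 (e.g. CD4 T in control skin) stay structurally 0.
  The published study reports no per-sample scatter, so the concentration
  is a package default, chosen once. Concentration ∞ gives the target
  exactly.
* **Intensities.** Each marker has a two-component model; a cell draws
  from the positive component when its true type's signature includes the
  marker. Defaults are log-normal components (meanlog 0.0 / 2.2, sdlog
  0.4 for both) — ~5.5 pooled SDs apart on the log scale, typical of a
  clean, well-titrated stain. Normal and Weibull families are available to
  exercise all three fit families.
* **Compartments.** A two-level dermis/epidermis label: keratinocytes are
  80% epidermal, all other types 20% (both configurable). Real sections
  have spatial structure; this label only supports stratified counting.
* **Counts.** The expression stand-in draws negative-binomial counts
  (var = μ + φμ², default φ = 0.05) for 400 genes including 20
  housekeeping genes (log-normal baselines, tighter and higher for
  housekeeping), with log2 fold changes planted into the non-reference
  group. Housekeeping genes never carry planted effects.
* **Per-sample cell counts** are not reported in the source study; the
  default of 5 samples × 2000 cells per subtype and panel is an invented,
  documented choice sized so pooled subtype compositions carry ≲0.5 pp of
  counting noise.

What the generator deliberately omits: spatial coordinates and neighbor
structure, autofluorescence and channel crosstalk, segmentation errors
(doublets, split nuclei), slide-to-slide staining shifts (intensities are
i.i.d. given the type), and zero-inflated marker dropout. Passing tests
therefore demonstrate correctness of the statistical machinery under a
well-specified bimodal-intensity model, not robustness to those artifacts.

## Gating

For each marker the per-cell intensities are fitted with a two-component
mixture by EM (families: normal; log-normal, fitted as a normal mixture of
log intensities with the Jacobian folded into likelihoods; Weibull, with a
numeric weighted-MLE M-step solved by bracketed root finding on the shape).
Implementation details:

* **Initialization and restarts.** Three deterministic restarts: a
  percentile-seeded 1-D k-means split, and hard splits at the 90th and
  99th percentiles. The tail splits matter: 2-means on one dimension
  minimizes within-cluster variance and therefore always cuts the bulk,
  so it can never seed a ~1%-weight positive population (Granzyme B, M1).
  The best restart by log-likelihood wins. EM runs to |Δloglik| < 1e-8 or
  500 iterations; the log-likelihood history is recorded and is
  non-decreasing by construction.
* **Degeneracy.** A collapsing scale (< 1e-6 of the data scale) or vanishing
  component weight raises an explicit fit failure; if all restarts of all
  requested families fail, gating reports the error rather than guessing.
  A fit is flagged `low_separation` when the component means differ by
  less than 0.1 pooled SD **or** when two components are not decisively
  better than one (BIC margin 10) — the signature of a marker with no
  positive population.
* **Family selection** is by minimum BIC (5 free parameters per
  two-component fit); ties break in the order normal < lognormal < weibull.
* **asinh transform.** `asinh(x / cofactor)` (cofactor default 1) is a
  candidate preprocessing step, not a default: raw-scale and asinh-scale
  fits are both attempted and compared by BIC mapped to the original
  intensity scale through the transform's Jacobian, because a skewness
  rule would force the transform on every log-normal marker and measurably
  degrade the fit. asinh is also the fallback whenever no family fits the
  raw values (e.g. zero or negative intensities with positive-support
  families).
* **Calls.** A cell is positive when its posterior probability of the
  higher-mean component strictly exceeds 0.95 (a posterior of exactly 0.95
  is negative). The one-sided threshold trades false positives for misses:
  at 5.5 SD separation the miss rate among true positives is ~2–3% while
  false positives are ~0; at exactly 4 SD separation even the Bayes rule
  has 2.3% error per component, so the package's ≥98% call-accuracy
  guarantee applies to markers separated by ≳5 pooled SDs.
* **Pooling.** Fits are per marker per sample by default (robust to
  slide-to-slide staining variation); a cohort-pooled mode fits each
  marker once across all cells and is what the analysis drivers use, since
  the generator has no slide effects and pooling maximizes the cells
  available to rare components.
* **Phenotypes.** Panel rules are an explicit priority list; the first
  rule whose required markers are all positive wins, all-negative cells
  are "other". T-cell panel: Treg (FoxP3+) → IL17A+ → GranzymeB+ → CD8 T →
  CD4 T → keratinocyte; the hierarchy makes categories mutually exclusive
  and FoxP3 dominance keeps CD4+FoxP3+ cells as Tregs (a CD4
  co-requirement for Tregs is configurable but off by default). Macrophage
  panel: M1 (CD68+pSTAT1+) and M2 (CD68+cMaf+) at equal priority with the
  tie broken by the higher posterior of the distinguishing marker, then
  CD68-only macrophage → neutrophil → keratinocyte.

## Compositions

Percentages are counts over all cells of a stratum (sample or subtype ×
compartment), "other" included, rows summing to 100. Pooling a subtype is
cell-weighted — cells are concatenated and then counted — which differs
from averaging per-sample percentages when sample sizes differ. Derived
rows: Total T cells = CD4 T + CD8 T + Treg + GranzymeB+ + IL17A+; Total
macrophages = CD68-only + M1 + M2 (M1/M2 stay reported as sub-fractions of
all cells). Summaries print at 3 significant figures.

**Panel merging.** The two panels are stained on serial sections, so each
panel sees only its own cell types and bins everything else as "other"
(macrophages are "other" to the T-cell panel and vice versa). Naively
averaging the two "other" bins would double-count: e.g. at the classical-LP
composition the T-lineage total would land ~11 pp below truth after
renormalization. The merge rule therefore takes each named category from
its home panel, averages keratinocyte (visible on both) with cell-count
weights, and defines "other" as the remainder 100 − Σ(named) −
keratinocyte, clipped at 0 and renormalized. With a shared ground truth
this recovers the full composition exactly; with independent section
sampling and gating noise the residual error is ≲1–2 pp per category at
the default cohort size. How the original study combined its two panels is
not documented; this rule is the package's own and the remainder
construction means "other" absorbs the named categories' estimation noise.

## Compositional inference

All permutation machinery is written in the package and vectorized over
permutations; p-values use the +1 correction
p = (#{stat ≥ stat_obs} + 1)/(n_perm + 1), so p ≥ 1/(n_perm+1) and is never
0. Comparisons against the observed statistic allow 1e-9 relative slack so
permutations that are exact relabelings of the observed grouping count as
ties rather than falling to floating-point noise.

* **Bray–Curtis**: Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ) on percentage compositions (counts
  and percentages give the same value up to the shared normalization).
* **PERMANOVA**: pseudo-F = (SS_A/(g−1))/(SS_W/(n−g)) with
  SS_T = (1/n)Σ_{i<j}d²ᵢⱼ and SS_W = Σ_g (1/n_g)Σ_{i<j∈g}d²ᵢⱼ; seeded
  label permutations, default 9999. Pairwise tests restrict the distance
  matrix to each subtype pair and report raw (unadjusted) p-values, with
  per-pair child seeds spawned from the master seed. Groups of size 1 are
  rejected (no within-group distances).
* **SIMPER**: the contribution of category i is the mean over all
  cross-group sample pairs of |x_ai − x_bi|/Σ_k(x_ak + x_bk); contributions
  sum to the mean between-group Bray–Curtis exactly (identity tested to
  1e-10), and percentages are of that total. The p-value permutes group
  labels (default 999) and asks how often a permuted contribution reaches
  the observed one.
* **NMDS**: Kruskal stress-1 minimized by alternating isotonic
  (pool-adjacent-violators) regression of configuration distances on
  dissimilarity ranks — primary treatment of ties, implemented by ordering
  tied blocks by current distance — with a Guttman/SMACOF update;
  disparities rescaled each iteration to Σd̂² = Σd². Initialization is
  classical (Torgerson) metric scaling; restarts 2–20 jitter it with
  seeded noise, best final stress wins. Stress history is recorded and
  non-increasing within a run (tolerance 1e-8).
* **CLR**: ln(xᵢ/g(x)) after closing to proportions; zeros are replaced
  multiplicatively with δ = half the smallest nonzero proportion of the
  matrix (capped at 0.5/#zeros so replaced rows stay positive). Output
  sums to 0 by construction.
* **CLR-ANOVA**: one-way fixed-effects ANOVA per CLR column
  (scipy's F test); zero within-group variance with unequal means is
  reported with the F → ∞, p = 0 convention and flagged.
* **Fisher**: 2×2 tables exactly, by point-probability summation over the
  hypergeometric support (matches the classical two-sided convention to
  1e-12); r×c tables by seeded Monte-Carlo over tables with the observed
  margins (row-wise multivariate hypergeometric sampling, fully vectorized
  for two-row tables), counting tables at most as probable as the observed
  one, default 10⁵ draws.

## Differential-expression screen

An explicitly simplified stand-in for proprietary panel pipelines, so the
workflow is runnable end to end: per-sample scale factors from housekeeping
geometric means (cohort geometric mean of per-sample geometric means over
the sample's own; +0.5 pseudocount on housekeeping zeros, logged), Welch
t-tests on log2(x+1) normalized counts (the simplest defensible model for
~10-per-group targeted panels; swappable), Benjamini–Hochberg step-up
adjustment (via statsmodels, property-tested against the brute-force
definition), and significance = |fold change| ≥ 1.5 AND adjusted p ≤ 0.05,
both inclusive; fold changes below 1 are reported as negative reciprocals.
Known bias: the +1 pseudocount shrinks estimated |log2FC| for
down-regulated or low-count genes (a planted −1.5 typically estimates
around −1.1 at the default dispersion). Heatmap column ordering uses
average-linkage clustering of 1 − Pearson distances, with distance 1 to a
constant column by convention. Background subtraction with negative-control
probes and pathway/gene-set scoring are out of scope.

## Problem sizes and numerical choices

Default analysis scale: 5 subtypes × 5 samples × 2000 cells × 2 panels
(100k cells), 9999 permutations for PERMANOVA, 999 for SIMPER, 20 NMDS
restarts, 2×10⁴–10⁵ Monte-Carlo draws for r×c Fisher tests; the whole
chain runs in a few minutes on one core. The analysis drivers and the
reproduction script restrict mixture families to normal/log-normal: the
Weibull M-step solves a root per EM iteration and is reserved for the
moderate-n unit tests, and the generator's intensities are log-normal, so
nothing is lost at cohort scale. Tie-breaks are deterministic everywhere
(family order in BIC ties, declaration order in phenotype-rule ties at
equal posterior); every stochastic routine takes an explicit integer seed
and identical seeds reproduce outputs byte for byte.

## Known limitations

* Gating assumes exactly two components per marker; autofluorescent
  subpopulations or k > 2 structure are out of scope.
* The ≥98% positivity-accuracy guarantee holds for well-separated markers
  (≳5 pooled SDs); near 4 SDs the 0.95-posterior rule under-calls
  positives by design.
* The panel-merge "other" category absorbs estimation noise from all named
  categories.
* Synthetic validation does not cover segmentation artifacts or spatial
  effects (see generator caveats above).
* Real published effect sizes from the motivating study (specific
  fold changes, PERMANOVA p-values on patient data) are not reproduction
  targets: the underlying per-cell and expression data are not deposited.
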