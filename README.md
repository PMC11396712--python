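# plexcompo

Cell-phenotyping and compositional statistics for multiplex
immunohistochemistry (mIHC), built as a reproducible analysis pipeline on
synthetic cohorts with known ground truth.

Studies that compare inflammatory-disease subtypes by mIHC typically:
segment cells and export per-cell mean marker intensities; call each cell
positive/negative per marker from a two-component mixture fitted to the
intensity histogram; combine calls into composite phenotypes (Treg, Tc17,
M1/M2 macrophage, keratinocyte, ...); and compare per-sample cell-type
compositions between groups with community-ecology machinery. `plexcompo`
implements that whole chain for a two-panel lichen-planus-style design
(T-cell panel: CD8, FoxP3, IL17A, GranzymeB, PanCK, CD4; macrophage panel:
pSTAT1, MPO, cMaf, PanCK, CD68), and — because such per-cell exports are
rarely deposited — a synthetic-cohort generator parameterized by published
subtype compositions, so every stage is testable against ground truth.

## The statistics at the core

* **Gating** — per marker, a 2-component mixture f(x) = w⁻f⁻(x) + w⁺f⁺(x)
  (normal, log-normal or Weibull; chosen by BIC; EM with restarts) and the
  call rule P(positive | x) = w⁺f⁺(x) / (w⁻f⁻(x) + w⁺f⁺(x)) > 0.95.
* **Compositions** — percentages over mutually exclusive phenotypes per
  sample × compartment; cell-weighted pooling per subtype; two-panel merge.
* **Between-group inference** — Bray–Curtis dissimilarity
  d(a,b) = Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ); NMDS (Kruskal stress-1, isotonic + SMACOF);
  PERMANOVA pseudo-F with seeded label permutations (overall and pairwise);
  SIMPER decomposition of mean between-group dissimilarity into per-type
  contributions; per-type ANOVA after the centered log-ratio transform
  clr(x)ᵢ = ln(xᵢ/g(x)); Fisher's exact test on pooled compositions
  (exact 2×2, Monte-Carlo r×c with fixed margins).
* **Expression screen** — housekeeping geometric-mean normalization, Welch
  t on log2(x+1), Benjamini–Hochberg, significance at |FC| ≥ 1.5 and
  adjusted p ≤ 0.05.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The analysis is a sequence of numbered drivers; each reads/writes under
`results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1      # cells + counts + truth
python analysis/02_gate_phenotypes.py --seed 1      # mixture gating
python analysis/03_compositions.py                  # compositions + summary
python analysis/04_ordination.py --seed 1           # BC / NMDS / PERMANOVA / SIMPER
python analysis/05_clr_anova_fisher.py --seed 1     # CLR-ANOVA + Fisher
python analysis/06_de_screen.py                     # DE screen
```

With seed 1, gating recovers per-marker positivity at 99.3–99.98% accuracy,
and the pooled merged composition tracks the generator truth to within
~1.8 percentage points in every category, e.g. (from
`analysis/03_compositions.py`):

```
subtype              NDC  classical  genital   oral  planopilaris
Treg                2.34      29.20    14.50  39.90          3.93
keratinocyte       61.40      26.50    24.60  23.20         52.90
Total T cells       3.73      48.60    24.70  53.60          6.90
Total macrophages   0.23       9.77     8.96   9.91          3.64
```

(compare the simulation targets: classical Tregs 30.3%, Total T cells
48.8%; control keratinocytes 62.1%). The ordination step then reports

```
PERMANOVA overall: pseudo-F = 89.39, p = 0.001 (999 permutations)
NMDS: stress = 0.0309, converged = True
SIMPER classical vs NDC (top): keratinocyte 31.9%, Treg 24.6%, other 18.1%
```

i.e. the subtype compositions separate decisively (p at the permutation
floor), the 2-D embedding is faithful (stress ≈ 0.03), and the
classical-vs-control dissimilarity is driven by keratinocyte dilution and
Treg infiltration — exactly what was planted. The DE screen flags the 3
planted genes out of 380 with 0 false positives.

Library use mirrors the scripts:

```python
from plexcompo import synthetic, pipeline

cfg = synthetic.default_cohort_config(samples_per_subtype=5,
                                      cells_per_sample=2000, seed=1)
result = pipeline.run_cohort_pipeline(cfg, seed=1)
print(result.merged_pooled.round(2))
```

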