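# muscleomics

Statistics for two-group muscle multi-omics contrasts: label-free
**spectral-count differential proteomics** via the Rsc log-ratio statistic,
**Fisher over-representation analysis** of the resulting protein sets, and a
**targeted amino-acid / acylcarnitine metabolomics** chain (log10 + Pareto
preprocessing, PLS-DA with VIP scores, normality-gated univariate testing,
volcano classification, Euclidean hierarchical clustering).

The package is aimed at proteomics/metabolomics analysts working with pooled
gel-lane spectral-count designs — one pooled sample per group, e.g. trained
vs untrained muscle biopsies — and small targeted metabolite panels
(n ≈ 9 per group, ~50 analytes). Every stage ships with a synthetic-data
generator carrying planted ground truth, so the whole chain is testable
without any external download.

## The statistics

**Rsc.** With spectral counts `n1`, `n2` for a protein in the two lanes and
lane totals `t1`, `t2`, the log2 abundance ratio is

```
Rsc = log2((n2 + f)/(n1 + f)) + log2((t1 − n1 + f)/(t2 − n2 + f))
```

with correction factor `f = 0.5` keeping the statistic finite at zero
counts. The contrast is oriented so positive Rsc means higher abundance in
the focus (numerator) group. Proteins with `Rsc ≥ 1.40` or `≤ −1.40` are
called over-/underexpressed (boundaries inclusive). Identifications enter
quantitation only with ≥ 2 assigned peptides, each scoring > 19.

**ORA.** For a query set of k term members out of n, against a background of
N containing K, the one-sided Fisher (hypergeometric upper-tail) p-value is
computed per term and adjusted by Benjamini–Hochberg FDR.

**PLS-DA / VIP.** NIPALS PLS1 against a ±1 group coding on the
log10-transformed, Pareto-scaled panel. Variable importance in projection:

```
VIP_j = sqrt( p · Σ_a w_ja² · SSY_a / Σ_a SSY_a )
```

(p variables, unit-norm weights w, SSY_a the Y-variance explained by
component a), normalized so mean(VIP²) = 1; metabolites with VIP > 1.5 are
reported as discriminant. Univariate testing uses Welch's t when both groups
pass the D'Agostino–Pearson normality test and a two-sided Mann–Whitney
(exact for small tie-free samples) otherwise.

## Worked example

```python
from muscleomics import (ProteomeSimConfig, SpectralCountContrast,
                         MetaboSimConfig, simulate_metabolite_panel, PLSDA)
from muscleomics.simulate import simulate_identifications

# pooled proteome: 500 proteins, 10% planted up / 10% down at log2FC = 2
ids, truth = simulate_identifications(ProteomeSimConfig(n_proteins=500, seed=1))
res = SpectralCountContrast.from_dataframe(ids, focus="VPG", reference="CG").fit()
print(res.summary_text())

panel, _ = simulate_metabolite_panel(MetaboSimConfig(
    planted_effects={"Orn": 1.0, "Cit": -1.0, "C16": -1.0}, seed=1))
print(PLSDA.from_panel(panel).fit().summary_text())
```

prints

```
Spectral-count contrast: VPG (focus) vs CG (reference)
  proteins quantified : 500
  f = 0.5, |Rsc| threshold = 1.4, filter: peptides >= 2, score > 19.0
  over  (Rsc >= 1.4)  : 43
  under (Rsc <= -1.4) : 55
  unchanged                 : 402

PLS-DA: VPG (+1) vs CG (-1), 18 samples x 50 variables
  component 1: explained Y variance 91.6%  (X variance 16.5%)
  component 2: explained Y variance 6.3%  (X variance 7.7%)
  top VIP: Orn=3.25, C16=3.20, Cit=3.15, Val=1.40, C14=1.27
```

Of the 98 differential calls, 85 are planted proteins (the planted effect
here is log2FC = 2, close to the 1.40 threshold; the remaining calls are
nulls dragged across it by the compositional shift discussed in
`docs/methods.md`). The PLS-DA isolates the three planted metabolites as
the top VIP scores, far above the 1.5 cutoff.

The same chains are scriptable from the shell:

```
muscleomics simulate proteome --out sim --seed 1
muscleomics proteomics --in sim/identifications.tsv --out results
muscleomics metabolomics --panel panel.tsv --groups groups.tsv --out results
muscleomics run-all --config pipeline.yaml
```

A packaged reference table of published per-protein Rsc values
(`muscleomics.load_reference_rsc_table()`) classifies to 92 overexpressed +
96 underexpressed = 188 differential proteins at the default threshold.

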