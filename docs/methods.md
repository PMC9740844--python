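# Methods

## Spectral-count contrast (Rsc)

The proteomics stage models a pooled two-group design: all subjects of a
group are pooled into one gel lane, so each group contributes a single
vector of spectral counts (SpC) and a lane total. The per-protein statistic

    Rsc = log2((n2 + f)/(n1 + f)) + log2((t1 − n1 + f)/(t2 − n2 + f))

is a shrunken log2 ratio of count proportions: the additive correction
`f` (default 0.5) acts like a half-count pseudo-observation, removing the
discontinuity at SpC = 0 and shrinking low-count ratios toward zero; the
second term adjusts for unequal lane depth. Orientation is a genuine
ambiguity in the field's notation (the symbol `n2` leads the numerator while
prose conventions often name the focus group "sample 1"); this package makes
the contrast explicit — `SpectralCountContrast(focus=..., reference=...)` —
and guarantees positive Rsc = higher in `focus`. Antisymmetry under lane
swap and exact zero for proportion-matched lanes are tested properties.

Identification acceptance (≥ 2 assigned peptides, weakest counted peptide
scoring strictly > 19) is applied *before* lane totals are computed, so only
quantifiable proteins define sequencing depth. Classification uses inclusive
boundaries at |Rsc| = 1.40 (≈ 2.6-fold). All four constants (`f`, threshold,
peptide floor, score floor) are configuration keys defaulting to these
values.

Known limitation — compositionality. Spectral counting observes
*proportions* of lane totals, not absolute amounts. If differential mass is
unbalanced between lanes (e.g. strongly upregulated proteins add ~60% more
total abundance to one lane), every unchanged protein's proportion shrinks
in that lane and acquires a nonzero expected Rsc of −log2(mass ratio). The
synthetic recovery experiment makes this visible: with 10% of proteins
planted up and 10% down at log2FC = 3 applied one-sidedly, null proteins
shift by ≈ −0.65 log2 units and ~5–10% of them cross the −1.40 threshold.
This is a property of the statistic under unbalanced perturbations, not of
the implementation; real designs with approximately mass-balanced changes do
not show it (the no-effect noise floor is ≈ 1% differential calls at these
depths).

## Over-representation analysis

One-sided (enrichment-only) Fisher exact p per term, i.e. the hypergeometric
upper tail P(X ≥ k) on the 2×2 table, matching how functional-annotation
servers test GO terms. Choices:

* **Background** defaults to the filtered identification universe, not the
  genome: with spectral-count data, only identifiable proteins could ever
  appear in a query, and a genome background would inflate significance.
* **Degenerate terms** with fewer than 2 background members are skipped
  (configurable) — a single-member term can only produce p = K/N trivia.
* The **EASE variant** (discounting one hit, k−1) is available as a flag but
  off by default; plain Fisher is the documented default.
* **FDR** is Benjamini–Hochberg step-up; gating may use raw p ≤ 0.05 or
  FDR ≤ 0.05 (both inclusive), selected by `mode`.

## Metabolite-panel chain

Concentration matrices (metabolite × sample, already normalized to total
protein) must be strictly positive. Preprocessing is log10 followed by
Pareto scaling — centering and division by the square root of the sample
standard deviation (ddof = 1) — the usual compromise between unit-variance
scaling (which inflates noise variables) and no scaling (which lets abundant
metabolites dominate). Constant variables pass through centered-only with a
warning.

**PLS-DA** is NIPALS PLS1 against a centered ±1 group coding: per component,
weight w ∝ Xᵀy (unit norm), scores t = Xw, X- and y-loadings by regression
on t, then deflation. Explained Y-variance per component is q²·tᵀt over the
initial Σy², reported as a fraction (printed as percent). Rank deficiency
truncates the requested components with a warning. **VIP** follows the
weighted-sum-of-squares definition; mean(VIP²) = 1 by construction, so the
conventional cutoffs VIP > 1.0 ("above average importance") and > 1.5
(strongly discriminant, the default here) are both meaningful; the cutoff is
strictly exclusive and configurable.

**Univariate testing** operates on raw (untransformed) concentrations —
mirroring how bench statistics packages test the analyzed variable — and is
gated per metabolite: both groups are screened with the D'Agostino–Pearson
omnibus normality test; Welch's unpaired t is used only when both pass
(p > 0.05), otherwise a two-sided Mann–Whitney. The omnibus test's skewness
and kurtosis components need n ≥ 8 per group, so smaller groups fall back to
Mann–Whitney with a warning; groups under 3 are an error. Mann–Whitney is
exact when min(n) ≤ 8 with no ties and a tie/continuity-corrected normal
approximation otherwise. Fold changes are log2 ratios of raw group means;
the volcano classification gates on p ≤ 0.05 and a log2FC threshold
defaulting to 0 (significance-only), because a nonzero default cannot be
justified for panels whose meaningful effects can be small on the log scale.

**Clustering** for heatmap display ranks metabolites by univariate p, keeps
the top 40 (or all, with a warning) and clusters both axes on the
preprocessed matrix with Euclidean distances. Ward linkage is the default
(the common choice of metabolomics web suites); single/complete/average are
available, and the output (leaf orders, merge heights, ordered matrix) is
JSON-serializable so plotting is decoupled from computation. The chain is
fully deterministic — no RNG is used anywhere in this module.

## Synthetic data

The generators define the study conditions the tests exercise:

* **Proteome**: per-protein baseline abundances are log-normal with ln-scale
  sd 1.0 (heavy-tailed, keeping a tail of low-count proteins so the f = 0.5
  correction is exercised; real proteomes are, if anything, more dispersed).
  Planted effects multiply/divide *group-A* abundance by 2^log2FC. Counts
  are multinomial conditioned on the configured lane total — exactly the
  pooled single-lane design — so realized totals match configured totals.
  Defaults: 500 proteins, 20,000 spectra/lane (lane totals are rarely
  published; they are plainly configurable), 10% up / 10% down at
  log2FC = 2. Configs whose mean expected count falls below 1 are rejected
  as degenerate. Stream order: baselines, then group-A counts, then group-B
  counts, from a single seeded generator.
* **Metabolome**: a 50-analyte amino-acid/acylcarnitine panel (flow-injection
  MS/MS style nomenclature), n = 9 per group. Baselines are log-normal
  (ln-sd 1, spanning a few orders of magnitude as AA/AC panels do); each
  value is the group mean times mean-one log-normal noise with CV 0.2, a
  typical targeted-assay biological+technical spread. Planted effects are
  multiplicative on group-A means. All values are strictly positive, so the
  log10 transform is always defined.
* **Annotations**: uniform random term memberships, plus an optional planted
  term drawing each member from a designated subset with probability 0.9 —
  enough contrast that the planted term should rank first in a query
  matching the subset.

What the generators do *not* emulate: correlated metabolite blocks (real
acylcarnitines co-vary along oxidation pathways), missing values, batch or
run-order effects, peptide-level identity, or count overdispersion beyond
multinomial sampling. Passing recovery tests therefore demonstrates
correctness of the statistical chain under clean planted signal, not
performance on messy real data.

## Numerical notes

* Fisher p-values come from the vectorized hypergeometric survival function;
  tests pin them to exact integer enumeration over the full table space
  N ≤ 60 and to an independent Fisher-exact route.
* BH adjustment delegates to a standard step-up implementation and is
  oracle-tested against the direct m·p/i cumulative-minimum formula.
* PLS deflation stops when ‖Xᵀy‖ falls below 1e−12 (relative); VIP is
  undefined (error) if no Y-variance is explained.
* Classification ties at the threshold are resolved by the inclusive rule;
  enrichment result ordering breaks p ties by term id for determinism.
* Problem sizes in tests and the acceptance script (500 proteins, 20,000
  spectra/lane, n = 9/group, 1,000 BH vectors, full N ≤ 60 Fisher space)
  were chosen so the entire suite completes in well under a minute while
  estimating every rate on at least a few hundred trials.
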