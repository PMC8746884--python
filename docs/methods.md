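# Methods

This note documents the statistical procedures implemented in `gibra`, the
assumptions behind them, the choices made where a convention was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Study design assumed throughout

Four diet arms — control (n = 8), scGOS:lcFOS prebiotic (n = 10), n-3 PUFA
(n = 10), combination (n = 10) — giving 38 animals. Group comparisons are
restricted to five selected pairs: control versus each diet, and each
single diet versus the combination. Litter identifiers are generated and
carried in metadata but no litter random effect is modelled: mixed-model
behaviour statistics are outside this package's scope.

## Rarefaction and alpha diversity

Rarefaction draws an exact multivariate hypergeometric subsample (uniform,
without replacement, one draw per sample) to a common depth, default
45 000 reads; samples below depth are dropped with a warning and the seed
is recorded. Shannon diversity is reported in natural log units and Pielou
evenness as `H / ln S` (the vegan conventions); evenness is undefined (NaN,
excluded from summaries) when a sample has fewer than two observed taxa.
Group tests on diversity indices run on square-root-transformed values,
with raw values reported alongside.

All multi-group comparisons outside differential abundance use a
normality-gated test: Shapiro–Wilk per group at α = 0.05; if every group
passes, one-way ANOVA with pooled-variance pairwise t tests and Sidak
adjustment over the five selected pairs; otherwise Kruskal–Wallis with Dunn
z tests (tie-corrected) and Sidak-style adjustment with exponent equal to
the number of selected pairs. A group that is entirely constant is treated
as non-normal; a fully constant response is flagged degenerate.

## Differential abundance

Per-genus Kruskal–Wallis across the four diets on relative abundances from
the rarefied table. The "average abundance < 1%" filter is interpreted as
the grand mean of per-sample relative abundances across **all** samples
(not per group); filtered genera are flagged and never tested. Benjamini–
Hochberg step-up adjustment runs across the retained genera only, with
significance at FDR-P < 0.05 and Dunn post-hocs over the selected pairs for
significant genera.

## Beta diversity and ordination

The ordination input is the square-root-transformed genus relative-
abundance matrix (a state flag prevents the transform from being applied
twice). Bray–Curtis dissimilarities feed ANOSIM with midrank ties and the
permutation estimator `p = (1 + #{R* ≥ R}) / (1 + n_perm)`, so the smallest
attainable p at 999 permutations is 0.001. Pairwise ANOSIM runs on the
sub-matrix of each selected pair and its p-values are reported unadjusted.

Non-metric MDS is fixed at two dimensions: SMACOF iterations alternate an
isotonic (monotone) regression of configuration distances on dissimilarity
rank with a Guttman transform, minimising Kruskal stress-1
`√(Σ(d̂−e)² / Σe²)`. An update is accepted only while stress does not
increase, so the recorded stress trace is non-increasing by construction;
convergence is declared at relative stress change < 1e-6 or 300 iterations.
The best of 20 random restarts plus one classical-scaling start is kept.
Taxa vectors are Pearson correlations of each (square-root-scale) taxon
with the two axes; the combined statistic `√(r₁² + r₂²)` is thresholded at
0.6. Note the combined statistic can exceed 1 when the axes are correlated
in-sample; it is a retention score, not a correlation coefficient.

## Inferred SCFA-producer model

Producer categories are literature-derived genus lists (7 acetate, 4
propionate, 10 butyrate producers); bracketed and unbracketed Ruminococcus
are distinct Greengenes labels and are kept distinct. Matching is exact on
the whitespace-normalised terminal lineage label, with a documented alias
map for alternate spellings ("Parabacteroidetes" ↔ "Parabacteroides"); the
printed spelling remains the default key. A category's value is the plain
sum of matched genera's relative abundances × 100 — no abundance weighting
or pathway inference — computed on the rarefied composition before any
square-root transform. Valerate is grouped with the branched-chain acids
(iso-butyrate, iso-valerate) in reporting, and the total-SCFA column is
always the row sum of constituent acids.

## Recursive ensemble feature selection

Eight classifier families: Bagging, Random Forest, Gradient Boosting
(impurity-based importances), and Logistic Regression, linear-kernel
Support Vector, Stochastic Gradient Descent, Passive Aggressive, Ridge
(absolute coefficients on standardised inputs; the linear kernel is
mandated for the SVM so a coefficient ranking exists). Standardisation is
refit inside each training fold — a leakage test asserts fold-wise
behaviour against an independently coded cross-validation oracle.

Cross-validation is stratified 5-fold (shuffled per repetition seed); with
n = 38 and imbalanced labels this is less noisy than leave-one-out for ROC
estimation. Per cycle each family is ranked (importances averaged over
folds, ties broken by stable input order), the eight rankings are fused by
Borda count, and the top ⌈0.8·m⌉ features are retained. From 87 features
the 10-cycle schedule visits 87, 70, 56, 45, 36, 29, 24, 20, 16, 13, 11.
Because reported signatures can sit off this grid, an optional fine-grained
tail (`fine_tail`, default on) continues reducing by one feature per cycle
below the final grid size so any size down to 2 is visitable; this tail is
an extension of the 80% schedule, not part of it.

"Mean accuracy of all classifiers" is the unweighted mean of the eight
families' cross-validated accuracies at a feature count, averaged over
repetitions. The best signature size is the accuracy-curve maximum (ties
resolved toward the smaller signature); its members are the top features
by Borda score aggregated across repetitions at that size. The ROC family
is the one with the highest mean cross-validated accuracy on the
signature; AUC is reported as mean ± sd across repetition seeds using
cross-validated decision scores.

The direction-of-change table compares feature means between label groups
with a two-sided rank-sum test; an arrow is printed only when the test
supports the sign at α = 0.10, otherwise "-" — the no-change category such
tables contain is otherwise undefined. The open-field table uses the
flipped orientation (label 0 versus label 1).

## Synthetic-data generator

The generator produces the statistical structure the analyses assume, not
raw sequence data: no reads, chimeras or OTU clustering are simulated, and
litter covariance is generated as labels only.

* **Counts**: 60 genera over 9 phyla with a fixed long-tailed mouse-caecal
  baseline (S24-7 and Lachnospiraceae dominant). Diet effects are natural-
  log-fold shifts applied to the baseline and renormalised; the default
  planted set follows the eight differential genera and their reported
  directions (prebiotic/combination raise Allobaculum and S24-7 and deplete
  Oscillospira; fish-oil raises Turicibacter, Akkermansia, Rikenellaceae;
  the combination additionally depletes unclassified Ruminococcaceae and
  Lachnospiraceae). Shift magnitudes are ±0.7–1.0 log, with the combination
  Akkermansia bloom at +2.0 log (~7-fold, within reported prebiotic
  responses) — calibrated once so the downstream propionate contrast is
  detectable at the stated ≥ 80% rate. Per-sample compositions are
  Dirichlet-multinomial with concentration 150 (16S-typical
  overdispersion); library sizes are uniform on [45 000, 60 000] so
  rarefaction at 45 000 never drops a sample.
* **SCFA**: concentration = intercept + slope × producer-category relative
  abundance + Gaussian noise, truncated at zero (acetate 15 + 150·a ± 4,
  propionate 1 + 60·a ± 0.8, butyrate 1 + 25·a ± 1 mM/kg), giving
  concentration ranges like targeted caecal measurements and a
  producer–concentration correlation well above 0.5 at n = 38. Valerate and
  the branched-chain acids are uncoupled intercept + noise.
* **Host features**: 26 per-group Gaussian features (MLN and spleen T-cell
  percentages; monoamines in amygdala, prefrontal cortex, dorsal
  hippocampus), with small planted group shifts echoing the reported
  immune/monoamine effects, plus a Shannon-diversity feature: 60 + 26 + 1 =
  87 features.
* **Behaviour**: marbles buried ~ Binomial(20, p) with logit(p) a signed
  sum of the five standardised planted features (coefficient 1.2 each);
  centre entries ~ Poisson with the analogous log link around rate 9.5.
  Each behaviour's planted features share a per-animal latent factor
  (loading 0.7: log-fold units for genera, sd units for host features).
  Without that shared factor five independent planted features dilute each
  other and single-feature discriminability caps near AUC 0.70; the factor
  models the gut–brain covariation under which each planted feature is
  individually informative, and the loading was calibrated once so
  single-feature AUC ≈ 0.8, then frozen.

What passing tests on this generator show: the statistics are correctly
implemented, calibrated under null configurations, and powerful enough to
recover planted effects of the stated size under 16S-like noise. What they
do not show: performance on real data with litter confounding, taxa
correlation structure beyond the planted factor, compositional artefacts of
unequal sequencing depth, or measurement error in the host assays.

## Numerical and reproducibility choices

All randomness flows from one master seed through named `SeedSequence`
substreams per stage; identical configuration + seed reproduces every
artifact byte for byte (CSV floats are formatted with `%.10g`, JSON keys
sorted). Degenerate inputs are handled explicitly: all-zero count rows are
rejected, single-taxon evenness is NaN, a zero Bacteroidetes denominator
yields an infinity marker excluded from transforms, constant features are
dropped from selection with a warning, and a behaviour label with a single
class skips REFS with a warning.

Problem sizes used by the test-suite simulations are scaled to keep the
default run practical on a single core: REFS recovery runs use 2
repetitions per fit (10 seeded fits), the fine tail disabled (recovery is
judged at the 80%-grid sizes), null-calibration batches use 10–200
replicates as stated per test, and the pipeline determinism check uses a
reduced three-family REFS configuration. These sizes are the package's
defaults for its own verification; the library defaults (10 repetitions,
fine tail on) remain available for analyses.

## Known limitations

* Evenness and Shannon are computed on rarefied counts only; no coverage
  or breakaway-style richness estimation.
* ANOSIM assumes exchangeability of samples under the null; litter
  structure, if real, would inflate significance.
* The producer model is a fixed genus-list aggregation; it does not weight
  by metabolic capacity and ignores strain variation.
* The fine-grained REFS tail below the 80% grid is an extension; how the
  original procedure reached signature sizes off the grid is not
  reconstructable and our curve at those sizes should be interpreted
  accordingly.
* With 38 samples, REFS accuracy and AUC retain selection optimism despite
  cross-validation; the null-calibration test bounds, but does not remove,
  that bias.
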