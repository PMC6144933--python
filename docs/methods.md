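# Methods

## Problem and model

`ncdna` discriminates non-coding DNA (ncDNA, the positive class) from
protein-coding DNA (cDNA, the negative class) from sequence alone. The
pipeline has four stages:

1. **k-mer composition encoding.** A sequence P = R₁R₂…R_L is represented
   by the sliding-window frequencies of all 4^k k-mers,

       fᵢ = nᵢ / (L − k + 1),   i = 1, …, 4^k,  k ∈ {1, …, 6},

   in lexicographic order A < C < G < T. The six single-k encodings are the
   standard mono- through hexanucleotide compositions (MNC, DNC, TNC, TrNC,
   PNC, HNC); the combined encoding concatenates all six blocks into a
   5460-dimensional vector (4 + 16 + 64 + 256 + 1024 + 4096). Tetramer
   composition (TrNC, 256 features) is the workhorse encoding. k-mers are
   counted strand-specifically; no reverse-complement collapsing.

2. **F-score feature ranking.** Each feature is scored by

       F(i) = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / (s²ᵢ⁺ + s²ᵢ⁻),

   the squared deviations of the class means from the overall mean over the
   sum of within-class sample variances (n − 1 denominators). Larger F
   means better single-feature discrimination. The 256 tetramer scores can
   be arranged on a 16×16 grid (rows = first two bases, columns = last two)
   for heat-map display, and a ranked list drives incremental feature
   selection (nested top-n subsets, accuracy-maximizing n reported).

3. **RBF-SVM classification.** A support vector machine with kernel
   K(x, y) = exp(−γ‖x − y‖²). The penalty C and width γ are chosen by
   exhaustive grid search over the canonical powers-of-two ranges
   C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}, scored by stratified
   inner 5-fold CV accuracy; ties resolve toward smaller C, then smaller γ.
   Frequencies already live in [0, 1], so no further feature scaling is
   applied. Decision scores > 0 are labeled ncDNA; a score of exactly 0 is
   called cDNA by convention. KNN (k = 5, Euclidean), Gaussian naive Bayes,
   a 100-tree random forest and a single CART tree are available as
   baselines behind the same interface.

4. **Evaluation protocol.** Stratified 10-fold cross-validation, repeated
   5 times with reshuffled folds, metrics averaged over repeats. With N⁺,
   N⁻ the class totals and N₋⁺, N₊⁻ the cross-class errors:

       Sn  = 1 − N₋⁺/N⁺          Sp  = 1 − N₊⁻/N⁻
       Acc = 1 − (N₋⁺+N₊⁻)/(N⁺+N⁻)
       MCC = [1 − (N₋⁺/N⁺ + N₊⁻/N⁻)]
             / sqrt[(1 + (N₊⁻−N₋⁺)/N⁺)(1 + (N₋⁺−N₊⁻)/N⁻)]

   These class-total forms are algebraically identical to the textbook
   TP/TN/FP/FN definitions (MCC = phi coefficient); the test suite verifies
   the identity exhaustively over all tables with N± ≤ 12. ROC curves are
   built from pooled decision scores per repeat with tied scores grouped;
   the trapezoid AUC then equals the normalized Mann–Whitney U statistic
   (ties counted half).

## Aggregation and numerical conventions

- **Pooling rule.** Confusion counts are summed over the 10 folds of one
  repeat before computing metrics (micro-averaging), then the five
  per-repeat metric vectors are averaged. Pooled accuracy within a repeat
  therefore equals total-correct / total-tested exactly.
- **Stratification.** Folds are stratified so per-fold class ratios deviate
  from the global ratio by at most one sample; plain random folds are
  available as a toggle (`stratified=False`).
- **Ambiguous bases.** Residues outside {A, C, G, T} are kept in the record
  (I/O is lossless) but excluded at encoding time: any window containing an
  ambiguous base is skipped and the frequency denominator becomes the count
  of valid windows. For clean sequences this reduces to L − k + 1; either
  way each 4^k block sums to 1. A sequence shorter than k, or with no valid
  window, is a hard encoding error rather than a zero vector.
- **Degenerate statistics.** A feature constant within both classes gets
  F-score 0 (with a warning) so the ranking stays total; ranking ties break
  lexicographically by k-mer. An MCC with a vanishing denominator (an empty
  predicted or actual class) is defined as 0.
- **Combined encoding.** Plain concatenation of the six normalized blocks;
  each block keeps its own sum-to-one normalization and no re-weighting is
  applied across blocks.
- **Incremental selection step.** Default step 1 for feature spaces up to
  64 columns, 8 above that, with the final curve point always covering the
  full feature set so the curve end matches a plain CV run.

## Synthetic benchmark generator

Real coding/non-coding training data requires a genome download, so the
package ships a seeded generator that emulates the two-class setting:

- Sequences come from a Markov chain whose order is tied to the longest
  planted k-mer (order k − 1; order 0, i.e. i.i.d. bases, without bias).
  At each step the next-base weights start from the background composition
  (default uniform 0.25); any base completing a planted k-mer given the
  current context is up-weighted by that k-mer's enrichment factor, then
  the weights renormalize. This plants specific tetramer enrichments
  cleanly, which i.i.d. base sampling cannot.
- Lengths are uniform on 100–800 nt by default — a stand-in for the
  empirical length range of annotated non-coding elements, which
  concentrates in that window. The default scale, 300 + 300 records,
  keeps a full pipeline run in seconds.
- With all enrichment factors at 1 the two classes are statistically
  identical; this null case underpins the chance-level checks. Enrichment
  monotonicity (larger factor → larger F-score for the planted k-mer) is
  property-tested over factors 1, 2, 4, 8.

What the generator does **not** emulate: real genome base composition and
GC content, codon structure in coding sequence, repeat families, or
redundancy structure. Passing tests on synthetic data therefore demonstrate
that the machinery is correct and can recover planted signal at realistic
sample sizes — not that any particular accuracy will be achieved on real
genomes.

## Scale limitation on the real benchmark

The published accuracy figures for this task (high-90s percent accuracy on
a yeast coding/non-coding benchmark of ~6000 sequences per class) were
obtained on an Ensembl-derived, redundancy-reduced dataset that is an
external download; it is not shipped here and those values are **not
reproducible** from the synthetic fixtures and are asserted nowhere in this
package. Verifying real-data behaviour is an optional integration check for
users who download such a benchmark themselves (encode with `--k 4`, then
`ncdna cv --tune`); the package's own guarantees are the property-based
ones above: formula equivalence, encoder exactness, planted-signal
recovery, pipeline power on separated classes, chance-level behaviour on
null data, and bitwise seeded determinism.

## Problem sizes used in the shipped checks

Acceptance-style runs use the generator's default study conditions
(300 + 300 sequences, lengths 100–800 nt): planted-signal recovery plants
three tetramers at ×4 over 20 seeded replicates; the power run plants four
tetramers at ×8; the null run plants nothing. Grid searches in these runs
use a reduced grid (C ∈ {1, 8, 64, 512}, γ ∈ {0.5, 2, 8, 32, 128}, inner
3-fold) — a coarse sweep of the same powers-of-two space the full grid
covers. Unit tests use smaller fixtures (tens of records, 100–300 nt).

## Known limitations

- The generator's enrichment acts through (k−1)-order transition weights;
  overlapping planted k-mers interact (e.g. TATA and ATAT share contexts),
  so realized enrichments are approximate, not exact multipliers.
- Grid search optimizes accuracy only; no probability calibration.
- Binary classification only; no multiclass, no gapped or
  reverse-complement-collapsed k-mer variants, no PseKNC-style encodings.
- The F-score ranks features marginally; correlated features (overlapping
  k-mers are intrinsically correlated) can share credit for one signal, so
  top-n subsets are not guaranteed minimal.
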