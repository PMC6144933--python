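# ncdna

Tools for discriminating non-coding DNA (ncDNA) from protein-coding DNA
(cDNA) by sequence composition: k-mer frequency encoding, F-score feature
ranking, RBF-kernel SVM classification with grid search, and a repeated
stratified 10-fold cross-validation protocol reporting Sn/Sp/Acc/MCC and
ROC/AUC. A seeded synthetic benchmark generator with planted k-mer
enrichments makes the whole pipeline testable without any genome download.

Intended users: bioinformaticians building sequence-class predictors from
labeled FASTA sets, and anyone who needs a clean, deterministic reference
implementation of the k-mer + F-score + SVM pipeline.

## The method

A sequence P = R₁R₂…R_L is encoded by its sliding-window k-mer composition

    fᵢ = nᵢ / (L − k + 1),   i = 1, …, 4^k,   k = 1, …, 6,

with k-mers in lexicographic order (A<C<G<T); k = 4 (tetramer composition,
256 features) is the standard choice, and a combined 5460-dimensional
encoding concatenates all six blocks. Features are ranked by the F-score

    F(i) = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / (s²ᵢ⁺ + s²ᵢ⁻),

classified with an SVM using the RBF kernel K(x, y) = exp(−γ‖x − y‖²)
(C, γ grid-searched over powers of two), and evaluated by stratified
10-fold cross-validation repeated five times, with

    Sn = 1 − N₋⁺/N⁺,  Sp = 1 − N₊⁻/N⁻,  Acc = 1 − (N₋⁺+N₊⁻)/(N⁺+N⁻),

and the Matthews correlation coefficient (equal to the phi coefficient).
See `docs/methods.md` for conventions, assumptions and limitations.

## Worked example

Generate a synthetic benchmark with three tetramers enriched ×4 in the
positive class, encode at k = 4, rank, and cross-validate:

    ncdna simulate --n-pos 300 --n-neg 300 \
        --bias TATA:4 --bias TTTT:4 --bias ATAT:4 \
        --seed 1 --out-dir demo
    ncdna encode demo/positive.fasta demo/negative.fasta --k 4 --out demo/table.tsv
    ncdna rank demo/table.tsv --out demo/ranking.tsv --heatmap demo/grid.tsv
    ncdna cv --table demo/table.tsv --folds 10 --repeats 5 --seed 1 \
        --C 8 --gamma 32 --out demo/cv.tsv

The ranking recovers the planted tetramers at the top — these are the three
largest F-scores among all 256 tetramers, an order of magnitude above the
unplanted background:

    rank  kmer  f_score
    1     TATA  0.573539849659
    2     ATAT  0.549009800097
    3     TTTT  0.285073256435
    4     CGGG  0.0249602580755

and the cross-validation summary prints sensitivity, specificity and
accuracy as percentages, MCC and AUC on their own scales:

    classifier  Sn(%)  Sp(%)  Acc(%)  MCC    AUC
    svm         86.73  94.00  90.37   0.810  0.9516

i.e. with a moderate ×4 enrichment the SVM recovers ~90% accuracy; stronger
separation (e.g. ×8 on four tetramers) pushes accuracy above 95%, and with
no planted bias it sits at chance. Add `--tune` to grid-search (C, γ)
instead of fixing them. The same operations are available as library calls
(`ncdna.encode_dataset`, `ncdna.rank_features`, `ncdna.cross_validate`,
…), and every run writes a machine-readable run record with the full
configuration and seed.

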