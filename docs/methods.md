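# Methods

`enhancerselect` implements the in-silico arm of sequence-based enhancer
selection for cell type-specific viral probes: starting from differential
chromatin-accessibility tables, it builds labelled sequence datasets,
trains gapped k-mer SVMs and a convolutional network to discriminate the
target cell type's regulatory sequences, ranks candidate enhancers by
ensemble agreement, and attributes each candidate's score to individual
nucleotides so that putative binding sites can be called and perturbed.
This note records the models, the parameter choices that matter, the
numerical decisions, and what the synthetic benchmark does and does not
demonstrate.

## Dataset construction

**SVM path.** Differential open-chromatin regions (OCRs) between two cell
populations are filtered with strict thresholds, padj < 0.01 and
|log2FoldDifference| > 1 (both inequalities strict, matching the printed
forms used upstream by count-based differential testing). Windows of 500 bp
are centred on peak summits — summit regions are strongly motif-enriched,
and 500 bp is a convenient cloning length — retaining summits greedily in
file order when several fall within 100 bp of each other. Windows whose
closest edge comes within 2000 bp of a TSS are removed (enhancers, not
promoters, are the design target), as is any window overlapping a
super-enhancer by ≥ 1 bp (too large for probe design, and governed by
different sequence rules) or containing an uncertain base. Windows that
would run past a chromosome end are dropped rather than shifted, which
would break summit-centring; duplicate windows keep their first occurrence.
The TSS distance is measured edge-to-point — the conservative reading of
"within 2000 bp".

**CNN path.** Fixed 200 bp genome bins labelled by the sign of their fold
difference; bins overlapping a blacklist region or containing uncertain
bases are removed, and each surviving bin contributes the 1000 bp sequence
around its centre. No TSS or super-enhancer filter is applied on this path,
mirroring how bin-based CNN datasets are prepared in practice.

**Splits** are a function of chromosome only: train chr3–7, 10–19, X;
validation chr8–9; test chr1–2 for the SVMs (the human scheme adds
chr20–22); the CNN holds out chr4 for validation and chr8–9 for testing.
Chromosome-level held-out evaluation prevents leakage through overlapping
or homologous windows.

## Gapped k-mer SVM

A sequence is represented by counts of gapped k-mers: each length-l
substring contributes one instance for every choice of k informative
positions (C(l, k) per l-mer), the others being wildcards. Similarity is
the cosine of two count vectors, K̂ ∈ [0, 1]; the inner product is exact
(untruncated) — the mismatch parameter `d` used by approximate
implementations for speed is recorded in the configuration for provenance
but has no effect here. Because training windows are summit-centred, the
center-weighted variants multiply each l-mer instance by
w(dist) = 2^(−dist/H) with dist the offset of the l-mer centre from the
window centre; the amplitude M cancels under the w(0) = 1 normalization
and is recorded only. Defaults M = 50, H = 50 bp; the RBF variant maps
K̂ ↦ exp(γ(K̂ − 1)) with γ = 2 by default. These functional forms are
documented stand-ins for the external tool's unpublished `-t 4`/`-t 5`
kernels; equivalence with that tool is not claimed. With `rc_collapse`
(default on) every pattern is pooled with its reverse complement, making
features, kernels and scores exactly strand-symmetric — appropriate for
accessibility, which is unstranded.

Training L2-normalizes the feature rows (so the linear kernel equals K̂)
and fits an L1-hinge soft-margin SVM with per-class penalties C
(negatives) and C·w (positives). The linear fit is a dual coordinate
descent (the standard hinge-dual algorithm) compiled with numba and run in
place on float32 sparse rows; this keeps the peak memory footprint near
the size of the feature matrix itself, where generic solvers require a
float64 copy plus an internal 16-byte-per-entry representation. The
intercept is a regularized implicit constant feature, the common liblinear
convention. RBF models are fitted on the precomputed Gram matrix and kept
as a support expansion; linear models are collapsed to explicit primal
weights (the two scoring routes agree to ≤ 1e-6 and are cross-checked in
the tests against an independent SVM fit). Grid search selects the
configuration with the highest validation F1 at decision threshold 0,
breaking ties toward smaller l and then smaller C. The standard deviation
of the validation decision scores is stored with the model; downstream
scores are reported in these SD units so that models trained on different
comparisons are comparable.

## Convolutional network

The architecture takes a one-hot 4 × 1000 matrix (rows A, C, G, T) through
1000 unpadded convolution filters of width 8 spanning all four rows
(ReLU), optionally 0–2 further width-8 convolutions with 100 filters,
max-pooling with size and stride 13, dropout (0.2 / 0.4 / 0.5), and a
single sigmoid output; training is plain SGD (lr 0.01, momentum 0, batch
30, 100 epochs) on binary cross-entropy. With no padding the shape
arithmetic is closed-form: conv length 993, pooled length 76 and a
76,001-parameter dense layer at V = 0 (75 / 7,501 at V ≥ 1); these counts
are asserted in the tests. Forward pass, backpropagation and the optimizer
are written directly on numpy arrays (the heavy steps are BLAS matmuls via
im2col); gradients are verified against central finite differences.
Model selection across the grid uses either minimum validation log-loss or
a validation auROC/auPRC rule that treats differences within 0.02 as ties,
resolved toward fewer layers and lower dropout. Selection compares
final-epoch models (no per-epoch checkpointing), and inputs are reshuffled
every epoch; weight initialization is Glorot uniform, seeded.

**Scaled configuration.** For CPU-scale testing the network is trained
with 50 first-layer filters for 10 epochs. At that width, randomly
initialized filters rarely align with a short motif within so few SGD
steps — runs either "ignite" or stay at chance — so the scaled
configuration (kept strictly separate from the full-size defaults)
(i) initializes the first layer from the most class-discriminative
training k-mers, as one-hot templates centred by the empirical background
base frequencies and paired with their reverse complements (a documented
motif-seeding initialization; training split only), (ii) uses batch 5 and
lr 0.12 (more, larger steps), and (iii) the strongest dropout of the grid
(0.5). Background-frequency centring matters: with uniform centring on a
GC-skewed background every filter acquires a mean drive and high-rate SGD
can collapse the entire ReLU layer. The scaled path trains four restart
seeds and selects on the validation split with the module's normal
selection rule, which removes the residual seed-to-seed spread of short
runs.

## Evaluation

auROC is the pairwise-concordance probability (ties count ½; random
baseline 0.5); auPRC uses the average-precision step convention whose
random baseline is the positive fraction — trapezoidal interpolation is
avoided as optimistic. F1 is computed at threshold 0 for SVM decision
scores and 0.5 for CNN probabilities, with F1 = 0 when nothing is
predicted positive. Correlations are Pearson and Spearman (mean ranks on
ties); zero-variance input is an error rather than a silent NaN. The
implementations are thin wrappers over scikit-learn/scipy; the test suite
re-derives them with brute-force oracles (explicit pair counting,
threshold enumeration, subset enumeration for the hypergeometric test).

## Candidate prioritization

A candidate must (i) overlap (≥ 1 bp) a positive-class differential region
in *every* pairwise comparison — the matching rule across datasets is not
standardized, and 1 bp overlap is the permissive, reproducible choice —
and (ii) score positive in every SVM (probability > 0.5 for any CNN).
Survivors are ranked by the percentile (100·mean-rank/n, mean ranks on
ties) of their SD-normalized score within each model. Marker regions for a
cluster are its enriched regions minus any overlap with another cluster's
enriched set; query-vs-marker overlap is tested with the hypergeometric
upper tail P(X ≥ k) over an explicit universe size, and the Bonferroni
multiplier is an explicit argument — no hidden default. Gold-standard
agreement between two log2-fold-difference tables uses the shared regions
only (dropping and counting the rest) and requires at least three.

## Nucleotide-level interpretation

For explicit-linear models the decision score decomposes exactly over
gapped k-mer instances; each instance's contribution (weight ×
center-weight / feature-vector norm) is split evenly over its k
informative positions. The sum of the per-base *actual* importances equals
score − intercept to machine precision (asserted to 1e-6). The
*hypothetical* importance of base b at position i is the same attribution
at i recomputed on the sequence with i→b, including the exact norm of the
substituted feature vector; the incremental computation touches only the
l·C(l−1, k−1) affected instances and is verified against full
refeaturization. For non-linear models both tracks fall back to in-silico
mutagenesis, defining each base's hypothetical as its substitution score
minus the mean of the three alternatives (so the reference base's
hypothetical equals the actual importance in both paths). *Normalized*
importance subtracts the mean of the four hypotheticals per position: a
position loses importance when other bases would score similarly. The
mean-centring formula is this package's concrete choice for that verbal
contract.

Site calling takes the top 5% of normalized importance, merges positions
across gaps of ≤ 2 bp, ranks segments by summed importance and constrains
the top two to 6–8 bp (longer segments trimmed to their best-sum window,
shorter ones grown toward the more important neighbour). PWM scanning uses
per-position log2((p + ε)/background) with ε = 0.001, both strands, and
exact null p-values from a dynamic program over motif positions with
scores discretized at 1/1000 bit (the DP is validated against full 4^w
enumeration); the reporting threshold is p < 1e-4, the conventional
scanner default. Scrambling permutes the bases of a called site (multiset
preserved) and re-scans only the windows overlapping the site against the
guard motifs, resampling (≤ 50 tries) if a new hit at p < 1e-4 appears;
the guard targets newly *introduced* sites, so hits destroyed by the
scramble do not block it. Mutant effects are reported as SD-normalized
score deltas per model with a cross-model mean.

## Synthetic benchmark

The generator emulates the statistical shape of differential-accessibility
inputs: an i.i.d. genome at GC 0.45, well-separated summit-carrying peaks,
positive-class rows with log2FoldDifference ~ Normal(2.5, 0.8) truncated
above 1 and padj log-uniform in [1e-30, 1e-3] (mirrored for negatives), a
1:1.5 class ratio (inside the 1:0.4–1:3.7 range of real sorted and
single-nucleus training sets), and planted PWM instances near the summits
of positive regions (plant probability 0.9, uniform strand, within
±100 bp). Distractor regions exercise each preparation filter: TSS-proximal
and super-enhancer-overlapping rows (planted like other positive rows —
their removal is positional, and real promoter-proximal differential
regions still contain the cell type's motifs), regions with uncertain
bases, blacklist-overlapping regions for the CNN path, and
non-significant filler rows. A truth table records every planted site and
a roster records every region's role, so tests can verify that each
distractor is removed by exactly its intended filter.

**Signal strength.** The planted motifs are 8-bp PWMs with consensus
probability 0.97 per column (≈ 14 bits), in the range of real
high-information TF PWMs such as nuclear-receptor response elements. This
choice is deliberate and load-bearing: localizing one site in a 500–1000 bp
both-strand window requires ~10–11 bits, and at a weaker 0.92 (11.8 bits)
the *oracle that scans with the true planted PWM* only reaches auROC
≈ 0.85 (500 bp) / 0.81–0.88 (1000 bp) — no classifier can beat the data.
At 0.97, demonstration positives carry two independent instances
(homotypic/heterotypic site pairs, as in real enhancers) and the oracle
ceiling rises to ≈ 0.93–0.96, with the trained SVM and CNN sitting just
below it. The interpretation fixture plants three instances per positive
(plant probability 1), so that a top-5% importance set (25 bases of a
500 bp window) can meaningfully localize to planted sites (~30 positions
including ±1 bp flanks).

**What passing does not show.** The background is i.i.d., not the
repeat-rich, GC-heterogeneous, nucleosome-structured genome; effect sizes
and planting rates are stylized; positives differ from negatives by
planted motifs alone, whereas real differential OCRs differ in dinucleotide
composition, shape features and co-binding grammar. Success here
demonstrates the correctness and end-to-end wiring of the method — exact
featurization, faithful training and selection, calibrated statistics,
exact attribution — not field performance on real chromatin data, for
which the published accession-scale datasets are required.

## Problem sizes and numerical choices

The demonstration bundle has 2000 labelled regions (800 positive / 1200
negative) plus 145 distractor/filler rows on a 14 Mb twenty-chromosome
genome; the interpretation bundle has 1200 labelled regions. The SVM grid
is l ∈ {8, 10} × k ∈ {5, 6} with C = w = 1; the DCD runs ≤ 100 epochs at
tolerance 1e-3 with per-epoch Fisher–Yates reshuffling (seeded). Column
indices use int32 (the canonical column space for k ≤ 8 fits comfortably),
feature values float32 during training and float64 elsewhere; the stored
validation-score SD is computed through the same scoring path used at
prediction time so normalization is exactly consistent. Degenerate inputs
raise: empty grids, single-class training data, zero-norm feature vectors,
zero-variance correlation inputs, unassignable chromosomes, N-containing
sequences at scoring time (per-sequence NaN with a logged error, the run
continues).
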