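# enhancerselect

Sequence-based prioritization of cell type-specific enhancer candidates
from differential chromatin accessibility.

Enhancer-driven AAV probes can label a neuron subtype that no single
marker-gene promoter resolves, but chromatin accessibility alone is a
noisy proxy for enhancer activity: many differentially accessible regions
fail to drive selective expression in vivo. `enhancerselect` implements
the machine-learning filter that closes this gap. Starting from
differential open-chromatin tables (region, log2FoldDifference, padj,
summits) produced by standard count-based testing, it:

1. **builds labelled sequence datasets** — 500 bp summit-centred windows
   for the SVMs (strict thresholds padj < 0.01, |log2FD| > 1; TSS-proximal,
   super-enhancer-overlapping and N-containing windows removed) and
   1000 bp windows around 200 bp bins for the CNN, with chromosome
   held-out train/validation/test splits;
2. **trains classifiers** of the target cell type's regulatory sequence —
   gapped k-mer SVMs (exact C(l,k)-gapped word counts, cosine kernel
   K̂ = ⟨x,y⟩/(‖x‖‖y‖), optional centre weighting 2^(−dist/H) and RBF
   transform exp(γ(K̂−1)), validation-F1 grid selection) and a
   convolutional network (1000 × 8×4 filters → ReLU → max-pool 13 →
   dropout → sigmoid, SGD on log-loss);
3. **ranks candidates by ensemble agreement** — differential in every
   pairwise comparison, scored positive by every model, then percentile
   ranks of SD-normalized scores — and provides the validation statistics
   used to judge a new probe (gold-standard log2FD correlation,
   cluster-marker definition, hypergeometric overlap enrichment with
   explicit Bonferroni correction);
4. **explains scores at nucleotide resolution** — an exact per-base
   decomposition of the linear gkm score (actual + hypothetical
   importance, ISM for non-linear models), top-5% motif-site calling,
   an exact-p-value PWM scanner, and guarded site scrambling with
   re-scoring across models.

A synthetic planted-motif generator (`enhancerselect.simulate`) produces
self-contained fixture bundles — genome FASTA, narrowPeak peaks,
differential TSV tables, TSS/super-enhancer/blacklist BEDs, and a truth
table of planted sites — so the entire pipeline is testable end to end
without any external sequencing data.

## Worked example

```bash
# 1. a synthetic bundle: 2000 labelled regions with planted motifs
enhancerselect simulate --preset demo --seed 7 --out demo/

# 2. summit-centred, filtered, split 500 bp sequences
enhancerselect prepare \
    --differential demo/differential_vs_rest.tsv \
    --genome demo/genome.fa --tss demo/tss.bed \
    --super-enhancers demo/super_enhancers.bed \
    --scheme svm_mouse --out prepared
# -> 2020 examples (910 pos / 1200 neg rows; removed 30 TSS-proximal,
#    30 super-enhancer, 30 N)

# 3. grid-train the gapped k-mer SVM (l in {8,10} x k in {5,6})
enhancerselect train-svm --fasta prepared.fa --out svm.npz
# -> selected l=8 k=6 C=1.0 w=1.0 kernel=wgkm; val F1 0.877

# 4. held-out performance
enhancerselect evaluate --model svm.npz --fasta prepared.fa \
    --split test --report report.json
# -> auROC 0.9645  auPRC 0.9693  F1 0.8980  (n=200)

# 5. rank candidates across the ensemble
enhancerselect rank --fasta prepared.fa --models svm.npz \
    --consensus demo/differential_vs_subtype_a.tsv,demo/differential_vs_subtype_b.tsv \
    --out candidates.tsv
# -> 611 of 2020 candidates pass all filters
```

The numbers mean: of 2110 candidate windows, the three positional filters
removed exactly the 90 planted distractor regions; the selected SVM
separates held-out positive-class from negative-class sequences with
test-set auROC 0.96 (random = 0.5) and auPRC 0.97 (random = positive
fraction ≈ 0.40); `candidates.tsv` carries one row per candidate with raw
and SD-normalized scores, consensus/all-positive flags and percentile
ranks — the top-ranked surviving candidate is the analogue of a probe
sequence chosen for cloning.

Library use mirrors the CLI (`simulate.simulate_bundle`,
`regions.prepare_svm_examples`, `gkm.train`, `cnn.train_grid`,
`prioritize.build_candidate_table`, `interpret.per_base_importance`, ...);
see `docs/methods.md` for the models, parameter meanings, and the design
decisions behind them.

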