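# Methods

## Mutation encoding

Every somatic alteration is represented by three tokens.

**Motif.** A word of exactly three symbols over Σ = {A,C,G,T} ∪ 𝓜.
𝓜 contains 21 mutation symbols: the six substitutions expressed with
respect to the pyrimidine reference base, `[del A]`…`[del T]`,
`[ins A]`…`[ins T]`, the breakpoint symbols `[SV_del]`, `[SV_dup]`,
`[SV_inv]`, `[SV_bnd]`, and the mobile-element symbols `[MEI_L1]`,
`[MEI_Alu]`, `[MEI_SVA]`. Layout rules:

* SNV: 5′ flank, substitution, 3′ flank. If the reference base is a purine
  the whole triple is reverse-complemented first, so the two strand
  descriptions of one event collapse to a single canonical motif (verified
  by a property test).
* MNV: one substitution symbol per base, in adjacent slots; a 2-bp MNV keeps
  its 5′ flanking base in slot one. Orientation is chosen so the first
  substituted reference base is a pyrimidine; when both orientations qualify
  the lexicographically smaller serialization wins, and when neither does
  (purine-first in both readings, e.g. ApC) the forward description is kept.
* Indels: one `[del X]`/`[ins X]` symbol per deleted/inserted base. A
  single-base event is centred between its flanks (`T[del C]C`); a 2-base
  event keeps the 5′ flank; events longer than 3 bases are truncated to
  their first three symbols with a logged warning (the 3-symbol alphabet
  caps representable length).
* SV/MEI breakpoints: the breakpoint symbol in slot one followed by the two
  reference bases 3′ of the breakend; when another mutation co-locates with
  those bases its substitution symbol occupies the slot instead
  (`[SV_del][C>G]T`).

An `N` in any required context position makes the mutation unencodable; it
is skipped and counted in the run log.

**Position.** `<chrom>_<floor(pos / 10⁶)>` with 1-based positions, so all
mutations in one megabase share a token (`chr1_11` covers
chr1:11,000,000–11,999,999).

**Annotation.** The (genic, exonic, strand-class) tuple with strand class
∈ {same, opposite, both, intergenic}, comparing the strand that carries the
motif's pyrimidine reference base against the overlapping gene's strand.
For indels, SVs and MEIs, which have no pyrimidine normalization, the
forward strand is used. The dictionary always holds the full 16-element
product space even though some combinations (e.g. intergenic ∧ genic) never
occur, keeping indices stable across corpora.

**Dictionaries** are corpus-derived by default (positions observed in real
cohorts number fewer than the combinatorial bin count, so enumerating is
wasteful); index 0 is PAD, index 1 is UNK, and unseen tokens at inference
map to UNK and are counted. An `enumerate_snv` mode pre-seeds all 96
combinatorial SNV motifs for corpora where SNV coverage matters.

**Negative examples** (off by default) add, per tumour, the dataset-wide
median per-tumour count of each mutation-type group (SNV, MNV, indel, SV,
MEI), sampled as real mutated positions from *other* tumours and encoded as
the plain reference triplet at the donor's position/annotation tokens.
Medians of integer counts can be half-integral for even cohort sizes; they
are rounded half-up so the injected count is a whole number.

## Model

Per-modality embedding tables of width *d* are concatenated and linearly
projected back to *d* (keeping *d* the single capacity knob). The encoder
stacks `n_encoder_layers` post-norm transformer blocks: multi-head scaled
dot-product attention softmax(QK′/√d_head)·V with a learned output
projection, residual connection and layer normalization, then a
position-wise feed-forward sublayer (hidden width 4*d*, GELU) with its own
residual and normalization. No positional encoding is used anywhere, making
the full network permutation-invariant after mean pooling — the bag-of-
mutations contract, fuzz-tested.

Pooling is the mean over the mutation axis and happens **before** the fully
connected layers; whether pooling precedes or follows the FC stack is an
open design point, and mean-pool-then-FC was chosen for magnitude stability
under variable catalogue size. The classifier head is zero-initialized, so
an untrained model outputs exactly uniform probabilities and the initial
loss is ln C. Tumour-level features are the pre-softmax logits, so a
10-component ensemble over 24 classes yields 240 features per tumour.

The loss is cross-entropy with the correct-class probability clamped at
1e-12 and a max-subtraction-stabilized softmax. The network is implemented
in NumPy (float64) with a small reverse-mode autodiff tape
(`mutatt.autodiff`); analytic gradients are verified against central
differences to relative error < 1e-4 in the suite. No dropout or weight
decay is applied.

## Training and evaluation

Defaults follow the reference recipe: SGD with learning rate 6e-4 (constant
— no schedule), momentum 0.9, minibatch size one tumour, 150 epochs, at most
5000 mutations per tumour with the subsample re-drawn every epoch (a mild
augmentation effect). The best-validation-accuracy epoch's weights are
returned. All randomness (initialization, shuffling, subsampling, folds,
negative injection) flows from one run seed through named substreams.

Cross-validation stratifies ten folds within each class (per-class fold
sizes differ by at most one); the hyperparameter grid spans embedding
dimensions {128, 256, 512}, encoder layers {1, 2, 4}, heads {1, 2} and FC
layers {1, 2} — 36 configurations per mutation-type combination — with
per-fold winners chosen by validation top-1, ties broken by smaller
parameter count then grid order. Ensembles sum component logits. Metrics
use the standard confusion-matrix formulas (precision TP/(TP+FP), recall
TP/(TP+FN), F1 2TP/(2TP+FP+FN)); top-k counts a prediction correct when the
true class is among the k highest scores. Calibration uses ten equal-width
confidence bins; prediction stability over repeated subsampled predictions
is the fraction of repeats agreeing with the modal call. The sparse-data
analysis subsamples each test catalogue to fixed sizes n and re-scores.
Burden strata are exposed as quantiles rather than fixed cut-offs, since
published cut-offs are data-derived.

## Interpretation

Tumour-level features (concatenated component logits) are projected to 2-D
with UMAP (delegated to umap-learn, seed recorded). For factorization the
feature columns are min-shifted to non-negative (the shift is stored so
factors remain comparable across runs) and decomposed with scikit-learn NMF
(Frobenius loss, NNDSVDA initialization); a reconstruction-error-versus-k
curve supports knee analysis. Signature association fits, per signature,
ordinary least squares of log(s+1) on all factor loadings, reporting
coefficients, p-values, per-signature R², and Benjamini–Hochberg q-values
across all (signature, factor) tests at a 10% FDR flag; collinear factors
are dropped with a warning.

Attention mining uses the **raw, unscaled** QK′ matrix of the first encoder
layer's first head by default (the √d-scaled and post-softmax variants are
available behind a flag, and layer/head are configurable). Entries strictly
above 0.9× the tumour's own maximum are retained, mapped back to motif and
position tokens, averaged per (query, key) pair within the tumour and then
across tumours of each type; the mutation-type composition of retained
pairs is also reported.

## Synthetic data

The simulator exists so every pipeline stage is testable without cohort
access. A toy genome (uniform random sequence, configurable contigs and
gene density) is written as FASTA+BED; each class is a trinucleotide
substitution distribution on the 96-simplex, fractions of MNVs, indels, SVs
and MEIs, a preference distribution over 1-Mb bins, and a log-normal burden.
SNVs are placed at genome positions whose reference context matches the
drawn category exactly — implemented as a precomputed index of positions
grouped by (bin, canonical trinucleotide) with uniform draws inside the
group, which is distributionally identical to rejection sampling but O(1)
per draw; bounded retries redraw the bin and then the category when a
context is absent. This guarantees encoder/reference consistency: every
simulated variant encodes without error.

The four default presets (UV-like with dipyrimidine C>T and CC>TT doublets,
smoking-like C>A-rich, MSI-like indel-rich, SV-rich) are caricatures for
testing, not biological models. The generator reproduces none of
replication timing, clonality, coverage or calling noise, so passing tests
demonstrate correct mechanics and recoverability of planted class structure
— not real-data performance.

## Desk-scale study conditions

The end-to-end recovery experiment uses 200 training and 100 held-out
tumours (four classes, 500 mutations each, seeded), a tiny model (d=64, one
encoder layer, one head) and 20 training epochs: with the zero-initialized
head and the reference learning rate the loss plateaus for roughly the
first 1,500 steps and then converges rapidly, with held-out accuracy
saturating by epoch 9–10, so 20 epochs is comfortably past convergence on
these separable cohorts while keeping the suite fast. The attention
contribution is assessed by comparing the same configuration with the
encoder removed (embeddings → pooling → classifier) across the
downsampling grid n ∈ {10, 50, 100, 300, 500}; the encoder-free variant
trains poorly at this recipe and scores markedly lower.

## Known limitations

* Motifs cap complex events at three symbols; longer indels/MNVs are
  truncated (left-anchored) with a warning.
* Indel placement follows the caller's left-alignment; no re-normalization
  is attempted.
* Co-located mutation symbols in SV motifs are supported at the encoding
  API level but the file-reading pipeline does not currently detect
  breakend/SNV co-location automatically.
* The NumPy implementation targets desk-scale problems; attention is
  O(l²) per tumour, which is why catalogues are capped (default 5000
  mutations) and subsampled.
* Cohort-scale published accuracies, dictionary sizes (2915 position /
  3692 motif tokens) and production parameter counts depend on consortium
  data and are not reproducible here.
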