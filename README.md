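# mutatt — attention-based tumour typing from somatic mutation catalogues

`mutatt` predicts the histological type of a tumour from its catalogue of
somatic mutations — SNVs, MNVs, short indels, structural-variant breakpoints
and mobile-element insertions — and learns tumour-level representations that
are useful beyond the class labels (subtype exploration, signature
association, attention-pattern mining). It is aimed at cancer-genomics
analysts working with per-tumour variant callsets (VCF/MAF/TSV on a
reference genome with a gene model).

## The model

Instead of aggregating mutations into count tables, every mutation is kept
as an individual token triple:

* **motif** — a 3-symbol word over the alphabet Σ = {A,C,G,T} ∪ 𝓜, where 𝓜
  holds 21 mutation symbols: six pyrimidine-normalized substitutions
  ([C>A], [C>G], [C>T], [T>A], [T>C], [T>G]), four single-base deletions and
  four insertions, four SV breakpoint symbols and three mobile-element
  classes. An ApCpG>ApTpG substitution becomes `A[C>T]G`; a diadenine
  deletion preceded by a cytosine becomes `C[del A][del A]`; a deletion
  breakpoint with a co-located C>G substitution followed by thymine becomes
  `[SV_del][C>G]T`.
* **position** — the 1-Mbp genomic bin, e.g. `chr1_11` for
  chr1:11,000,000–11,999,999.
* **annotation** — one of 2×2×4 = 16 combinations of genic, exonic and
  strand-orientation attributes.

Each modality is embedded, the embeddings are concatenated and projected to
dimension *d*, and the resulting *l*×*d* bag of mutation vectors passes
through encoder blocks of multi-head scaled dot-product attention,

    Attention(Q, K, V) = softmax(QK′ / √d) · V,

with residual connections and layer normalization but **no positional
encoding** — a tumour is a bag of mutations and predictions are invariant to
their order. Mean pooling and fully connected layers yield per-class logits;
training minimizes cross-entropy L = −Σᵢ yᵢ log ŷᵢ with SGD (learning rate
6·10⁻⁴, momentum 0.9, minibatch one tumour, subsampling catalogues above
5000 mutations anew each epoch). Ten-fold stratified cross-validation
selects one model per fold; the ensemble sums component logits, and the
concatenated component logits (components × classes values, e.g. 10×24 =
240) serve as tumour-level features for UMAP projection, non-negative matrix
factorization into latent factors M1…Mk, and least-squares association of
log(s+1) signature exposures with those factors (Benjamini–Hochberg FDR).
Attention mining thresholds each tumour's raw QK′ matrix at 0.9× its
maximum and maps the retained query/key pairs back to motifs and position
bins.

A seeded synthetic-cohort simulator (toy genome + class-conditional
trinucleotide spectra, indel/SV fractions and positional-bin preferences)
makes the entire pipeline testable at desk scale with no external data.

## Worked example

```python
import numpy as np
from pathlib import Path
from mutatt import (
    make_toy_genome, default_class_specs, simulate_cohort,
    ReferenceGenome, read_variants, encode_catalogues,
    build_dictionaries, tokenize_catalogue,
    ModelConfig, TrainConfig, train,
    EnsembleModel, ensemble_predict, topk_metrics,
)

work = Path("example")
genome = make_toy_genome(work / "genome", n_contigs=2, contig_length=2_000_000, seed=0)
specs = default_class_specs(genome.n_bins, burden_log_mean=np.log(300.0))
cohort = simulate_cohort(specs, n_per_class=15, genome=genome, out_dir=work / "cohort", seed=1)

reference = ReferenceGenome(genome.fasta_path)
variants = [v for p in sorted(cohort.vcf_paths.values())
            for v in read_variants(p, sample=p.stem)]
catalogues, _ = encode_catalogues(variants, reference, labels=cohort.labels)
dicts = build_dictionaries(catalogues)
tokenized = [tokenize_catalogue(c, dicts) for c in catalogues]

train_set = [tc for tc in tokenized if not tc.sample_id.endswith(("3", "7"))]
test_set = [tc for tc in tokenized if tc.sample_id.endswith(("3", "7"))]
labels = sorted({tc.class_label for tc in tokenized})
config = ModelConfig(
    n_classes=4, dict_sizes={k: len(d) for k, d in dicts.items()},
    embedding_dim=64, n_encoder_layers=1, n_heads=1, n_fc_layers=1,
    class_labels=labels,
)
result = train(config, train_set, test_set, TrainConfig(epochs=40, seed=2))
print(f"best validation accuracy: {result.best_val_accuracy:.2f} (epoch {result.best_epoch})")

ensemble = EnsembleModel([result.model])
scores, truth = [], []
for tc in test_set:
    pred, features = ensemble_predict(ensemble, tc, seed=0)
    scores.append(pred.logits)
    truth.append(labels.index(tc.class_label))
metrics = topk_metrics(np.vstack(scores), truth, k_list=[1, 3])
print(f"held-out top-1 accuracy: {metrics['topk'][1]:.2f}")
print(f"held-out top-3 accuracy: {metrics['topk'][3]:.2f}")
print("confusion matrix (rows = true class):")
print(metrics["confusion_matrix"])
```

Output:

```
best validation accuracy: 1.00 (epoch 38)
held-out top-1 accuracy: 1.00
held-out top-3 accuracy: 1.00
confusion matrix (rows = true class):
[[3 0 0 0]
 [0 3 0 0]
 [0 0 3 0]
 [0 0 0 3]]
```

The four synthetic classes (UV-like, smoking-like, mismatch-repair-
deficient-like, SV-rich) differ in trinucleotide spectrum, mutation-type mix
and 1-Mb bin preference; a tiny one-layer model separates them perfectly on
held-out tumours. The 4-vector of per-class logits returned for each tumour
doubles as its tumour-level feature vector.

A `mutatt` console command exposes the same pipeline from the shell
(`mutatt simulate`, `train`, `predict`, `evaluate`, `features`, `project`,
`factors`, `associate`, `attention`); see `mutatt --help`.

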