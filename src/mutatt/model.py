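"""The attention-based tumour-type classifier.

Three stages, trained end-to-end with backpropagation:

1. *Embedding*: each mutation's (motif, position, annotation) token indices
   are looked up in per-modality embedding tables of width ``d``,
   concatenated, and linearly projected back to ``d``.
2. *Attention encoder*: ``n_encoder_layers`` blocks of multi-head scaled
   dot-product attention, ``softmax(QK'/sqrt(d)) V``, with residual
   connections, layer normalization and a position-wise feed-forward
   sublayer. No positional encoding is used: a tumour is a bag of
   mutations and predictions are invariant to their order.
3. *Classifier*: mean pooling over mutations, ``n_fc_layers`` fully
   connected layers, and a linear head producing one logit per tumour type.
   The pre-softmax logits double as the tumour-level feature vector.

The loss is cross-entropy, L = -sum_i y_i log(yhat_i) with one-hot y.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .autodiff import Node, Tape
from .encoding import TokenizedCatalogue, PAD_INDEX

MODALITIES = ("motif", "position", "annotation")


@dataclass
class ModelConfig:
    n_classes: int
    dict_sizes: dict[str, int]
    embedding_dim: int = 128
    n_encoder_layers: int = 1
    n_heads: int = 1
    n_fc_layers: int = 1
    max_mutations: int = 5000
    modalities: tuple[str, ...] = ("motif", "position")
    class_labels: list[str] | None = None
    ffn_multiplier: int = 4

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        if self.embedding_dim % self.n_heads != 0:
            raise ValueError("embedding_dim must be divisible by n_heads")
        if self.max_mutations < 1:
            raise ValueError("max_mutations must be >= 1")
        if self.n_encoder_layers < 0 or self.n_fc_layers < 0:
            raise ValueError("layer counts must be non-negative")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {unknown}")
        for m in self.modalities:
            if m not in self.dict_sizes:
                raise ValueError(f"dict_sizes missing modality {m!r}")


@dataclass
class TumourPrediction:
    sample_id: str
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_index: int
    predicted_label: str | None = None
    true_label: str | None = None
    low_confidence: bool = False

    @classmethod
    def from_logits(cls, sample_id, logits, class_labels=None, true_label=None,
                    low_confidence=False) -> "TumourPrediction":
        logits = np.asarray(logits, dtype=float)
        z = logits - logits.max()
        p = np.exp(z)
        p /= p.sum()
        k = int(np.argmax(logits))
        return cls(
            sample_id=sample_id,
            logits=logits,
            probabilities=p,
            predicted_index=k,
            predicted_label=class_labels[k] if class_labels else None,
            true_label=true_label,
            low_confidence=low_confidence,
        )


def cross_entropy_loss(probabilities: np.ndarray, label: int, eps: float = 1e-12) -> float:
    """L = -sum_i y_i log(yhat_i) with one-hot y; correct-class prob clamped at eps."""
    p = np.asarray(probabilities, dtype=float)
    if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be non-negative and sum to 1")
    return float(-math.log(max(p[label], eps)))


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray):
    """Reference (forward-only) attention: softmax(QK'/sqrt(d)) V.

    Returns (output, weights, raw_scores) where raw_scores = QK'.
    """
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    d = Q.shape[-1]
    scores = Q @ K.T
    z = scores / math.sqrt(d)
    z = z - z.max(axis=-1, keepdims=True)
    w = np.exp(z)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V, w, scores


class MutationSetClassifier:
    """Bag-of-mutations attention classifier with NumPy parameters."""

    def __init__(self, config: ModelConfig, seed: int = 0, head_init: str = "zeros"):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.embedding_dim
        h = config.ffn_multiplier * d
        p: dict[str, np.ndarray] = {}

        def init(*shape):
            return rng.normal(0.0, 0.02, size=shape)

        for m in config.modalities:
            p[f"emb_{m}"] = init(config.dict_sizes[m], d)
        p["proj_W"] = init(len(config.modalities) * d, d)
        p["proj_b"] = np.zeros(d)
        for i in range(config.n_encoder_layers):
            p[f"enc{i}_Wq"] = init(d, d)
            p[f"enc{i}_Wk"] = init(d, d)
            p[f"enc{i}_Wv"] = init(d, d)
            p[f"enc{i}_Wo"] = init(d, d)
            p[f"enc{i}_bq"] = np.zeros(d)
            p[f"enc{i}_bk"] = np.zeros(d)
            p[f"enc{i}_bv"] = np.zeros(d)
            p[f"enc{i}_bo"] = np.zeros(d)
            p[f"enc{i}_ln1_g"] = np.ones(d)
            p[f"enc{i}_ln1_b"] = np.zeros(d)
            p[f"enc{i}_ln2_g"] = np.ones(d)
            p[f"enc{i}_ln2_b"] = np.zeros(d)
            p[f"enc{i}_ffn_W1"] = init(d, h)
            p[f"enc{i}_ffn_b1"] = np.zeros(h)
            p[f"enc{i}_ffn_W2"] = init(h, d)
            p[f"enc{i}_ffn_b2"] = np.zeros(d)
        for j in range(config.n_fc_layers):
            p[f"fc{j}_W"] = init(d, d)
            p[f"fc{j}_b"] = np.zeros(d)
        if head_init == "zeros":
            p["head_W"] = np.zeros((d, config.n_classes))
        else:
            p["head_W"] = init(d, config.n_classes)
        p["head_b"] = np.zeros(config.n_classes)
        self.params = p

    # -- forward ------------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _prepare_tokens(self, tokens: Mapping[str, np.ndarray]) -> tuple[dict, bool]:
        """Replace an empty catalogue by a single PAD token (flagged)."""
        first = tokens[self.config.modalities[0]]
        if len(first) == 0:
            pad = {m: np.array([PAD_INDEX]) for m in self.config.modalities}
            return pad, True
        out = {}
        for m in self.config.modalities:
            idx = np.asarray(tokens[m], dtype=np.int64)
            if idx.max(initial=0) >= self.config.dict_sizes[m] or idx.min(initial=0) < 0:
                raise IndexError(f"token index outside the {m} dictionary; map unseen tokens to UNK upstream")
            out[m] = idx
        return out, False

    def _forward(
        self,
        tape: Tape,
        tokens: Mapping[str, np.ndarray],
        capture_attention: bool = False,
    ):
        cfg = self.config
        nodes = {name: tape.node(arr) for name, arr in self.params.items()}
        d, nh = cfg.embedding_dim, cfg.n_heads
        dh = d // nh

        embedded = [tape.gather(nodes[f"emb_{m}"], tokens[m]) for m in cfg.modalities]
        x = tape.add(tape.matmul(tape.concat(embedded), nodes["proj_W"]), nodes["proj_b"])
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError("non-finite activations entering the encoder")

        attention_raw: list[list[np.ndarray]] = []
        for i in range(cfg.n_encoder_layers):
            q = tape.add(tape.matmul(x, nodes[f"enc{i}_Wq"]), nodes[f"enc{i}_bq"])
            k = tape.add(tape.matmul(x, nodes[f"enc{i}_Wk"]), nodes[f"enc{i}_bk"])
            v = tape.add(tape.matmul(x, nodes[f"enc{i}_Wv"]), nodes[f"enc{i}_bv"])
            heads, layer_raw = [], []
            for hh in range(nh):
                lo, hi = hh * dh, (hh + 1) * dh
                qh = tape.slice_last(q, lo, hi)
                kh = tape.slice_last(k, lo, hi)
                vh = tape.slice_last(v, lo, hi)
                scores = tape.matmul(qh, tape.transpose(kh))  # raw QK'
                if capture_attention:
                    layer_raw.append(scores.data.copy())
                weights = tape.softmax_last(tape.scale(scores, 1.0 / math.sqrt(dh)))
                heads.append(tape.matmul(weights, vh))
            if capture_attention:
                attention_raw.append(layer_raw)
            attn = tape.add(
                tape.matmul(heads[0] if nh == 1 else tape.concat(heads), nodes[f"enc{i}_Wo"]),
                nodes[f"enc{i}_bo"],
            )
            x = tape.layer_norm(tape.add(x, attn), nodes[f"enc{i}_ln1_g"], nodes[f"enc{i}_ln1_b"])
            ff = tape.add(
                tape.matmul(
                    tape.gelu(tape.add(tape.matmul(x, nodes[f"enc{i}_ffn_W1"]), nodes[f"enc{i}_ffn_b1"])),
                    nodes[f"enc{i}_ffn_W2"],
                ),
                nodes[f"enc{i}_ffn_b2"],
            )
            x = tape.layer_norm(tape.add(x, ff), nodes[f"enc{i}_ln2_g"], nodes[f"enc{i}_ln2_b"])

        pooled = tape.mean_rows(x)  # (1, d): order-invariant bag pooling
        for j in range(cfg.n_fc_layers):
            pooled = tape.gelu(tape.add(tape.matmul(pooled, nodes[f"fc{j}_W"]), nodes[f"fc{j}_b"]))
        logits = tape.add(tape.matmul(pooled, nodes["head_W"]), nodes["head_b"])
        return logits, nodes, attention_raw

    # -- public API ----------------------------------------------------------

    def logits(self, tokens: Mapping[str, np.ndarray]) -> tuple[np.ndarray, bool]:
        """Class logits for one tokenized catalogue; second value flags empties."""
        prepared, empty = self._prepare_tokens(tokens)
        logits, _, _ = self._forward(Tape(), prepared)
        return logits.data.ravel().copy(), empty

    def attention_scores(
        self, tokens: Mapping[str, np.ndarray], layer: int = 0, head: int = 0,
        variant: str = "raw",
    ) -> np.ndarray:
        """Attention matrix A = QK' for one catalogue (pre-softmax, unscaled).

        ``variant`` may be 'raw' (default), 'scaled' (divided by sqrt(d_head))
        or 'softmax' (the attention weights themselves).
        """
        prepared, _ = self._prepare_tokens(tokens)
        _, _, raw = self._forward(Tape(), prepared, capture_attention=True)
        A = raw[layer][head]
        if variant == "raw":
            return A
        dh = self.config.embedding_dim // self.config.n_heads
        A = A / math.sqrt(dh)
        if variant == "scaled":
            return A
        if variant == "softmax":
            z = A - A.max(axis=-1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=-1, keepdims=True)
        raise ValueError(f"unknown attention variant {variant!r}")

    def loss_and_grads(self, tokens: Mapping[str, np.ndarray], label: int):
        """Cross-entropy loss and parameter gradients for one tumour."""
        prepared, _ = self._prepare_tokens(tokens)
        tape = Tape()
        logits, nodes, _ = self._forward(tape, prepared)
        loss, probs = tape.cross_entropy_logits(logits, label)
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite loss")
        tape.backward(loss)
        grads = {name: (node.grad if node.grad is not None else np.zeros_like(node.data))
                 for name, node in nodes.items()}
        return float(loss.data), grads, probs

    def clone(self) -> "MutationSetClassifier":
        other = object.__new__(MutationSetClassifier)
        other.config = self.config
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other


def subsample_catalogue(
    tc: TokenizedCatalogue, n_max: int, rng: np.random.Generator
) -> TokenizedCatalogue:
    """Uniform subsample without replacement when the catalogue exceeds n_max."""
    if len(tc) <= n_max:
        return tc
    keep = rng.choice(len(tc), size=n_max, replace=False)
    return tc.subset(np.sort(keep))


def predict(
    catalogue: TokenizedCatalogue,
    model: MutationSetClassifier,
    seed: int = 0,
    n_repeats: int = 1,
):
    """Predict one tumour; catalogues above the mutation cap are subsampled.

    With ``n_repeats > 1`` returns (predictions, agreement) where agreement is
    the fraction of repeats matching the modal predicted class.
    """
    rng = np.random.default_rng(seed)
    labels = model.config.class_labels
    preds = []
    for _ in range(max(1, n_repeats)):
        sub = subsample_catalogue(catalogue, model.config.max_mutations, rng)
        logits, empty = model.logits(sub.tokens())
        preds.append(
            TumourPrediction.from_logits(
                catalogue.sample_id, logits, labels,
                true_label=catalogue.class_label, low_confidence=empty,
            )
        )
    if n_repeats <= 1:
        return preds[0]
    votes = np.array([p.predicted_index for p in preds])
    modal = np.bincount(votes).argmax()
    agreement = float(np.mean(votes == modal))
    return preds, agreement


# ---------------------------------------------------------------------------
# Checkpoints: weights (.npz) + self-describing JSON sidecar
# ---------------------------------------------------------------------------


def save_checkpoint(model: MutationSetClassifier, path_prefix: str | Path,
                    dictionaries=None) -> None:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(prefix) + ".npz", **model.params)
    sidecar = {"config": asdict(model.config)}
    if dictionaries is not None:
        sidecar["dictionaries"] = {
            name: json.loads(d.to_json()) for name, d in dictionaries.items()
        }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path_prefix: str | Path):
    """Returns (model, dictionaries-or-None); bit-exact reload."""
    from .encoding import TokenDictionary

    prefix = str(path_prefix)
    sidecar = json.loads(Path(prefix + ".json").read_text())
    cfg_dict = sidecar["config"]
    cfg_dict["modalities"] = tuple(cfg_dict["modalities"])
    config = ModelConfig(**cfg_dict)
    model = MutationSetClassifier(config, seed=0)
    with np.load(prefix + ".npz") as data:
        model.params = {k: data[k].copy() for k in data.files}
    dicts = None
    if "dictionaries" in sidecar:
        dicts = {
            name: TokenDictionary.from_json(json.dumps(obj))
            for name, obj in sidecar["dictionaries"].items()
        }
    return model, dicts
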