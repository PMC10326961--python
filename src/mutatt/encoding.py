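"""Tokenization of somatic mutations into (motif, position, annotation) triples.

Each mutation is described by three modalities:

* a 3-symbol *motif* over the alphabet of the four bases plus 21 mutation
  symbols (6 pyrimidine-normalized substitutions, 4 single-base deletions,
  4 insertions, 4 structural-variant breakpoints, 3 mobile-element
  insertions), e.g. ``A[C>T]G`` for an ApCpG>ApTpG substitution,
  ``C[del A][del A]`` for a diadenine deletion preceded by a cytosine, or
  ``[SV_del][C>G]T`` for a deletion breakpoint with a co-located C>G
  substitution followed by a thymine;
* a *position token* naming the 1-Mbp genomic bin, e.g. ``chr1_11`` for
  chr1:11,000,000-11,999,999;
* an *annotation token* from the 2 x 2 x 4 = 16 product of genic, exonic and
  strand-orientation attributes.

Token dictionaries map tokens to dense integer indices with reserved PAD and
UNK entries, giving one-hot-equivalent input for the model.
"""

from __future__ import annotations

import json
import logging
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import (
    TYPE_GROUPS,
    GeneModelIndex,
    ReferenceGenome,
    ReferenceWindow,
    SomaticVariant,
    VariantClass,
    reverse_complement,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Symbol alphabet
# ---------------------------------------------------------------------------

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTION_SYMBOLS = ("[C>A]", "[C>G]", "[C>T]", "[T>A]", "[T>C]", "[T>G]")
DELETION_SYMBOLS = tuple(f"[del {b}]" for b in BASES)
INSERTION_SYMBOLS = tuple(f"[ins {b}]" for b in BASES)
SV_BREAKPOINT_SYMBOLS = ("[SV_del]", "[SV_dup]", "[SV_inv]", "[SV_bnd]")
MEI_SYMBOLS = ("[MEI_L1]", "[MEI_Alu]", "[MEI_SVA]")

MUTATION_SYMBOLS = (
    SUBSTITUTION_SYMBOLS + DELETION_SYMBOLS + INSERTION_SYMBOLS
    + SV_BREAKPOINT_SYMBOLS + MEI_SYMBOLS
)  # 21 symbols
ALPHABET = BASES + MUTATION_SYMBOLS

_SV_SYMBOL = {
    VariantClass.SV_DEL: "[SV_del]",
    VariantClass.SV_DUP: "[SV_dup]",
    VariantClass.SV_INV: "[SV_inv]",
    VariantClass.SV_BND: "[SV_bnd]",
    VariantClass.MEI_L1: "[MEI_L1]",
    VariantClass.MEI_ALU: "[MEI_Alu]",
    VariantClass.MEI_SVA: "[MEI_SVA]",
}

_SYMBOL_RE = re.compile(r"\[[^\]]*\]|[ACGT]")

#: the 96 combinatorial SNV motifs, ordered 5' base x substitution x 3' base
ALL_SNV_MOTIFS = tuple(
    f"{l}{sub}{r}" for l in BASES for sub in SUBSTITUTION_SYMBOLS for r in BASES
)

STRAND_CLASSES = ("same", "opposite", "both", "intergenic")


class EncodingError(ValueError):
    """Mutation cannot be encoded (e.g. N in required context)."""


# ---------------------------------------------------------------------------
# Motif tokens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifToken:
    """Ordered triple of alphabet symbols; serializes by concatenation."""

    symbols: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.symbols) != 3:
            raise ValueError("motif must have exactly 3 symbols")
        for s in self.symbols:
            if s not in ALPHABET:
                raise ValueError(f"unknown symbol {s!r}")

    def __str__(self) -> str:
        return "".join(self.symbols)

    @classmethod
    def parse(cls, text: str) -> "MotifToken":
        symbols = _SYMBOL_RE.findall(text)
        if "".join(symbols) != text:
            raise ValueError(f"cannot parse motif {text!r}")
        return cls(tuple(symbols))

    @property
    def is_pure_reference(self) -> bool:
        return all(s in BASES for s in self.symbols)


def motif_mutation_group(motif: str) -> str:
    """Coarse type of a serialized motif: SNV/MNV/indel/SV/MEI/reference."""
    symbols = MotifToken.parse(motif).symbols
    n_sub = sum(s in SUBSTITUTION_SYMBOLS for s in symbols)
    if any(s in MEI_SYMBOLS for s in symbols):
        return "MEI"
    if any(s in SV_BREAKPOINT_SYMBOLS for s in symbols):
        return "SV"
    if any(s in DELETION_SYMBOLS or s in INSERTION_SYMBOLS for s in symbols):
        return "indel"
    if n_sub >= 2:
        return "MNV"
    if n_sub == 1:
        return "SNV"
    return "reference"


# ---------------------------------------------------------------------------
# Encoded mutations and catalogues
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncodedMutation:
    """One mutation as its three tokens plus bookkeeping fields.

    ``ref_context`` keeps the plain reference triplet at the encoded locus
    (in the orientation used by the motif) so that negative examples can be
    constructed from real mutated sites without re-querying the genome.
    ``pyrimidine_strand`` is '+' when the motif was taken from the forward
    strand and '-' when it was reverse-complemented.
    """

    motif: str
    position_token: str
    annotation: str
    var_class: VariantClass
    is_negative: bool = False
    ref_context: str | None = None
    pyrimidine_strand: str = "+"


@dataclass
class TumourCatalogue:
    """A labelled bag of encoded mutations for one sample (order-free)."""

    sample_id: str
    mutations: list[EncodedMutation]
    class_label: str | None = None


# ---------------------------------------------------------------------------
# Motif encoding
# ---------------------------------------------------------------------------


def _require_bases(*bases: str) -> None:
    for b in bases:
        if b not in BASES:
            raise EncodingError(f"context contains non-ACGT base {b!r}")


def _sub_symbol(ref: str, alt: str) -> str:
    sym = f"[{ref}>{alt}]"
    if sym not in SUBSTITUTION_SYMBOLS:
        raise EncodingError(f"invalid substitution {ref}>{alt}")
    return sym


def encode_motif(
    variant: SomaticVariant,
    context: ReferenceWindow,
    colocated: Mapping[int, str] | None = None,
) -> tuple[MotifToken, str, str]:
    """Encode one variant as a 3-symbol motif.

    Returns ``(motif, ref_context, pyrimidine_strand)`` where ``ref_context``
    is the plain reference triplet at the same slots/orientation and
    ``pyrimidine_strand`` the strand the motif was read from.

    ``colocated`` optionally maps 3' offsets (1 or 2) from an SV/MEI
    breakend to substitution symbols of co-located mutations, supporting
    composite motifs such as ``[SV_del][C>G]T``.
    """
    vc = variant.var_class
    if vc is VariantClass.SNV:
        return _encode_snv(variant, context)
    if vc is VariantClass.MNV:
        return _encode_mnv(variant, context)
    if vc is VariantClass.DEL:
        return _encode_deletion(variant, context)
    if vc is VariantClass.INS:
        return _encode_insertion(variant, context)
    return _encode_breakpoint(variant, context, colocated)


def _encode_snv(variant: SomaticVariant, context: ReferenceWindow) -> tuple[MotifToken, str, str]:
    ref, alt = variant.ref, variant.alt
    centre = context.base_at(variant.pos)
    if centre != ref:
        raise EncodingError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: context has {centre}, call has {ref}"
        )
    left = context.base_at(variant.pos - 1)
    right = context.base_at(variant.pos + 1)
    _require_bases(left, ref, right)
    if ref in PYRIMIDINES:
        motif = MotifToken((left, _sub_symbol(ref, alt), right))
        return motif, f"{left}{ref}{right}", "+"
    # purine reference base: reverse-complement the whole triple
    motif = MotifToken((_COMP[right], _sub_symbol(_COMP[ref], _COMP[alt]), _COMP[left]))
    return motif, f"{_COMP[right]}{_COMP[ref]}{_COMP[left]}", "-"


def _mnv_orientations(variant: SomaticVariant, context: ReferenceWindow):
    """Forward and reverse-complement candidate layouts for an MNV."""
    ref, alt = variant.ref, variant.alt
    n = len(ref)
    left = context.base_at(variant.pos - 1)
    right = context.base_at(variant.pos + n)
    fwd_subs = [(ref[i], alt[i]) for i in range(n)]
    rc_ref, rc_alt = reverse_complement(ref), reverse_complement(alt)
    rev_subs = [(rc_ref[i], rc_alt[i]) for i in range(n)]
    # 5' flank in reverse orientation is the complement of the forward 3' flank
    return [
        ("+", left, fwd_subs),
        ("-", _COMP[right], rev_subs),
    ]


def _mnv_layout(flank5: str, subs: list[tuple[str, str]]) -> tuple[str, ...]:
    symbols = [_sub_symbol(r, a) for r, a in subs[:3]]
    if len(subs) > 3:
        logger.warning("MNV longer than 3 bp truncated to its first 3 substitutions")
    if len(symbols) >= 3:
        return tuple(symbols[:3])
    _require_bases(flank5)
    return (flank5, *symbols)


def _encode_mnv(variant: SomaticVariant, context: ReferenceWindow) -> tuple[MotifToken, str, str]:
    candidates = []
    for strand, flank5, subs in _mnv_orientations(variant, context):
        if subs[0][0] in PYRIMIDINES:
            candidates.append((strand, flank5, subs))
    if not candidates:  # neither orientation starts with a pyrimidine reference base
        candidates = [_mnv_orientations(variant, context)[0]]
    encoded = []
    for strand, flank5, subs in candidates:
        layout = _mnv_layout(flank5, subs)
        ref_ctx = _mnv_ref_context(flank5, subs, layout)
        encoded.append((str(MotifToken(layout)), MotifToken(layout), ref_ctx, strand))
    encoded.sort(key=lambda t: t[0])  # lexicographic tie-break when both qualify
    _, motif, ref_ctx, strand = encoded[0]
    return motif, ref_ctx, strand


def _mnv_ref_context(flank5: str, subs: list[tuple[str, str]], layout: tuple[str, ...]) -> str:
    refs = [r for r, _ in subs]
    if len(layout) == 3 and layout[0] not in SUBSTITUTION_SYMBOLS:
        return flank5 + "".join(refs[:2])
    return "".join(refs[:3])


def _encode_deletion(variant: SomaticVariant, context: ReferenceWindow) -> tuple[MotifToken, str, str]:
    deleted = variant.deleted_bases()
    start = variant.deletion_start()
    k = min(len(deleted), 3)
    if len(deleted) > 3:
        logger.warning("deletion longer than 3 bp truncated to its first 3 bases")
    _require_bases(*deleted[:k])
    symbols = [f"[del {b}]" for b in deleted[:k]]
    if k == 1:
        left = context.base_at(start - 1)
        right = context.base_at(start + 1)
        _require_bases(left, right)
        return MotifToken((left, symbols[0], right)), f"{left}{deleted[0]}{right}", "+"
    if k == 2:
        left = context.base_at(start - 1)
        _require_bases(left)
        return MotifToken((left, *symbols)), f"{left}{deleted[0]}{deleted[1]}", "+"
    return MotifToken(tuple(symbols)), deleted[:3], "+"


def _encode_insertion(variant: SomaticVariant, context: ReferenceWindow) -> tuple[MotifToken, str, str]:
    inserted = variant.inserted_bases()
    anchor = variant.pos  # base 5' of the insertion point
    k = min(len(inserted), 3)
    if len(inserted) > 3:
        logger.warning("insertion longer than 3 bp truncated to its first 3 bases")
    _require_bases(*inserted[:k])
    symbols = [f"[ins {b}]" for b in inserted[:k]]
    left = context.base_at(anchor)
    if k == 1:
        right = context.base_at(anchor + 1)
        _require_bases(left, right)
        return MotifToken((left, symbols[0], right)), f"{left}{left}{right}", "+"
    if k == 2:
        _require_bases(left)
        return MotifToken((left, *symbols)), f"{left}{left}{left}", "+"
    return MotifToken(tuple(symbols)), left * 3, "+"


def _encode_breakpoint(
    variant: SomaticVariant,
    context: ReferenceWindow,
    colocated: Mapping[int, str] | None,
) -> tuple[MotifToken, str, str]:
    symbol = _SV_SYMBOL[variant.var_class]
    colocated = colocated or {}
    slots, refs = [symbol], []
    for offset in (1, 2):
        base = context.base_at(variant.pos + offset)
        _require_bases(base)
        refs.append(base)
        slots.append(colocated.get(offset, base))
    return MotifToken(tuple(slots)), "".join([refs[0], refs[0], refs[1]]), "+"


# ---------------------------------------------------------------------------
# Position and annotation tokens
# ---------------------------------------------------------------------------

MEGABASE = 1_000_000


def position_token(chrom: str, pos: int) -> str:
    """1-Mbp bin token: all positions in chrN:k*1e6..(k+1)*1e6-1 share 'chrN_k'."""
    if pos < 1:
        raise ValueError("pos must be >= 1")
    return f"{chrom}_{pos // MEGABASE}"


def annotation_token(
    genic: bool,
    exonic: bool,
    gene_strands: Iterable[str],
    pyrimidine_strand: str = "+",
) -> str:
    """Serialize the (genic, exonic, strand-class) annotation tuple.

    Strand class: 'same'/'opposite' compare the strand carrying the motif's
    pyrimidine reference base with the single overlapping gene's strand;
    'both' when genes on both strands overlap; 'intergenic' otherwise.
    """
    strands = set(gene_strands)
    if not genic:
        strand_class = "intergenic"
    elif strands == {"+", "-"}:
        strand_class = "both"
    elif len(strands) == 1:
        strand_class = "same" if next(iter(strands)) == pyrimidine_strand else "opposite"
    else:  # genic but strand unknown
        strand_class = "both" if len(strands) > 1 else "same"
    return serialize_annotation(genic, exonic, strand_class)


def serialize_annotation(genic: bool, exonic: bool, strand_class: str) -> str:
    if strand_class not in STRAND_CLASSES:
        raise ValueError(f"unknown strand class {strand_class!r}")
    return f"genic={int(genic)}|exonic={int(exonic)}|strand={strand_class}"


#: the full 16-token annotation space (2 x 2 x 4)
ALL_ANNOTATION_TOKENS = tuple(
    serialize_annotation(g, e, s)
    for g in (False, True)
    for e in (False, True)
    for s in STRAND_CLASSES
)


# ---------------------------------------------------------------------------
# Whole-variant encoding
# ---------------------------------------------------------------------------


def _context_flank(variant: SomaticVariant) -> int:
    if variant.var_class is VariantClass.SNV:
        return 1
    if variant.var_class is VariantClass.MNV:
        return len(variant.ref) + 1
    if variant.var_class is VariantClass.DEL:
        return len(variant.deleted_bases()) + 2
    if variant.var_class is VariantClass.INS:
        return 2
    return 2  # SV/MEI: two bases 3' of the breakend


def encode_variant(
    variant: SomaticVariant,
    genome: ReferenceGenome,
    gene_index: GeneModelIndex | None = None,
) -> EncodedMutation:
    """Full per-variant encoding: motif + position + annotation tokens."""
    window = genome.fetch_context(variant.chrom, variant.pos, _context_flank(variant))
    motif, ref_ctx, pyr_strand = encode_motif(variant, window)
    pos_tok = position_token(variant.chrom, variant.pos)
    if gene_index is not None:
        genic, exonic, strands = gene_index.annotate_position(variant.chrom, variant.pos)
    else:
        genic, exonic, strands = False, False, frozenset()
    ann = annotation_token(genic, exonic, strands, pyr_strand)
    return EncodedMutation(
        motif=str(motif),
        position_token=pos_tok,
        annotation=ann,
        var_class=variant.var_class,
        ref_context=ref_ctx,
        pyrimidine_strand=pyr_strand,
    )


def encode_catalogues(
    variants: Iterable[SomaticVariant],
    genome: ReferenceGenome,
    gene_index: GeneModelIndex | None = None,
    labels: Mapping[str, str] | None = None,
) -> tuple[list[TumourCatalogue], dict]:
    """Group variants by sample and encode them; unencodable ones are skipped.

    Returns the catalogues and a log dict with per-reason skip counts.
    """
    catalogues: dict[str, TumourCatalogue] = {}
    log = {"n_encoded": 0, "n_skipped": 0, "skip_reasons": {}}
    for v in variants:
        cat = catalogues.get(v.sample_id)
        if cat is None:
            label = labels.get(v.sample_id) if labels else None
            cat = catalogues[v.sample_id] = TumourCatalogue(v.sample_id, [], label)
        try:
            cat.mutations.append(encode_variant(v, genome, gene_index))
            log["n_encoded"] += 1
        except (EncodingError, LookupError) as exc:
            log["n_skipped"] += 1
            reason = type(exc).__name__
            log["skip_reasons"][reason] = log["skip_reasons"].get(reason, 0) + 1
            logger.warning("skipping %s:%d (%s)", v.chrom, v.pos, exc)
    return list(catalogues.values()), log


# ---------------------------------------------------------------------------
# Token dictionaries
# ---------------------------------------------------------------------------

PAD, UNK = "<PAD>", "<UNK>"
PAD_INDEX, UNK_INDEX = 0, 1


@dataclass
class TokenDictionary:
    """Dense token->index map with reserved PAD (0) and UNK (1) entries."""

    modality: str
    token_to_index: dict[str, int] = field(default_factory=dict)
    unk_count: int = 0

    @classmethod
    def from_tokens(cls, modality: str, tokens: Iterable[str]) -> "TokenDictionary":
        mapping = {PAD: PAD_INDEX, UNK: UNK_INDEX}
        for tok in sorted(set(tokens)):
            mapping[tok] = len(mapping)
        return cls(modality, mapping)

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def n_real_tokens(self) -> int:
        return len(self.token_to_index) - 2

    def index(self, token: str) -> int:
        idx = self.token_to_index.get(token)
        if idx is None:
            self.unk_count += 1
            return UNK_INDEX
        return idx

    def token(self, index: int) -> str:
        try:
            return self._index_to_token[index]
        except AttributeError:
            object.__setattr__(self, "_index_to_token",
                               {i: t for t, i in self.token_to_index.items()})
            return self._index_to_token[index]

    def to_json(self) -> str:
        return json.dumps({"modality": self.modality, "tokens": self.token_to_index})

    @classmethod
    def from_json(cls, text: str) -> "TokenDictionary":
        obj = json.loads(text)
        return cls(obj["modality"], {str(k): int(v) for k, v in obj["tokens"].items()})


def build_dictionaries(
    catalogues: Sequence[TumourCatalogue],
    mode: str = "observed",
) -> dict[str, TokenDictionary]:
    """Build the three modality dictionaries from a corpus.

    ``observed`` keeps exactly the distinct tokens seen; ``enumerate_snv``
    additionally pre-seeds all 96 combinatorial SNV motifs. The annotation
    dictionary is always the full 16-token product space.
    """
    if not catalogues or all(not c.mutations for c in catalogues):
        raise ValueError("cannot build dictionaries from an empty corpus")
    motifs: set[str] = set(ALL_SNV_MOTIFS) if mode == "enumerate_snv" else set()
    positions: set[str] = set()
    for cat in catalogues:
        for m in cat.mutations:
            motifs.add(m.motif)
            positions.add(m.position_token)
    return {
        "motif": TokenDictionary.from_tokens("motif", motifs),
        "position": TokenDictionary.from_tokens("position", positions),
        "annotation": TokenDictionary.from_tokens("annotation", ALL_ANNOTATION_TOKENS),
    }


@dataclass
class TokenizedCatalogue:
    """Integer-indexed catalogue ready for the model (one index per modality)."""

    sample_id: str
    motif_idx: np.ndarray
    position_idx: np.ndarray
    annotation_idx: np.ndarray
    is_negative: np.ndarray
    class_label: str | None = None

    def __len__(self) -> int:
        return len(self.motif_idx)

    def tokens(self) -> dict[str, np.ndarray]:
        return {
            "motif": self.motif_idx,
            "position": self.position_idx,
            "annotation": self.annotation_idx,
        }

    def subset(self, indices: np.ndarray) -> "TokenizedCatalogue":
        return TokenizedCatalogue(
            self.sample_id,
            self.motif_idx[indices],
            self.position_idx[indices],
            self.annotation_idx[indices],
            self.is_negative[indices],
            self.class_label,
        )


def tokenize_catalogue(
    catalogue: TumourCatalogue, dicts: Mapping[str, TokenDictionary]
) -> TokenizedCatalogue:
    """Map a catalogue to integer triples; unseen tokens become UNK (counted)."""
    motif_d, pos_d, ann_d = dicts["motif"], dicts["position"], dicts["annotation"]
    return TokenizedCatalogue(
        catalogue.sample_id,
        np.array([motif_d.index(m.motif) for m in catalogue.mutations], dtype=np.int64),
        np.array([pos_d.index(m.position_token) for m in catalogue.mutations], dtype=np.int64),
        np.array([ann_d.index(m.annotation) for m in catalogue.mutations], dtype=np.int64),
        np.array([m.is_negative for m in catalogue.mutations], dtype=bool),
        catalogue.class_label,
    )


# ---------------------------------------------------------------------------
# Negative examples
# ---------------------------------------------------------------------------


def inject_negatives(
    catalogues: Sequence[TumourCatalogue], seed: int
) -> list[TumourCatalogue]:
    """Add non-mutation events as negative examples to every tumour.

    For each mutation-type group, the dataset-wide median per-tumour count is
    added to every tumour as negatives: real mutated positions sampled from
    *other* tumours, encoded as the pure reference triplet (no mutation
    symbols) at the same position/annotation tokens. Fractional medians are
    rounded half-up.
    """
    if len(catalogues) < 2:
        raise ValueError("negative injection needs at least 2 tumours")
    rng = np.random.default_rng(seed)
    groups = sorted(set(TYPE_GROUPS.values()))
    counts = {
        g: [sum(1 for m in c.mutations if TYPE_GROUPS[m.var_class] == g and not m.is_negative)
            for c in catalogues]
        for g in groups
    }
    medians = {g: int(statistics.median(v) + 0.5) for g, v in counts.items()}

    donors_by_group: dict[str, list[tuple[int, EncodedMutation]]] = {g: [] for g in groups}
    for ci, cat in enumerate(catalogues):
        for m in cat.mutations:
            if not m.is_negative and m.ref_context is not None:
                donors_by_group[TYPE_GROUPS[m.var_class]].append((ci, m))

    augmented = []
    for ci, cat in enumerate(catalogues):
        new_mutations = list(cat.mutations)
        for g in groups:
            need = medians[g]
            if need == 0:
                continue
            pool = [dm for dci, dm in donors_by_group[g] if dci != ci]
            if not pool:
                raise ValueError(f"no donor mutations of type {g} outside tumour {cat.sample_id}")
            picks = rng.choice(len(pool), size=need, replace=len(pool) < need)
            for p in np.atleast_1d(picks):
                donor = pool[int(p)]
                new_mutations.append(
                    EncodedMutation(
                        motif=donor.ref_context,
                        position_token=donor.position_token,
                        annotation=donor.annotation,
                        var_class=donor.var_class,
                        is_negative=True,
                        ref_context=donor.ref_context,
                        pyrimidine_strand=donor.pyrimidine_strand,
                    )
                )
        augmented.append(TumourCatalogue(cat.sample_id, new_mutations, cat.class_label))
    return augmented


# ---------------------------------------------------------------------------
# SNV150 baseline featurization
# ---------------------------------------------------------------------------

_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTION_SYMBOLS)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SNV150_BLOCKS = (6, 48, 96)  # context-free, one-flank (5' 4x6 + 3' 6x4), two-flank


def snv150_features(catalogue: TumourCatalogue) -> np.ndarray:
    """150-dimensional SNV count featurization (aggregated-count baseline input).

    Concatenates 6 context-free substitution counts, 48 one-flank counts
    (4x6 with the 5' base, then 6x4 with the 3' base) and 96 two-flank
    counts. Every SNV increments one bin in the 6-block, two bins in the
    48-block (one per flank) and one in the 96-block.
    """
    vec = np.zeros(150, dtype=np.int64)
    for m in catalogue.mutations:
        if m.is_negative or m.var_class is not VariantClass.SNV:
            continue
        left, sub, right = MotifToken.parse(m.motif).symbols
        s, l, r = _SUB_INDEX[sub], _BASE_INDEX[left], _BASE_INDEX[right]
        vec[s] += 1
        vec[6 + l * 6 + s] += 1
        vec[6 + 24 + s * 4 + r] += 1
        vec[54 + l * 24 + s * 4 + r] += 1
    return vec


# ---------------------------------------------------------------------------
# Catalogue / dictionary persistence (bit-exact TSV + JSON round trips)
# ---------------------------------------------------------------------------


def write_catalogue_tsv(catalogue: TumourCatalogue, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": catalogue.sample_id,
            "motif": [m.motif for m in catalogue.mutations],
            "position_token": [m.position_token for m in catalogue.mutations],
            "annotation": [m.annotation for m in catalogue.mutations],
            "var_class": [m.var_class.value for m in catalogue.mutations],
            "is_negative": [int(m.is_negative) for m in catalogue.mutations],
            "ref_context": [m.ref_context or "" for m in catalogue.mutations],
            "pyrimidine_strand": [m.pyrimidine_strand for m in catalogue.mutations],
            "class_label": catalogue.class_label or "",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalogue_tsv(path: str | Path) -> TumourCatalogue:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mutations = [
        EncodedMutation(
            motif=row.motif,
            position_token=row.position_token,
            annotation=row.annotation,
            var_class=VariantClass(row.var_class),
            is_negative=bool(int(row.is_negative)),
            ref_context=row.ref_context or None,
            pyrimidine_strand=row.pyrimidine_strand,
        )
        for row in df.itertuples(index=False)
    ]
    sample_id = df["sample_id"].iloc[0] if len(df) else ""
    label = df["class_label"].iloc[0] if len(df) and df["class_label"].iloc[0] else None
    return TumourCatalogue(sample_id, mutations, label)


def save_dictionaries(dicts: Mapping[str, TokenDictionary], path: str | Path) -> None:
    payload = {name: json.loads(d.to_json()) for name, d in dicts.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_dictionaries(path: str | Path) -> dict[str, TokenDictionary]:
    payload = json.loads(Path(path).read_text())
    return {name: TokenDictionary.from_json(json.dumps(obj)) for name, obj in payload.items()}
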