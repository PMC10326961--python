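"""Seeded simulator of labelled tumour cohorts on a toy genome.

Each class is described by a :class:`SyntheticClassSpec`: a trinucleotide
substitution spectrum on the 96-category simplex, fractions of MNVs, indels,
SVs and mobile-element insertions, a preference distribution over the toy
genome's 1-Mb bins, and a log-normal mutation-burden distribution. Variants
are placed so that the reference context at each site matches the drawn
category exactly: the genome is pre-indexed by (1-Mb bin, canonical
pyrimidine-centred trinucleotide) and positions are drawn uniformly within
the matching group, which realizes context-conditional placement in O(1)
per draw (bounded-retry fallbacks cover contexts absent from a bin).

Everything is deterministic under the seed; cohorts are written as
uncompressed per-tumour VCFs plus a labels TSV, alongside the FASTA (+index)
and BED gene model of the toy genome, so the entire pipeline can run from
files with no external data. The default four-class presets loosely mimic
UV-exposed (C>T at dipyrimidines plus CC>TT doublets), smoking-related
(C>A-rich), mismatch-repair-deficient (indel-rich) and SV-rich profiles --
test material only, with no claim of biological fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .encoding import ALL_SNV_MOTIFS, BASES, SUBSTITUTION_SYMBOLS
from .variants import SomaticVariant, VariantClass

_BASE_CODE = {b: i for i, b in enumerate(BASES)}  # A0 C1 G2 T3
_PYR_CODES = (1, 3)  # C, T
_SUB_ALTS = {"C": ("A", "G", "T"), "T": ("A", "C", "G")}

#: canonical 96 SNV categories: (5' base, substitution, 3' base), motif order
SNV_CATEGORIES = tuple(
    (l, sub, r) for l in BASES for sub in SUBSTITUTION_SYMBOLS for r in BASES
)


def _category_context_index(cat: tuple[str, str, str]) -> int:
    """32-way canonical context index (5' x pyrimidine-centre x 3')."""
    l, sub, r = cat
    centre = sub[1]  # '[C>T]' -> 'C'
    return _BASE_CODE[l] * 8 + (0 if centre == "C" else 1) * 4 + _BASE_CODE[r]


# ---------------------------------------------------------------------------
# Class specifications
# ---------------------------------------------------------------------------


@dataclass
class SyntheticClassSpec:
    name: str
    snv_spectrum: np.ndarray  # 96-simplex over SNV_CATEGORIES
    mnv_fraction: float = 0.0
    indel_fraction: float = 0.0
    sv_fraction: float = 0.0
    mei_fraction: float = 0.0
    position_preference: np.ndarray | None = None  # over genome 1-Mb bins
    burden_log_mean: float = np.log(500.0)
    burden_log_sigma: float = 0.3
    mnv_doublets: tuple[tuple[str, str], ...] = (("CC", "TT"),)

    def __post_init__(self) -> None:
        self.snv_spectrum = np.asarray(self.snv_spectrum, dtype=float)
        if self.snv_spectrum.shape != (96,) or (self.snv_spectrum < 0).any():
            raise ValueError("snv_spectrum must be a non-negative 96-vector")
        total = self.snv_spectrum.sum()
        if total <= 0:
            raise ValueError("snv_spectrum must not be all zero")
        self.snv_spectrum = self.snv_spectrum / total
        fracs = (self.mnv_fraction, self.indel_fraction, self.sv_fraction, self.mei_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("type fractions must lie in [0,1] and sum with the SNV fraction to 1")
        if self.position_preference is not None:
            pref = np.asarray(self.position_preference, dtype=float)
            if (pref < 0).any() or pref.sum() <= 0:
                raise ValueError("position_preference must be non-negative and not all zero")
            self.position_preference = pref / pref.sum()

    @property
    def snv_fraction(self) -> float:
        return 1.0 - self.mnv_fraction - self.indel_fraction - self.sv_fraction - self.mei_fraction

    def to_jsonable(self) -> dict:
        return {
            "name": self.name,
            "snv_spectrum": self.snv_spectrum.tolist(),
            "mnv_fraction": self.mnv_fraction,
            "indel_fraction": self.indel_fraction,
            "sv_fraction": self.sv_fraction,
            "mei_fraction": self.mei_fraction,
            "position_preference": None if self.position_preference is None
            else self.position_preference.tolist(),
            "burden_log_mean": self.burden_log_mean,
            "burden_log_sigma": self.burden_log_sigma,
            "mnv_doublets": [list(d) for d in self.mnv_doublets],
        }


def spectrum_from_weights(weights: Mapping[tuple[str, str, str] | str, float]) -> np.ndarray:
    """Build a 96-spectrum from sparse weights keyed by category or motif string."""
    spec = np.zeros(96)
    motif_index = {m: i for i, m in enumerate(ALL_SNV_MOTIFS)}
    for key, w in weights.items():
        if isinstance(key, str):
            spec[motif_index[key]] += w
        else:
            l, sub, r = key
            spec[motif_index[f"{l}{sub}{r}"]] += w
    return spec


def _uniform_spectrum() -> np.ndarray:
    return np.full(96, 1.0 / 96)


def default_class_specs(n_bins: int, burden_log_mean: float = np.log(500.0)) -> list[SyntheticClassSpec]:
    """Four desk-scale presets with distinct spectra, type mixes and bin preferences."""
    uv = np.zeros(96)
    smoke = np.zeros(96)
    msi = np.zeros(96)
    for i, (l, sub, r) in enumerate(SNV_CATEGORIES):
        if sub == "[C>T]" and l in ("C", "T"):  # dipyrimidine C>T
            uv[i] = 4.0
        elif sub == "[C>T]":
            uv[i] = 0.5
        if sub == "[C>A]":
            smoke[i] = 3.0
        elif sub == "[T>A]":
            smoke[i] = 0.5
        if sub in ("[C>T]", "[T>C]"):
            msi[i] = 1.0
    uv[uv == 0] = 0.05
    smoke[smoke == 0] = 0.05
    msi[msi == 0] = 0.2

    def pref(phase: int) -> np.ndarray:
        w = np.ones(n_bins)
        w[phase::4] = 3.0
        return w

    return [
        SyntheticClassSpec("uv_like", uv, mnv_fraction=0.05, indel_fraction=0.02,
                           position_preference=pref(0), burden_log_mean=burden_log_mean),
        SyntheticClassSpec("smoking_like", smoke, indel_fraction=0.03,
                           position_preference=pref(1), burden_log_mean=burden_log_mean),
        SyntheticClassSpec("msi_like", msi, indel_fraction=0.30,
                           position_preference=pref(2), burden_log_mean=burden_log_mean),
        SyntheticClassSpec("sv_rich", _uniform_spectrum(), sv_fraction=0.20, mei_fraction=0.02,
                           position_preference=pref(3), burden_log_mean=burden_log_mean),
    ]


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


@dataclass
class ToyGenome:
    fasta_path: Path
    genes_bed: Path
    exons_bed: Path
    contigs: dict[str, int]
    sequences: dict[str, str] = field(repr=False, default_factory=dict)

    @property
    def n_bins(self) -> int:
        return sum(-(-length // 1_000_000) for length in self.contigs.values())

    def bin_ranges(self) -> list[tuple[str, int, int]]:
        """Global bin list as (chrom, start, end) 1-based inclusive."""
        out = []
        for chrom, length in self.contigs.items():
            for b in range(-(-length // 1_000_000)):
                out.append((chrom, b * 1_000_000 + 1, min((b + 1) * 1_000_000, length)))
        return out


def make_toy_genome(
    out_dir: str | Path,
    n_contigs: int = 2,
    contig_length: int = 3_000_000,
    gene_density: float = 0.3,
    seed: int = 0,
) -> ToyGenome:
    """Random reference + gene model, deterministic under the seed.

    Writes FASTA (with .fai index), a BED6 gene model and a BED6 exon model.
    Contig lengths of at least 1 Mb are recommended so several position bins
    exist.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    contigs = {f"chr{i + 1}": contig_length for i in range(n_contigs)}
    sequences = {}
    fasta_path = out_dir / "toy_genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom, length in contigs.items():
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
            sequences[chrom] = seq
            fh.write(f">{chrom}\n")
            for i in range(0, length, 80):
                fh.write(seq[i: i + 80] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(fasta_path))  # writes toy_genome.fa.fai

    genes_bed = out_dir / "toy_genes.bed"
    exons_bed = out_dir / "toy_exons.bed"
    gene_id = 0
    with open(genes_bed, "w") as gfh, open(exons_bed, "w") as efh:
        for chrom, length in contigs.items():
            covered = 0
            cursor = 0
            while gene_density > 0 and covered < gene_density * length and cursor < length - 10_000:
                gap = int(rng.integers(1_000, 50_000))
                glen = int(rng.integers(5_000, 80_000))
                start = cursor + gap
                end = min(start + glen, length)
                if end - start < 1_000:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                gene_id += 1
                gfh.write(f"{chrom}\t{start}\t{end}\tgene{gene_id}\t0\t{strand}\n")
                n_exons = int(rng.integers(1, 6))
                for estart in sorted(rng.integers(start, end - 100, size=n_exons).tolist()):
                    eend = min(estart + int(rng.integers(50, 400)), end)
                    efh.write(f"{chrom}\t{estart}\t{eend}\tgene{gene_id}_exon\t0\t{strand}\n")
                covered += end - start
                cursor = end
    return ToyGenome(fasta_path, genes_bed, exons_bed, contigs, sequences)


# ---------------------------------------------------------------------------
# Context index and cohort simulation
# ---------------------------------------------------------------------------


class _ContextIndex:
    """Positions grouped by (global 1-Mb bin, canonical trinucleotide context)."""

    def __init__(self, genome: ToyGenome):
        self.bins = genome.bin_ranges()
        self._groups: dict[tuple[int, int], np.ndarray] = {}
        self._orient: dict[str, np.ndarray] = {}
        bin_offset = 0
        for chrom, length in genome.contigs.items():
            seq = genome.sequences[chrom]
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.full(256, -1, dtype=np.int8)
            for b, c in _BASE_CODE.items():
                lut[ord(b)] = c
            codes = lut[codes]
            # centre positions 3..length-2 (1-based) leave room for SV context
            centre = np.arange(3, length - 1)  # 0-based centre indices
            l, c, r = codes[centre - 1], codes[centre], codes[centre + 1]
            is_pyr = (c == 1) | (c == 3)
            cl = np.where(is_pyr, l, 3 - r)
            cc = np.where(is_pyr, c, 3 - c)
            cr = np.where(is_pyr, r, 3 - l)
            ctx = cl * 8 + np.where(cc == 1, 0, 1) * 4 + cr
            self._orient[chrom] = is_pyr
            n_bins_here = -(-length // 1_000_000)
            gbin = bin_offset + (centre + 1) // 1_000_000  # bin of the 1-based position
            key = gbin.astype(np.int64) * 32 + ctx
            order = np.argsort(key, kind="stable")
            sorted_key = key[order]
            sorted_pos = centre[order] + 1  # back to 1-based
            uniq, starts = np.unique(sorted_key, return_index=True)
            ends = np.append(starts[1:], len(sorted_key))
            for u, s, e in zip(uniq, starts, ends):
                self._groups[(int(u) // 32, int(u) % 32)] = sorted_pos[s:e]
            bin_offset += n_bins_here
        # per-chrom pyrimidine orientation lookup needs global positions
        self._genome = genome

    def sample_position(self, gbin: int, ctx: int, rng: np.random.Generator) -> tuple[str, int] | None:
        group = self._groups.get((gbin, ctx))
        if group is None or len(group) == 0:
            return None
        pos = int(group[rng.integers(0, len(group))])
        chrom = self.bins[gbin][0]
        return chrom, pos

    def is_pyrimidine_site(self, chrom: str, pos: int) -> bool:
        # orientation array is aligned with 0-based centres starting at 3
        return bool(self._orient[chrom][pos - 4])


@dataclass
class SyntheticCohort:
    genome: ToyGenome
    labels: dict[str, str]
    vcf_paths: dict[str, Path]
    labels_tsv: Path
    spec_json: Path


def simulate_cohort(
    specs: Sequence[SyntheticClassSpec],
    n_per_class: int,
    genome: ToyGenome,
    out_dir: str | Path,
    seed: int = 0,
    burdens: Mapping[str, int] | None = None,
) -> SyntheticCohort:
    """Simulate a labelled cohort; writes per-tumour VCFs and a labels TSV.

    Per tumour: draw the burden from the class's log-normal (unless
    ``burdens`` fixes it per sample), then for each mutation draw the type
    from the class fractions, the SNV category from the class spectrum and
    the genomic bin from the class preference, placing the variant at a
    reference position whose context matches.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    index = _ContextIndex(genome)
    n_bins = genome.n_bins

    labels: dict[str, str] = {}
    vcf_paths: dict[str, Path] = {}
    for spec in specs:
        pref = spec.position_preference
        if pref is None:
            pref = np.full(n_bins, 1.0 / n_bins)
        if len(pref) != n_bins:
            raise ValueError(f"position preference of {spec.name} has {len(pref)} bins, genome has {n_bins}")
        for t in range(n_per_class):
            sample_id = f"{spec.name}_{t:03d}"
            labels[sample_id] = spec.name
            if burdens and sample_id in burdens:
                burden = int(burdens[sample_id])
            else:
                burden = max(1, int(round(rng.lognormal(spec.burden_log_mean, spec.burden_log_sigma))))
            variants = _simulate_tumour(sample_id, spec, burden, pref, genome, index, rng)
            path = out_dir / f"{sample_id}.vcf"
            _write_vcf(variants, genome, path)
            vcf_paths[sample_id] = path

    labels_tsv = out_dir / "labels.tsv"
    with open(labels_tsv, "w") as fh:
        fh.write("sample_id\tclass_label\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")
    spec_json = out_dir / "class_specs.json"
    spec_json.write_text(json.dumps([s.to_jsonable() for s in specs], indent=1))
    return SyntheticCohort(genome, labels, vcf_paths, labels_tsv, spec_json)


def _simulate_tumour(sample_id, spec, burden, pref, genome, index, rng) -> list[SomaticVariant]:
    type_probs = np.array([
        spec.snv_fraction, spec.mnv_fraction, spec.indel_fraction,
        spec.sv_fraction, spec.mei_fraction,
    ])
    type_probs = type_probs / type_probs.sum()
    variants = []
    for _ in range(burden):
        kind = rng.choice(5, p=type_probs)
        if kind == 0:
            variants.append(_simulate_snv(sample_id, spec, pref, index, rng))
        elif kind == 1:
            variants.append(_simulate_mnv(sample_id, spec, pref, genome, index, rng))
        elif kind == 2:
            variants.append(_simulate_indel(sample_id, pref, genome, index, rng))
        elif kind == 3:
            variants.append(_simulate_sv(sample_id, pref, genome, index, rng))
        else:
            variants.append(_simulate_mei(sample_id, pref, index, rng))
    return variants


def _draw_bin(pref: np.ndarray, rng) -> int:
    return int(rng.choice(len(pref), p=pref))


def _simulate_snv(sample_id, spec, pref, index, rng) -> SomaticVariant:
    for _ in range(200):
        cat_i = int(rng.choice(96, p=spec.snv_spectrum))
        cat = SNV_CATEGORIES[cat_i]
        ctx = _category_context_index(cat)
        for _ in range(20):  # redraw the bin if this context is missing there
            hit = index.sample_position(_draw_bin(pref, rng), ctx, rng)
            if hit is not None:
                chrom, pos = hit
                _, sub, _ = cat
                pyr_ref, pyr_alt = sub[1], sub[3]  # '[C>T]' -> C, T
                if index.is_pyrimidine_site(chrom, pos):
                    ref, alt = pyr_ref, pyr_alt
                else:
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    ref, alt = comp[pyr_ref], comp[pyr_alt]
                return SomaticVariant(sample_id, chrom, pos, ref, alt, VariantClass.SNV)
    raise RuntimeError("could not place an SNV matching the requested contexts")


def _random_position(pref, index, rng) -> tuple[str, int]:
    gbin = _draw_bin(pref, rng)
    chrom, start, end = index.bins[gbin]
    return chrom, int(rng.integers(start + 3, end - 3))


def _simulate_mnv(sample_id, spec, pref, genome, index, rng) -> SomaticVariant:
    ref2, alt2 = spec.mnv_doublets[int(rng.integers(0, len(spec.mnv_doublets)))]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc_ref2 = "".join(comp[b] for b in reversed(ref2))
    rc_alt2 = "".join(comp[b] for b in reversed(alt2))
    for _ in range(500):
        chrom, pos = _random_position(pref, index, rng)
        dinuc = genome.sequences[chrom][pos - 1: pos + 1]
        if dinuc == ref2:
            return SomaticVariant(sample_id, chrom, pos, ref2, alt2, VariantClass.MNV)
        if dinuc == rc_ref2:
            return SomaticVariant(sample_id, chrom, pos, rc_ref2, rc_alt2, VariantClass.MNV)
    # fall back to an arbitrary non-identical doublet at the last position
    ref = dinuc
    alt = "".join(comp[b] for b in ref)
    return SomaticVariant(sample_id, chrom, pos, ref, alt, VariantClass.MNV)


def _simulate_indel(sample_id, pref, genome, index, rng) -> SomaticVariant:
    chrom, pos = _random_position(pref, index, rng)
    seq = genome.sequences[chrom]
    anchor = seq[pos - 1]
    if rng.random() < 0.5:  # 1-bp deletion, left-anchored VCF convention
        return SomaticVariant(sample_id, chrom, pos, anchor + seq[pos], anchor, VariantClass.DEL)
    inserted = "ACGT"[rng.integers(0, 4)]
    return SomaticVariant(sample_id, chrom, pos, anchor, anchor + inserted, VariantClass.INS)


_SV_ALTS = (
    ("<DEL>", VariantClass.SV_DEL),
    ("<DUP>", VariantClass.SV_DUP),
    ("<INV>", VariantClass.SV_INV),
    (None, VariantClass.SV_BND),
)


def _simulate_sv(sample_id, pref, genome, index, rng) -> SomaticVariant:
    chrom, pos = _random_position(pref, index, rng)
    alt, vc = _SV_ALTS[int(rng.integers(0, 4))]
    if alt is None:  # breakend notation
        mate_chrom, mate_pos = _random_position(pref, index, rng)
        alt = f"N]{mate_chrom}:{mate_pos}]"
    return SomaticVariant(sample_id, chrom, pos, genome.sequences[chrom][pos - 1], alt, vc)


_MEI_ALTS = (
    ("<INS:ME:L1>", VariantClass.MEI_L1),
    ("<INS:ME:ALU>", VariantClass.MEI_ALU),
    ("<INS:ME:SVA>", VariantClass.MEI_SVA),
)


def _simulate_mei(sample_id, pref, index, rng) -> SomaticVariant:
    chrom, pos = _random_position(pref, index, rng)
    alt, vc = _MEI_ALTS[int(rng.integers(0, 3))]
    return SomaticVariant(sample_id, chrom, pos, "N", alt, vc)


def _write_vcf(variants: Sequence[SomaticVariant], genome: ToyGenome, path: Path) -> None:
    sv_info = {
        VariantClass.SV_DEL: "SVTYPE=DEL;END={end}",
        VariantClass.SV_DUP: "SVTYPE=DUP;END={end}",
        VariantClass.SV_INV: "SVTYPE=INV;END={end}",
        VariantClass.SV_BND: "SVTYPE=BND",
        VariantClass.MEI_L1: "SVTYPE=INS",
        VariantClass.MEI_ALU: "SVTYPE=INS",
        VariantClass.MEI_SVA: "SVTYPE=INS",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            info = sv_info.get(v.var_class, ".").format(end=v.pos + 10_000)
            ref = v.ref if v.ref != "N" else genome.sequences[v.chrom][v.pos - 1]
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{ref}\t{v.alt}\t.\tPASS\t{info}\n")
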