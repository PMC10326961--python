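"""Somatic variant input/output and genomic context lookups.

Variants arrive as VCF 4.x, MAF (TCGA MC3 style) or a minimal five-column
TSV. Every record becomes a :class:`SomaticVariant` with a variant class
inferred from the alleles (SNV/MNV/indel) or from structural-variant
conventions (symbolic ALT alleles, breakend notation, SVTYPE). Reference
sequence context comes from an indexed FASTA via pyfaidx, and genic/exonic/
strand annotation from an interval index built from BED6 or GFF3 gene models.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted on load.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed record in a variant file; message names the record."""


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    MNV = "MNV"
    DEL = "DEL"
    INS = "INS"
    SV_DEL = "SV_DEL"
    SV_DUP = "SV_DUP"
    SV_INV = "SV_INV"
    SV_BND = "SV_BND"
    MEI_L1 = "MEI_L1"
    MEI_ALU = "MEI_ALU"
    MEI_SVA = "MEI_SVA"

    def __str__(self) -> str:  # plain value in TSV output
        return self.value


#: coarse groups used for negative-example medians and reporting
TYPE_GROUPS = {
    VariantClass.SNV: "SNV",
    VariantClass.MNV: "MNV",
    VariantClass.DEL: "indel",
    VariantClass.INS: "indel",
    VariantClass.SV_DEL: "SV",
    VariantClass.SV_DUP: "SV",
    VariantClass.SV_INV: "SV",
    VariantClass.SV_BND: "SV",
    VariantClass.MEI_L1: "MEI",
    VariantClass.MEI_ALU: "MEI",
    VariantClass.MEI_SVA: "MEI",
}

_SV_CLASSES = frozenset(
    {
        VariantClass.SV_DEL,
        VariantClass.SV_DUP,
        VariantClass.SV_INV,
        VariantClass.SV_BND,
        VariantClass.MEI_L1,
        VariantClass.MEI_ALU,
        VariantClass.MEI_SVA,
    }
)

_ALLELE_RE = re.compile(r"^[ACGTN]+$")
_SIMPLE_ALLELE_RE = re.compile(r"^[ACGTNacgtn-]+$")
_BND_RE = re.compile(r"[\[\]]")


def _norm_allele(allele: str) -> str:
    """Uppercase plain sequence alleles; leave symbolic/breakend alleles as-is."""
    return allele.upper() if _SIMPLE_ALLELE_RE.match(allele) else allele


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic variant call, 1-based coordinates, VCF-style alleles."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: VariantClass
    flagged: bool = False  # e.g. contig absent from the reference

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        vc = self.var_class
        if vc is VariantClass.SNV:
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"invalid SNV alleles {self.ref}>{self.alt}")
        elif vc is VariantClass.MNV:
            if len(self.ref) != len(self.alt) or len(self.ref) < 2:
                raise ValueError(f"invalid MNV alleles {self.ref}>{self.alt}")
        elif vc in (VariantClass.DEL, VariantClass.INS):
            longer_ref = len(self.ref) > len(self.alt)
            if vc is VariantClass.DEL and not (longer_ref or self.alt == "-"):
                raise ValueError(f"invalid DEL alleles {self.ref}>{self.alt}")
            if vc is VariantClass.INS and not (len(self.alt) > len(self.ref) or self.ref == "-"):
                raise ValueError(f"invalid INS alleles {self.ref}>{self.alt}")

    # -- indel helpers honouring both VCF (anchored) and MAF ("-") styles --

    def deleted_bases(self) -> str:
        if self.var_class is not VariantClass.DEL:
            raise ValueError("not a deletion")
        if self.alt == "-":
            return self.ref
        return self.ref[len(self.alt):]

    def deletion_start(self) -> int:
        """1-based position of the first deleted base."""
        if self.alt == "-":
            return self.pos
        return self.pos + len(self.alt)

    def inserted_bases(self) -> str:
        if self.var_class is not VariantClass.INS:
            raise ValueError("not an insertion")
        if self.ref == "-":
            return self.alt
        return self.alt[len(self.ref):]


@dataclass
class ParseLog:
    """Counters collected while reading a variant file."""

    n_records: int = 0
    n_variants: int = 0
    skipped: Counter = field(default_factory=Counter)
    flagged_contigs: Counter = field(default_factory=Counter)


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Normalize 'chr' prefixes to a single configured style ('chr' or 'plain')."""
    base = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{base}" if style == "chr" else base


def classify_alleles(ref: str, alt: str, svtype: str | None = None) -> VariantClass | None:
    """Infer the variant class from REF/ALT (and SVTYPE for symbolic records).

    Returns None for unrepresentable records (unknown SVTYPE), which callers
    should skip with a logged warning.
    """
    alt_u = alt.upper()
    if alt_u.startswith("<"):
        if "DEL" in alt_u and "ME" not in alt_u:
            return VariantClass.SV_DEL
        if "DUP" in alt_u:
            return VariantClass.SV_DUP
        if "INV" in alt_u:
            return VariantClass.SV_INV
        if "INS:ME" in alt_u or "INS_ME" in alt_u:
            if "L1" in alt_u or "LINE" in alt_u:
                return VariantClass.MEI_L1
            if "ALU" in alt_u:
                return VariantClass.MEI_ALU
            if "SVA" in alt_u:
                return VariantClass.MEI_SVA
        return None
    if _BND_RE.search(alt_u):
        return VariantClass.SV_BND
    if svtype:
        sv = svtype.upper()
        mapping = {
            "DEL": VariantClass.SV_DEL,
            "DUP": VariantClass.SV_DUP,
            "INV": VariantClass.SV_INV,
            "BND": VariantClass.SV_BND,
            "TRA": VariantClass.SV_BND,
        }
        if sv in mapping:
            return mapping[sv]
        return None
    ref_u = ref.upper()
    if ref_u == "-" or alt_u == "-":  # MAF style indels
        return VariantClass.INS if ref_u == "-" else VariantClass.DEL
    if not (_ALLELE_RE.match(ref_u) and _ALLELE_RE.match(alt_u)):
        return None
    if len(ref_u) == len(alt_u):
        if len(ref_u) == 1:
            return VariantClass.SNV if ref_u != alt_u else None
        return VariantClass.MNV
    return VariantClass.DEL if len(ref_u) > len(alt_u) else VariantClass.INS


def read_variants(
    path: str | Path,
    fmt: str | None = None,
    sample: str | None = None,
    known_contigs: Iterable[str] | None = None,
    chrom_style: str = "chr",
    log: ParseLog | None = None,
) -> list[SomaticVariant]:
    """Read a somatic callset; one SomaticVariant per record/ALT allele.

    Multi-allelic records are split into one variant per ALT. Records on
    contigs absent from ``known_contigs`` are flagged, not dropped. Records
    with an unrepresentable class (unknown SVTYPE) are skipped and counted.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.name.lower()
        if suffix.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif suffix.endswith(".maf"):
            fmt = "maf"
        else:
            fmt = "tsv"
    log = log if log is not None else ParseLog()
    known = {normalize_chrom(c, chrom_style) for c in known_contigs} if known_contigs else None

    if fmt == "vcf":
        variants = list(_iter_vcf(path, sample, chrom_style, log))
    elif fmt == "maf":
        variants = list(_iter_maf(path, sample, chrom_style, log))
    elif fmt == "tsv":
        variants = list(_iter_tsv(path, sample, chrom_style, log))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if known is not None:
        out = []
        for v in variants:
            if v.chrom not in known:
                log.flagged_contigs[v.chrom] += 1
                v = SomaticVariant(v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.var_class, flagged=True)
            out.append(v)
        variants = out
    log.n_variants = len(variants)
    return variants


def _iter_vcf(path: Path, sample: str | None, chrom_style: str, log: ParseLog) -> Iterator[SomaticVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if len(vcf_samples) > 1 and sample is None:
        raise ValueError(f"{path} is multi-sample ({len(vcf_samples)} samples); pass a sample selector")
    if sample is None:
        sample = vcf_samples[0] if vcf_samples else path.name.split(".")[0]
    for i, rec in enumerate(vcf, start=1):
        log.n_records += 1
        try:
            chrom = normalize_chrom(rec.CHROM, chrom_style)
            svtype = rec.INFO.get("SVTYPE")
            for alt in rec.ALT:
                vc = classify_alleles(rec.REF, alt, svtype)
                if vc is None:
                    log.skipped[f"unknown_class:{svtype or alt}"] += 1
                    logger.warning("skipping record %d in %s: unrepresentable class", i, path)
                    continue
                yield SomaticVariant(sample, chrom, rec.POS, rec.REF.upper(), _norm_allele(alt), vc)
        except ParseError:
            raise
        except Exception as exc:  # cyvcf2 errors carry little context
            raise ParseError(f"malformed VCF record {i} in {path}: {exc}") from exc


_MAF_TYPE = {"SNP": VariantClass.SNV, "DNP": VariantClass.MNV, "TNP": VariantClass.MNV,
             "ONP": VariantClass.MNV, "INS": VariantClass.INS, "DEL": VariantClass.DEL}


def _iter_maf(path: Path, sample: str | None, chrom_style: str, log: ParseLog) -> Iterator[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    required = ["Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MAF missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        log.n_records += 1
        try:
            vt = str(row.Variant_Type).upper()
            if vt not in _MAF_TYPE:
                log.skipped[f"maf_type:{vt}"] += 1
                continue
            sid = sample or str(getattr(row, "Tumor_Sample_Barcode", "sample"))
            yield SomaticVariant(
                sid,
                normalize_chrom(str(row.Chromosome), chrom_style),
                int(row.Start_Position),
                str(row.Reference_Allele).upper(),
                _norm_allele(str(row.Tumor_Seq_Allele2)),
                _MAF_TYPE[vt],
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"malformed MAF record at line {i} of {path}: {exc}") from exc


def _iter_tsv(path: Path, sample: str | None, chrom_style: str, log: ParseLog) -> Iterator[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: TSV missing columns {missing}")
    has_class = "var_class" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        log.n_records += 1
        try:
            vc = VariantClass(row.var_class) if has_class else classify_alleles(row.ref, row.alt)
            if vc is None:
                log.skipped["unknown_class"] += 1
                continue
            yield SomaticVariant(
                sample or str(row.sample),
                normalize_chrom(str(row.chrom), chrom_style),
                int(row.pos),
                str(row.ref).upper(),
                _norm_allele(str(row.alt)),
                vc,
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"malformed TSV record at line {i} of {path}: {exc}") from exc


def write_variants_tsv(variants: Sequence[SomaticVariant], path: str | Path) -> None:
    """Canonical per-sample TSV cache; read_variants() round-trips it exactly."""
    df = pd.DataFrame(
        {
            "sample": [v.sample_id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "var_class": [v.var_class.value for v in variants],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference genome access
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceWindow:
    chrom: str
    start: int  # 1-based, inclusive
    sequence: str

    def base_at(self, pos: int) -> str:
        """Reference base at 1-based genomic position ``pos``."""
        return self.sequence[pos - self.start]


class ReferenceGenome:
    """Indexed FASTA wrapper serving uppercased windows, N-padded at contig ends."""

    def __init__(self, fasta_path: str | Path, chrom_style: str = "chr"):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(fasta_path), sequence_always_upper=True)
        self.chrom_style = chrom_style
        self._names = {normalize_chrom(name, chrom_style): name for name in self._fasta.keys()}

    @property
    def contigs(self) -> list[str]:
        return list(self._names)

    def contig_length(self, chrom: str) -> int:
        return len(self._fasta[self._names[normalize_chrom(chrom, self.chrom_style)]])

    def fetch_context(self, chrom: str, pos: int, flank: int) -> ReferenceWindow:
        """Window of 2*flank+1 bases centred on ``pos`` (1-based)."""
        key = normalize_chrom(chrom, self.chrom_style)
        if key not in self._names:
            raise LookupError(f"contig {chrom!r} not in reference")
        record = self._fasta[self._names[key]]
        length = len(record)
        if not 1 <= pos <= length:
            raise LookupError(f"position {chrom}:{pos} outside contig (length {length})")
        lo = pos - flank  # 1-based
        hi = pos + flank
        core = record[max(lo, 1) - 1: min(hi, length)].seq.upper()
        pad_left = "N" * max(0, 1 - lo)
        pad_right = "N" * max(0, hi - length)
        return ReferenceWindow(key, lo, pad_left + core + pad_right)


# ---------------------------------------------------------------------------
# Gene model annotation
# ---------------------------------------------------------------------------


class GeneModelIndex:
    """Interval index answering genic/exonic/strand queries at a position."""

    def __init__(self) -> None:
        from intervaltree import IntervalTree

        self._tree_cls = IntervalTree
        self._genes: dict[str, "IntervalTree"] = {}
        self._exons: dict[str, "IntervalTree"] = {}
        self.chrom_style = "chr"

    def add_gene(self, chrom: str, start: int, end: int, strand: str) -> None:
        """Add a gene interval, 1-based inclusive coordinates."""
        chrom = normalize_chrom(chrom, self.chrom_style)
        self._genes.setdefault(chrom, self._tree_cls())[start: end + 1] = strand

    def add_exon(self, chrom: str, start: int, end: int) -> None:
        chrom = normalize_chrom(chrom, self.chrom_style)
        self._exons.setdefault(chrom, self._tree_cls())[start: end + 1] = True

    @classmethod
    def from_bed(
        cls,
        genes_bed: str | Path,
        exons_bed: str | Path | None = None,
        chrom_style: str = "chr",
    ) -> "GeneModelIndex":
        """Build from BED6 files (0-based half-open, converted on load)."""
        idx = cls()
        idx.chrom_style = chrom_style
        for chrom, start, end, strand in _iter_bed6(genes_bed):
            idx.add_gene(chrom, start + 1, end, strand)
        if exons_bed is not None:
            for chrom, start, end, _strand in _iter_bed6(exons_bed):
                idx.add_exon(chrom, start + 1, end)
        return idx

    @classmethod
    def from_gff3(cls, gff3_path: str | Path, chrom_style: str = "chr") -> "GeneModelIndex":
        import gffutils

        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        idx = cls()
        idx.chrom_style = chrom_style
        for gene in db.features_of_type("gene"):
            idx.add_gene(gene.seqid, gene.start, gene.end, gene.strand)
        for exon in db.features_of_type("exon"):
            idx.add_exon(exon.seqid, exon.start, exon.end)
        return idx

    def annotate_position(self, chrom: str, pos: int) -> tuple[bool, bool, frozenset]:
        """(genic, exonic, gene_strands) at a 1-based position; empty overlap is valid."""
        chrom = normalize_chrom(chrom, self.chrom_style)
        gene_hits = self._genes[chrom][pos] if chrom in self._genes else set()
        exon_hits = self._exons[chrom][pos] if chrom in self._exons else set()
        strands = frozenset(iv.data for iv in gene_hits)
        return (bool(gene_hits), bool(exon_hits), strands)


def _iter_bed6(path: str | Path) -> Iterator[tuple[str, int, int, str]]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"malformed BED line {i} in {path}")
            strand = fields[5] if len(fields) >= 6 else "+"
            yield fields[0], int(fields[1]), int(fields[2]), strand
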