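"""Shared fixtures: a small toy genome and simulated cohort, built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mutatt.encoding import build_dictionaries, encode_catalogues, tokenize_catalogue
from mutatt.synthetic import default_class_specs, make_toy_genome, simulate_cohort
from mutatt.variants import GeneModelIndex, ReferenceGenome, read_variants

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

GENOME_SEED = 20240915


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    out = tmp_path_factory.mktemp("genome")
    return make_toy_genome(out, n_contigs=2, contig_length=1_500_000,
                           gene_density=0.3, seed=GENOME_SEED)


@pytest.fixture(scope="session")
def ref_genome(toy_genome):
    return ReferenceGenome(toy_genome.fasta_path)


@pytest.fixture(scope="session")
def gene_index(toy_genome):
    return GeneModelIndex.from_bed(toy_genome.genes_bed, toy_genome.exons_bed)


@pytest.fixture(scope="session")
def small_cohort(toy_genome, tmp_path_factory):
    """Four classes x 4 tumours, ~120 mutations each, written as VCFs."""
    out = tmp_path_factory.mktemp("cohort")
    specs = default_class_specs(toy_genome.n_bins, burden_log_mean=np.log(120.0))
    for s in specs:
        s.burden_log_sigma = 0.1
    return simulate_cohort(specs, n_per_class=4, genome=toy_genome, out_dir=out, seed=7)


@pytest.fixture(scope="session")
def small_catalogues(small_cohort, ref_genome, gene_index):
    variants = []
    for sid, path in sorted(small_cohort.vcf_paths.items()):
        variants.extend(read_variants(path, sample=sid))
    catalogues, log = encode_catalogues(
        variants, ref_genome, gene_index, labels=small_cohort.labels
    )
    assert log["n_skipped"] == 0
    return catalogues


@pytest.fixture(scope="session")
def small_tokenized(small_catalogues):
    dicts = build_dictionaries(small_catalogues)
    return [tokenize_catalogue(c, dicts) for c in small_catalogues], dicts
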