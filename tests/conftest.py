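"""Shared fixtures: a small deterministic synthetic data set used across
module test files. Everything is generated at test time; no stored data."""

import pytest

import cistromekit as ck


@pytest.fixture(scope="session")
def genome():
    g, _ = ck.generate_genome(n_chroms=2, chrom_length=300_000, seed=11)
    return g


@pytest.fixture(scope="session")
def genes(genome):
    gs, _ = ck.generate_gene_models(genome, n_genes=20, seed=12)
    return gs


@pytest.fixture(scope="session")
def long_motif():
    return ck.builtin_psfm("PU1_long")


@pytest.fixture(scope="session")
def short_motif():
    return ck.builtin_psfm("PU1_short")


@pytest.fixture(scope="session")
def planted(genome, genes, long_motif, short_motif):
    """100 peaks, category mix 14/42/15/9/20 %, plant mix 40/30/30 %."""
    peaks, modified, truth = ck.generate_peaks_with_motifs(
        genome, genes, n_peaks=100,
        psfm_long=long_motif, psfm_short=short_motif, seed=13,
    )
    return peaks, modified, truth
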