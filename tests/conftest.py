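import pytest

import nucruler as nr


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by read-only tests.

    100 GRF sites with the default array geometry (phasing 80 bp, linker
    60 bp, three nucleosomes per side, 15 bp jitter) at 50 reads per dyad.
    """
    genome, sites = nr.make_synthetic_genome(
        n_chrom=1, chrom_length=400_000, n_sites=100,
        site_kind="GRF", min_separation=3500, seed=101,
    )
    params = nr.ArrayParams()
    dyads = nr.sample_array_dyads(genome, sites, params, seed=102)
    reads = nr.dyads_to_reads(dyads, genome, reads_per_dyad=50, seed=103)
    return genome, sites, params, dyads, reads


@pytest.fixture(scope="session")
def jitter_free_dataset():
    """Noise-free arrays: every dyad exactly on its lattice position."""
    genome, sites = nr.make_synthetic_genome(
        n_chrom=1, chrom_length=400_000, n_sites=60,
        site_kind="GRF", min_separation=3500, seed=201,
    )
    params = nr.ArrayParams(jitter_sd=0.0)
    dyads = nr.sample_array_dyads(genome, sites, params, seed=202)
    reads = nr.dyads_to_reads(dyads, genome, reads_per_dyad=30, seed=203)
    return genome, sites, params, dyads, reads
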