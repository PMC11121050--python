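import pytest

from mutprof import synthetic_data as sd


@pytest.fixture(scope="session")
def small_fixture():
    """Two ponds, three mutant lines, genes present; exercises every stage."""
    return sd.simulate_fixture(
        seed=42,
        n_chromosomes=2,
        chrom_length=60_000,
        gene_count=8,
        ponds={"WT1": ("mutA", "mutB"), "WT2": ("mutC",)},
        n_mutations_per_line=400,
        n_background=150,
        n_filter_fail=12,
    )


@pytest.fixture(scope="session")
def small_fixture_dir(small_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    paths = sd.write_fixture(outdir, small_fixture)
    return outdir, paths


@pytest.fixture(scope="session")
def flat_genome():
    """Gene-free 1 Mb chromosome for hotspot statistics."""
    return sd.generate_genome(1, 1_000_000, 0, seed=2)
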