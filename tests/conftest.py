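import numpy as np
import pytest

from truthbench import fixtures
from truthbench.genome import read_fasta
from truthbench.simulate import SimulationConfig, run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_fixture(tmp_path_factory):
    """2 x 100 kb genome with 50 genes and 500 biallelic VCF sites."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = fixtures.make_fixture(
        str(outdir), {"chr1": 100_000, "chr2": 100_000},
        n_genes=50, n_vcf_sites=500, seed=3)
    return paths


@pytest.fixture(scope="session")
def toy_genome(toy_fixture):
    return read_fasta(toy_fixture["genome"])


@pytest.fixture(scope="session")
def simulated_dataset(toy_fixture, tmp_path_factory):
    """A full 20k-read-pair simulation over the toy fixture, with VCF
    mixing and fusions, reused across integration tests."""
    outdir = tmp_path_factory.mktemp("dataset") / "ds"
    config = SimulationConfig(
        genome=toy_fixture["genome"], gtf=toy_fixture["gtf"], vcf=toy_fixture["vcf"],
        n_fusions=8, n_read_pairs=20_000, read_length=101, seed=7,
        outdir=str(outdir))
    result = run_simulation(config)
    return config, result
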