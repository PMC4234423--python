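import pytest

from ampliqc.synthetic_data import SimulationParams, simulate_all


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A small but fully featured simulation: 2 genes x 6 assays, 4
    samples, one homozygous deletion, injected variants."""
    return SimulationParams(
        seed=7, n_genes=2, amplicons_per_gene=6, n_samples=4,
        n_variants=40, deletion_assays=[("S02", "GENE02-3")])


@pytest.fixture(scope="session")
def bundle(small_params):
    return simulate_all(small_params)


@pytest.fixture()
def amp_regions(bundle):
    return [a.region for a in bundle.panel]
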