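import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from editrecode.datamodel import Gene, SpeciesDataset  # noqa: E402
from editrecode.simulate import SimParams, simulate_pair  # noqa: E402


@pytest.fixture
def toy_gene() -> Gene:
    return Gene(gene_id="g1", species_id="sp", cds="ATGAAATAA")


SMALL_PARAMS = dict(
    n_genes=8, mean_codons=80, min_codons=40,
    n_conserved_recoding=30, n_non_conserved_recoding=3,
    n_species_specific=6, n_a_lost=4,
)


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated species pair with mild divergence, plus truth."""
    return simulate_pair(SimParams(seed=7, substitution_rate=0.01, **SMALL_PARAMS))


@pytest.fixture(scope="session")
def noiseless_pair():
    """A small simulated pair with zero background divergence."""
    return simulate_pair(SimParams(seed=11, substitution_rate=0.0, **SMALL_PARAMS))


@pytest.fixture
def tiny_dataset() -> SpeciesDataset:
    ds = SpeciesDataset(species_id="sp")
    ds.add_gene(Gene(gene_id="g1", species_id="sp", cds="ATGAAATAA"))
    return ds
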