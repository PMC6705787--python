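import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from s1census.records_io import ProteinRecord
from s1census.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_record(
    accession: str,
    sequence: str = "M" * 150,
    boundaries=((1, 70), (81, 150)),
    protein_name: str = "30S ribosomal protein S1",
    gene_name: str = "rpsA",
    phylum: str = "Proteobacteria",
    lineage=None,
    has_extra_domains: bool = False,
) -> ProteinRecord:
    if lineage is None:
        lineage = ("Bacteria", phylum, f"{phylum} bacterium")
    return ProteinRecord(
        accession=accession,
        protein_name=protein_name,
        gene_name=gene_name,
        lineage=tuple(lineage),
        phylum=phylum,
        sequence=sequence,
        s1_boundaries=tuple(boundaries),
        has_extra_domains=has_extra_domains,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_family():
    """A clean 60-record simulated family shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_records=60))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
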