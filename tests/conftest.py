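import numpy as np
import pandas as pd
import pytest

from pancimp.aggregate import aggregate_by_cgi, filter_cgis
from pancimp.matrices import ProbeAnnotation, ProbeBetaMatrix
from pancimp.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=123))


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-tissue dataset for fast structural tests."""
    return simulate_dataset(
        SimulationConfig(
            n_tissues=2,
            samples_per_tissue=(60, 60),
            n_cgis=120,
            signature_size=6,
            n_genes=60,
            n_predictive_genes=6,
            n_open_sea_probes=10,
            seed=42,
        )
    )


def aggregate_tissue(dataset, tissue):
    return filter_cgis(aggregate_by_cgi(dataset.probes[tissue], dataset.annotation))


@pytest.fixture
def toy_annotation():
    """Three CGIs with island/shore/shelf probes plus one open-sea probe."""
    rows = [
        ("p1", "chr1", 100, "cgiA", "island", "G1"),
        ("p2", "chr1", 150, "cgiA", "island", "G1"),
        ("p3", "chr1", 1600, "cgiA", "shore", "G1"),
        ("p4", "chr2", 100, "cgiB", "island", "G2;G3"),
        ("p5", "chr2", 3500, "cgiB", "shelf", ""),
        ("p6", "chr3", 100, "cgiC", "island", ""),
        ("p7", "chr9", 999, None, "open_sea", ""),
    ]
    return ProbeAnnotation(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "cgi_id", "relation", "genes"])
    )


@pytest.fixture
def toy_probes():
    data = {
        "s1": [0.2, 0.4, 0.6, 0.1, 0.5, 0.3, 0.9],
        "s2": [0.3, np.nan, 0.9, 0.2, 0.6, 0.4, 0.8],
    }
    return ProbeBetaMatrix(
        beta=pd.DataFrame(data, index=[f"p{i}" for i in range(1, 8)])
    )
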