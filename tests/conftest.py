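import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pulserate.simulate import SimulationConfig, simulate_experiment, write_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured noisy experiment."""
    return SimulationConfig(
        n_genes=600,
        n_replicates=3,
        seed=11,
        feature_prevalence={"tf": 0.3, "me3": 0.2, "cts": 0.3},
    )


@pytest.fixture(scope="session")
def sim(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def noise_free_sim():
    """Noise-free, contamination-free experiment for exact-recovery checks."""
    config = SimulationConfig(
        n_genes=300, seed=5, nb_dispersion=0.0, contamination_frac=0.0
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(small_config, outdir)
    return outdir


def toy_count_table(counts, lengths=None, metadata=None, regions=None):
    """Build a CountTable from a dict of {library: values} over simple genes."""
    from pulserate.quantify import CountTable

    frame = pd.DataFrame(counts)
    n = len(frame)
    if regions is None:
        regions = ["exonic"] * n
    genes = list(frame.index) if not isinstance(frame.index, pd.RangeIndex) else [
        f"g{i}" for i in range(1, n + 1)
    ]
    index = pd.MultiIndex.from_arrays([genes, regions], names=["gene_id", "region"])
    frame.index = index
    if lengths is None:
        lengths = pd.Series(1000.0, index=index, name="length")
    else:
        lengths = pd.Series(np.asarray(lengths, dtype=float), index=index, name="length")
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "fraction": ["total"] * len(frame.columns),
                "condition": ["ctrl"] * len(frame.columns),
                "replicate": range(1, len(frame.columns) + 1),
            },
            index=pd.Index(frame.columns, name="library_id"),
        )
    return CountTable(data=frame.astype(float), metadata=metadata, lengths=lengths, units="counts")
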