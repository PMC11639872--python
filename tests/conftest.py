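import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coralstress.core_data import SampleMetadata
from coralstress.synthetic import SimulationConfig, simulate_counts

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default-size simulated species (counts, metadata, truth)."""
    cfg = SimulationConfig(seed=11)
    return simulate_counts(cfg) + (cfg,)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated species for fast unit tests."""
    cfg = SimulationConfig(seed=7, n_genes_host=400, n_genes_symbiont=200)
    return simulate_counts(cfg) + (cfg,)


@pytest.fixture()
def toy_meta():
    rows = []
    for colony in (1, 2, 3):
        for trt in ("control", "heated"):
            for tp in (4, 24):
                rows.append(
                    {
                        "sample_id": f"c{colony}_{trt}_{tp}",
                        "species": "toy",
                        "colony": f"colony{colony}",
                        "treatment": trt,
                        "timepoint_h": tp,
                    }
                )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A tiny on-disk fixture bundle (2 species) for pipeline/CLI tests."""
    from coralstress.synthetic import write_bundle

    cfg = SimulationConfig(
        seed=5, n_species=2, n_genes_host=300, n_genes_symbiont=150, sequence_length=120
    )
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(cfg, out)
    return out, cfg
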