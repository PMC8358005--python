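import numpy as np
import pandas as pd
import pytest

from recipase import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sim():
    """Mixed null/cis/imprinted simulation, modest size, fixed seed."""
    config = sd.SimulationConfig(
        n_genes=60,
        snps_per_gene_mean=2.0,
        seed=101,
        frac_imprinted_paternal=0.1,
        frac_imprinted_maternal=0.1,
        frac_cis_effect=0.1,
    )
    counts, truth = sd.simulate_allele_counts(config)
    return config, counts, truth


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, small_sim):
    """Fixture bundle written to disk once per session."""
    _, counts, truth = small_sim
    de_x, de_y, shared = sd.simulate_de_tables(
        n_genes=60, frac_shared_de=0.2, target_correlation=-0.8, seed=101
    )
    out_dir = tmp_path_factory.mktemp("bundle")
    paths = sd.write_fixture_bundle(counts, truth, out_dir, de_tables=[de_x, de_y])
    return {"paths": paths, "counts": counts, "truth": truth, "de": (de_x, de_y, shared)}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
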