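"""Shared fixtures: toy barcode spaces and one cached small simulation."""

import numpy as np
import pytest

from pipflow import (BarcodeSchema, SimConfig, SubBarcodeSet, Whitelist,
                     build_whitelist)
from pipflow.pipeline import run_simulated_pipeline


@pytest.fixture(scope="session")
def toy_schema() -> BarcodeSchema:
    """Two rounds of 3-mers with comfortable spacing; 4-barcode space."""
    return BarcodeSchema(
        rounds=(
            SubBarcodeSet(1, ("AAA", "CCC")),
            SubBarcodeSet(2, ("GGG", "TTT")),
        ),
        umi_length=4,
    )


@pytest.fixture(scope="session")
def toy_whitelist(toy_schema) -> Whitelist:
    return build_whitelist(toy_schema)


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Zero-noise 60-cell barnyard with explicit 5% doublets, 2% ambient."""
    return SimConfig(
        seed=11,
        n_cells=60,
        loading_lambda=None,
        doublet_rate=0.05,
        n_ambient_barcodes=250,
        genes_per_species=50,
        umis_per_cell_log_mean=np.log(200.0),
    )


@pytest.fixture(scope="session")
def small_pipeline(small_sim_config, tmp_path_factory):
    """One end-to-end run on the small zero-noise simulation, shared across
    tests (simulation, counting and calling are deterministic under the
    config seed)."""
    workdir = tmp_path_factory.mktemp("small_sim")
    return run_simulated_pipeline(small_sim_config, workdir,
                                  n_iterations=1500)
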