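import logging

import pytest

from primingkit import (
    IncubationDesign,
    generate_transect,
    partition_sites,
    simulate_transect,
)

# clamp warnings flood the log on noisy fixtures
logging.getLogger("primingkit.partitioning").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design() -> IncubationDesign:
    return IncubationDesign()


@pytest.fixture(scope="session")
def transect(design):
    """Default 30-site transect with known truth."""
    return generate_transect(30, seed=42)


@pytest.fixture(scope="session")
def noiseless_partition(design, transect):
    """Partition table from a zero-noise simulation of the transect."""
    records = simulate_transect(
        transect, design, seed=42, flux_noise_rel=0.0, atom_pc_noise_abs=0.0
    )
    return partition_sites(records, design, per_replicate=True)


@pytest.fixture(scope="session")
def noisy_partition(design, transect):
    """Partition table at the default measurement-noise level."""
    records = simulate_transect(transect, design, seed=42)
    return partition_sites(records, design, per_replicate=True)
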