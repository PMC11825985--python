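from __future__ import annotations

import pytest

from synfam.cli import load_inputs
from synfam.fixtures import SimulationConfig, event_fixture, simulate


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Small evolved dataset exercising duplications, losses and inversions."""
    out = tmp_path_factory.mktemp("sim")
    result = simulate(
        SimulationConfig(
            n_samples=6,
            genes_per_contig=12,
            contigs_per_sample=2,
            seed=11,
        ),
        out,
    )
    return result


@pytest.fixture(scope="session")
def sim_inputs(sim_dataset):
    """Parsed (table, gene_trees, species_tree, msas, gene_orders)."""
    return load_inputs(sim_dataset.out_dir)


@pytest.fixture(scope="session")
def planted_events(tmp_path_factory):
    """Dataset with exactly one tandem duplication and one loss, plus descriptor."""
    out = tmp_path_factory.mktemp("events")
    return event_fixture(out, seed=3)
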