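import pytest

from wgs_bakeoff.cohort import default_design
from wgs_bakeoff.synth import (SimulationConfig, make_reference,
                               simulate_annotation_table,
                               simulate_center_callsets, simulate_read_pairs)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(genome_length=50_000, seed=11, n_variant_sites=1_000)


@pytest.fixture(scope="session")
def reference(small_config):
    ref, truth = make_reference(small_config)
    return ref, truth


@pytest.fixture(scope="session")
def read_sim(reference, small_config):
    pairs, log = simulate_read_pairs(reference[0], small_config)
    return pairs, log


@pytest.fixture(scope="session")
def callset_sim(reference, design, small_config):
    return simulate_center_callsets(
        reference[0], design, small_config, n_centers=3,
        per_center_discordance=[0.0, 0.01, 0.02])


@pytest.fixture(scope="session")
def annotation(callset_sim, design, small_config):
    return simulate_annotation_table(callset_sim.truth, design, small_config,
                                     callset_sim.causal_pos)
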