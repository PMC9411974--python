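import numpy as np
import pytest

from mrbench import (
    Dataset,
    InstrumentSpec,
    SimulationConfig,
    TraitGraph,
    sample_trait_graph,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_traits=5,
        iv_per_trait_min=4,
        iv_per_trait_max=6,
        n_samples=600,
        n_replicates=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config) -> Dataset:
    rng = tiny_config.replicate_rng(0)
    graph = sample_trait_graph(tiny_config, rng)
    return simulate_dataset(graph, tiny_config, rng)


def make_chain_graph(effects: dict[tuple[str, str], float],
                     instruments: dict[str, InstrumentSpec] | None = None,
                     n_traits: int = 3) -> TraitGraph:
    """Hand-built trait graph for oracle tests."""
    traits = [f"trait_{i + 1:02d}" for i in range(n_traits)]
    return TraitGraph(traits, dict(effects), instruments or {})
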