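"""Generator: graph sampling, structural-equation data, and path truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrbench import (
    InstrumentSpec,
    SimulationConfig,
    TraitGraph,
    run_gwas,
    sample_trait_graph,
    simulate_dataset,
    total_effect_matrix,
    true_causal_matrix,
)
from mrbench.simulate import Dataset, read_dataset, write_dataset

from conftest import make_chain_graph


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_traits": 1},
        {"iv_per_trait_min": 8, "iv_per_trait_max": 4},
        {"p_pleio": 1.5},
        {"maf_range": (0.1, 0.9)},
        {"effect_magnitude_range": (-0.2, 0.4)},
        {"noise_sd": 0.0},
    ],
)
def test_config_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_no_children_means_no_edges():
    cfg = SimulationConfig(n_traits=2, mean_children=0.0, seed=1)
    graph = sample_trait_graph(cfg)
    assert graph.direct_effects == {}


def test_no_pleiotropy_means_empty_pleiotropy_maps():
    cfg = SimulationConfig(p_pleio=0.0, seed=2)
    graph = sample_trait_graph(cfg)
    assert all(not s.pleiotropic_effects for s in graph.instruments.values())
    cfg = SimulationConfig(p_pleio=1.0, seed=2)
    graph = sample_trait_graph(cfg)
    assert all(len(s.pleiotropic_effects) == 1 for s in graph.instruments.values())


def test_sampled_graphs_are_acyclic_with_valid_instruments():
    cfg = SimulationConfig(p_pleio=0.3, seed=3)
    for r in range(5):
        graph = sample_trait_graph(cfg, cfg.replicate_rng(r))
        graph.validate()  # raises on cycles / invalid instruments
        assert all(s.effect != 0 for s in graph.instruments.values())


def test_mean_instrument_count_matches_expectation():
    # Monte-Carlo mean of uniform counts vs the direct expectation
    cfg = SimulationConfig(seed=4)
    rng = np.random.default_rng(4)
    counts = [
        len(sample_trait_graph(cfg, rng).instruments) for _ in range(1000)
    ]
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - cfg.expected_total_instruments) <= 3 * se
    assert abs(cfg.expected_total_instruments - 225.0) < 1e-12


def test_pure_noise_traits_have_unit_sd():
    graph = make_chain_graph({}, n_traits=3)
    cfg = SimulationConfig(n_traits=3, n_samples=4000, noise_sd=1.0, seed=5)
    ds = simulate_dataset(graph, cfg, np.random.default_rng(5))
    means = ds.trait_matrix().mean(axis=0)
    sds = ds.trait_matrix().std(axis=0)
    assert np.all(np.abs(means) < 4 / np.sqrt(cfg.n_samples))
    assert np.allclose(sds, 1.0, atol=0.06)


def test_single_instrument_effect_recovered_by_ols():
    b, f = 0.35, 0.3
    graph = make_chain_graph(
        {}, {"iv_001": InstrumentSpec("trait_01", b, f)}, n_traits=2
    )
    cfg = SimulationConfig(n_traits=2, n_samples=5000, seed=6)
    ds = simulate_dataset(graph, cfg, np.random.default_rng(6))
    row = run_gwas(ds).query("instrument == 'iv_001' and trait == 'trait_01'").iloc[0]
    assert abs(row["beta"] - b) <= 3 * row["se"]


def test_chain_effect_recovered_by_covariance_ratio():
    c = 0.3
    graph = make_chain_graph({("trait_01", "trait_02"): c}, n_traits=2)
    cfg = SimulationConfig(n_traits=2, n_samples=20000, seed=7)
    ds = simulate_dataset(graph, cfg, np.random.default_rng(7))
    a = ds.traits["trait_01"].to_numpy()
    bvals = ds.traits["trait_02"].to_numpy()
    ratio = np.cov(a, bvals)[0, 1] / np.var(a)
    assert abs(ratio - c) < 0.05


def _dfs_reachable(edges: set[tuple[int, int]], n: int) -> set[tuple[int, int]]:
    adj = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
    out = set()
    for start in range(n):
        stack, seen = [start], set()
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        out |= {(start, v) for v in seen if v != start}
    return out


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_transitive_closure_matches_dfs_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    order = rng.permutation(n)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35:
                edges.add((int(order[i]), int(order[j])))
    traits = [f"trait_{i + 1:02d}" for i in range(n)]
    graph = TraitGraph(
        traits, {(traits[a], traits[b]): 0.2 for a, b in edges}, {}
    )
    truth = true_causal_matrix(graph)
    expected = {
        (traits[a], traits[b]) for a, b in _dfs_reachable(edges, n)
    }
    assert truth.positive_pairs() == expected
    # transitively closed and acyclic
    r = truth.reachable.to_numpy()
    assert not np.any(np.diag(r))
    assert not np.any(r & r.T)
    closed = (r @ r).astype(bool)
    assert np.all(r[closed])


def test_chain_reachability_and_total_effect():
    graph = make_chain_graph(
        {("trait_01", "trait_02"): 0.5, ("trait_02", "trait_03"): -0.4}
    )
    truth = true_causal_matrix(graph)
    assert truth.is_causal("trait_01", "trait_03")
    assert not truth.is_causal("trait_03", "trait_01")
    total = total_effect_matrix(graph)
    assert total.loc["trait_01", "trait_03"] == pytest.approx(0.5 * -0.4)
    assert total.loc["trait_01", "trait_02"] == pytest.approx(0.5)
    assert total.loc["trait_03", "trait_01"] == 0.0


def test_cycle_rejected():
    graph = make_chain_graph(
        {("trait_01", "trait_02"): 0.5, ("trait_02", "trait_01"): 0.5}, n_traits=2
    )
    with pytest.raises(ValueError, match="cycle"):
        true_causal_matrix(graph)


def test_dataset_roundtrip(tmp_path, tiny_dataset):
    write_dataset(tiny_dataset, tmp_path / "rep")
    back = read_dataset(tmp_path / "rep")
    assert back.trait_ids == tiny_dataset.trait_ids
    assert back.instrument_ids == tiny_dataset.instrument_ids
    np.testing.assert_array_equal(
        back.genotypes.to_numpy(), tiny_dataset.genotypes.to_numpy()
    )
    np.testing.assert_allclose(
        back.traits.to_numpy(), tiny_dataset.traits.to_numpy(), rtol=1e-9
    )
    assert back.graph.direct_effects == tiny_dataset.graph.direct_effects


def test_replicate_streams_are_reproducible(tiny_config):
    g1 = sample_trait_graph(tiny_config, tiny_config.replicate_rng(1))
    g2 = sample_trait_graph(tiny_config, tiny_config.replicate_rng(1))
    g3 = sample_trait_graph(tiny_config, tiny_config.replicate_rng(2))
    assert g1.direct_effects == g2.direct_effects
    assert g1.direct_effects != g3.direct_effects or g1.instruments != g3.instruments


def test_instruments_marginally_associate_only_with_descendants():
    # with no pleiotropy, an instrument tags its primary trait and that
    # trait's descendants; other traits stay null
    graph = make_chain_graph(
        {("trait_01", "trait_02"): 0.6},
        {
            "iv_001": InstrumentSpec("trait_01", 0.5, 0.4),
            "iv_002": InstrumentSpec("trait_03", 0.5, 0.4),
        },
        n_traits=3,
    )
    cfg = SimulationConfig(n_traits=3, n_samples=8000, seed=8)
    ds = simulate_dataset(graph, cfg, np.random.default_rng(8))
    gwas = run_gwas(ds).set_index(["instrument", "trait"])
    assert gwas.loc[("iv_001", "trait_01"), "pval"] < 1e-8
    assert gwas.loc[("iv_001", "trait_02"), "pval"] < 1e-4
    assert gwas.loc[("iv_001", "trait_03"), "pval"] > 0.01
    assert gwas.loc[("iv_002", "trait_01"), "pval"] > 0.01
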