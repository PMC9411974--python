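"""GWAS statistics, Bonferroni selection, UniqueIV filtering, allele scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrbench import (
    InstrumentSet,
    InstrumentSpec,
    SimulationConfig,
    conditional_association_pvals,
    run_gwas,
    select_instruments,
    simulate_dataset,
    unique_iv_filter,
    weighted_allele_score,
)
from mrbench.simulate import Dataset, TraitGraph

from conftest import make_chain_graph


def _manual_dataset(genotypes: np.ndarray, traits: np.ndarray) -> Dataset:
    m, t = genotypes.shape[1], traits.shape[1]
    ivs = [f"iv_{i + 1:03d}" for i in range(m)]
    names = [f"trait_{i + 1:02d}" for i in range(t)]
    graph = TraitGraph(
        names,
        {},
        {g: InstrumentSpec(names[0], 0.1, 0.5) for g in ivs},
    )
    return Dataset(
        genotypes=pd.DataFrame(genotypes.astype(np.int8), columns=ivs),
        traits=pd.DataFrame(traits, columns=names),
        graph=graph,
    )


def test_gwas_matches_hand_computed_ols():
    g = np.array([0, 1, 0, 1, 1, 0])
    y = np.array([0.2, 1.1, -0.3, 0.9, 1.4, 0.1])
    ds = _manual_dataset(g[:, None], y[:, None])
    row = run_gwas(ds).iloc[0]
    xc, yc = g - g.mean(), y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    rss = ((yc - beta * xc) ** 2).sum()
    se = np.sqrt(rss / (len(g) - 2) / (xc @ xc))
    p = 2 * stats.t.sf(abs(beta / se), df=len(g) - 2)
    assert row["beta"] == pytest.approx(beta, rel=1e-12)
    assert row["se"] == pytest.approx(se, rel=1e-12)
    assert row["pval"] == pytest.approx(p, rel=1e-10)


def test_gwas_perfect_fit_and_degenerate_column():
    g = np.array([0, 1, 0, 1, 1, 0, 1, 0])
    G = np.column_stack([g, np.zeros_like(g)])  # second column has no variance
    Y = g.astype(float)[:, None]
    tab = run_gwas(_manual_dataset(G, Y)).set_index("instrument")
    assert tab.loc["iv_001", "beta"] == pytest.approx(1.0)
    assert tab.loc["iv_001", "pval"] < 1e-12
    assert tab.loc["iv_002", "beta"] == 0.0
    assert tab.loc["iv_002", "pval"] == 1.0


def test_gwas_null_pvalues_are_uniform():
    rng = np.random.default_rng(9)
    G = (rng.random((400, 50)) < 0.3).astype(np.int8)
    Y = rng.normal(size=(400, 10))
    pvals = run_gwas(_manual_dataset(G, Y))["pval"].to_numpy()
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _pval_table(pvals: dict[str, float], trait: str = "trait_01") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "instrument": list(pvals),
            "trait": trait,
            "beta": 0.2,
            "se": 0.05,
            "pval": list(pvals.values()),
        }
    )


def test_selection_threshold_is_bonferroni():
    # 0.05 / 225 ≈ 2.222e-4: instruments at or under the corrected level pass
    thr = 0.05 / 225
    tab = _pval_table({"a": thr * 0.99, "b": thr * 1.01, "c": 1.0})
    got = select_instruments(tab, "trait_01", alpha=0.05, n_tests=225)
    assert got.instruments == ["a"]
    assert got.weights == {"a": 0.2}
    empty = select_instruments(_pval_table({"a": 1.0, "b": 1.0}), "trait_01")
    assert not empty


def test_selection_is_monotone_in_alpha():
    rng = np.random.default_rng(10)
    tab = _pval_table({f"iv{i}": p for i, p in enumerate(rng.random(50))})
    prev: set[str] = set()
    for alpha in (0.5, 0.2, 0.05, 0.01):
        got = set(select_instruments(tab, "trait_01", alpha=alpha, n_tests=10).instruments)
        if prev:
            assert got <= prev
        prev = got


def test_null_selection_count_matches_binomial_expectation():
    rng = np.random.default_rng(11)
    alpha, n_tests, m, reps = 0.05, 20, 500, 300
    counts = [
        len(
            select_instruments(
                _pval_table({f"iv{i}": p for i, p in enumerate(rng.random(m))}),
                "trait_01",
                alpha=alpha,
                n_tests=n_tests,
            )
        )
        for _ in range(reps)
    ]
    expected = m * alpha / n_tests
    se = np.sqrt(m * (alpha / n_tests) * (1 - alpha / n_tests) / reps)
    assert abs(np.mean(counts) - expected) <= 4 * se


def test_unique_iv_removes_pleiotropic_instrument_keeps_clean():
    graph = make_chain_graph(
        {},
        {
            "iv_001": InstrumentSpec("trait_01", 0.5, 0.4, {"trait_02": 0.5}),
            **{
                f"iv_{i:03d}": InstrumentSpec("trait_01", 0.5, 0.4)
                for i in range(2, 10)
            },
        },
        n_traits=2,
    )
    cfg = SimulationConfig(n_traits=2, n_samples=4000, seed=12)
    ds = simulate_dataset(graph, cfg, np.random.default_rng(12))
    gwas = run_gwas(ds)
    base = select_instruments(gwas, "trait_01")
    assert "iv_001" in base.instruments
    filtered = unique_iv_filter(ds, "trait_01", base, ci_alpha=0.01)
    assert "iv_001" not in filtered.instruments
    clean = [g for g in base.instruments if g != "iv_001"]
    kept = [g for g in clean if g in filtered.instruments]
    assert len(kept) >= 0.7 * len(clean)
    # always a subset of the Bonferroni selection
    assert set(filtered.instruments) <= set(base.instruments)


def test_unique_iv_identity_when_no_other_traits():
    rng = np.random.default_rng(13)
    g = (rng.random((200, 3)) < 0.4).astype(np.int8)
    y = g @ np.array([0.5, 0.4, 0.3]) + rng.normal(size=200)
    ivs = ["iv_001", "iv_002", "iv_003"]
    graph = TraitGraph(
        ["trait_01"], {}, {i: InstrumentSpec("trait_01", 0.3, 0.4) for i in ivs}
    )
    ds = Dataset(
        genotypes=pd.DataFrame(g, columns=ivs),
        traits=pd.DataFrame(y, columns=["trait_01"]),
        graph=graph,
    )
    base = select_instruments(run_gwas(ds), "trait_01")
    filtered = unique_iv_filter(ds, "trait_01", base)
    assert filtered.instruments == base.instruments


def test_conditional_test_blocks_descendant_path():
    # g -> T1 -> T2: given T1, g carries no information about T2
    graph = make_chain_graph(
        {("trait_01", "trait_02"): 0.6},
        {f"iv_{i:03d}": InstrumentSpec("trait_01", 0.5, 0.4) for i in range(1, 7)},
        n_traits=2,
    )
    cfg = SimulationConfig(n_traits=2, n_samples=6000, seed=14)
    ds = simulate_dataset(graph, cfg, np.random.default_rng(14))
    pvals = conditional_association_pvals(ds, "trait_01")["trait_02"]
    assert (pvals > 0.01).mean() >= 5 / 6


def test_allele_score_arithmetic_and_invariants():
    g = np.array([[0, 1], [1, 1], [0, 0], [1, 0]])
    ds = _manual_dataset(g, np.zeros((4, 1)))
    iset = InstrumentSet("trait_01", ["iv_001", "iv_002"], {"iv_001": 0.5, "iv_002": -0.2})
    score = weighted_allele_score(ds, iset)
    np.testing.assert_allclose(score.values, [-0.2, 0.3, 0.0, 0.5])
    # recomputation invariant
    w = np.array([0.5, -0.2])
    np.testing.assert_array_equal(score.values, g.astype(float) @ w)
    one = weighted_allele_score(
        ds, InstrumentSet("trait_01", ["iv_001"], {"iv_001": 1.0})
    )
    np.testing.assert_array_equal(one.values, g[:, 0].astype(float))
    with pytest.raises(ValueError):
        weighted_allele_score(ds, InstrumentSet("trait_01", [], {}))


def test_instrument_set_requires_matching_weights():
    with pytest.raises(ValueError):
        InstrumentSet("trait_01", ["iv_001"], {"iv_002": 1.0})
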