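"""Synthetic cohorts with a known causal trait network and genetic instruments.

The generator draws a random acyclic causal graph over a set of continuous
traits, assigns each trait a block of binary instrumental variables, optionally
adds horizontal pleiotropy (direct instrument effects on non-primary traits),
and simulates individual-level data from the implied linear-Gaussian structural
equation model:

    trait_t = sum_g a_gt * genotype_g + sum_p b_pt * trait_p + N(0, noise_sd^2)

where ``a_gt`` collects the primary and pleiotropic instrument effects on trait
``t`` and ``b_pt`` the direct effects of parent traits.  Ground truth for the
benchmark is *path* causality: trait ``i`` is causal on trait ``j`` iff a
directed path i -> j exists in the trait graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "InstrumentSpec",
    "TraitGraph",
    "Dataset",
    "TruthMatrix",
    "sample_trait_graph",
    "simulate_dataset",
    "simulate_replicates",
    "true_causal_matrix",
    "total_effect_matrix",
    "write_dataset",
    "read_dataset",
]


def _trait_name(i: int) -> str:
    return f"trait_{i + 1:02d}"


def _iv_name(i: int) -> str:
    return f"iv_{i + 1:03d}"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults reproduce the benchmark's stated conditions: 15 continuous
    traits, 10–20 binary instruments per trait (≈225 in total), traits causal
    on around 1–2 other traits, and horizontal pleiotropy controlled by
    ``p_pleio``, the per-instrument probability of carrying a direct
    pleiotropic effect on another trait.
    """

    n_traits: int = 15
    iv_per_trait_min: int = 10
    iv_per_trait_max: int = 20
    p_pleio: float = 0.0
    n_samples: int = 2000
    n_replicates: int = 100
    mean_children: float = 1.5
    effect_magnitude_range: tuple[float, float] = (0.1, 0.4)
    maf_range: tuple[float, float] = (0.1, 0.5)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traits < 2:
            raise ValueError("n_traits must be >= 2")
        if not (0 < self.iv_per_trait_min <= self.iv_per_trait_max):
            raise ValueError("need 0 < iv_per_trait_min <= iv_per_trait_max")
        if not 0.0 <= self.p_pleio <= 1.0:
            raise ValueError("p_pleio must lie in [0, 1]")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mean_children < 0:
            raise ValueError("mean_children must be >= 0")
        lo, hi = self.effect_magnitude_range
        if not (0 < lo <= hi):
            raise ValueError("effect_magnitude_range must be positive and ordered")
        flo, fhi = self.maf_range
        if not (0 < flo <= fhi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5] and be ordered")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def expected_total_instruments(self) -> float:
        """Expected instrument count: n_traits × (iv_min + iv_max)/2."""
        return self.n_traits * (self.iv_per_trait_min + self.iv_per_trait_max) / 2.0

    def replicate_rng(self, replicate: int) -> np.random.Generator:
        """Deterministic, independent random stream for one replicate."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(replicate,))
        )


@dataclass(frozen=True)
class InstrumentSpec:
    """A binary instrument: its primary trait, effect, allele frequency and
    any direct (pleiotropic) effects on other traits."""

    primary_trait: str
    effect: float
    frequency: float
    pleiotropic_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class TraitGraph:
    """Ground-truth weighted causal DAG over traits plus instrument assignments."""

    trait_ids: list[str]
    direct_effects: dict[tuple[str, str], float]
    instruments: dict[str, InstrumentSpec]

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)

    @property
    def instrument_ids(self) -> list[str]:
        return list(self.instruments)

    def trait_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.trait_ids)
        g.add_edges_from(self.direct_effects)
        return g

    def validate(self) -> None:
        traits = set(self.trait_ids)
        for (p, c) in self.direct_effects:
            if p not in traits or c not in traits:
                raise ValueError(f"edge ({p}, {c}) references unknown trait")
        if not nx.is_directed_acyclic_graph(self.trait_digraph()):
            raise ValueError("trait graph contains a cycle")
        for gid, spec in self.instruments.items():
            if spec.primary_trait not in traits:
                raise ValueError(f"{gid}: unknown primary trait")
            if spec.effect == 0:
                raise ValueError(f"{gid}: primary effect must be nonzero")
            if not 0 < spec.frequency < 1:
                raise ValueError(f"{gid}: allele frequency must lie in (0, 1)")
            for t in spec.pleiotropic_effects:
                if t == spec.primary_trait or t not in traits:
                    raise ValueError(f"{gid}: invalid pleiotropy target {t}")

    def effect_matrix(self) -> pd.DataFrame:
        """Trait-by-trait direct-effect matrix B with B[parent, child]."""
        B = pd.DataFrame(
            0.0, index=self.trait_ids, columns=self.trait_ids, dtype=float
        )
        for (p, c), b in self.direct_effects.items():
            B.loc[p, c] = b
        return B

    def instrument_effect_matrix(self) -> pd.DataFrame:
        """Instrument-by-trait direct-effect matrix (primary + pleiotropic)."""
        A = pd.DataFrame(
            0.0, index=self.instrument_ids, columns=self.trait_ids, dtype=float
        )
        for gid, spec in self.instruments.items():
            A.loc[gid, spec.primary_trait] = spec.effect
            for t, b in spec.pleiotropic_effects.items():
                A.loc[gid, t] = b
        return A

    def to_dict(self) -> dict:
        return {
            "trait_ids": list(self.trait_ids),
            "edges": [
                {"parent": p, "child": c, "effect": b}
                for (p, c), b in self.direct_effects.items()
            ],
            "instruments": {
                gid: {
                    "primary_trait": s.primary_trait,
                    "effect": s.effect,
                    "frequency": s.frequency,
                    "pleiotropic_effects": dict(s.pleiotropic_effects),
                }
                for gid, s in self.instruments.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitGraph":
        return cls(
            trait_ids=list(d["trait_ids"]),
            direct_effects={
                (e["parent"], e["child"]): float(e["effect"]) for e in d["edges"]
            },
            instruments={
                gid: InstrumentSpec(
                    primary_trait=s["primary_trait"],
                    effect=float(s["effect"]),
                    frequency=float(s["frequency"]),
                    pleiotropic_effects={
                        k: float(v) for k, v in s["pleiotropic_effects"].items()
                    },
                )
                for gid, s in d["instruments"].items()
            },
        )


@dataclass
class Dataset:
    """One replicate: binary genotype matrix, continuous trait matrix, truth graph."""

    genotypes: pd.DataFrame
    traits: pd.DataFrame
    graph: TraitGraph

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.traits):
            raise ValueError("genotype and trait matrices disagree on sample count")
        if list(self.genotypes.columns) != self.graph.instrument_ids:
            raise ValueError("genotype columns do not match graph instruments")
        if list(self.traits.columns) != list(self.graph.trait_ids):
            raise ValueError("trait columns do not match graph traits")

    @property
    def n_samples(self) -> int:
        return len(self.traits)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.traits.columns)

    @property
    def instrument_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def genotype_matrix(self) -> np.ndarray:
        return self.genotypes.to_numpy(dtype=float)

    def trait_matrix(self) -> np.ndarray:
        return self.traits.to_numpy(dtype=float)


@dataclass
class TruthMatrix:
    """Directed-path reachability over traits; entry (i, j) is True iff a
    directed path i -> j exists.  The diagonal is False."""

    reachable: pd.DataFrame

    def positive_pairs(self) -> set[tuple[str, str]]:
        r = self.reachable
        return {
            (i, j)
            for i in r.index
            for j in r.columns
            if i != j and bool(r.loc[i, j])
        }

    @property
    def n_positives(self) -> int:
        return int(self.reachable.to_numpy().sum())

    @property
    def n_negatives(self) -> int:
        t = len(self.reachable)
        return t * (t - 1) - self.n_positives

    def is_causal(self, a: str, b: str) -> bool:
        return bool(self.reachable.loc[a, b])


def sample_trait_graph(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TraitGraph:
    """Draw a random causal DAG over traits and assign instruments.

    Traits are placed in a uniformly random order; each trait draws a
    Poisson(``mean_children``) child count, truncated to the number of
    downstream traits, and connects to that many downstream traits chosen
    uniformly without replacement.  Edge and instrument effect magnitudes are
    uniform on ``effect_magnitude_range`` with random sign; allele frequencies
    are uniform on ``maf_range``.  Each instrument independently is
    horizontally pleiotropic with probability ``p_pleio``, in which case it
    gains a direct effect on one uniformly chosen non-primary trait, so
    ``p_pleio`` is the expected fraction of invalid instruments.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_traits
    traits = [_trait_name(i) for i in range(n)]
    if config.mean_children > n - 1:
        warnings.warn(
            "mean_children exceeds the number of available downstream traits; "
            "child counts will be heavily truncated",
            stacklevel=2,
        )
    lo, hi = config.effect_magnitude_range

    def draw_effect() -> float:
        mag = rng.uniform(lo, hi)
        return float(mag if rng.random() < 0.5 else -mag)

    order = rng.permutation(n)
    edges: dict[tuple[str, str], float] = {}
    for pos in range(n):
        parent = traits[order[pos]]
        downstream = [traits[order[q]] for q in range(pos + 1, n)]
        k = int(min(rng.poisson(config.mean_children), len(downstream)))
        if k == 0:
            continue
        picks = rng.choice(len(downstream), size=k, replace=False)
        for c in picks:
            edges[(parent, downstream[int(c)])] = draw_effect()

    instruments: dict[str, InstrumentSpec] = {}
    counter = 0
    for t in traits:
        n_iv = int(rng.integers(config.iv_per_trait_min, config.iv_per_trait_max + 1))
        for _ in range(n_iv):
            gid = _iv_name(counter)
            counter += 1
            pleio: dict[str, float] = {}
            if rng.random() < config.p_pleio:
                others = [z for z in traits if z != t]
                pleio[others[int(rng.integers(len(others)))]] = draw_effect()
            instruments[gid] = InstrumentSpec(
                primary_trait=t,
                effect=draw_effect(),
                frequency=float(rng.uniform(*config.maf_range)),
                pleiotropic_effects=pleio,
            )
    graph = TraitGraph(traits, edges, instruments)
    graph.validate()
    return graph


def simulate_dataset(
    graph: TraitGraph,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """Simulate one cohort from the linear-Gaussian structural model.

    Genotypes are Bernoulli(frequency); traits are generated in topological
    order as the sum of instrument effects (primary and pleiotropic), parent
    trait effects, and independent Gaussian noise.
    """
    graph.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ivs = graph.instrument_ids
    traits = graph.trait_ids
    freqs = np.array([graph.instruments[g].frequency for g in ivs])
    G = (rng.random((config.n_samples, len(ivs))) < freqs).astype(np.int8)
    A = graph.instrument_effect_matrix().to_numpy()
    B = graph.effect_matrix().to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_samples, len(traits)))
    base = G.astype(float) @ A + noise
    Y = np.zeros_like(base)
    t_index = {t: i for i, t in enumerate(traits)}
    for t in nx.topological_sort(graph.trait_digraph()):
        j = t_index[t]
        Y[:, j] = base[:, j] + Y @ B[:, j]
    return Dataset(
        genotypes=pd.DataFrame(G, columns=ivs),
        traits=pd.DataFrame(Y, columns=traits),
        graph=graph,
    )


def simulate_replicates(config: SimulationConfig) -> Iterator[tuple[int, Dataset]]:
    """Yield (replicate index, Dataset), each from its own seeded stream.

    A fresh causal graph is drawn for every replicate, so replicate averages
    integrate over both graph structure and sampling noise.
    """
    for r in range(config.n_replicates):
        rng = config.replicate_rng(r)
        graph = sample_trait_graph(config, rng)
        yield r, simulate_dataset(graph, config, rng)


def true_causal_matrix(graph: TraitGraph) -> TruthMatrix:
    """Boolean directed-path reachability (transitive closure of the DAG)."""
    dg = graph.trait_digraph()
    if not nx.is_directed_acyclic_graph(dg):
        raise ValueError("trait graph contains a cycle")
    closure = nx.transitive_closure_dag(dg)
    r = pd.DataFrame(
        False, index=graph.trait_ids, columns=graph.trait_ids, dtype=bool
    )
    for a, b in closure.edges:
        r.loc[a, b] = True
    np.fill_diagonal(r.values, False)
    return TruthMatrix(r)


def total_effect_matrix(graph: TraitGraph) -> pd.DataFrame:
    """Path-traced total causal effects between traits.

    Entry (i, j) sums, over every directed path i -> j, the product of edge
    effects along the path: with direct-effect matrix B this is
    (I - B)^{-1} - I, which terminates because B is nilpotent on a DAG.
    """
    B = graph.effect_matrix().to_numpy()
    n = B.shape[0]
    total = np.linalg.inv(np.eye(n) - B) - np.eye(n)
    return pd.DataFrame(total, index=graph.trait_ids, columns=graph.trait_ids)


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write genotypes.tsv, traits.tsv and graph.json into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    dataset.genotypes.to_csv(d / "genotypes.tsv", sep="\t", index=False)
    dataset.traits.to_csv(d / "traits.tsv", sep="\t", index=False)
    (d / "graph.json").write_text(json.dumps(dataset.graph.to_dict(), indent=1))


def read_dataset(directory: str | Path) -> Dataset:
    d = Path(directory)
    graph = TraitGraph.from_dict(json.loads((d / "graph.json").read_text()))
    genotypes = pd.read_csv(d / "genotypes.tsv", sep="\t").astype(np.int8)
    traits = pd.read_csv(d / "traits.tsv", sep="\t")
    return Dataset(genotypes=genotypes, traits=traits, graph=graph)
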