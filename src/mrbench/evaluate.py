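"""Orchestration: run replicates, threshold discoveries, and summarise
FDR, power, discovery counts and ROC curves per method, filter and
pleiotropy level.

Discovery semantics differ by method family: MR methods discover an ordered
pair when the (BY-adjusted, by default) slope p-value is at or under a
p-value threshold; the BN method discovers it when the directed-edge
probability is at or above an edge-probability threshold.  Ground truth is
directed-path reachability in the replicate's trait graph.  Pairs an analysis
cannot test (empty instrument set, too few instruments) are recorded as
untested and can never be discovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import bn as bnmod
from . import instruments as instr
from . import mr as mrmod
from .simulate import (
    Dataset,
    SimulationConfig,
    TruthMatrix,
    sample_trait_graph,
    simulate_dataset,
    true_causal_matrix,
)

__all__ = [
    "EvaluationConfig",
    "ReplicateResult",
    "RocCurve",
    "ExperimentResult",
    "analyse_replicate",
    "discoveries",
    "fdr_power",
    "roc_curve",
    "score_table",
    "summarise",
    "run_experiment",
    "write_outputs",
]

log = logging.getLogger("mrbench")

ALL_METHODS: tuple[tuple[str, bool], ...] = tuple(
    (m, f) for m in ("IVW", "Egger", "PRESSO", "BN") for f in (False, True)
)


@dataclass(frozen=True)
class EvaluationConfig:
    """Analysis-side knobs: thresholds, method roster, bootstrap sizes."""

    mr_thresholds: tuple[float, ...] = (0.1, 0.05, 0.01)
    bn_thresholds: tuple[float, ...] = (0.7, 0.8, 0.9)
    p_pleio_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4)
    methods: tuple[tuple[str, bool], ...] = ALL_METHODS
    adjust_mr: bool = True
    compute_roc: bool = True
    roc_points: int = 200
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    gwas_alpha: float = 0.05
    unique_iv_alpha: float = 0.01

    def __post_init__(self) -> None:
        for thr in (*self.mr_thresholds, *self.bn_thresholds):
            if not 0 < thr < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if not self.p_pleio_grid or not self.methods:
            raise ValueError("p_pleio_grid and methods must be nonempty")
        known = {"IVW", "Egger", "PRESSO", "BN"}
        for m, f in self.methods:
            if m not in known or not isinstance(f, bool):
                raise ValueError(f"unknown method entry ({m!r}, {f!r})")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.presso_n_sim < 100:
            raise ValueError("presso_n_sim must be >= 100")


_MR_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "filtered",
    "estimate",
    "se",
    "pval",
    "pval_adjusted",
    "n_instruments_used",
    "n_outliers_removed",
]
_BN_COLUMNS = [
    "t1",
    "t2",
    "filtered",
    "strength",
    "direction_12",
    "prob_12",
    "prob_21",
    "n_boot",
]


@dataclass
class ReplicateResult:
    """All per-pair statistics of one replicate plus its ground truth."""

    mr: pd.DataFrame
    bn: pd.DataFrame
    truth: TruthMatrix


def _mr_input(
    beta: pd.DataFrame,
    se: pd.DataFrame,
    iset: instr.InstrumentSet,
    exposure: str,
    outcome: str,
) -> mrmod.MrInput:
    ids = iset.instruments
    return mrmod.MrInput(
        beta_exposure=beta.loc[ids, exposure].to_numpy(),
        se_exposure=se.loc[ids, exposure].to_numpy(),
        beta_outcome=beta.loc[ids, outcome].to_numpy(),
        se_outcome=se.loc[ids, outcome].to_numpy(),
        instrument_ids=tuple(ids),
    )


def analyse_replicate(
    dataset: Dataset,
    config: EvaluationConfig,
    rng: np.random.Generator | None = None,
) -> ReplicateResult:
    """Run every requested method on one simulated cohort.

    Pipeline: marginal GWAS -> Bonferroni instrument sets (and, when needed,
    UniqueIV-filtered sets, one per exposure, conditioning on every other
    trait) -> MR estimators on every ordered trait pair with enough
    instruments -> BY adjustment per method and filter -> four-variable BN on
    every unordered pair.

    The outcome trait stays inside the conditioning loop deliberately: when
    the exposure truly causes the outcome, the instrument's influence flows
    through the exposure, so the conditional test is null and valid
    instruments are not lost, while instruments with a direct pleiotropic
    effect on the outcome — the ones that create false discoveries — are
    removed.
    """
    if rng is None:
        rng = np.random.default_rng()
    truth = true_causal_matrix(dataset.graph)
    gwas = instr.run_gwas(dataset)
    traits = dataset.trait_ids
    mr_requested = [(m, f) for m, f in config.methods if m != "BN"]
    bn_requested = sorted({f for m, f in config.methods if m == "BN"})
    need_filter = any(f for _, f in config.methods)

    base = {
        t: instr.select_instruments(gwas, t, alpha=config.gwas_alpha) for t in traits
    }
    cond: dict[str, pd.DataFrame] = {}
    if need_filter:
        for t in traits:
            if base[t]:
                cond[t] = instr.conditional_association_pvals(
                    dataset, t, base[t].instruments
                )
    beta = gwas.pivot(index="instrument", columns="trait", values="beta")
    se = gwas.pivot(index="instrument", columns="trait", values="se")

    unique: dict[str, instr.InstrumentSet] = {}
    if need_filter:
        for t in traits:
            unique[t] = instr.unique_iv_filter(
                dataset,
                t,
                base[t],
                ci_alpha=config.unique_iv_alpha,
                cond_pvals=cond.get(t),
            )

    def pair_set(exposure: str, partner: str, filtered: bool) -> instr.InstrumentSet:
        del partner  # the conditioning loop covers every non-exposure trait
        return unique[exposure] if filtered else base[exposure]

    mr_rows: list[dict] = []
    if mr_requested:
        filters_needed = sorted({f for _, f in mr_requested})
        for exposure in traits:
            if not base[exposure]:
                continue
            for outcome in traits:
                if outcome == exposure:
                    continue
                for filtered in filters_needed:
                    iset = pair_set(exposure, outcome, filtered)
                    if not iset:
                        continue
                    inp = _mr_input(beta, se, iset, exposure, outcome)
                    for method, f in mr_requested:
                        if f != filtered:
                            continue
                        if inp.n_instruments < mrmod.MIN_INSTRUMENTS[method]:
                            continue
                        if method == "IVW":
                            res = mrmod.ivw(inp, exposure, outcome, filtered)
                        elif method == "Egger":
                            res = mrmod.mr_egger(inp, exposure, outcome, filtered)
                        else:
                            res = mrmod.mr_presso(
                                inp,
                                n_sim=config.presso_n_sim,
                                outlier_alpha=config.presso_outlier_alpha,
                                rng=rng,
                                exposure=exposure,
                                outcome=outcome,
                                filtered=filtered,
                            )
                        if res is None:
                            continue
                        mr_rows.append(
                            {
                                "exposure": res.exposure,
                                "outcome": res.outcome,
                                "method": res.method,
                                "filtered": res.filtered,
                                "estimate": res.estimate,
                                "se": res.se,
                                "pval": res.pval,
                                "pval_adjusted": np.nan,
                                "n_instruments_used": res.n_instruments_used,
                                "n_outliers_removed": len(res.outliers_removed),
                            }
                        )
    mr_df = pd.DataFrame(mr_rows, columns=_MR_COLUMNS)
    if len(mr_df):
        # BY adjustment scope: per method x filter, across all tested pairs
        for (_, _), idx in mr_df.groupby(["method", "filtered"]).groups.items():
            mr_df.loc[idx, "pval_adjusted"] = mrmod.by_adjust(
                mr_df.loc[idx, "pval"].to_numpy()
            )

    bn_rows: list[dict] = []
    for filtered in bn_requested:
        for t1, t2 in combinations(traits, 2):
            if not base[t1] or not base[t2]:
                continue
            iset1 = pair_set(t1, t2, filtered)
            iset2 = pair_set(t2, t1, filtered)
            if not iset1 or not iset2:
                continue
            data4 = bnmod.assemble_pair_data(dataset, iset1, iset2)
            ep = bnmod.average_network(data4, n_boot=config.n_boot, rng=rng)
            bn_rows.append(
                {
                    "t1": t1,
                    "t2": t2,
                    "filtered": filtered,
                    "strength": ep.strength,
                    "direction_12": ep.direction_12,
                    "prob_12": ep.prob_12,
                    "prob_21": ep.prob_21,
                    "n_boot": ep.n_boot,
                }
            )
    bn_df = pd.DataFrame(bn_rows, columns=_BN_COLUMNS)
    return ReplicateResult(mr=mr_df, bn=bn_df, truth=truth)


def score_table(
    rep: ReplicateResult, method: str, filtered: bool, adjusted: bool = True
) -> dict[tuple[str, str], float]:
    """Per-ordered-pair discovery statistic for one method and filter flag."""
    scores: dict[tuple[str, str], float] = {}
    if method == "BN":
        df = rep.bn[rep.bn["filtered"] == filtered]
        for row in df.itertuples(index=False):
            scores[(row.t1, row.t2)] = float(row.prob_12)
            scores[(row.t2, row.t1)] = float(row.prob_21)
    else:
        df = rep.mr[(rep.mr["method"] == method) & (rep.mr["filtered"] == filtered)]
        col = "pval_adjusted" if adjusted else "pval"
        for row in df.itertuples(index=False):
            scores[(row.exposure, row.outcome)] = float(getattr(row, col))
    return scores


def discoveries(
    scores: Mapping[tuple[str, str], float], threshold: float, mode: str
) -> set[tuple[str, str]]:
    """Threshold a score table: p-values discover at <= threshold,
    edge probabilities at >= threshold.  Untested pairs are never discoveries."""
    if mode == "pvalue":
        return {pair for pair, s in scores.items() if s <= threshold}
    if mode == "probability":
        return {pair for pair, s in scores.items() if s >= threshold}
    raise ValueError("mode must be 'pvalue' or 'probability'")


def fdr_power(
    found: set[tuple[str, str]], truth: TruthMatrix
) -> tuple[float, float, int]:
    """Empirical FDR, power and discovery count against directed-path truth.

    FDR is 0 by convention when nothing is discovered; power is 0 when the
    graph has no true directed-path pair (degenerate replicate).
    """
    pos = truth.positive_pairs()
    tp = len(found & pos)
    fp = len(found) - tp
    fdr = fp / len(found) if found else 0.0
    power = tp / len(pos) if pos else 0.0
    return fdr, power, len(found)


@dataclass
class RocCurve:
    """Replicate-mean TPR/FPR along a threshold grid for one method."""

    thresholds: np.ndarray
    mean_tpr: np.ndarray
    mean_fpr: np.ndarray
    mode: str


def roc_curve(
    tables: Sequence[Mapping[tuple[str, str], float]],
    truths: Sequence[TruthMatrix],
    grid: np.ndarray | None = None,
    mode: str = "pvalue",
    n_points: int = 200,
) -> RocCurve:
    """Mean true/false positive rates over replicates at each grid threshold.

    The grid is ``n_points`` evenly spaced thresholds augmented with every
    observed statistic, so the mean curve is step-accurate.  Denominators use
    the full ordered-pair universe: positives = directed-path pairs, negatives
    = all remaining off-diagonal pairs, so curves need not reach (1, 1) when
    statistics are truncated (BY p-values at 1, zero BN probabilities).
    """
    if not tables or len(tables) != len(truths):
        raise ValueError("need one score table per replicate truth")
    if mode not in ("pvalue", "probability"):
        raise ValueError("mode must be 'pvalue' or 'probability'")
    observed = np.concatenate(
        [np.fromiter(t.values(), dtype=float) for t in tables if t] or [np.array([])]
    )
    if grid is None:
        grid = np.unique(np.concatenate([np.linspace(0.0, 1.0, n_points), observed]))
    grid = np.asarray(grid, dtype=float)
    tprs = np.zeros((len(tables), grid.size))
    fprs = np.zeros((len(tables), grid.size))
    for i, (table, truth) in enumerate(zip(tables, truths)):
        pos = truth.positive_pairs()
        n_pos = len(pos)
        n_neg = truth.n_negatives
        s_true = np.sort(
            np.array([v for k, v in table.items() if k in pos], dtype=float)
        )
        s_false = np.sort(
            np.array([v for k, v in table.items() if k not in pos], dtype=float)
        )
        if mode == "pvalue":
            tp = np.searchsorted(s_true, grid, side="right")
            fp = np.searchsorted(s_false, grid, side="right")
        else:
            tp = s_true.size - np.searchsorted(s_true, grid, side="left")
            fp = s_false.size - np.searchsorted(s_false, grid, side="left")
        tprs[i] = tp / n_pos if n_pos else 0.0
        fprs[i] = fp / n_neg if n_neg else 0.0
    return RocCurve(
        thresholds=grid,
        mean_tpr=tprs.mean(axis=0),
        mean_fpr=fprs.mean(axis=0),
        mode=mode,
    )


def summarise(
    results: Sequence[ReplicateResult], config: EvaluationConfig
) -> pd.DataFrame:
    """Replicate-mean FDR, power and discovery count per method x threshold."""
    rows = []
    for method, filtered in config.methods:
        is_bn = method == "BN"
        thresholds = config.bn_thresholds if is_bn else config.mr_thresholds
        mode = "probability" if is_bn else "pvalue"
        tables = [
            score_table(r, method, filtered, adjusted=config.adjust_mr)
            for r in results
        ]
        for thr in thresholds:
            stats = [
                fdr_power(discoveries(t, thr, mode), r.truth)
                for t, r in zip(tables, results)
            ]
            fdrs, powers, counts = zip(*stats)
            rows.append(
                {
                    "method": method,
                    "filtered": filtered,
                    "threshold": thr,
                    "mean_fdr": float(np.mean(fdrs)),
                    "mean_power": float(np.mean(powers)),
                    "mean_discoveries": float(np.mean(counts)),
                    "n_replicates": len(results),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExperimentResult:
    summary: pd.DataFrame
    roc: pd.DataFrame
    manifest: dict


def _child_seed(seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def run_experiment(
    sim_config: SimulationConfig, eval_config: EvaluationConfig
) -> ExperimentResult:
    """End-to-end study: simulate, analyse and aggregate over the pleiotropy
    grid.  Replicate failures are logged, skipped and counted in the manifest."""
    summaries: list[pd.DataFrame] = []
    roc_rows: list[pd.DataFrame] = []
    failures: dict[str, int] = {}
    for i, p in enumerate(eval_config.p_pleio_grid):
        cfg = replace(sim_config, p_pleio=float(p), seed=_child_seed(sim_config.seed, i))
        results: list[ReplicateResult] = []
        for r in range(cfg.n_replicates):
            rng = cfg.replicate_rng(r)
            try:
                graph = sample_trait_graph(cfg, rng)
                dataset = simulate_dataset(graph, cfg, rng)
                results.append(analyse_replicate(dataset, eval_config, rng))
            except Exception:  # noqa: BLE001 - per-replicate isolation
                log.exception("replicate %d at p_pleio=%.2f failed; skipping", r, p)
                failures[f"{p}"] = failures.get(f"{p}", 0) + 1
            else:
                log.debug("replicate %d at p_pleio=%.2f done", r, p)
        if not results:
            continue
        s = summarise(results, eval_config)
        s.insert(0, "p_pleio", p)
        summaries.append(s)
        if eval_config.compute_roc:
            truths = [r.truth for r in results]
            for method, filtered in eval_config.methods:
                mode = "probability" if method == "BN" else "pvalue"
                tables = [
                    score_table(r, method, filtered, adjusted=eval_config.adjust_mr)
                    for r in results
                ]
                curve = roc_curve(
                    tables, truths, mode=mode, n_points=eval_config.roc_points
                )
                roc_rows.append(
                    pd.DataFrame(
                        {
                            "method": method,
                            "filtered": filtered,
                            "p_pleio": p,
                            "threshold": curve.thresholds,
                            "mean_tpr": curve.mean_tpr,
                            "mean_fpr": curve.mean_fpr,
                        }
                    )
                )
    summary = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    roc = (
        pd.concat(roc_rows, ignore_index=True)
        if roc_rows
        else pd.DataFrame(
            columns=["method", "filtered", "p_pleio", "threshold", "mean_tpr", "mean_fpr"]
        )
    )
    manifest = {
        "package_version": __version__,
        "simulation_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(sim_config).items()
        },
        "evaluation_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(eval_config).items()
        },
        "failed_replicates": failures,
    }
    return ExperimentResult(summary=summary, roc=roc, manifest=manifest)


def write_outputs(result: ExperimentResult, directory: str | Path) -> None:
    """Write summary.tsv, roc.tsv and manifest.json into ``directory``."""
    import json

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    result.summary.round(4).to_csv(d / "summary.tsv", sep="\t", index=False)
    result.roc.round(6).to_csv(d / "roc.tsv", sep="\t", index=False)
    (d / "manifest.json").write_text(json.dumps(_jsonable(result.manifest), indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
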