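"""Instrument handling: marginal GWAS, Bonferroni selection, UniqueIV-style
conditional-independence filtering, and weighted allele scores.

The UniqueIV filter operationalises the idea of keeping only instruments that
show no evidence of affecting any trait other than their exposure except
through the exposure itself: an instrument g is retained for exposure X iff,
for every other trait Z, the coefficient of g in the regression Z ~ g + X is
non-significant.  Descendant traits of X can be conditionally associated with
g through the causal path, so callers analysing a specific (X, Y) pair exclude
the outcome Y from the conditioning loop to avoid filtering away true signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Dataset

__all__ = [
    "InstrumentSet",
    "AlleleScore",
    "run_gwas",
    "select_instruments",
    "conditional_association_pvals",
    "unique_iv_filter",
    "weighted_allele_score",
    "write_gwas",
]


@dataclass
class InstrumentSet:
    """Instruments selected for one exposure, with their marginal-beta weights."""

    exposure: str
    instruments: list[str]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.instruments) != set(self.weights):
            raise ValueError("weights must be keyed exactly by the instrument ids")

    def __len__(self) -> int:
        return len(self.instruments)

    def __bool__(self) -> bool:
        return bool(self.instruments)


@dataclass
class AlleleScore:
    """Per-sample weighted sum of instrument genotypes for one trait."""

    trait_id: str
    values: np.ndarray


def run_gwas(dataset: Dataset) -> pd.DataFrame:
    """Marginal association scan: one simple linear regression per
    (instrument, trait) pair.

    Returns a long-format table with columns ``instrument, trait, beta, se,
    pval`` where ``beta`` is the OLS slope of trait on genotype, ``se`` its
    standard error and ``pval`` the two-sided t-test p-value (df = n - 2).
    Zero-variance genotype columns are flagged with beta 0, infinite se and
    pval 1.
    """
    G = dataset.genotype_matrix()
    Y = dataset.trait_matrix()
    n = dataset.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    Gc = G - G.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = (Gc**2).sum(axis=0)  # (m,)
    sxy = Gc.T @ Yc  # (m, t)
    syy = (Yc**2).sum(axis=0)  # (t,)
    degenerate = sxx <= 0
    safe_sxx = np.where(degenerate, 1.0, sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / safe_sxx[:, None]
        rss = np.clip(syy[None, :] - beta * sxy, 0.0, None)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / safe_sxx[:, None])
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    beta[degenerate, :] = 0.0
    se[degenerate, :] = np.inf
    pval[degenerate, :] = 1.0
    ivs = dataset.instrument_ids
    traits = dataset.trait_ids
    out = pd.DataFrame(
        {
            "instrument": np.repeat(ivs, len(traits)),
            "trait": np.tile(traits, len(ivs)),
            "beta": beta.ravel(),
            "se": se.ravel(),
            "pval": pval.ravel(),
        }
    )
    return out


def select_instruments(
    gwas: pd.DataFrame,
    exposure: str,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> InstrumentSet:
    """Bonferroni instrument selection for one exposure.

    Retains instruments with pval <= alpha / n_tests, where ``n_tests``
    defaults to the total number of instruments in the table (the nominal
    "~225 available IVs" is an expectation, not a constant).  Weights are the
    marginal betas on the exposure.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests is None:
        n_tests = int(gwas["instrument"].nunique())
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    rows = gwas[gwas["trait"] == exposure]
    hit = rows[rows["pval"] <= alpha / n_tests]
    return InstrumentSet(
        exposure=exposure,
        instruments=list(hit["instrument"]),
        weights=dict(zip(hit["instrument"], hit["beta"])),
    )


def conditional_association_pvals(
    dataset: Dataset,
    exposure: str,
    instrument_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-sided p-values for the genotype coefficient in Z ~ 1 + g + X.

    Rows are instruments, columns are traits Z != exposure X.  Closed-form
    two-covariate OLS from centred cross-products; degenerate fits (e.g.
    zero-variance genotype) yield p = 1.
    """
    ivs = list(instrument_ids) if instrument_ids is not None else dataset.instrument_ids
    others = [t for t in dataset.trait_ids if t != exposure]
    n = dataset.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")
    if not ivs or not others:
        return pd.DataFrame(index=ivs, columns=others, dtype=float)
    G = dataset.genotypes[ivs].to_numpy(dtype=float)
    x = dataset.traits[exposure].to_numpy(dtype=float)
    Z = dataset.traits[others].to_numpy(dtype=float)
    Gc = G - G.mean(axis=0)
    xc = x - x.mean()
    Zc = Z - Z.mean(axis=0)
    sgg = (Gc**2).sum(axis=0)  # (k,)
    sgx = Gc.T @ xc  # (k,)
    sxx = float(xc @ xc)
    sgz = Gc.T @ Zc  # (k, q)
    sxz = xc @ Zc  # (q,)
    szz = (Zc**2).sum(axis=0)  # (q,)
    det = sgg * sxx - sgx**2  # (k,)
    bad = det <= 1e-12
    safe_det = np.where(bad, 1.0, det)
    coef_g = (sgz * sxx - sgx[:, None] * sxz[None, :]) / safe_det[:, None]
    coef_x = (sgg[:, None] * sxz[None, :] - sgx[:, None] * sgz) / safe_det[:, None]
    rss = np.clip(szz[None, :] - coef_g * sgz - coef_x * sxz[None, :], 0.0, None)
    sigma2 = rss / (n - 3)
    var_g = sigma2 * (sxx / safe_det)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(var_g > 0, coef_g / np.sqrt(np.where(var_g > 0, var_g, 1.0)), 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 3)
    pval[bad, :] = 1.0
    return pd.DataFrame(pval, index=ivs, columns=others)


def unique_iv_filter(
    dataset: Dataset,
    exposure: str,
    base_set: InstrumentSet,
    ci_alpha: float = 0.01,
    exclude_traits: Iterable[str] = (),
    cond_pvals: pd.DataFrame | None = None,
) -> InstrumentSet:
    """UniqueIV-style filter: keep instruments conditionally independent of
    every non-exposure trait given the exposure.

    ``exclude_traits`` lists traits skipped in the conditioning loop (the
    outcome of the pair under analysis).  ``cond_pvals`` may be supplied to
    reuse a precomputed :func:`conditional_association_pvals` table.  Always a
    subset of ``base_set``; in a single-trait system it is the identity.
    """
    if base_set.exposure != exposure:
        raise ValueError("base_set was selected for a different exposure")
    if not 0 < ci_alpha < 1:
        raise ValueError("ci_alpha must lie in (0, 1)")
    if not base_set.instruments:
        return InstrumentSet(exposure, [], {})
    if cond_pvals is None:
        cond_pvals = conditional_association_pvals(
            dataset, exposure, base_set.instruments
        )
    drop = set(exclude_traits) | {exposure}
    cols = [c for c in cond_pvals.columns if c not in drop]
    if not cols:
        keep = list(base_set.instruments)
    else:
        p = cond_pvals.loc[base_set.instruments, cols].to_numpy(dtype=float)
        mask = (p > ci_alpha).all(axis=1)
        keep = [g for g, ok in zip(base_set.instruments, mask) if ok]
    return InstrumentSet(
        exposure, keep, {g: base_set.weights[g] for g in keep}
    )


def weighted_allele_score(dataset: Dataset, iset: InstrumentSet) -> AlleleScore:
    """Per-sample weighted genotype sum: score_i = sum_g w_g * genotype_ig."""
    if not iset.instruments:
        raise ValueError("cannot build an allele score from an empty instrument set")
    w = np.array([iset.weights[g] for g in iset.instruments], dtype=float)
    values = dataset.genotypes[iset.instruments].to_numpy(dtype=float) @ w
    return AlleleScore(trait_id=iset.exposure, values=values)


def write_gwas(gwas: pd.DataFrame, path: str | Path) -> None:
    gwas.to_csv(path, sep="\t", index=False)
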