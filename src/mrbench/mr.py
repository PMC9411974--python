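"""Summary-statistic Mendelian-randomization estimators.

Three estimators operate on per-instrument (exposure effect, outcome effect)
pairs with their standard errors:

* ``ivw`` — fixed-effect inverse-variance-weighted regression through the
  origin, weights 1/se_y^2.
* ``mr_egger`` — the same weighted regression with a free intercept absorbing
  directional pleiotropy; the causal estimate is the slope.
* ``mr_presso`` — a residual-sum-of-squares heterogeneity test with a
  parametric-bootstrap reference distribution, per-instrument outlier removal
  (Bonferroni-adjusted), and IVW re-estimation on the retained instruments.

Slope tests use a normal reference with fixed-effect standard errors
(dispersion fixed at 1), the common summary-statistic convention.
``by_adjust`` wraps Benjamini–Yekutieli step-up adjustment, which controls the
FDR under arbitrary dependence between tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["MrInput", "MrResult", "ivw", "mr_egger", "mr_presso", "by_adjust"]

MIN_INSTRUMENTS = {"IVW": 1, "Egger": 3, "PRESSO": 4}

_P_FLOOR = 1e-300  # keep p-values in (0, 1]


@dataclass
class MrInput:
    """Per-instrument summary statistics for one exposure–outcome pair."""

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    instrument_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = self.beta_exposure.shape[0]
        if k < 1:
            raise ValueError("need at least one instrument")
        for name in ("se_exposure", "beta_outcome", "se_outcome"):
            if getattr(self, name).shape[0] != k:
                raise ValueError("summary-statistic vectors must share a length")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")
        if self.instrument_ids is not None and len(self.instrument_ids) != k:
            raise ValueError("instrument_ids length mismatch")

    @property
    def n_instruments(self) -> int:
        return int(self.beta_exposure.shape[0])

    def subset(self, mask: np.ndarray) -> "MrInput":
        ids = (
            tuple(np.asarray(self.instrument_ids)[mask])
            if self.instrument_ids is not None
            else None
        )
        return MrInput(
            self.beta_exposure[mask],
            self.se_exposure[mask],
            self.beta_outcome[mask],
            self.se_outcome[mask],
            ids,
        )


@dataclass
class MrResult:
    """One method's causal estimate for an ordered trait pair."""

    exposure: str
    outcome: str
    method: str
    estimate: float
    se: float
    pval: float
    n_instruments_used: int
    filtered: bool = False
    outliers_removed: tuple[str, ...] = ()
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    global_pval: float | None = None


def _norm_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR)


def ivw(
    inp: MrInput,
    exposure: str = "exposure",
    outcome: str = "outcome",
    filtered: bool = False,
) -> MrResult:
    """Fixed-effect IVW: weighted regression through the origin.

    estimate = sum(w b_x b_y) / sum(w b_x^2), se = sum(w b_x^2)^{-1/2},
    with w = 1/se_y^2; two-sided normal test of estimate/se.
    """
    w = 1.0 / inp.se_outcome**2
    sxx = float(np.sum(w * inp.beta_exposure**2))
    if sxx <= 0:
        raise ValueError("IVW slope undefined: all exposure effects are zero")
    estimate = float(np.sum(w * inp.beta_exposure * inp.beta_outcome)) / sxx
    se = sxx**-0.5
    return MrResult(
        exposure=exposure,
        outcome=outcome,
        method="IVW",
        estimate=estimate,
        se=se,
        pval=_norm_p(estimate / se),
        n_instruments_used=inp.n_instruments,
        filtered=filtered,
    )


def mr_egger(
    inp: MrInput,
    exposure: str = "exposure",
    outcome: str = "outcome",
    filtered: bool = False,
) -> MrResult | None:
    """Weighted regression of b_y on b_x with a free intercept.

    Returns None (a recorded no-test) with fewer than 3 instruments.  The
    causal estimate and p-value refer to the slope; the intercept (directional
    pleiotropy) is kept as metadata.
    """
    if inp.n_instruments < MIN_INSTRUMENTS["Egger"]:
        return None
    w = 1.0 / inp.se_outcome**2
    W = float(w.sum())
    xbar = float(np.sum(w * inp.beta_exposure)) / W
    ybar = float(np.sum(w * inp.beta_outcome)) / W
    xc = inp.beta_exposure - xbar
    sxx = float(np.sum(w * xc**2))
    if sxx <= 0:
        raise ValueError("Egger slope undefined: no spread in exposure effects")
    slope = float(np.sum(w * xc * (inp.beta_outcome - ybar))) / sxx
    se_slope = sxx**-0.5
    intercept = ybar - slope * xbar
    se_intercept = float(np.sqrt(1.0 / W + xbar**2 / sxx))
    return MrResult(
        exposure=exposure,
        outcome=outcome,
        method="Egger",
        estimate=slope,
        se=se_slope,
        pval=_norm_p(slope / se_slope),
        n_instruments_used=inp.n_instruments,
        filtered=filtered,
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_pval=_norm_p(intercept / se_intercept),
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised over the left-out instrument.

    Supports batched inputs of shape (..., k); the sums run over the last axis.
    """
    sxy = w * bx * by
    sxx = w * bx * bx
    tot_xy = sxy.sum(axis=-1, keepdims=True)
    tot_xx = sxx.sum(axis=-1, keepdims=True)
    denom = tot_xx - sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (tot_xy - sxy) / denom
    return np.where(denom > 0, out, 0.0)


def mr_presso(
    inp: MrInput,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    exposure: str = "exposure",
    outcome: str = "outcome",
    filtered: bool = False,
) -> MrResult | None:
    """MR-PRESSO: global heterogeneity test, outlier removal, IVW re-fit.

    The observed global statistic is RSS = sum_j w_j (b_yj - beta_(-j) b_xj)^2
    with leave-one-out IVW slopes beta_(-j) and w_j = 1/se_yj^2.  The reference
    distribution is a parametric bootstrap: b_x* ~ N(b_x, se_x^2),
    b_y* ~ N(beta_(-j) b_x, se_y^2), with leave-one-out slopes recomputed on
    each simulated set.  Per-instrument outlier p-values come from each
    instrument's simulated residual-term distribution, Bonferroni-adjusted
    across instruments; flagged instruments are removed and the final estimate
    is plain IVW on the remainder.  Returns None with fewer than 4 instruments
    or when every instrument is flagged.
    """
    if inp.n_instruments < MIN_INSTRUMENTS["PRESSO"]:
        return None
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    k = inp.n_instruments
    bx, by = inp.beta_exposure, inp.beta_outcome
    w = 1.0 / inp.se_outcome**2
    loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    bx_sim = rng.normal(bx, inp.se_exposure, size=(n_sim, k))
    by_sim = rng.normal(loo * bx, inp.se_outcome, size=(n_sim, k))
    loo_sim = _loo_slopes(bx_sim, by_sim, w)
    res_sim = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = res_sim.sum(axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    outlier_p = (1 + (res_sim >= res_obs).sum(axis=0)) / (1 + n_sim)
    adjusted = np.minimum(1.0, outlier_p * k)
    flagged = adjusted < outlier_alpha
    if flagged.all():
        return None
    retained = inp.subset(~flagged)
    base = ivw(retained, exposure, outcome, filtered)
    removed: tuple[str, ...]
    if inp.instrument_ids is not None:
        removed = tuple(np.asarray(inp.instrument_ids)[flagged])
    else:
        removed = tuple(str(i) for i in np.nonzero(flagged)[0])
    return MrResult(
        exposure=exposure,
        outcome=outcome,
        method="PRESSO",
        estimate=base.estimate,
        se=base.se,
        pval=base.pval,
        n_instruments_used=retained.n_instruments,
        filtered=filtered,
        outliers_removed=removed,
        global_pval=global_pval,
    )


def by_adjust(pvals) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]
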