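"""Four-variable Bayesian-network analysis of one trait pair.

For a pair of traits T1, T2 with weighted allele scores S1, S2, the admissible
network space is constrained: S1 -> T1 and S2 -> T2 are fixed, no other edges
touch the score nodes, so the only free edge is between the two traits.  That
leaves three candidate structures — no trait edge, T1 -> T2, or T2 -> T1 —
scored exhaustively with a linear-Gaussian BIC (no search heuristics or random
restarts are needed).

Bootstrap model averaging turns the discrete choice into edge probabilities:
the rows are resampled with replacement, the best structure is tallied, and

    strength      = P(an edge appears between T1 and T2)
    direction_12  = P(edge points T1 -> T2 | edge appears)
    prob_12       = strength * direction_12     (directed-edge probability)

``prob_12 + prob_21 = strength <= 1`` by construction; pairs whose bootstraps
never fit an edge get probability zero in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .instruments import AlleleScore, InstrumentSet, weighted_allele_score
from .simulate import Dataset

__all__ = [
    "Structure",
    "FourVarData",
    "EdgeProbability",
    "gaussian_bic_score",
    "best_structure",
    "average_network",
    "assemble_pair_data",
]

_EPS = 1e-12
# column order inside FourVarData.matrix
_T1, _T2, _S1, _S2 = 0, 1, 2, 3


class Structure(Enum):
    NONE = "none"
    T1_TO_T2 = "t1->t2"
    T2_TO_T1 = "t2->t1"


# tie-break preference: NONE, then T1->T2, then T2->T1
_STRUCTURES = (Structure.NONE, Structure.T1_TO_T2, Structure.T2_TO_T1)
_INDEX = {s: i for i, s in enumerate(_STRUCTURES)}


@dataclass
class FourVarData:
    """Continuous columns T1, T2, S1, S2 for one trait pair."""

    t1: str
    t2: str
    matrix: np.ndarray  # (n, 4), columns T1, T2, S1, S2

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (n_samples, 4)")

    @classmethod
    def from_columns(
        cls,
        t1: str,
        t2: str,
        trait1: np.ndarray,
        trait2: np.ndarray,
        score1: np.ndarray,
        score2: np.ndarray,
    ) -> "FourVarData":
        return cls(t1, t2, np.column_stack([trait1, trait2, score1, score2]))

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class EdgeProbability:
    """Bootstrap-averaged directed-edge probabilities for one trait pair."""

    strength: float
    direction_12: float
    prob_12: float
    prob_21: float
    n_boot: int
    n_t1_t2: int
    n_t2_t1: int
    n_none: int

    @classmethod
    def from_tallies(cls, n12: int, n21: int, n_boot: int) -> "EdgeProbability":
        if n12 + n21 > n_boot:
            raise ValueError("tallies exceed bootstrap count")
        strength = (n12 + n21) / n_boot
        direction = n12 / (n12 + n21) if (n12 + n21) > 0 else 0.0
        return cls(
            strength=strength,
            direction_12=direction,
            prob_12=strength * direction,
            prob_21=strength * (1.0 - direction),
            n_boot=n_boot,
            n_t1_t2=int(n12),
            n_t2_t1=int(n21),
            n_none=int(n_boot - n12 - n21),
        )


def _gauss_ll(rss, n: int):
    """Maximised Gaussian log-likelihood given residual sum of squares."""
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def _structure_scores(S: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """BIC network scores for the three structures, from centred scatter S.

    ``S`` may be batched with shape (..., 4, 4); returns (scores, valid) with
    scores of shape (..., 3) in the order (NONE, T1->T2, T2->T1) and a boolean
    validity mask flagging singular/degenerate fits.

    Per-node score = maximised log-likelihood - (d/2) ln n with
    d = #coefficients + intercept + variance.  The score-node terms (S1, S2
    marginals) are shared by all three structures and included for a full
    network score.
    """
    S00 = S[..., _T1, _T1]
    S11 = S[..., _T2, _T2]
    S22 = S[..., _S1, _S1]
    S33 = S[..., _S2, _S2]
    S01 = S[..., _T1, _T2]
    S02 = S[..., _T1, _S1]
    S03 = S[..., _T1, _S2]
    S12 = S[..., _T2, _S1]
    S13 = S[..., _T2, _S2]

    with np.errstate(divide="ignore", invalid="ignore"):
        rss_t1_s1 = S00 - S02**2 / S22
        rss_t2_s2 = S11 - S13**2 / S33
        # T2 ~ S2 + T1
        det12 = S33 * S00 - S03**2
        quad12 = (S00 * S13**2 - 2.0 * S03 * S13 * S01 + S33 * S01**2) / det12
        rss_t2_full = S11 - quad12
        # T1 ~ S1 + T2
        det21 = S22 * S11 - S12**2
        quad21 = (S11 * S02**2 - 2.0 * S12 * S02 * S01 + S22 * S01**2) / det21
        rss_t1_full = S00 - quad21

        valid = (
            (S00 > _EPS)
            & (S11 > _EPS)
            & (S22 > _EPS)
            & (S33 > _EPS)
            & (det12 > _EPS)
            & (det21 > _EPS)
            & (rss_t1_s1 > _EPS)
            & (rss_t2_s2 > _EPS)
            & (rss_t2_full > _EPS)
            & (rss_t1_full > _EPS)
        )
        one = np.ones_like(S00)
        rss_t1_s1 = np.where(valid, rss_t1_s1, one)
        rss_t2_s2 = np.where(valid, rss_t2_s2, one)
        rss_t2_full = np.where(valid, rss_t2_full, one)
        rss_t1_full = np.where(valid, rss_t1_full, one)
        s22 = np.where(valid, S22, one)
        s33 = np.where(valid, S33, one)

        shared = _gauss_ll(s22, n) + _gauss_ll(s33, n)
        half_logn = 0.5 * np.log(n)
        # d: score nodes 2 each; trait node = #parents + intercept + variance
        score_none = (
            shared
            + _gauss_ll(rss_t1_s1, n)
            + _gauss_ll(rss_t2_s2, n)
            - half_logn * 10.0
        )
        score_12 = (
            shared
            + _gauss_ll(rss_t1_s1, n)
            + _gauss_ll(rss_t2_full, n)
            - half_logn * 11.0
        )
        score_21 = (
            shared
            + _gauss_ll(rss_t1_full, n)
            + _gauss_ll(rss_t2_s2, n)
            - half_logn * 11.0
        )
    scores = np.stack([score_none, score_12, score_21], axis=-1)
    return scores, valid


def _scatter(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc


def gaussian_bic_score(data: FourVarData, structure: Structure) -> float:
    """BIC network score of one admissible structure (higher is better)."""
    n = data.n_samples
    if n <= 6:
        raise ValueError("need more than 6 samples to score a structure")
    scores, valid = _structure_scores(_scatter(data.matrix), n)
    if not bool(valid):
        raise np.linalg.LinAlgError("singular regression while scoring structure")
    return float(scores[_INDEX[structure]])


def best_structure(data: FourVarData) -> Structure:
    """Exhaustive argmax over the three admissible structures.

    Ties break toward NONE, then T1->T2 (fixed order).
    """
    n = data.n_samples
    if n <= 6:
        raise ValueError("need more than 6 samples to score a structure")
    scores, valid = _structure_scores(_scatter(data.matrix), n)
    if not bool(valid):
        raise np.linalg.LinAlgError("singular regression while scoring structure")
    return _STRUCTURES[int(np.argmax(scores))]


def average_network(
    data: FourVarData,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> EdgeProbability:
    """Bootstrap model averaging over the three-structure space.

    Rows are resampled with replacement ``n_boot`` times; the best structure
    of each resample is tallied.  Resamples with a degenerate (zero-variance
    or singular) fit fall back to NONE.  Fully deterministic given ``rng``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    X = data.matrix
    n = data.n_samples
    if n <= 6:
        raise ValueError("need more than 6 samples to score a structure")
    tallies = np.zeros(3, dtype=int)
    chunk = max(1, min(n_boot, 500_000 // n))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        Xb = X[idx]  # (b, n, 4)
        sums = Xb.sum(axis=1)  # (b, 4)
        M2 = np.einsum("bni,bnj->bij", Xb, Xb, optimize=True)
        S = M2 - sums[:, :, None] * sums[:, None, :] / n
        scores, valid = _structure_scores(S, n)
        choice = np.argmax(scores, axis=-1)
        choice = np.where(valid, choice, 0)
        tallies += np.bincount(choice, minlength=3)
        done += b
    return EdgeProbability.from_tallies(
        n12=int(tallies[1]), n21=int(tallies[2]), n_boot=n_boot
    )


def assemble_pair_data(
    dataset: Dataset, iset1: InstrumentSet, iset2: InstrumentSet
) -> FourVarData:
    """Build the four-column table (T1, T2, S1, S2) for one trait pair.

    Allele-score weights come from the original (full-data) GWAS; bootstrap
    resampling later acts on rows of this assembled table only.
    """
    s1 = weighted_allele_score(dataset, iset1)
    s2 = weighted_allele_score(dataset, iset2)
    return FourVarData.from_columns(
        iset1.exposure,
        iset2.exposure,
        dataset.traits[iset1.exposure].to_numpy(dtype=float),
        dataset.traits[iset2.exposure].to_numpy(dtype=float),
        s1.values,
        s2.values,
    )
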