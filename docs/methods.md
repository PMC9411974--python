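# Methods

## The generative model

Each replicate draws a fresh causal system and cohort.

**Trait graph.** The `n_traits` (default 15) traits are placed in a uniformly
random order.  Each trait draws a child count from Poisson(`mean_children`,
default 1.5), truncated to the number of traits after it in the order, and
connects to that many downstream traits chosen uniformly without replacement.
This realises "causal on around 1–2 other traits" while guaranteeing
acyclicity by construction.  Edge effects have magnitude uniform on
`effect_magnitude_range` (default [0.1, 0.4]) with random sign.

**Instruments.** Every trait receives a block of binary instruments, count
uniform on [`iv_per_trait_min`, `iv_per_trait_max`] (defaults 10, 20, so
≈225 instruments in total), allele frequency uniform on `maf_range` (default
[0.1, 0.5]), and a primary effect drawn like an edge effect.  With
probability `p_pleio` an instrument is horizontally pleiotropic: it gains one
direct effect on a uniformly chosen non-primary trait.  `p_pleio` is thus the
expected fraction of invalid instruments.  We considered the alternative
reading in which every (instrument, other-trait) pair independently gains an
effect with probability `p_pleio`; it makes pleiotropy-free instruments
essentially extinct already at `p_pleio = 0.2` ((1−0.2)¹⁴ ≈ 4%), so
conditional-independence filtering strips nearly all instruments and
filtered MR loses both power and FDR control — qualitatively incompatible
with the benchmark this package reproduces, where filtering lowers FDR at
usable power.  The per-instrument reading is therefore the package's model.

**Data.** Genotypes are Bernoulli(frequency) 0/1 variables (a haploid
simplification; no linkage disequilibrium, no dosages).  Traits follow the
linear-Gaussian structural equations, generated in topological order:

    trait_t = Σ_g a_gt · genotype_g + Σ_p b_pt · trait_p + ε_t,
    ε_t ~ N(0, noise_sd²),  noise_sd default 1.

The sample size default is `n_samples = 2000`, chosen so that Bonferroni
selection at 0.05/225 retains most true instruments (a per-instrument
association χ² of roughly 20–80 at the default effect and frequency ranges).

**Ground truth.** `true_causal_matrix` is the transitive closure of the trait
DAG: (i, j) is a positive iff a directed path i → j exists.  All 210 ordered
pairs of 15 traits form the discovery universe; `total_effect_matrix` gives
the path-traced total effect (I − B)⁻¹ − I used for parameter-recovery
checks.

**Randomness.** One master seed; replicate r uses the independent child
stream `SeedSequence(seed, spawn_key=(r,))`, so any replicate can be re-run
in isolation.  The experiment driver derives one child seed per pleiotropy
level the same way.

## Instrument processing

`run_gwas` fits the simple regression of every trait on every instrument
(closed-form OLS; two-sided t test, df = n − 2).  Bonferroni selection keeps
instruments with p ≤ alpha/#instruments, where #instruments is the
replicate's actual count, not the nominal 225.  Selected marginal betas are
the allele-score weights: score_i = Σ_g w_g · genotype_ig.

**UniqueIV filter.** The filter retains an instrument g for exposure X iff
for *every* other trait Z the coefficient of g in the regression
Z ~ 1 + g + X is non-significant at `ci_alpha` (default 0.01, two-sided t,
df = n − 3) — i.e. g shows no evidence of reaching any trait except through
X.  Two consequences of the linear-Gaussian model shape this rule:

* If X truly causes Y, all of g's influence on Y flows through X, so
  g ⊥ Y | X holds and valid instruments are *not* filtered away.  For this
  reason the outcome of a pair under analysis stays inside the conditioning
  loop; one filtered set per exposure serves every pair.
* Conditioning on X opens the collider path g → X ← parent, inducing a small
  conditional association between g and X's ancestors.  At the default
  effect sizes the induced partial correlation (≈0.02) sits well below the
  detection boundary at n = 2000 and `ci_alpha` = 0.01, so the collider
  leakage costs little; with much larger samples or stricter effects it
  would make the filter conservative.

## MR estimators

All three estimators consume one-sample summary statistics: exposure and
outcome betas come from the same simulated cohort's GWAS (the design being
benchmarked does the same), so winner's-curse and sample-overlap effects are
part of the measured behaviour, not removed.

* **IVW** — weights 1/se_y²; fixed-effect closed form; the slope test uses a
  normal reference with se = (Σw b_x²)^{-1/2}.
* **MR-Egger** — same weights with a free intercept; slope and intercept
  standard errors are fixed-effect (dispersion pinned at 1) for consistency
  with IVW; requires ≥ 3 instruments, otherwise the pair is recorded as
  untested.
* **MR-PRESSO** — observed statistic RSS = Σ_j w_j (b_yj − β̂₍₋ⱼ₎ b_xj)² with
  leave-one-out IVW slopes; the reference distribution simulates
  b_x* ~ N(b_x, se_x²), b_y* ~ N(β̂₍₋ⱼ₎ b_x, se_y²) and recomputes the
  leave-one-out slopes on each simulated set (`presso_n_sim` rounds, default
  1000; global p uses the +1/(n+1) add-one rule).  Per-instrument outlier
  p-values come from each instrument's simulated residual-term distribution,
  Bonferroni-adjusted; flagged instruments are removed and the reported
  estimate/p-value is plain IVW on the remainder (identical to IVW when
  nothing is flagged).  The global test p is kept as metadata only — the
  discovery statistic is always the slope test, matching how "causal
  predictions" are counted.  Requires ≥ 4 instruments.

**Multiplicity.** Per replicate, method and filter variant, slope p-values
across all tested ordered pairs are Benjamini–Yekutieli adjusted
(`statsmodels`' step-up implementation), the FDR control valid under
arbitrary dependence.  Adjustment can be disabled (`adjust_mr=False`) to
study raw-p ROC behaviour.

## Four-variable Bayesian network

For a pair (T1, T2) with allele scores (S1, S2), the admissible structures
fix S1 → T1 and S2 → T2 and forbid all other score edges, leaving exactly
three candidates: no trait edge, T1 → T2, T2 → T1.  Each is scored by a
linear-Gaussian BIC: per node, the maximised Gaussian log-likelihood given
its parents (OLS with intercept, MLE variance) minus (d/2)·ln n with
d = #coefficients + intercept + variance.  BIC is the conventional score for
this model family; AIC would only reweight the complexity penalty.  The
argmax over three candidates is exhaustive — no search, restarts or
tie-break heuristics beyond a fixed preference order (NONE, then T1 → T2)
for exact score ties.

`average_network` draws `n_boot` row resamples with replacement (default
1000; desk-scale runs use 300), tallies the best structure of each, and
reports strength = (#T1→T2 + #T2→T1)/n_boot, direction = #T1→T2 / #edges
(defined 0 when no edge ever appears), and the directed-edge probabilities
prob_12 = strength × direction, prob_21 = strength × (1 − direction).
Resamples with a degenerate fit (zero-variance column, singular normal
equations) tally as NONE.  The implementation vectorises the bootstrap
through batched scatter matrices and closed-form 2×2 solves; a test pins it
to the one-resample-at-a-time route.  Allele-score weights are computed once
per dataset from the full-data GWAS and held fixed across bootstrap
resamples — the cheaper of the two possible readings, adopted deliberately.

Because a pair whose bootstraps never fit an edge has probability exactly 0
in both directions, the BN's ROC curve cannot reach TPR = FPR = 1 at any
positive threshold; the evaluation keeps this boundary behaviour instead of
interpolating over it.

## Evaluation conventions

* Discovery rules: MR pairs at adjusted p ≤ threshold (defaults 0.1, 0.05,
  0.01); BN ordered pairs at directed-edge probability ≥ threshold (defaults
  0.7, 0.8, 0.9).
* Empirical FDR contributes 0 for a replicate with zero discoveries (the
  standard convention); power is TP / #directed-path positives and is
  defined 0 for the rare edge-free graph.
* Pairs without usable instruments (empty Bonferroni or UniqueIV set, or too
  few instruments for a method) are untested: they can never be discovered
  and therefore depress power, mirroring a pipeline that drops them.
* ROC curves evaluate ~200 evenly spaced thresholds plus every observed
  statistic; TPR/FPR denominators always use the full positive/negative
  universes, so BY truncation at 1 and zero BN probabilities cap the curves
  below (1, 1).

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the study at desk scale — 30
replicates × 300 bootstraps for the BN headline FDRs, 20 replicates per
pleiotropy level for the method-ordering and parameter-recovery checks, and
reduced MR-PRESSO simulation counts (200–400) where only calibration or
ordering is at stake.  These sizes keep replicate-mean Monte-Carlo error
comfortably inside the comparison tolerances while remaining quick on a
single CPU; the full-scale configuration (100 replicates, 1000 bootstraps)
is the library default.

## What the generator does and does not emulate

It reproduces the benchmark's stated conditions: random sparse causal DAGs,
binary instruments in the stated counts, controlled pleiotropy, continuous
traits, and the full analysis chain.  It does not model linkage
disequilibrium, diploid dosages, case-control traits, assortative or
population structure, measurement error, or two-sample designs.  Conclusions
from passing tests are therefore about the relative behaviour of the methods
under an idealised SEM, not about their absolute performance on biobank
data.  Two further caveats: the exact effect-size distributions and sample
size of the original external simulation code are not published, so these
are configuration with declared defaults; and the UniqueIV rule here is a
single-test surrogate for a richer pipeline, with `ci_alpha` exposed for
sensitivity analysis.  Under this package's conditions the desk-scale BN
FDRs come out below the original study's reported levels (single-digit
percentages rather than 17%/27%) — the simulator's sparser pleiotropy and
exactly-linear model make the four-variable BN cleaner than in the original
data — while every qualitative ordering the study reports (filtering lowers
MR FDR under pleiotropy; filtered MR-PRESSO is at or near the lowest FDR;
BN FDR below unfiltered MR under pleiotropy) is reproduced.

## Known limitations

* MR-PRESSO's outlier test shares the LOO slopes between observed and
  simulated statistics; with very few instruments (4–6) the global p is
  slightly conservative.
* Egger standard errors ignore overdispersion; under strong balanced
  pleiotropy its p-values are anti-conservative, which is visible in the
  unfiltered-Egger FDR at `p_pleio ≥ 0.3`.
* The BN direction probability is driven by the allele scores; traits with
  weak instrument sets yield strength ≈ 1 but direction ≈ 0.5 for strongly
  coupled pairs, splitting the directed probability below typical
  thresholds.
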