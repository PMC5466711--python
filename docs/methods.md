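# Methods

## Model

Every estimator in the package assumes the three-level Gaussian
random-effects model for a single connectome edge observed over K
subjects, J scan conditions and I sessions:

y_ijk = μ + δ_k + γ_jk + ε_ijk,  δ_k ~ N(0, σ₃²), γ_jk ~ N(0, σ₂²),
ε_ijk ~ N(0, σ₀²), all mutually independent.

δ is a stable subject trait, γ a subject-by-condition interaction, and ε
session-to-session noise. There is no fixed condition main effect:
conditions enter only through the random interaction. A flag on the
results object could be used to normalize ICCs differently, but the model
itself is fitted exactly as written. Edges are modeled marginally — the
model is per-edge, so cross-edge covariance is irrelevant to every
univariate estimator and enters only I2C2, which is covariance-agnostic by
construction (it uses trace functionals only).

The two reliability coefficients are

- ICC(between conditions) = σ₃² / (σ₃² + σ₂²),
- ICC(between sessions)  = (σ₃² + σ₂²) / (σ₃² + σ₂² + σ₀²).

The between-condition denominator deliberately excludes σ₀²: the
coefficient asks how much of the condition-relevant variance is subject
trait, not how large that variance is relative to session noise.
`icc_between_condition(..., include_residual=True)` gives the
total-variance-normalized variant for users who want it.

Connectivity values are Fisher-z transformed before fitting by default:
the z scale has unbounded support, which matches the Gaussian assumption,
and near-stabilizes the sampling variance of a correlation. Raw-r panels
are accepted (``units="r"``) but the model makes no allowance for their
bounded support.

## Estimators

**Balanced ANOVA (method of moments).** For complete data the three mean
squares

- MS_subject = J·I·Σ_k (ȳ_k − ȳ)² / (K − 1)
- MS_cell  = I·Σ_{k,j} (ȳ_jk − ȳ_k)² / (K(J − 1))
- MS_error  = Σ (y − ȳ_jk)² / (K·J·(I − 1))

have expectations σ₀² + I σ₂² + I J σ₃², σ₀² + I σ₂², σ₀², giving the
unbiased moment estimators σ̂₀² = MS_error, σ̂₂² = (MS_cell − MS_error)/I,
σ̂₃² = (MS_subject − MS_cell)/(I·J). Negative moment estimates are clamped
to zero and the clamping count is logged — the estimator is unbiased only
before clamping. With J = 1 the reduced two-level (one-way) formulas are
used and σ₂² is fixed at zero.

**EM for the REML criterion.** With missing sessions the design is
unbalanced and the package maximizes the restricted likelihood by EM,
treating the random effects as missing data. Because both random effects
are nested within subject, the marginal covariance is block-diagonal by
subject, V_k = σ₀²I + σ₂²C_k + σ₃²11ᵀ with C_k the same-condition
indicator, so each iteration inverts only per-subject blocks (≤ J·I
observations) and is vectorized across all edges that share a missingness
pattern (scan-level dropout masks all edges of a scan, so in practice all
of them). The EM updates keep every component nonnegative by
construction. Plain EM converges linearly — very slowly when one
component is small relative to the residual — so every fourth iteration
the engine attempts an Aitken extrapolation of the parameter trajectory
and accepts it only where the restricted log-likelihood does not
decrease. Convergence is declared when the extrapolation-estimated
distance to the fixed point falls below 1e−10 relative to the edge's data
variance, with a 500-iteration cap; edges that hit the cap are flagged
`converged=False` (typically a fraction of a percent, all with boundary
estimates). On complete balanced data with interior estimates the REML
solution coincides with the moment estimator, which the tests verify to
1e−6 relative; an independent cross-check against lme4's REML fit of the
same nested model (via Rscript) guards the unbalanced path. The residual
variance is floored at 1e−10 times the data variance so V stays
invertible even when the within-subject variance is genuinely zero.

`fit(method="auto")` dispatches: method of moments when the panel is
complete, EM-REML whenever any observation is missing.

**Per-condition ICC.** Within one condition the model reduces to the
two-level y_ik = μ + b_k + e_ik; the same EM engine is run without the
cell component and the ICC is σ̂_b²/(σ̂_b² + σ̂_w²).

**I2C2.** The multivariate (image-level) reliability of a p-dimensional
edge vector is estimated by the trace ratio λ̂ = 1 − tr_within/tr_total,
where tr_within pools squared deviations of replicates from their subject
means (divided by Σ_k (n_k − 1)) and tr_total pools deviations from the
grand mean (divided by S − 1), clamped to [0, 1]. The replicate unit
matters: `panel_to_replicates` defaults to *session* replicates with the
J condition vectors concatenated into the image, so within-subject
variation is purely between-session and the population target equals the
between-session ICC — the univariate consistency the tests check. Network
blocks are, by default, all edges *incident* to a network (matching a
network-wise display of reliabilities); a `within` mode restricts to
edges internal to the network.

**Fingerprinting.** Scan similarity is the Pearson correlation between
edge vectors (raw r units by convention; the transform choice does not
affect orderings materially). Same-subject and different-subject pair
sets are summarized by mean, SD, and the normal-approximation 95% CI of
the mean (mean ± 1.96·SD/√n_pairs); with tens of thousands of pairs the
CI is much narrower than the SD, which is the expected behavior for this
statistic. By default all same-subject pairs are pooled across sessions
and conditions; strata flags restrict to same-condition or same-session
pairs. Identification assigns each scan the subject of its most similar
other scan, ties broken toward the lowest scan index.

**Scalar quality measures.** Per-scan scalar metrics (e.g. mean FD, SNR)
get a two-level test-retest ICC per (measure, condition) and a one-way
ANOVA of condition; the ANOVA's unit of observation is the scan (values
pooled over subjects and sessions), with a subject-averaged variant by
flag. Under exchangeability the scan-level test is exact for Gaussian
data, which the type-I-error simulation confirms at the nominal 5%.

## Synthetic data

`simulate_edge_panel` draws the model exactly: independent edges, effects
drawn once per (subject), (subject, condition) and (subject, condition,
session) and summed. Defaults are the study conditions used throughout
the tests: K=10, J=4 (rest, inscapes, movie, flanker), I=12,
(σ₃², σ₂², σ₀²) = (0.04, 0.01, 0.10) in z² units — a between-condition
ICC of 0.80 and a between-session ICC of 1/3 — with μ = 0.3 (a typical
within-network z value). `default_missing_cells` reproduces the dropout
pattern of three subjects each missing one flanker session.

`simulate_timeseries_panel` embeds the same draws in per-scan T×R
Gaussian time series: a shared base correlation matrix (block structure:
within-network r = 0.35, between-network r = 0.10 over a Yeo-7-style
partition plus a no-overlap bucket) is z-transformed, the scan's effect
draws are added edge-wise, the result is mapped back through tanh and
repaired to the nearest positive-definite correlation matrix (eigenvalue
clipping at 1e−8, diagonal renormalization), and sampling factorizes
through the Cholesky root. T defaults to 414 frames (≈10 min at TR
1.45 s). Random streams are keyed by (seed, subject, condition, session)
through `numpy.random.SeedSequence`, so outputs are independent of
iteration order and bitwise reproducible.

What the generator does *not* emulate: cross-edge covariance beyond what
the shared base matrix induces, temporal autocorrelation, head motion,
physiological noise, condition main effects, or heavy-tailed edge
distributions. Passing tests therefore demonstrate estimator correctness
under the model's own assumptions, not robustness of the pipeline to real
acquisition artifacts.

## Scan-duration analysis

`duration_pseudosessions` samples, per subject and condition, sessions
without replacement into four disjoint groups of m = minutes/10 sessions,
concatenates each group's time series in time, and correlates the longer
series as one pseudo-session. Concatenation averages the m session
effects and shrinks the sampling noise of the correlation, so the
per-condition test-retest ICC rises with duration — the monotonicity the
tests assert at 10/20/30 minutes with the pseudo-session count held at
four. The number of pseudo-sessions is held constant so the comparison
isolates duration from replicate count.

## Counterbalanced schedules

A schedule assigns each of the four conditions to one slot per session
such that (1) each session contains every condition once, (2) each
condition occupies each slot n_sessions/n_slots times, and (3) every
ordered condition pair (a, b) occurs as a within-session a→b transition
equally often — for the 12×4 default, all slot and predecessor counts are
exactly 3. Non-rest conditions rotate three stimulus exemplars so that
each appears once in every block of three sessions; rest has a single
exemplar fixed at 1. The search is randomized depth-first backtracking
over session rows (candidate rows are permutations, pruned when any slot
or predecessor count would exceed its target) with up to 10,000 seeded
restarts and a per-restart node budget; infeasible parameter
combinations (non-integral targets) are rejected up front with the
violated constraint named. Cohort generation offsets the seed per subject
so condition and exemplar orderings vary across participants.

## Numerical choices and edge cases

- Percentiles use linear interpolation between order statistics.
- Network-sorted edge order: blocks ordered by the canonical network list
  (visual, somatomotor, dorsal attention, ventral attention, limbic,
  frontoparietal, default, no-overlap), then ascending ROI index pairs;
  edge labels are lexicographically sorted ROI pairs, so vectors from
  permuted ROI orderings agree as (label, value) multisets.
- |r| = 1 under Fisher-z raises unless clipping (default 0.999999 in the
  pipeline) is enabled.
- Zero-variance ROI columns and constant edge vectors raise errors naming
  the offender rather than propagating NaNs.
- Degenerate ICC denominators return NaN, never a silent 0 or 1.
- Motion derivatives are backward differences with a zero first row.
- Nuisance designs drop exactly collinear columns before fitting and
  error (listing the dropped columns) only if still rank-deficient.

## Problem sizes in tests

The test suite and the acceptance script run at V = 50–1000 edges,
R = 8–20 ROIs and T = 120–414 frames — sizes at which every Monte-Carlo
tolerance asserted (5% on mean components, ±0.10/±0.06 on median ICCs,
0.05 on I2C2) is comfortably inside the estimator's sampling noise while
a full run stays around a minute. The statistics scale linearly in edges
and quadratically in ROIs; nothing in the implementation is specific to
these sizes.
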