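# Methods

This note documents the statistical machinery in `mdcfa`: the data
generator and what it emulates, the tetrachoric estimation step, the CFA
models and their identification, the robust scaling, the simulation
design, and the numerical and design choices that were genuinely open.

## Synthetic data generator

`datagen` draws n×p matrices from N(0, R) with R compound-symmetric:
unit diagonal and λ² off-diagonal, the correlation structure implied by a
single common factor with equal loadings λ. Sampling goes through the
Cholesky factor of R, which is equivalent to generating factor scores plus
uniquenesses. Defaults are the study conditions used throughout:
n = 500, p = 20, λ = 0.35 (off-diagonal 0.1225 — small enough that both
good and bad model fit are reachable), and a median split
(`split_prob = 0.5`, cut at Φ⁻¹(0.5) = 0) mapping continuous scores to
binary items. The split probability is configurable; 0.5 was also checked
empirically to be the only split consistent with the complete-data fit
level this generator is meant to reproduce.

Planned missingness is defined by a `MissingDesign`: a fixed set of
columns (1-based; the canonical sets are columns 17–20 and 11–20), a
per-column rate (0.2/0.4/0.6), and a row-selection scheme. Exactly
round(rate·n) entries per design column are blanked.

**Row-selection scheme.** Two schemes are implemented.

* `"shared"` (default): one seeded row sample is blanked in every design
  column. This is the block/booklet reading of a planned missing data
  design — a designed subset of respondents skips the whole affected item
  block — and it is the scheme under which missingness produces *common*
  systematic variation across the affected columns, which is the premise
  of the missing-data latent variable. After zero replacement, the
  affected items share deterministic zeros, so their mutual tetrachoric
  correlations rise far above the attribute level (≈0.36 / 0.52 / 0.66 at
  20/40/60% against an attribute baseline of 0.1225), while correlations
  between affected and unaffected items attenuate (≈0.10 / 0.09 / 0.07).
  A one-factor model with fixed loadings cannot represent this and
  misfits in proportion to the amount of missingness; one extra
  missing-factor variance absorbs most of it.
* `"independent"`: rows are drawn per column. Missingness is then
  unstructured; zero replacement only attenuates (the affected block's
  internal correlations fall toward rate²·0.1225) and no common
  missing-data variation arises. This scheme is kept for contrast; the
  missing-data factor has little to absorb under it.

Zero replacement preserves the margin identity
Pr(X=1, incomplete) = (1 − rate)·Pr(X=1, complete) exactly in
expectation (hypergeometric row sampling at n = 500 keeps per-column
deviations within ~0.02).

What the generator does **not** emulate: real planned designs with
multiple rotated booklet groups, missingness correlated with the latent
trait (MNAR beyond the design), unequal loadings, multidimensional
structure, or ordinal (multi-category) items. Passing tests therefore
demonstrate the behavior of the method under an idealized one-factor
population with design-driven missingness, not robustness to violations
of those assumptions.

## Tetrachoric correlations

Each binary item is treated as a dichotomized standard normal variable
V_i with threshold τ_i = Φ⁻¹(1 − p₁ᵢ) fixed from the item's margin.
For a pair, the correlation of (V_i, V_j) is estimated by two-step
maximum likelihood: with thresholds fixed, the multinomial log-likelihood
of the 2×2 table is maximized over ρ. The profile score is proportional
to n₁₁/π₁₁ − n₁₀/π₁₀ − n₀₁/π₀₁ + n₀₀/π₀₀ (the bivariate-normal density
factor is positive), which is strictly decreasing in ρ, so the maximizer
is found by vectorized bisection (54 iterations, interval width ~1e-16)
over all p(p−1)/2 pairs simultaneously. Bivariate rectangle
probabilities use an Owen's-T evaluation of the bivariate normal CDF,
deterministic and accurate to ~1e-14 (cross-checked in the tests against
scipy's quadrature and a dense grid-search likelihood oracle).

Numerical policies: tables containing a zero cell receive a +0.5
continuity correction on every cell; |ρ| is bounded at 0.999; degenerate
margins (a constant column) raise an error naming the item. Matrices
that fall below the positive-definiteness floor (smallest eigenvalue
1e-6) are ridge-smoothed: add c to the diagonal and rescale by 1/(1+c)
with the smallest c reaching the floor, preserving the correlation
metric; the ridge magnitude is recorded on the result and the operation
is idempotent. Probability-based covariances
(Pr(both 1) − Pr(1)·Pr(1)) are provided as the simpler alternative input
statistic; missing entries count as not-1 there, so no replacement step
is needed.

## CFA models and estimation

`ModelSpec` holds the loading pattern (numbers or `"free"`) for the
attribute factor and, optionally, the missing-data factor; factors are
orthogonal (their covariance is fixed to 0, as required for interpreting
φ_missing as missing-data variance) and all uniquenesses are free.
Identification: each factor needs a fixed nonzero loading or a fixed
variance. In the free two-factor model the missing factor loads only on
design columns; if *every* column is a design column, the first missing
loading is fixed to 0 to keep the bifactor identified. Free-parameter
counts at p = 20: 21 (one-factor fixed, df 189), 40 (one-factor free,
df 170), 22 (two-factor fixed, df 188), 50 (two-factor free with ten
design columns, df 160). With four design columns the free two-factor
model has t = 44 and df = 166 by the same counting rule.

The ML discrepancy F = ln|Σ(θ)| + tr(S Σ⁻¹) − ln|S| − p is minimized by
L-BFGS-B with analytic gradients (dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)·dΣ]); the input
correlation matrix is analyzed as a covariance matrix and χ² = (N−1)·F.
Starting values: factor variance at the mean off-diagonal of S (free
loadings at its square root), uniquenesses at the complement; up to five
jittered restarts on failure; a non-PD Σ(θ) excursion is handled by a
smallest-eigenvalue penalty with its exact gradient. Uniquenesses are
bounded below at 1e-6; a clamped uniqueness is flagged as a Heywood case
and the fit marked nonconvergent. Convergence requires the gradient
max-norm below 1e-7 relative to the objective scale (1e-7·max(1, F) —
an absolute 1e-7 is unattainable in double precision when F is of order
several units, as it is for badly misfitting models).

## Robust scaling and fit indices

Γ, the (N−1)-scaled covariance of the unique elements of S, is estimated
by a respondent-level bootstrap (default B = 200; the simulation profile
uses B = 100): rows of the zero-replaced binary matrix are resampled with
replacement and the *entire* tetrachoric pipeline is re-run per resample,
including PD smoothing, so Γ reflects exactly the statistic that was
computed. Resamples with a degenerate margin are redrawn and counted.
The Satorra–Bentler factor is c = tr(UΓ)/df with
U = W − WΔ(ΔᵀWΔ)⁻¹ΔᵀW, W = ½Dᵀ(Σ̂⁻¹⊗Σ̂⁻¹)D the normal-theory weight at
the solution and Δ = ∂vech Σ/∂θ at θ̂; scaled χ² = raw χ²/c. Under
normal-theory Γ, c = 1 exactly (U annihilates the model tangent space),
which the tests verify. For a saturated model (df = 0) scaling is
undefined and the raw statistic is returned with a flag.

Indices follow the standard definitions; RMSEA uses (N−1) in the
denominator, matching the χ² multiplier, and SRMR is computed from
correlation-metric residuals over all unique elements, untouched by
scaling. The independence model (free diagonal, df p(p−1)/2) is the
baseline for NNFI/CFI. **Convention:** by default (`"scaled-model"`) the
SB-scaled χ² enters the model side of every χ²-based index while the
baseline enters raw. The alternatives (`"scaled"` — both scaled;
`"raw"` — no scaling) are selectable. The default was chosen because it
is the only convention whose complete-data CFI/NNFI levels (≈0.98/0.99)
line up with the fit levels this machinery is meant to reproduce;
scaling the baseline as well depresses CFI to ≈0.95 on identical input.
Model comparisons use the ΔCFI ≥ 0.01 and ΔRMSEA ≥ 0.015 criteria.

## Simulation design

The full design crosses missingness conditions {none; 4 columns (17–20);
10 columns (11–20)} × {20, 40, 60% per column} with the four model
families. One base data matrix is generated per replication index and
modified to show each missing-data condition, so between-condition
comparisons share Monte-Carlo noise. Seeds derive from a master seed via
`SeedSequence`, making every cell independently reproducible. Two-factor
models are fit to incomplete data only. Nonconvergent or Heywood
replications are excluded from cell means and counted; a cell with more
than 10% exclusions is flagged unreliable. Cell summaries report the
mean and a normal-approximation 95% CI (mean ± 1.96·SD/√reps).

The desk-scale profile is 100 replications with B = 100 bootstrap
resamples (about 0.5 s per replication-condition on one CPU; the full
four-table design runs in ~10 minutes). A fuller 300/200 profile is a
flag away (`--reps 300 --bootstrap 200`), tripling the runtime; the
reported means move by less than the CI half-widths between profiles.

## Known limitations

* The two-step tetrachoric estimator and its bootstrap Γ assume a
  bivariate-normal latent response; zero-replaced items violate this by
  construction (their latent distribution is a mixture). The bootstrap Γ
  remains a valid sampling-covariance estimate of the statistic actually
  computed, but analytic Γ formulas from other software can differ
  there, and with them the scaled χ² of badly misfitting models.
* SRMR levels track the sampling noise of the tetrachorics
  (per-pair SD ≈ 0.07 at n = 500 under a median split), so the
  complete-data SRMR sits near 0.065; software whose tetrachoric
  estimates are noisier will print larger SRMRs at the same RMSEA/CFI.
* Standard errors of parameter estimates, mean structures, multi-group
  models, polychoric (multi-category) input, and the weighted
  semi-hierarchical variant of the missing-data model are out of scope.
* Fit with φ_missing free can in principle go negative (the optimizer
  does not constrain it); under the shared scheme the estimate is
  positive in practice.
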