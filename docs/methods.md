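# Methods

## Model

For SNP j = 1..L (uncorrelated, from non-overlapping samples of one source
population) the observed summary statistics are modelled as

    γ̂_j ~ Normal(γ_j, σ_Xj²)          (SNP–exposure)
    Γ̂_j ~ Normal(β γ_j + α_j, φ σ_Yj²) (SNP–outcome)

with causal effect β, horizontal-pleiotropy effects α_j, and multiplicative
overdispersion φ ≥ 1. Under no pleiotropy (α_j = 0, φ = 1) the Wald ratios
β̂_j = Γ̂_j/γ̂_j are homogeneous up to sampling noise with variance
(σ_Yj² + β² σ_Xj²)/γ̂_j² — the key point being that replacing γ_j by its
estimate inflates the ratio variance by β² σ_Xj². The generalized weight

    w_j(β, φ) = γ̂_j² / (φ σ_Yj² + β² σ_Xj²)

and generalized Q(w(β, φ), β) = Σ_j w_j(β, φ)(β̂_j − β)² are the single
primitive from which every estimator and test in the package is built. No
γ̂–Γ̂ covariance terms appear anywhere: the two samples are assumed
independent (two-sample designs with partial overlap are out of scope).

An exact distributional fact worth noting: at the true (β, φ) each term
w_j(β,φ)(β̂_j − β)² = (Γ̂_j − βγ̂_j)²/(φσ_Yj² + β²σ_Xj²) is exactly χ²₁,
independently across SNPs — the generalized Q at the truth is exactly χ²_L.
Estimating β from the same data costs roughly one degree of freedom, hence
the χ²_{L−1} reference used throughout for Q at a fitted estimate.

## Estimators

- *first*, *second*: closed-form IVW with w_j(0, 1) and w_j(β̂_j, 1).
- *iterative*: β⁽⁰⁾ = first-order estimate; β⁽ⁱ⁾ = IVW with w(β⁽ⁱ⁻¹⁾, 1);
  stop when |β⁽ⁱ⁾ − β⁽ⁱ⁻¹⁾| < `tol` (default 1e-10, `max_iter` 100;
  convergence typically takes 3–6 iterations; non-convergence is flagged,
  not raised).
- *exact (fixed-effect)*: β̂ = argmin_β Q(w(β, 1), β). Q(β) is bounded (it
  tends to the summed per-SNP F statistics as |β| → ∞) and can be multimodal
  with weak instruments, so the minimizer uses a 401-point grid over
  [β̂_first ± 10·max(SE_first, IQR of ratios)] — widened adaptively if the
  grid minimum lands on an edge — followed by bounded scalar polish of every
  grid-local minimum; ties break toward the lowest β. A multimodal grid is
  flagged on the result.
- *exact (random-effects)*: (β̂, φ̂) jointly solve Q(w(β, φ), β) = L − 1
  subject to ∂Q/∂β = 0, computed by profiling: β(φ) minimizes Q at fixed φ,
  and φ̂ solves the scalar equation by bracketed root-finding (bracket grown
  geometrically from [1, 2]; beyond φ = 10⁶ an extreme-heterogeneity error
  is raised). If the fixed-effect minimized Q ≤ L − 1 then φ̂ = 1 and the
  fixed-effect fit is returned (φ is truncated below at 1 everywhere).

## Inference

All Wald-type inference uses Student-t with L − 1 df, not the normal — this
matters at L ≲ 30. Multiplicative random effects for the regression-style
schemes set φ̂ = max(1, Q/(L − 1)) and inflate the fixed-effect SE
(Σ w_j)^{-1/2} by √φ̂; the additive random-effects model is not implemented
(the multiplicative form is the standard choice for summary-data MR).

Exact fixed-effect CIs come in two constructions:

1. symmetric t: β̂ ± t_{0.975, L−1} (Σ w_j(β̂, 1))^{-1/2};
2. Q-inversion: {β : Q(w(β, 1), β) ≤ χ²_{L−1}(q*)} with the small-sample
   adjustment q* = 2Φ(t_{0.975, L−1}) − 1 (→ 0.95 from above as L grows).
   The set is found by a vectorized scan for sign changes of Q − threshold
   over the (adaptively widened) search bracket plus Brent root-polishing.
   Because the global Q is a goodness-of-fit statistic, this set is
   typically wider than the symmetric interval (half-width
   ≈ SE·√(threshold − Q_min)), can be a union of disjoint intervals
   (`non_connected`), unbounded when the threshold exceeds the summed F
   statistics, or — in the ~5% of datasets where the minimized Q itself
   exceeds the threshold — empty, in which case the degenerate point set at
   the minimizer is returned. Coverage of this construction, not its width,
   is the reproduced quantity.

The exact random-effects CI uses a non-parametric bootstrap: L records
resampled with replacement B times (default 1000; resamples with < 3
distinct SNPs are redrawn and counted), the SE is the SD of the bootstrap
estimates, and the headline interval is the symmetric t interval on that SE,
with the percentile interval reported alongside. The bootstrap was chosen
over inverting Q because the inversion ignores uncertainty in φ̂.

The weighted median orders the ratios, forms normalized cumulative
first-order weights with the midpoint (w_j/2) convention, and interpolates
at 0.5; its SE is a parametric bootstrap redrawing γ̂_j and Γ̂_j from their
sampling distributions. Note the interpolating convention makes
"duplicate every SNP" only approximately invariant (the knots move within
their local spacing); the step-function median would be exactly invariant
but cannot reproduce the interpolated estimator this comparator follows.

## Outlier scanning

Per-SNP contributions Q_j are referred to χ²₁ (an approximation — β̂ is
estimated, and the contributions sum to a χ²_{L−1}-like total). Nominal
threshold: χ²₁(1 − α) = 3.84 at α = 0.05; Bonferroni: χ²₁(1 − α/L), computed
exactly for the given L. The scan is deliberately descriptive: no automated
removal loop is provided, only `leave_one_out` for explicit sensitivity
analyses. Exact weights make the most aggressive dilution correction and
therefore tend to flag at least as many SNPs as iterative weights; iterative
weights are the recommended basis for individual outlier status, exact
weights for the global test.

## Synthetic-data generator

`simulate_dataset` draws γ_j ≡ 1, σ_Xj = σ_X = 1/√(mean_f − 1) — which makes
E[γ̂²/σ_X²] equal the mean-F target exactly — and σ_Yj = σ_Y constant.
Pleiotropy is multiplicative (outcome noise inflated by φ, so ratio
variability is φ× its no-pleiotropy value) or additive
(α_j ~ Normal(0, τ²)). Defaults are the study conditions used throughout:
L = 25, mean F ∈ {10, 25, 40, 61, 100}, β ∈ {0, 0.05, 0.1}, φ = 2 for
random-effects studies, 10 000 replicates (the bundled studies and
acceptance script run 2000 and report Monte-Carlo SEs).

σ_Y defaults to 1/33 (σ_X at F = 10, divided by 11), held fixed across F
within a study. This calibration pins the weak-instrument regime where the
β²σ_X²/σ_Y² variance distortion is of order 1–3 at β = 0.05–0.1, and
analytically reproduces the observed first-order mean-Q inflation
(E[Q_first] ≈ (L−1)(1 + β²σ_X²/σ_Y²) ≈ 53 at β = 0.1, F = 10).

What the generator does *not* emulate: per-SNP variation in true instrument
strength γ_j and in σ_Yj, allele-frequency structure, selection of
instruments by significance (winner's curse), sample overlap, LD between
instruments, and directional (non-zero-mean) pleiotropy. Quantities that
depend only on (L, β, F, φ) — null behaviour of Q under every weighting,
unbiasedness and coverage of the exact schemes, φ recovery, strong-instrument
dilution — are therefore comparable to published reference values, while the
*magnitude* of first-order type-I-error inflation at low F additionally
depends on the σ_X/σ_Y ratio and is checked qualitatively (material
inflation, monotone in decreasing F), not numerically. Replicate r of every
study uses the r-th spawned child of `SeedSequence(seed)`, so results are
bit-reproducible and order-independent.

## Numerical choices and edge cases

- Weights are double precision, unclipped; a weight that is non-finite or
  non-positive (both SEs zero) raises rather than being capped.
- σ_Xj = 0 is allowed (the NOME limit, where all schemes coincide);
  σ_Yj must be strictly positive. γ̂_j = 0 raises a division error naming
  the SNP — silently dropping rows would change L and the Q df.
- df convention: L − 1 whenever β is any in-sample IVW estimate (all four
  schemes); L only for an externally fixed β (explicit flag).
- Grid-search tie-break: lowest β wins on exact Q ties.
- TSV I/O round-trips floats exactly (shortest-repr write,
  `float_precision="round_trip"` read).

## Problem sizes

The bundled Monte-Carlo studies run at L = 25 and 2000 replicates per
scenario (rate MC SE ≈ 0.005, mean-estimate MC SE ≈ 2–8 × 10⁻⁴), chosen to
make the full acceptance sweep complete in well under a minute while keeping
every comparison's Monte-Carlo error small relative to the effects of
interest. All runners accept larger `reps` (the reference designs used
10 000) and L up to hundreds of SNPs.

## Known limitations

- One-sample and partial-overlap designs, correlated (LD) instruments, and
  directional pleiotropy (MR-Egger-style intercepts and the heterogeneity
  statistic about that fit) are out of scope.
- Additive random-effects estimation is not provided; the additive model
  appears only as a simulation option for power studies.
- Bootstrap coverage studies of the exact random-effects interval are
  supported (`exact_bootstrap_B`) but expensive (B refits per replicate);
  the bundled studies default to the analytic multiplicative SE.
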