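# mrmodq

Modified-weight inverse-variance weighted (IVW) estimation and generalized
Cochran's *Q* heterogeneity analysis for **two-sample summary-data Mendelian
randomization (MR)**.

## The problem

Two-sample summary-data MR combines, for *L* uncorrelated SNPs, published
SNP–exposure association estimates (γ̂_j, σ_Xj) and SNP–outcome association
estimates (Γ̂_j, σ_Yj) from independent samples. Each valid instrument yields
a Wald ratio β̂_j = Γ̂_j/γ̂_j for the causal effect β, and the IVW estimate is
their inverse-variance weighted average

    β̂_IVW = Σ_j w_j β̂_j / Σ_j w_j,

with Cochran's Q = Σ_j w_j (β̂_j − β̂_IVW)² testing homogeneity against
χ²_{L−1}. Everything hinges on the weight w_j, i.e. on the variance assigned
to β̂_j. The variance implied by the fitted model with multiplicative
overdispersion φ ≥ 1 is

    Var(β̂_j) = (φ σ_Yj² + β² σ_Xj²) / γ̂_j²,   w_j(β, φ) = 1 / Var(β̂_j).

The two standard choices are special cases: **first-order** weights
substitute β = 0 (equivalently, assume no measurement error in γ̂_j — the
NOME assumption), and **second-order** weights substitute β = β̂_j. With weak
instruments (mean F-statistic γ̂²/σ_X² near 10) and a non-zero causal effect,
first-order weights understate Var(β̂_j) — Q then over-detects heterogeneity
and the estimate suffers regression dilution — while second-order weights
overstate it and remove nearly all power to detect real pleiotropy.

`mrmodq` implements two *modified* weighting schemes that fix both problems:

- **iterative** — refresh w_j(β) with successive IVW estimates until stable;
- **exact** — keep w_j as a proper function of β and minimize the
  generalized Q(w(β, 1), β) directly (a LIML-like estimator). Exact
  weighting holds Q faithful to χ²_{L−1} at every instrument strength and
  removes regression dilution bias.

Around these it provides: fixed-effect and multiplicative random-effects
inference (for exact weights, a joint (β, φ) solve of
Q(w(β, φ), β) = L − 1 subject to ∂Q/∂β = 0, with a non-parametric bootstrap
CI); a Q-inversion confidence set for the fixed-effect exact estimate;
per-SNP Q contributions with χ²₁ outlier thresholds (nominal and
Bonferroni); leave-one-out sensitivity analysis; a weighted-median
comparator; and a Monte-Carlo simulation engine for type-I error, power,
bias and coverage studies.

Intended users: genetic epidemiologists running summary-data MR analyses,
particularly with many (possibly weak) instruments.

## Worked example

Fit all four schemes to a synthetic weak-instrument dataset (25 SNPs,
true β = 0.1, mean F ≈ 10, multiplicative pleiotropy φ = 2):

```python
import numpy as np
from mrmodq import fit, weighted_median, outlier_scan, mean_f_statistic
from mrmodq.simulate import SimConfig, simulate_dataset

cfg = SimConfig(L=25, beta=0.1, mean_f=10.0, pleiotropy="multiplicative",
                phi=2.0, seed=7)
ds = simulate_dataset(cfg, np.random.default_rng(7))
print("mean F:", round(mean_f_statistic(ds), 1))
for scheme in ("first", "second", "iterative", "exact"):
    r = fit(ds, scheme=scheme, effects="multiplicative")
    print(f"{scheme:9s} beta={r.beta: .4f} se={r.se:.4f} "
          f"Q={r.q.q:.1f} (p={r.q.p_value:.3g}) phi={r.phi_hat:.2f}")
```

prints

```
mean F: 7.5
first     beta= 0.0943 se=0.0112 Q=68.8 (p=3.35e-06) phi=2.87
second    beta= 0.0719 se=0.0092 Q=24.5 (p=0.432) phi=1.02
iterative beta= 0.0943 se=0.0112 Q=33.1 (p=0.101) phi=1.38
exact     beta= 0.1081 se=0.0116 Q=30.3 (p=0.175) phi=1.63
```

Read this as the method's story in one dataset: first-order weighting
reports wildly significant heterogeneity (Q = 68.8 on 24 df) and a diluted
estimate; second-order weighting erases the (real, φ = 2) heterogeneity
entirely; the modified schemes report moderate heterogeneity and the exact
estimate (0.108) sits closest to the true β = 0.1. The weighted median
(`weighted_median(ds, B=1000, seed=7)` → 0.0854 ± 0.0129) is the robust
comparator. `outlier_scan(ds, r)` ranks per-SNP Q contributions against the
χ²₁ thresholds (3.84 nominal; 10.3 Bonferroni-corrected for L = 25).

The same analysis runs from the shell on any harmonized TSV with columns
`snp, beta_exposure, se_exposure, beta_outcome, se_outcome` (TwoSampleMR
dotted names also accepted):

```
mrmodq fit summary.tsv --scheme all --effects multiplicative --median --loo --out results/
mrmodq simulate --preset table1 --reps 2000 --seed 1 --out study/
```

Recommended practice, reflected in the CLI defaults: **exact** weights for
the global heterogeneity test, **iterative** weights for per-SNP outlier
status.

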