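"""Synthetic two-sample summary-data generator and Monte-Carlo study runners.

The data-generating process draws, for each of L instruments with true
SNP-exposure association gamma_j = 1:

    beta_exposure_j ~ Normal(1, sigma_x^2),  sigma_x = 1/sqrt(mean_f - 1)
    beta_outcome_j  ~ Normal(beta + alpha_j, phi * sigma_y^2)

so that the expected mean single-instrument F statistic,
E[beta_exposure^2]/sigma_x^2 = (1 + sigma_x^2)/sigma_x^2, equals exactly the
requested ``mean_f``. Pleiotropy is either absent (alpha_j = 0, phi = 1),
multiplicative (phi > 1 inflates the outcome sampling variance so ratio
-estimate variability is phi times its no-pleiotropy value), or additive
(alpha_j ~ Normal(0, tau2)). The reported per-SNP standard errors are the
sampling values sigma_x and sigma_y — the analyst does not see phi or tau2.

``sigma_y`` defaults to 1/33: with beta of order 0.05-0.1 this places the
weak-instrument (F = 10) regime where first-order weights understate the
ratio-estimate variance by a factor of 2-3, the regime of interest; see the
methods note for what this generator does and does not emulate.

Replicate r of a study uses the r-th spawned child of ``SeedSequence(seed)``,
so studies are bit-reproducible and safely parallelizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SummaryData
from .estimators import (
    _exact_minimize,
    _exact_random_point,
    _first_point,
    invert_q_ci,
)

__all__ = [
    "SimConfig",
    "StudySummary",
    "simulate_dataset",
    "run_heterogeneity_study",
    "run_estimation_study",
    "run_power_study",
]

DEFAULT_SIGMA_Y = 1.0 / 33.0
ALL_SCHEMES = ("first", "second", "iterative", "exact")


@dataclass(frozen=True)
class SimConfig:
    """Design of one Monte-Carlo scenario.

    ``mean_f`` is the target mean single-instrument F statistic (>= 2);
    ``pleiotropy`` selects the heterogeneity model and reads ``phi`` (>= 1,
    multiplicative variance inflation) or ``tau2`` (>= 0, additive pleiotropy
    variance) accordingly.
    """

    L: int = 25
    beta: float = 0.0
    mean_f: float = 10.0
    pleiotropy: str = "none"  # none | multiplicative | additive
    phi: float = 1.0
    tau2: float = 0.0
    sigma_y: float = DEFAULT_SIGMA_Y
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.mean_f <= 1:
            raise ValueError("mean_f must exceed 1")
        if self.pleiotropy not in ("none", "multiplicative", "additive"):
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if self.phi < 1 or self.tau2 < 0 or self.reps < 1:
            raise ValueError("invalid SimConfig")

    @property
    def sigma_x(self) -> float:
        """SNP-exposure SE implied by the mean-F target: 1/sqrt(mean_f - 1)."""
        return 1.0 / np.sqrt(self.mean_f - 1.0)


@dataclass(frozen=True)
class StudySummary:
    """Per-scheme Monte-Carlo aggregates with binomial MC standard errors."""

    config: SimConfig
    reps: int
    per_scheme: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scheme, agg in self.per_scheme.items():
            rows.append({"scheme": scheme, **agg})
        return pd.DataFrame(rows)

    def __getitem__(self, scheme: str) -> dict[str, float]:
        return self.per_scheme[scheme]


def _rate_se(rate: float, reps: int) -> float:
    return float(np.sqrt(rate * (1 - rate) / reps))


def simulate_dataset(cfg: SimConfig, rng: np.random.Generator) -> SummaryData:
    """Draw one synthetic harmonized summary-data table."""
    sx = cfg.sigma_x
    gx = rng.normal(1.0, sx, cfg.L)
    mu = np.full(cfg.L, cfg.beta)
    sd_out = cfg.sigma_y
    if cfg.pleiotropy == "multiplicative":
        sd_out = cfg.sigma_y * np.sqrt(cfg.phi)
    elif cfg.pleiotropy == "additive":
        mu = mu + rng.normal(0.0, np.sqrt(cfg.tau2), cfg.L)
    gy = rng.normal(mu, sd_out)
    ids = np.array([f"snp_{j + 1}" for j in range(cfg.L)], dtype=object)
    return SummaryData(
        ids, gx, np.full(cfg.L, sx), gy, np.full(cfg.L, cfg.sigma_y)
    )


# ---------------------------------------------------------------------------
# fast per-replicate fits (fixed-effect point + Q only)


def _fit_point_q(ds: SummaryData, scheme: str, tol: float = 1e-10,
                 max_iter: int = 100) -> tuple[float, float, np.ndarray]:
    """(beta_hat, Q, weights) for one fixed-effect scheme, minimal overhead."""
    g2 = ds.beta_exposure**2
    sx2 = ds.se_exposure**2
    sy2 = ds.se_outcome**2
    bj = ds.beta_outcome / ds.beta_exposure
    if scheme == "first":
        w = g2 / sy2
        b = float(np.sum(w * bj) / np.sum(w))
    elif scheme == "second":
        w = g2 / (sy2 + bj**2 * sx2)
        b = float(np.sum(w * bj) / np.sum(w))
    elif scheme == "iterative":
        w = g2 / sy2
        b = float(np.sum(w * bj) / np.sum(w))
        for _ in range(max_iter):
            w = g2 / (sy2 + b * b * sx2)
            b_new = float(np.sum(w * bj) / np.sum(w))
            if abs(b_new - b) < tol:
                b = b_new
                break
            b = b_new
        w = g2 / (sy2 + b * b * sx2)
    elif scheme == "exact":
        b, _, _ = _exact_minimize(ds, 1.0)
        w = g2 / (sy2 + b * b * sx2)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    q = float(np.sum(w * (bj - b) ** 2))
    return b, q, w


def _child_rngs(cfg: SimConfig) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(cfg.reps)]


def run_heterogeneity_study(
    cfg: SimConfig, schemes: Sequence[str] = ALL_SCHEMES
) -> StudySummary:
    """Monte-Carlo null behaviour (or power) of Q per weighting scheme.

    Each replicate simulates a dataset, fits each scheme's fixed-effect
    estimate, evaluates its Q at that estimate and compares against the 95th
    percentile of chi-squared with L - 1 df. With ``cfg.pleiotropy='none'``
    the rejection rate is the type-I error; otherwise it is power.
    """
    crit = float(stats.chi2.ppf(0.95, cfg.L - 1))
    qs = {s: np.empty(cfg.reps) for s in schemes}
    for r, rng in enumerate(_child_rngs(cfg)):
        ds = simulate_dataset(cfg, rng)
        for s in schemes:
            _, q, _ = _fit_point_q(ds, s)
            qs[s][r] = q
    per_scheme = {}
    for s in schemes:
        rate = float(np.mean(qs[s] > crit))
        per_scheme[s] = {
            "mean_q": float(np.mean(qs[s])),
            "sd_q": float(np.std(qs[s], ddof=1)),
            "rejection_rate": rate,
            "mc_se_rejection": _rate_se(rate, cfg.reps),
        }
    return StudySummary(cfg, cfg.reps, per_scheme)


def run_estimation_study(
    cfg: SimConfig,
    schemes: Sequence[str] = ALL_SCHEMES,
    exact_bootstrap_B: int = 0,
) -> StudySummary:
    """Monte-Carlo bias, SE and CI coverage per weighting scheme.

    Without pleiotropy all schemes are fitted as fixed-effect models; the
    exact scheme reports coverage of both the symmetric Student-t interval
    (``coverage``) and the Q-inversion interval (``coverage_inversion``).
    With pleiotropy, the regression schemes use multiplicative random-effects
    SEs and the exact scheme is the joint (beta, phi) fit; its bootstrap
    coverage is computed only when ``exact_bootstrap_B`` > 0 (costly).
    """
    L = cfg.L
    tcrit = float(stats.t.ppf(0.975, L - 1))
    random_effects = cfg.pleiotropy != "none"
    est = {s: np.empty(cfg.reps) for s in schemes}
    ses = {s: np.empty(cfg.reps) for s in schemes}
    cover = {s: np.zeros(cfg.reps) for s in schemes}
    cover_inv = np.zeros(cfg.reps)
    phis = np.ones(cfg.reps)
    for r, rng in enumerate(_child_rngs(cfg)):
        ds = simulate_dataset(cfg, rng)
        for s in schemes:
            if s == "exact" and random_effects:
                b, phi_hat, _, _ = _exact_random_point(ds)
                w = ds.beta_exposure**2 / (
                    phi_hat * ds.se_outcome**2 + b * b * ds.se_exposure**2
                )
                se = float(np.sum(w) ** -0.5)
                phis[r] = phi_hat
                if exact_bootstrap_B:
                    from .estimators import bootstrap_ci

                    se, ci, _ = bootstrap_ci(
                        ds, B=exact_bootstrap_B,
                        seed=int(rng.integers(2**31)), point=b,
                    )
                    cover[s][r] = ci[0] <= cfg.beta <= ci[1]
                else:
                    cover[s][r] = abs(b - cfg.beta) <= tcrit * se
            else:
                b, q, w = _fit_point_q(ds, s)
                se = float(np.sum(w) ** -0.5)
                if random_effects:
                    se *= max(1.0, q / (L - 1)) ** 0.5
                cover[s][r] = abs(b - cfg.beta) <= tcrit * se
                if s == "exact" and not random_effects:
                    qmin = q
                    inv = invert_q_ci(ds, _fit=(b, qmin))
                    cover_inv[r] = inv.contains(cfg.beta)
            est[s][r] = b
            ses[s][r] = se
    per_scheme = {}
    for s in schemes:
        agg = {
            "mean_estimate": float(np.mean(est[s])),
            "sd_estimate": float(np.std(est[s], ddof=1)),
            "mean_se": float(np.mean(ses[s])),
            "coverage": float(np.mean(cover[s])),
            "mc_se_coverage": _rate_se(float(np.mean(cover[s])), cfg.reps),
        }
        if s == "exact" and not random_effects:
            agg["coverage_inversion"] = float(np.mean(cover_inv))
            agg["mc_se_coverage_inversion"] = _rate_se(float(np.mean(cover_inv)), cfg.reps)
        if s == "exact" and random_effects:
            agg["mean_phi_hat"] = float(np.mean(phis))
            agg["mc_se_phi_hat"] = float(np.std(phis, ddof=1) / np.sqrt(cfg.reps))
        per_scheme[s] = agg
    return StudySummary(cfg, cfg.reps, per_scheme)


def run_power_study(
    base: SimConfig,
    variances: Sequence[float],
    Ls: Sequence[int] = (25,),
    schemes: Sequence[str] = ALL_SCHEMES,
) -> pd.DataFrame:
    """Power of Q to detect pleiotropy over a grid of pleiotropy magnitudes.

    ``variances`` are phi values (multiplicative model) or tau2 values
    (additive model), depending on ``base.pleiotropy``; a value at the null
    (phi = 1 or tau2 = 0) reproduces the type-I error. Seeds derive
    deterministically from ``base.seed`` and the grid position.
    """
    model = base.pleiotropy if base.pleiotropy != "none" else "multiplicative"
    rows = []
    for iL, L in enumerate(Ls):
        for iv, v in enumerate(variances):
            if model == "multiplicative":
                null_point = v <= 1.0
                cfg = replace(base, L=L, pleiotropy="none" if null_point else model,
                              phi=1.0 if null_point else v,
                              seed=base.seed + 1000 * iL + iv)
            else:
                null_point = v <= 0.0
                cfg = replace(base, L=L, pleiotropy="none" if null_point else model,
                              tau2=0.0 if null_point else v,
                              seed=base.seed + 1000 * iL + iv)
            summary = run_heterogeneity_study(cfg, schemes)
            for s in schemes:
                rows.append(
                    {
                        "L": L,
                        "pleiotropy_model": model,
                        "variance": v,
                        "scheme": s,
                        "rejection_rate": summary[s]["rejection_rate"],
                        "mc_se": summary[s]["mc_se_rejection"],
                        "reps": cfg.reps,
                    }
                )
    return pd.DataFrame(rows)
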