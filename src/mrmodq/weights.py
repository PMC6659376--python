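"""Generalized inverse-variance weight function and generalized Cochran's Q.

Every weighting scheme in this package is a special case of one weight
function. Writing beta_j = beta_outcome_j / beta_exposure_j for the per-SNP
ratio estimate, the variance of beta_j implied by the fitted two-sample model
with multiplicative overdispersion phi is

    Var(beta_j) = (phi * se_outcome_j**2 + beta**2 * se_exposure_j**2)
                  / beta_exposure_j**2

and the generalized weight is its reciprocal,

    w_j(beta, phi) = beta_exposure_j**2
                     / (phi * se_outcome_j**2 + beta**2 * se_exposure_j**2).

First-order weights substitute beta = 0 (the no-measurement-error limit),
second-order weights substitute beta = beta_j (the delta-method plug-in), and
phi = 1 is the fixed-effect model. The generalized Cochran's Q statistic

    Q(w(beta, phi), beta) = sum_j w_j(beta, phi) * (beta_j - beta)**2

tests homogeneity of the ratio estimates against chi-squared with L - 1
degrees of freedom when beta is estimated from the same data. The two samples
are assumed independent, so no exposure-outcome covariance term appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SummaryData, ratio_estimates

__all__ = [
    "WeightVector",
    "QResult",
    "weights",
    "first_order_weights",
    "second_order_weights",
    "q_statistic",
]


@dataclass(frozen=True)
class WeightVector:
    """Inverse-variance weights plus the (beta, phi) values substituted."""

    w: np.ndarray
    beta_used: float | np.ndarray
    phi_used: float

    def __len__(self) -> int:
        return int(self.w.shape[0])

    @property
    def total(self) -> float:
        return float(self.w.sum())


@dataclass(frozen=True)
class QResult:
    """Total heterogeneity statistic with its per-SNP decomposition."""

    q: float
    contributions: np.ndarray
    df: int
    p_value: float


def weights(ds: SummaryData, beta, phi: float = 1.0) -> WeightVector:
    """Generalized weights w_j(beta, phi) for a scalar or per-SNP beta.

    ``phi`` is the multiplicative overdispersion factor (>= 1); ``beta`` is
    the causal-effect value substituted into the ratio-estimate variance.
    """
    if phi < 1:
        raise ValueError(f"phi must be >= 1 (got {phi})")
    zero = ds.beta_exposure == 0
    if zero.any():
        raise ZeroDivisionError(
            f"zero beta_exposure for SNP {ds.snp_id[zero][0]!r}: weight undefined"
        )
    beta_arr = np.asarray(beta, dtype=float)
    if beta_arr.ndim not in (0, 1) or (beta_arr.ndim == 1 and beta_arr.shape[0] != ds.L):
        raise ValueError("beta must be a scalar or a length-L vector")
    denom = phi * ds.se_outcome**2 + beta_arr**2 * ds.se_exposure**2
    w = ds.beta_exposure**2 / denom
    if not np.isfinite(w).all() or (w <= 0).any():
        bad = ~np.isfinite(w) | (w <= 0)
        raise ValueError(f"degenerate weight for SNP {ds.snp_id[bad][0]!r}")
    return WeightVector(w=w, beta_used=beta if np.ndim(beta) == 0 else beta_arr, phi_used=float(phi))


def first_order_weights(ds: SummaryData) -> WeightVector:
    """Fixed-effect first-order weights, w_j(0, 1) = beta_exposure_j^2 / se_outcome_j^2."""
    return weights(ds, 0.0, 1.0)


def second_order_weights(ds: SummaryData) -> WeightVector:
    """Fixed-effect second-order (delta-method) weights, w_j(beta_j, 1).

    Algebraically identical to the textbook form
    (se_outcome^2/beta_exposure^2 + beta_outcome^2 se_exposure^2/beta_exposure^4)^-1.
    """
    return weights(ds, ratio_estimates(ds), 1.0)


def q_statistic(
    ds: SummaryData,
    w: WeightVector | np.ndarray,
    beta: float,
    beta_is_external: bool = False,
) -> QResult:
    """Generalized Cochran's Q about ``beta`` with the supplied weights.

    ``df`` is L - 1 when ``beta`` was estimated from the same data (the
    default, matching the chi-squared reference with one parameter fitted);
    pass ``beta_is_external=True`` for an externally fixed beta to use L.
    """
    w_arr = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if w_arr.shape[0] != ds.L:
        raise ValueError(f"weights (len {w_arr.shape[0]}) not aligned with dataset (L={ds.L})")
    beta_j = ratio_estimates(ds)
    contributions = w_arr * (beta_j - beta) ** 2
    q = float(contributions.sum())
    df = ds.L if beta_is_external else ds.L - 1
    p = float(stats.chi2.sf(q, df))
    return QResult(q=q, contributions=contributions, df=df, p_value=p)
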