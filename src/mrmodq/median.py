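"""Weighted-median causal estimator (robust comparator to IVW).

The weighted median of the per-SNP ratio estimates is consistent as long as
valid instruments carry more than half of the total weight, giving inherent
robustness to a minority of pleiotropic outliers. Weights are first-order
inverse-variance weights; the standard error comes from a parametric
bootstrap that redraws the summary associations from their sampling
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SummaryData, ratio_estimates

__all__ = ["MedianResult", "weighted_median"]


@dataclass(frozen=True)
class MedianResult:
    beta: float
    se: float
    ci: tuple[float, float]
    p_value: float
    B: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "method": "weighted_median",
            "beta": self.beta,
            "se": self.se,
            "ci": list(self.ci),
            "p": self.p_value,
            "B": self.B,
        }


def _weighted_median_point(beta_j: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median with the midpoint (w_j/2) convention.

    Order the ratios ascending, form s_j = (cumsum(w) - w_j/2) / sum(w), and
    linearly interpolate the ordered ratios at s = 0.5.
    """
    order = np.argsort(beta_j, kind="stable")
    b = beta_j[order]
    ww = w[order]
    s = (np.cumsum(ww) - ww / 2) / np.sum(ww)
    return float(np.interp(0.5, s, b))


def weighted_median(
    ds: SummaryData,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> MedianResult:
    """Weighted-median estimate with parametric-bootstrap SE.

    Each of the B bootstrap draws resamples every SNP's associations,
    beta_outcome_j ~ N(beta_outcome_j, se_outcome_j^2) and
    beta_exposure_j ~ N(beta_exposure_j, se_exposure_j^2), and recomputes the
    weighted median. The interval is the symmetric Student-t interval (L - 1
    df) about the point estimate.
    """
    if ds.L < 3:
        raise ValueError("weighted median requires L >= 3")
    rng = np.random.default_rng(seed)
    w = ds.beta_exposure**2 / ds.se_outcome**2
    point = _weighted_median_point(ratio_estimates(ds), w)
    draws = np.empty(B)
    for b in range(B):
        gx = rng.normal(ds.beta_exposure, ds.se_exposure)
        gy = rng.normal(ds.beta_outcome, ds.se_outcome)
        gx = np.where(gx == 0, np.finfo(float).tiny, gx)
        wb = gx**2 / ds.se_outcome**2
        draws[b] = _weighted_median_point(gy / gx, wb)
    se = float(np.std(draws, ddof=1))
    tcrit = stats.t.ppf(0.5 + level / 2, ds.L - 1)
    ci = (point - tcrit * se, point + tcrit * se)
    p = 2 * stats.t.sf(abs(point) / se, ds.L - 1) if se > 0 else (0.0 if point != 0 else 1.0)
    return MedianResult(point, se, ci, float(p), B, seed)
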