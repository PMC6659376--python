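"""Fixed-effect and multiplicative random-effects IVW estimation.

Four weighting schemes are provided, all built on the generalized weight
function in :mod:`mrmodq.weights`:

``first``
    w_j(0, 1): the standard IVW estimate. Exactly correct under the causal
    null, but under a non-zero causal effect with weak instruments it both
    dilutes the estimate toward the null (regression dilution) and understates
    the ratio-estimate variance, inflating Cochran's Q.
``second``
    w_j(beta_j, 1): delta-method plug-in weights. These over-correct the
    variance, deflating Q and removing power to detect heterogeneity.
``iterative``
    weights refreshed with successive IVW estimates, starting from the
    first-order estimate, until the estimate is stable (a two-step-GMM-like
    scheme iterated to convergence).
``exact``
    the weights remain a proper function of beta and the generalized Q is
    minimized directly over beta (a LIML-like estimator). Exact weighting
    removes regression dilution bias and keeps Q faithful to its chi-squared
    reference, at some cost in precision with few weak instruments.

Random-effects inference uses a multiplicative overdispersion factor phi >= 1.
For the regression-style schemes phi_hat = max(1, Q/(L-1)) rescales the fixed
-effect standard error; for exact weighting, (beta, phi) jointly solve
Q(w(beta, phi), beta) = L - 1 subject to dQ/dbeta = 0, with a non-parametric
bootstrap for the confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .core import SummaryData, ratio_estimates
from .weights import QResult, WeightVector, first_order_weights, q_statistic, weights

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "QInversionCI",
    "ivw_point",
    "fit_ivw",
    "fit_exact_fixed",
    "fit_exact_random",
    "invert_q_ci",
    "bootstrap_ci",
    "fit",
]

SCHEMES = ("first", "second", "iterative", "exact")


@dataclass
class FitResult:
    """A fitted IVW analysis: estimate, uncertainty and heterogeneity."""

    beta: float
    se: float
    ci: tuple[float, float]
    ci_method: str
    p_value: float
    q: QResult
    phi_hat: float
    scheme: str
    effects: str
    L: int
    n_iter: int = 0
    converged: bool = True
    multimodal: bool = False
    weights: WeightVector | None = None
    percentile_ci: tuple[float, float] | None = None
    q_inversion: "QInversionCI | None" = None

    def to_dict(self) -> dict:
        out = {
            "scheme": self.scheme,
            "effects": self.effects,
            "beta": self.beta,
            "se": self.se,
            "ci": list(self.ci),
            "ci_method": self.ci_method,
            "p": self.p_value,
            "Q": self.q.q,
            "df": self.q.df,
            "Q_p": self.q.p_value,
            "phi": self.phi_hat,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        if self.percentile_ci is not None:
            out["percentile_ci"] = list(self.percentile_ci)
        if self.q_inversion is not None:
            out["q_inversion_ci"] = [list(iv) for iv in self.q_inversion.intervals]
        return out


@dataclass(frozen=True)
class QInversionCI:
    """Confidence set from inverting the exact-weight Q statistic.

    The set {beta : Q(w(beta,1), beta) <= threshold} need not be an interval;
    ``intervals`` lists its connected components in ascending order.
    """

    intervals: tuple[tuple[float, float], ...]
    level: float
    threshold: float
    non_connected: bool
    unbounded: bool

    @property
    def lower(self) -> float:
        return self.intervals[0][0]

    @property
    def upper(self) -> float:
        return self.intervals[-1][1]

    def contains(self, beta: float) -> bool:
        return any(lo <= beta <= hi for lo, hi in self.intervals)


def ivw_point(ds: SummaryData, w: WeightVector | np.ndarray) -> float:
    """Inverse-variance weighted average of the ratio estimates.

    Equals the slope of the zero-intercept weighted regression of the
    outcome associations on the exposure associations, and minimizes
    Cochran's Q for the supplied (fixed) weights.
    """
    w_arr = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    beta_j = ratio_estimates(ds)
    return float(np.sum(w_arr * beta_j) / np.sum(w_arr))


# ---------------------------------------------------------------------------
# fast internal kernels (shared by the public fits and the simulation engine)


def _q_fun(ds: SummaryData) -> Callable[[float, float], float]:
    """Closure evaluating Q(w(beta, phi), beta) for scalars, precomputing arrays."""
    g2 = ds.beta_exposure**2
    sx2 = ds.se_exposure**2
    sy2 = ds.se_outcome**2
    bj = ds.beta_outcome / ds.beta_exposure

    def q_at(beta: float, phi: float = 1.0) -> float:
        return float(np.sum(g2 * (bj - beta) ** 2 / (phi * sy2 + beta * beta * sx2)))

    return q_at


def _first_point(ds: SummaryData) -> tuple[float, float]:
    """First-order IVW estimate and its fixed-effect SE (fast path)."""
    w = ds.beta_exposure**2 / ds.se_outcome**2
    bj = ds.beta_outcome / ds.beta_exposure
    sw = w.sum()
    return float(np.sum(w * bj) / sw), float(sw**-0.5)


def _default_bracket(ds: SummaryData) -> tuple[float, float]:
    b0, se0 = _first_point(ds)
    bj = ratio_estimates(ds)
    iqr = float(np.subtract(*np.percentile(bj, [75, 25])))
    half = 10.0 * max(se0, iqr)
    if half <= 0:
        half = max(1.0, abs(b0))
    return b0 - half, b0 + half


def _exact_minimize(
    ds: SummaryData,
    phi: float = 1.0,
    bracket: tuple[float, float] | None = None,
    grid_points: int = 401,
) -> tuple[float, float, bool]:
    """Globally minimize Q(w(beta, phi), beta) over beta.

    Coarse grid then local polish of every local minimum; ties broken toward
    the lowest beta. Q(beta) is bounded (it tends to the summed per-SNP F
    statistics as |beta| grows) and can be multimodal with weak instruments,
    hence grid-then-polish rather than a single descent.

    Returns (beta_hat, q_min, multimodal_flag).
    """
    q_at = _q_fun(ds)
    lo, hi = bracket if bracket is not None else _default_bracket(ds)
    for _expansion in range(8):
        grid = np.linspace(lo, hi, grid_points)
        g2 = ds.beta_exposure**2
        sx2 = ds.se_exposure**2
        sy2 = ds.se_outcome**2
        bj = ds.beta_outcome / ds.beta_exposure
        qgrid = np.sum(
            g2 * (bj[None, :] - grid[:, None]) ** 2
            / (phi * sy2[None, :] + grid[:, None] ** 2 * sx2[None, :]),
            axis=1,
        )
        i_best = int(np.argmin(qgrid))
        if 0 < i_best < grid_points - 1:
            break
        # global grid minimum at the bracket edge: widen and retry
        width = hi - lo
        lo, hi = lo - width, hi + width
    interior = (qgrid[1:-1] < qgrid[:-2]) & (qgrid[1:-1] <= qgrid[2:])
    minima_idx = [i + 1 for i in np.nonzero(interior)[0]]
    if not minima_idx:
        minima_idx = [i_best]
    multimodal = len(minima_idx) > 1
    if multimodal:
        logger.info("Q(beta) multimodal on grid (%d local minima); taking global minimum",
                    len(minima_idx))
    best_beta, best_q = None, np.inf
    for i in minima_idx:
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid_points - 1)]
        res = optimize.minimize_scalar(
            lambda x: q_at(x, phi), bounds=(a, b), method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun < best_q - 1e-13 or (best_beta is None):
            best_beta, best_q = float(res.x), float(res.fun)
    return best_beta, best_q, multimodal


# ---------------------------------------------------------------------------
# regression-style schemes: first, second, iterative


def _t_interval(beta: float, se: float, L: int, level: float) -> tuple[tuple[float, float], float]:
    """Symmetric Student-t CI and two-sided p-value for beta = 0, with L-1 df."""
    df = L - 1
    if df < 1 or se == 0:
        return (np.nan, np.nan), np.nan
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    ci = (beta - tcrit * se, beta + tcrit * se)
    p = 2 * stats.t.sf(abs(beta) / se, df)
    return ci, float(p)


def fit_ivw(
    ds: SummaryData,
    scheme: str = "first",
    effects: str = "fixed",
    ci_level: float = 0.95,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the IVW model with first-order, second-order or iterative weights.

    ``effects='multiplicative'`` inflates the fixed-effect SE by
    sqrt(phi_hat), phi_hat = max(1, Q/(L-1)), the multiplicative
    random-effects (overdispersion) model. All Wald inference uses Student-t
    with L - 1 degrees of freedom.
    """
    if scheme not in ("first", "second", "iterative"):
        raise ValueError(f"unknown regression scheme {scheme!r}")
    if effects not in ("fixed", "multiplicative"):
        raise ValueError(f"unknown effects model {effects!r}")
    if ds.L < 2:
        raise ValueError("at least 2 SNPs required for a standard error")
    n_iter, converged = 0, True
    if scheme == "first":
        w = first_order_weights(ds)
        beta = ivw_point(ds, w)
    elif scheme == "second":
        w = weights(ds, ratio_estimates(ds), 1.0)
        beta = ivw_point(ds, w)
    else:
        beta, _ = _first_point(ds)
        converged = False
        for n_iter in range(1, max_iter + 1):
            w = weights(ds, beta, 1.0)
            beta_new = ivw_point(ds, w)
            if abs(beta_new - beta) < tol:
                beta = beta_new
                converged = True
                break
            beta = beta_new
        w = weights(ds, beta, 1.0)
    qres = q_statistic(ds, w, beta)
    phi_hat = 1.0
    se = w.total**-0.5
    if effects == "multiplicative":
        phi_hat = max(1.0, qres.q / (ds.L - 1))
        se *= phi_hat**0.5
    ci, p = _t_interval(beta, se, ds.L, ci_level)
    return FitResult(
        beta=beta, se=se, ci=ci, ci_method="symmetric_t", p_value=p, q=qres,
        phi_hat=phi_hat, scheme=scheme, effects=effects, L=ds.L,
        n_iter=n_iter, converged=converged, weights=w,
    )


# ---------------------------------------------------------------------------
# exact weighting


def fit_exact_fixed(
    ds: SummaryData,
    ci_method: str = "symmetric_t",
    ci_level: float = 0.95,
    search_bracket: tuple[float, float] | None = None,
    grid_points: int = 401,
) -> FitResult:
    """Exact-weight fixed-effect fit: directly minimize Q(w(beta, 1), beta).

    SE is (sum_j w_j(beta_hat, 1))**-0.5; the CI is either the symmetric
    Student-t interval or the Q-inversion confidence set (``ci_method``).
    """
    if ci_method not in ("symmetric_t", "q_inversion"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    beta, qmin, multimodal = _exact_minimize(ds, 1.0, search_bracket, grid_points)
    w = weights(ds, beta, 1.0)
    qres = q_statistic(ds, w, beta)
    se = w.total**-0.5
    ci, p = _t_interval(beta, se, ds.L, ci_level)
    inversion = None
    if ci_method == "q_inversion" and ds.L >= 2:
        inversion = invert_q_ci(ds, level=ci_level, _fit=(beta, qmin))
        ci = (inversion.lower, inversion.upper)
    return FitResult(
        beta=beta, se=se, ci=ci, ci_method=ci_method, p_value=p, q=qres,
        phi_hat=1.0, scheme="exact", effects="fixed", L=ds.L,
        multimodal=multimodal, weights=w, q_inversion=inversion,
    )


def invert_q_ci(
    ds: SummaryData,
    level: float = 0.95,
    search_bracket: tuple[float, float] | None = None,
    _fit: tuple[float, float] | None = None,
) -> QInversionCI:
    """Confidence set {beta : Q(w(beta,1), beta) <= chi2_{L-1}(q*)}.

    Small-sample adjustment: the coverage target q* = 2*Phi(z) - 1 with z the
    (1+level)/2 percentile of Student-t with L - 1 df, which tends to
    ``level`` from above as L grows. The set is found by a dense scan for
    sign changes of Q(beta) - threshold followed by bracketed root-finding;
    with weak instruments it may be a union of disjoint intervals
    (``non_connected``) or unbounded (Q(beta) is bounded above by the summed
    F statistics, so a large threshold leaves the set open).
    """
    L = ds.L
    if L < 2:
        raise ValueError("Q inversion requires L >= 2")
    z = stats.t.ppf(0.5 + level / 2, L - 1)
    qstar = 2 * stats.norm.cdf(z) - 1
    threshold = float(stats.chi2.ppf(qstar, L - 1))
    q_at = _q_fun(ds)
    if _fit is None:
        beta_hat, qmin, _ = _exact_minimize(ds, 1.0, search_bracket)
    else:
        beta_hat, qmin = _fit
    if qmin > threshold:
        # estimate itself excluded only if Q's minimum exceeds the threshold;
        # return the degenerate point set at the minimizer
        return QInversionCI(((beta_hat, beta_hat),), level, threshold, False, False)

    q_limit = float(np.sum(ds.beta_exposure**2 / np.where(ds.se_exposure > 0,
                                                          ds.se_exposure, np.inf) ** 2))
    g = lambda b: q_at(b, 1.0) - threshold

    lo, hi = search_bracket if search_bracket is not None else _default_bracket(ds)
    lo = min(lo, beta_hat - 1e-9)
    hi = max(hi, beta_hat + 1e-9)
    unbounded = False
    for _ in range(8):
        if g(lo) > 0 and g(hi) > 0:
            break
        width = hi - lo
        lo, hi = lo - width, hi + width
    else:
        # Q(+-inf) = sum of F statistics; if that never exceeds the threshold
        # the set is unbounded on the side(s) that stay below it
        unbounded = threshold >= q_limit or g(lo) <= 0 or g(hi) <= 0

    grid = np.linspace(lo, hi, 2001)
    g2_ = ds.beta_exposure**2
    sx2_ = ds.se_exposure**2
    sy2_ = ds.se_outcome**2
    bj_ = ds.beta_outcome / ds.beta_exposure
    vals = np.sum(
        g2_ * (bj_[None, :] - grid[:, None]) ** 2
        / (sy2_[None, :] + grid[:, None] ** 2 * sx2_[None, :]),
        axis=1,
    ) - threshold
    inside = vals <= 0
    crossings = []
    for i in range(len(grid) - 1):
        if inside[i] != inside[i + 1]:
            crossings.append(float(optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-12)))
    intervals: list[tuple[float, float]] = []
    if inside[0]:
        crossings.insert(0, -np.inf)
        unbounded = True
    if inside[-1]:
        crossings.append(np.inf)
        unbounded = True
    for a, b in zip(crossings[::2], crossings[1::2]):
        intervals.append((a, b))
    if not intervals:  # numerical corner: fall back to the point estimate
        intervals = [(beta_hat, beta_hat)]
    non_connected = len(intervals) > 1
    if non_connected:
        logger.info("Q-inversion confidence set is non-connected: %s", intervals)
    return QInversionCI(tuple(intervals), level, threshold, non_connected, unbounded)


class ExtremeHeterogeneityError(RuntimeError):
    """Raised when no overdispersion phi <= 1e6 can absorb the heterogeneity."""


def _exact_random_point(ds: SummaryData) -> tuple[float, float, float, bool]:
    """Solve the exact-weight random-effects estimating equations.

    Profiles over phi: beta(phi) minimizes Q(w(beta, phi), beta) (the
    constraint dQ/dbeta = 0), and phi_hat solves Q(w(beta(phi), phi),
    beta(phi)) = L - 1. If the fixed-effect minimized Q is already <= L - 1,
    phi_hat = 1 (overdispersion is truncated below at 1).

    Returns (beta_hat, phi_hat, q_at_solution, multimodal).
    """
    L = ds.L
    beta1, q1, multimodal = _exact_minimize(ds, 1.0)
    if q1 <= L - 1:
        return beta1, 1.0, q1, multimodal
    # beta(phi) moves slowly in phi; reuse a local bracket around the last
    # minimizer to keep the profiling cheap and robust
    state = {"beta": beta1}

    def profiled_q(phi: float) -> float:
        b_prev = state["beta"]
        se_loc = (np.sum(ds.beta_exposure**2 / (phi * ds.se_outcome**2)) ** -0.5)
        bracket = (b_prev - 50 * se_loc, b_prev + 50 * se_loc)
        b, qv, _ = _exact_minimize(ds, phi, bracket, grid_points=201)
        state["beta"] = b
        return qv

    h = lambda phi: profiled_q(phi) - (L - 1)
    lo, hi = 1.0, 2.0
    h_hi = h(hi)
    while h_hi > 0:
        lo, hi = hi, hi * 4
        if hi > 1e6:
            raise ExtremeHeterogeneityError(
                f"profiled Q stays above L-1 even at phi={hi:g}: extreme heterogeneity"
            )
        h_hi = h(hi)
    phi_hat = float(optimize.brentq(h, lo, hi, xtol=1e-10, rtol=1e-12))
    beta_hat, q_sol, mm = _exact_minimize(ds, phi_hat)
    return beta_hat, phi_hat, q_sol, multimodal or mm


def fit_exact_random(
    ds: SummaryData,
    ci_level: float = 0.95,
    bootstrap_B: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Exact-weight multiplicative random-effects fit.

    Jointly estimates (beta, phi) from the estimating equations
    Q(w(beta, phi), beta) = L - 1 and dQ/dbeta = 0, with phi >= 1. The
    analytic SE (sum_j w_j(beta_hat, phi_hat))**-0.5 is always reported; pass
    ``bootstrap_B`` > 0 (with ``seed``) to replace SE and CI with the
    non-parametric bootstrap, the recommended interval when phi_hat > 1.
    """
    if ds.L < 3:
        raise ValueError("exact random-effects fit requires L >= 3 (df for phi)")
    beta, phi_hat, q_sol, multimodal = _exact_random_point(ds)
    w = weights(ds, beta, phi_hat)
    # the reported heterogeneity statistic uses fixed-effect (phi=1) weights at
    # the RE estimate; Q at (beta_hat, phi_hat) equals L-1 by construction
    qres = q_statistic(ds, weights(ds, beta, 1.0), beta)
    se = w.total**-0.5
    ci, p = _t_interval(beta, se, ds.L, ci_level)
    ci_method = "symmetric_t"
    percentile = None
    if bootstrap_B:
        se, ci, percentile = bootstrap_ci(
            ds, B=bootstrap_B, seed=seed, level=ci_level, point=beta
        )
        _, p = _t_interval(beta, se, ds.L, ci_level)
        ci_method = "bootstrap"
    return FitResult(
        beta=beta, se=se, ci=ci, ci_method=ci_method, p_value=p, q=qres,
        phi_hat=phi_hat, scheme="exact", effects="multiplicative", L=ds.L,
        multimodal=multimodal, weights=w, percentile_ci=percentile,
    )


def bootstrap_ci(
    ds: SummaryData,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    point: float | None = None,
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Non-parametric bootstrap for the exact random-effects estimate.

    Resamples the L SNP records with replacement B times and refits; the SE
    is the SD of the bootstrap estimates and the headline interval is the
    symmetric Student-t interval about the full-data estimate (a percentile
    interval is returned alongside). Resamples with fewer than 3 distinct
    SNPs are redrawn.

    Returns (se, symmetric_interval, percentile_interval).
    """
    rng = np.random.default_rng(seed)
    if point is None:
        point, _, _, _ = _exact_random_point(ds)
    estimates = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, ds.L, size=ds.L)
            if len(set(idx.tolist())) >= 3:
                break
            redraws += 1
        beta_b, _, _, _ = _exact_random_point(ds.take(idx))
        estimates[b] = beta_b
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    se = float(np.std(estimates, ddof=1))
    tcrit = stats.t.ppf(0.5 + level / 2, ds.L - 1)
    symmetric = (point - tcrit * se, point + tcrit * se)
    alpha = 1 - level
    percentile = tuple(np.quantile(estimates, [alpha / 2, 1 - alpha / 2]))
    return se, symmetric, percentile


def fit(
    ds: SummaryData,
    scheme: str = "first",
    effects: str = "multiplicative",
    **kwargs,
) -> FitResult:
    """Dispatch to the appropriate fitting routine for (scheme, effects)."""
    if scheme in ("first", "second", "iterative"):
        return fit_ivw(ds, scheme=scheme, effects=effects, **kwargs)
    if scheme == "exact":
        if effects == "fixed":
            return fit_exact_fixed(ds, **kwargs)
        return fit_exact_random(ds, **kwargs)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
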