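import numpy as np
import pytest

from mrmodq import (
    SummaryData,
    bootstrap_ci,
    first_order_weights,
    fit,
    fit_exact_fixed,
    fit_exact_random,
    fit_ivw,
    invert_q_ci,
    ivw_point,
    ratio_estimates,
    weights,
)
from mrmodq.weights import q_statistic

from conftest import make_dataset, random_dataset


def dense_grid_argmin_q(ds, phi=1.0, lo=-1.0, hi=1.0, step=1e-5):
    """Independent oracle: brute-force minimizer of the generalized Q."""
    grid = np.arange(lo, hi, step)
    bj = ds.beta_outcome / ds.beta_exposure
    q = np.sum(
        ds.beta_exposure**2 * (bj[None, :] - grid[:, None]) ** 2
        / (phi * ds.se_outcome**2 + grid[:, None] ** 2 * ds.se_exposure**2),
        axis=1,
    )
    return grid[int(np.argmin(q))]


def test_ivw_point_is_weighted_mean():
    ds = make_dataset([1.0, 1.0], 0.0, [0.0, 2.0], 1.0)
    assert ivw_point(ds, np.array([1.0, 1.0])) == pytest.approx(1.0)
    one = make_dataset([0.5], 0.01, [0.1], 0.05)
    assert ivw_point(one, first_order_weights(one)) == pytest.approx(0.2)


def test_ivw_point_minimizes_fixed_weight_q(rng):
    ds = random_dataset(rng, L=6)
    w = first_order_weights(ds)
    b = ivw_point(ds, w)
    grid = np.arange(b - 0.05, b + 0.05, 1e-6)
    qvals = [q_statistic(ds, w, g).q for g in grid]
    assert abs(grid[int(np.argmin(qvals))] - b) < 1e-5


def test_ivw_point_equals_wls_zero_intercept_slope(rng):
    import statsmodels.api as sm

    ds = random_dataset(rng, L=15)
    w = first_order_weights(ds)
    ours = ivw_point(ds, w)
    # WLS of outcome on exposure with no intercept, weights w_j / gamma_j^2
    wls = sm.WLS(ds.beta_outcome, ds.beta_exposure,
                 weights=w.w / ds.beta_exposure**2).fit()
    assert ours == pytest.approx(float(wls.params[0]), abs=1e-10)


def test_phi_hat_is_truncated_q_ratio(rng):
    for scheme in ("first", "second", "iterative"):
        ds = random_dataset(rng, L=10)
        res = fit_ivw(ds, scheme, "multiplicative")
        assert res.phi_hat == max(1.0, res.q.q / (ds.L - 1))


def test_multiplicative_se_inflation(rng):
    ds = random_dataset(rng, L=10, sigma_y=0.01)  # heterogeneous relative to SEs
    fixed = fit_ivw(ds, "first", "fixed")
    rand = fit_ivw(ds, "first", "multiplicative")
    assert rand.beta == fixed.beta
    assert rand.se == pytest.approx(fixed.se * rand.phi_hat**0.5)
    assert rand.ci[0] <= rand.beta <= rand.ci[1]


def test_iterative_reaches_fixed_point(rng):
    ds = random_dataset(rng, L=6, mean_f=10.0)
    res = fit_ivw(ds, "iterative", "fixed")
    assert res.converged
    # independent fixed-point oracle
    b = None
    b_next = ivw_point(ds, first_order_weights(ds))
    for _ in range(200):
        b = b_next
        b_next = ivw_point(ds, weights(ds, b, 1.0))
        if abs(b_next - b) < 1e-12:
            break
    assert res.beta == pytest.approx(b_next, abs=1e-8)
    assert res.beta == pytest.approx(ivw_point(ds, weights(ds, res.beta, 1.0)), abs=1e-9)


def test_nome_limit_all_schemes_agree():
    gx = np.array([0.8, 1.0, 1.2, 0.9, 1.1])
    ds = make_dataset(gx, 0.0, 0.1 * gx + np.array([0.01, -0.02, 0.005, 0.0, -0.01]), 0.05)
    betas = [
        fit_ivw(ds, "first", "fixed").beta,
        fit_ivw(ds, "second", "fixed").beta,
        fit_ivw(ds, "iterative", "fixed").beta,
        fit_exact_fixed(ds).beta,
    ]
    np.testing.assert_allclose(betas, betas[0], atol=1e-8)


def test_exact_fixed_matches_dense_grid(rng):
    for _ in range(3):
        ds = random_dataset(rng, L=8, mean_f=10.0)
        res = fit_exact_fixed(ds)
        oracle = dense_grid_argmin_q(ds, lo=res.beta - 0.3, hi=res.beta + 0.3)
        assert abs(res.beta - oracle) < 1e-4


def test_exact_fixed_single_snp():
    ds = make_dataset([0.5], 0.2, [0.1], 0.05)
    res = fit_exact_fixed(ds)
    assert res.beta == pytest.approx(0.2, abs=1e-8)
    assert res.q.q == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("scheme", ["first", "second", "iterative", "exact"])
def test_every_scheme_minimizes_its_own_q(rng, scheme):
    ds = random_dataset(rng, L=9, mean_f=12.0)
    if scheme == "exact":
        res = fit_exact_fixed(ds)
        q_at = lambda b: q_statistic(ds, weights(ds, b, 1.0), b).q
    else:
        res = fit_ivw(ds, scheme, "fixed")
        q_at = lambda b: q_statistic(ds, res.weights, b).q
    delta = 1e-4 * (1 + abs(res.beta))
    assert q_at(res.beta) <= q_at(res.beta + delta)
    assert q_at(res.beta) <= q_at(res.beta - delta)


def test_exact_fixed_invariant_to_common_se_rescale(rng):
    ds = random_dataset(rng, L=7, mean_f=10.0)
    scaled = SummaryData(ds.snp_id, ds.beta_exposure, 2.5 * ds.se_exposure,
                         ds.beta_outcome, 2.5 * ds.se_outcome)
    assert fit_exact_fixed(scaled).beta == pytest.approx(fit_exact_fixed(ds).beta, abs=1e-8)


def test_inversion_interval_contains_exact_estimate(rng):
    ds = random_dataset(rng, L=8, mean_f=10.0)
    res = fit_exact_fixed(ds, ci_method="q_inversion")
    assert res.q_inversion.contains(res.beta)
    assert res.ci[0] <= res.beta <= res.ci[1]


def test_inversion_empty_set_degenerates_to_point(rng):
    # Q's minimum can exceed the inversion threshold (an upper-tail event of
    # the minimized Q); the set then collapses to the point estimate
    ds = random_dataset(rng, L=100, mean_f=100.0)  # this draw has Q_min in the 5% tail
    inv = invert_q_ci(ds)
    assert inv.lower == inv.upper


def test_inversion_width_matches_quadratic_oracle():
    """With many strong instruments Q(beta) is locally quadratic with
    curvature sum(w), so the inversion half-width is se*sqrt(threshold -
    Q_min); the numeric root-finder must agree with that closed form."""
    ds = random_dataset(np.random.default_rng(1), L=100, mean_f=100.0)
    res = fit_exact_fixed(ds)
    inv = invert_q_ci(ds)
    assert not inv.non_connected and not inv.unbounded
    predicted = res.se * np.sqrt(inv.threshold - res.q.q)
    half_lo = res.beta - inv.lower
    half_hi = inv.upper - res.beta
    assert half_lo == pytest.approx(predicted, rel=0.05)
    assert half_hi == pytest.approx(predicted, rel=0.05)


def test_exact_random_boundary_continuity(homogeneous_ds):
    # homogeneous data: fixed-effect Q ~ 0 <= L-1, so phi_hat = 1 and the
    # RE estimate equals the fixed-effect exact estimate
    fixed = fit_exact_fixed(homogeneous_ds)
    rand = fit_exact_random(homogeneous_ds)
    assert rand.phi_hat == 1.0
    assert rand.beta == pytest.approx(fixed.beta, abs=1e-10)


def test_exact_random_recovers_overdispersion(rng):
    """Joint (beta, phi) solve recovers both parameters on average."""
    from mrmodq.simulate import SimConfig, run_estimation_study

    cfg = SimConfig(L=100, beta=0.1, mean_f=61.0, pleiotropy="multiplicative",
                    phi=2.0, reps=200, seed=17)
    agg = run_estimation_study(cfg, schemes=("exact",))["exact"]
    assert abs(agg["mean_estimate"] - 0.1) < 3 * agg["sd_estimate"] / np.sqrt(cfg.reps)
    assert abs(agg["mean_phi_hat"] - 2.0) < 3 * agg["mc_se_phi_hat"]


def test_exact_random_requires_df_for_phi(rng):
    ds = random_dataset(rng, L=2)
    with pytest.raises(ValueError, match="L >= 3"):
        fit_exact_random(ds)


def test_bootstrap_deterministic_and_degenerate(rng):
    ds = random_dataset(rng, L=10, mean_f=25.0)
    se1, ci1, pc1 = bootstrap_ci(ds, B=60, seed=5)
    se2, ci2, pc2 = bootstrap_ci(ds, B=60, seed=5)
    assert se1 == se2 and ci1 == ci2 and pc1 == pc2
    # all records identical -> every resample identical -> zero variance
    same = make_dataset(np.full(6, 1.0), 0.1, np.full(6, 0.2), 0.05)
    se, _, _ = bootstrap_ci(same, B=30, seed=1)
    assert se == pytest.approx(0.0, abs=1e-12)


def test_fit_dispatch(rng):
    ds = random_dataset(rng, L=10)
    assert fit(ds, "first", "fixed").scheme == "first"
    assert fit(ds, "exact", "fixed").effects == "fixed"
    assert fit(ds, "exact", "multiplicative").effects == "multiplicative"
    with pytest.raises(ValueError, match="scheme"):
        fit(ds, "egger")
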