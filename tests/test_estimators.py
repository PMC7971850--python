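"""Univariable MR estimators against independent oracles and exact constructions."""

import numpy as np
import pytest
import statsmodels.api as sm

from summr import (
    HarmonizedDataset,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mode_based,
    wald_ratio,
    weighted_median,
)
from summr.estimators import IVW, MREgger, ModeBased, WeightedMedian, _mode_point


def dataset(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    sx = np.full_like(bx, 0.005) if sx is None else np.asarray(sx, dtype=float)
    return HarmonizedDataset.from_arrays(bx, sx, np.asarray(by, float), np.asarray(sy, float))


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------


def test_wald_ratio_arithmetic():
    data = dataset([0.5], [0.1], [0.05])
    est = wald_ratio(data.retained[0])
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.1)


def test_wald_ratio_zero_outcome_and_sign_symmetry():
    assert wald_ratio(dataset([0.5], [0.0], [0.05]).retained[0]).beta == 0.0
    a = wald_ratio(dataset([0.5], [0.1], [0.05]).retained[0])
    b = wald_ratio(dataset([-0.5], [-0.1], [0.05]).retained[0])
    assert (a.beta, a.se) == (b.beta, b.se)


def test_wald_ratio_undefined_for_null_instrument():
    with pytest.raises(ValueError, match="beta_x = 0"):
        wald_ratio(dataset([0.0], [0.1], [0.05]).retained[0])


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def test_single_variant_ivw_reduces_to_wald_ratio():
    data = dataset([0.5], [0.1], [0.05])
    est = ivw(data)
    ref = wald_ratio(data.retained[0])
    assert est.beta == ref.beta and est.se == ref.se
    assert "single variant" in est.metadata["note"]


def test_exact_shared_ratio_recovered_with_zero_heterogeneity():
    bx = np.array([0.2, 0.4, 0.6, 0.8])
    data = dataset(bx, 0.37 * bx, np.full(4, 0.05))
    est_f = ivw(data, "fixed")
    est_r = ivw(data, "random")
    assert est_f.beta == pytest.approx(0.37, rel=1e-12)
    assert est_f.q == pytest.approx(0.0, abs=1e-20)
    assert est_r.se == est_f.se  # floor at 1: no underdispersion
    q, p = cochran_q(data, est_f.beta)
    assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_ivw_matches_wls_oracle_to_ten_digits(seed, random_arrays_dataset):
    data = random_arrays_dataset(seed)
    w = 1.0 / data.se_y**2
    fit = sm.WLS(data.beta_y, data.beta_x, weights=w).fit()
    est = ivw(data, "fixed")
    assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
    # unscaled WLS covariance is the fixed-effect variance
    se_oracle = fit.bse[0] / np.sqrt(fit.scale)
    assert est.se == pytest.approx(se_oracle, rel=1e-10)
    # Q equals the weighted residual sum of squares of the origin regression
    assert est.q == pytest.approx(fit.scale * (len(data.beta_y) - 1), rel=1e-10)
    # random-effects se applies the multiplicative floor
    est_r = ivw(data, "random")
    phi = max(1.0, np.sqrt(est.q / (len(data.beta_y) - 1)))
    assert est_r.se == pytest.approx(est.se * phi, rel=1e-12)


def test_degenerate_instruments_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        ivw(dataset([0.0, 0.0], [0.1, 0.2], [0.05, 0.05]))


# ---------------------------------------------------------------------------
# Cochran's Q
# ---------------------------------------------------------------------------


def test_cochran_q_two_variant_arithmetic():
    # ratios 0 and 1 with unit weights: Q = 0.5 around the midpoint
    data = dataset([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
    q, _ = cochran_q(data, 0.5)
    assert q == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def test_egger_exact_interpolation_of_linear_points():
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    by = 0.02 + 0.5 * bx
    est = egger(dataset(bx, by, np.full(5, 0.03)))
    assert est.intercept == pytest.approx(0.02, rel=1e-10)
    assert est.beta == pytest.approx(0.5, rel=1e-10)
    assert est.q == pytest.approx(0.0, abs=1e-20)


@pytest.mark.parametrize("seed", range(5))
def test_egger_matches_wls_oracle_to_ten_digits(seed, random_arrays_dataset):
    data = random_arrays_dataset(seed)
    sign = np.where(data.beta_x < 0, -1.0, 1.0)
    bx, by = sign * data.beta_x, sign * data.beta_y
    w = 1.0 / data.se_y**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    est = egger(data)
    assert est.intercept == pytest.approx(fit.params[0], rel=1e-10)
    assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
    k = len(bx)
    q = fit.scale * (k - 2)
    phi = max(1.0, np.sqrt(q / (k - 2)))
    se_unscaled = fit.bse / np.sqrt(fit.scale)
    assert est.intercept_se == pytest.approx(se_unscaled[0] * phi, rel=1e-10)
    assert est.se == pytest.approx(se_unscaled[1] * phi, rel=1e-10)


def test_egger_invariant_to_per_variant_orientation():
    rng = np.random.default_rng(1)
    bx = rng.uniform(0.1, 0.5, 8)
    by = 0.01 + 0.3 * bx + rng.normal(0, 0.02, 8)
    sy = np.full(8, 0.02)
    ref = egger(dataset(bx, by, sy))
    flip = np.array([1, -1] * 4, dtype=float)
    alt = egger(dataset(bx * flip, by * flip, sy))
    assert alt.beta == pytest.approx(ref.beta, rel=1e-12)
    assert alt.intercept == pytest.approx(ref.intercept, rel=1e-12)


def test_egger_needs_three_variants():
    with pytest.raises(ValueError, match=">= 3"):
        egger(dataset([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------


def test_weighted_median_equal_weights_interpolates_middle_ratio():
    data = dataset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    est = weighted_median(data, n_boot=100, seed=0)
    assert est.beta == pytest.approx(2.0)


def test_weighted_median_dominant_variant_controls_estimate():
    # first variant carries ~90% of the weight (tiny se_y)
    data = dataset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [0.1, 1.0, 1.0])
    est = weighted_median(data, n_boot=100, seed=0)
    assert est.beta < 1.6  # pinned near the heavy variant's ratio


def _grid_quantile_oracle(ratios, weights, q=0.5, n=200_001):
    """Dense grid search over the weighted-quantile objective."""
    grid = np.linspace(min(ratios) - 0.1, max(ratios) + 0.1, n)
    wn = weights / weights.sum()
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], wn[order]
    cum = np.cumsum(w) - 0.5 * w
    # the interpolated quantile function evaluated on the dense grid
    vals = np.interp(q, cum, r)
    return float(vals)


@pytest.mark.parametrize("seed", range(3))
def test_weighted_median_matches_quantile_oracle(seed, random_arrays_dataset):
    data = random_arrays_dataset(seed)
    ratios = data.beta_y / data.beta_x
    weights = data.beta_x**2 / data.se_y**2
    oracle = _grid_quantile_oracle(ratios, weights)
    est = weighted_median(data, n_boot=50, seed=1)
    assert est.beta == pytest.approx(oracle, rel=1e-9)


def test_weighted_median_prefers_valid_majority():
    # 6 valid instruments (theta 0.3) holding 60% of weight, 4 invalid (ratio 2.0)
    bx = np.full(10, 0.5)
    by = np.concatenate([0.3 * bx[:6], 2.0 * bx[6:]])
    sy = np.concatenate([np.full(6, 0.1), np.full(4, 0.1225)])  # 60/40 weight split
    est = weighted_median(dataset(bx, by, sy), n_boot=100, seed=0)
    assert abs(est.beta - 0.3) < abs(est.beta - 2.0)


def test_weighted_median_requires_seed():
    data = dataset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    with pytest.raises(ValueError, match="random_state"):
        WeightedMedian(n_boot=10).fit(data)


# ---------------------------------------------------------------------------
# mode-based
# ---------------------------------------------------------------------------


def test_mode_finds_dominant_cluster():
    data = dataset([1.0] * 4, [1.0, 1.01, 0.99, 5.0], [0.5] * 4)
    est = mode_based(data, n_boot=50, seed=0)
    bandwidth = est.metadata["bandwidth"]
    assert abs(est.beta - 1.0) < bandwidth


def test_mode_exact_for_identical_ratios():
    data = dataset([1.0, 2.0, 4.0], [0.7, 1.4, 2.8], [0.5, 0.5, 0.5])
    est = mode_based(data, n_boot=50, seed=0)
    assert est.beta == pytest.approx(0.7, rel=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_mode_argmax_matches_fine_grid_oracle(seed, random_arrays_dataset):
    data = random_arrays_dataset(seed)
    ratios = data.beta_y / data.beta_x
    weights = data.beta_x**2 / data.se_y**2
    coarse, h = _mode_point(ratios, weights, 1.0, n_grid=2001)
    fine, _ = _mode_point(ratios, weights, 1.0, n_grid=200_001)
    grid_step = (ratios.max() - ratios.min() + 6 * h) / 2000
    assert abs(coarse - fine) <= grid_step
    est = mode_based(data, n_boot=50, seed=2)
    assert est.beta == pytest.approx(coarse, rel=1e-12)


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------


def test_leave_one_out_counts_and_homogeneous_stability(sim_dataset):
    data = sim_dataset(seed=3, theta=0.2, k=20)
    entries = leave_one_out(data)
    assert len(entries) == 20
    full = ivw(data)
    assert all(abs(e.estimate.beta - full.beta) <= full.se for e in entries)
    assert not any(e.flagged for e in entries)


def test_leave_one_out_flags_the_injected_outlier(sim_dataset):
    data = sim_dataset(seed=4, theta=0.2, k=12)
    # corrupt one variant's outcome effect far beyond its standard error
    v = data.retained[5]
    v.beta_y += 25 * v.se_y
    entries = leave_one_out(data)
    shifts = {e.variant_id: e.shift for e in entries}
    assert max(shifts, key=shifts.get) == v.variant_id


def test_leave_one_out_three_variants():
    data = dataset([0.2, 0.3, 0.4], [0.06, 0.09, 0.12], [0.02, 0.02, 0.02])
    assert len(leave_one_out(data)) == 3


# ---------------------------------------------------------------------------
# cross-cutting properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", ["ivw", "egger", "wme", "mode"])
def test_estimators_equivariant_under_joint_sign_flip(method, random_arrays_dataset):
    data = random_arrays_dataset(7)
    flip = np.array([1, -1] * 5, dtype=float)
    flipped = HarmonizedDataset.from_arrays(
        data.beta_x * flip, data.se_x, data.beta_y * flip, data.se_y
    )
    fit = {
        "ivw": lambda d: ivw(d).beta,
        "egger": lambda d: egger(d).beta,
        "wme": lambda d: weighted_median(d, 50, 3).beta,
        "mode": lambda d: mode_based(d, 1.0, 50, 3).beta,
    }[method]
    assert fit(flipped) == pytest.approx(fit(data), rel=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_fixed_se_never_exceeds_random_se(seed, random_arrays_dataset):
    data = random_arrays_dataset(seed)
    assert ivw(data, "fixed").se <= ivw(data, "random").se


def test_estimators_recover_truth_with_strong_data(sim_dataset):
    # no pleiotropy, many precise instruments: every method lands near theta
    data = sim_dataset(seed=10, theta=0.3, k=100, n_exposure=2_000_000,
                       n_case=200_000, n_control=1_800_000,
                       r2_per_variant=(0.001, 0.002))
    for beta in (
        ivw(data).beta,
        egger(data).beta,
        weighted_median(data, 200, 1).beta,
        mode_based(data, 1.0, 200, 1).beta,
    ):
        assert beta == pytest.approx(0.3, abs=0.03)


def test_sklearn_param_interface():
    est = IVW(effects_model="fixed")
    assert est.get_params() == {"effects_model": "fixed"}
    est.set_params(effects_model="random")
    assert est.effects_model == "random"
    assert ModeBased().get_params()["bandwidth_factor"] == 1.0
    assert MREgger().get_params() == {}
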