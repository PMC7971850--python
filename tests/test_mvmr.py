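"""Multivariable MR: conditional estimates, strength Q, dataset assembly."""

import numpy as np
import pytest
import statsmodels.api as sm

from summr import (
    HarmonizedDataset,
    LDSource,
    MultiSimulationConfig,
    build_mvmr_dataset,
    instrument_strength_q,
    ivw,
    mvmr_fit,
    simulate_multi_exposure,
)

from conftest import make_variant


def mv_dataset(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    sx = np.full_like(bx, 0.005) if sx is None else np.asarray(sx, dtype=float)
    return HarmonizedDataset.from_arrays(
        bx, sx, np.asarray(by, float), np.asarray(sy, float),
        exposure_ids=tuple(f"x{i+1}" for i in range(bx.shape[1])),
    )


def random_mv(seed, k=20, m=2):
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.05, 0.02, (k, m))
    by = rng.normal(0.01, 0.02, k)
    sy = rng.uniform(0.005, 0.03, k)
    return mv_dataset(bx, by, sy)


def test_exact_linear_combination_recovered():
    rng = np.random.default_rng(0)
    bx = rng.uniform(0.05, 0.3, (8, 2))
    by = 0.0 * bx[:, 0] + 0.25 * bx[:, 1]
    res = mvmr_fit(mv_dataset(bx, by, np.full(8, 0.02)))
    assert res.beta == pytest.approx([0.0, 0.25], abs=1e-12)


def test_zero_column_reduces_to_univariable_ivw():
    rng = np.random.default_rng(1)
    bx1 = rng.uniform(0.05, 0.3, 10)
    by = 0.3 * bx1 + rng.normal(0, 0.01, 10)
    sy = np.full(10, 0.02)
    bx = np.column_stack([bx1, np.zeros(10)])
    res = mvmr_fit(mv_dataset(bx, by, sy))
    uni = ivw(HarmonizedDataset.from_arrays(bx1, np.full(10, 0.005), by, sy), "random")
    assert res.beta[0] == pytest.approx(uni.beta, rel=1e-12)
    assert res.beta[1] == 0.0 and np.isinf(res.se[1]) and res.pvalue[1] == 1.0


def test_single_exposure_fit_equals_univariable_ivw(random_arrays_dataset):
    data = random_arrays_dataset(3)
    res = mvmr_fit(data)
    uni = ivw(data, "random")
    assert res.beta[0] == pytest.approx(uni.beta, rel=1e-14)
    assert res.se[0] == pytest.approx(uni.se, rel=1e-14)
    assert res.pvalue[0] == pytest.approx(uni.pvalue, rel=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_mvmr_matches_wls_oracle_to_ten_digits(seed):
    data = random_mv(seed)
    bx = np.atleast_2d(data.beta_x)
    w = 1.0 / data.se_y**2
    fit = sm.WLS(data.beta_y, bx, weights=w).fit()
    res = mvmr_fit(data, compute_strength=False)
    assert res.beta == pytest.approx(fit.params, rel=1e-10)
    k, m = bx.shape
    q = fit.scale * (k - m)
    phi = max(1.0, np.sqrt(q / (k - m)))
    se_oracle = fit.bse / np.sqrt(fit.scale) * phi
    assert res.se == pytest.approx(se_oracle, rel=1e-10)


def test_conditional_estimates_invariant_to_column_order():
    data = random_mv(9, k=15)
    res = mvmr_fit(data, compute_strength=False)
    swapped_data = HarmonizedDataset.from_arrays(
        np.atleast_2d(data.beta_x)[:, ::-1],
        np.atleast_2d(data.se_x)[:, ::-1],
        data.beta_y,
        data.se_y,
        exposure_ids=("x2", "x1"),
    )
    swapped = mvmr_fit(swapped_data, compute_strength=False)
    assert swapped.beta == pytest.approx(res.beta[::-1], rel=1e-12)
    assert swapped.estimate_for("x1")["beta"] == pytest.approx(
        res.estimate_for("x1")["beta"], rel=1e-12
    )


def test_collinear_exposures_raise_diagnostic_error():
    rng = np.random.default_rng(2)
    bx1 = rng.uniform(0.05, 0.3, 10)
    bx = np.column_stack([bx1, 2 * bx1])
    with pytest.raises(ValueError, match="collinear"):
        mvmr_fit(mv_dataset(bx, 0.1 * bx1, np.full(10, 0.02)))


def test_more_exposures_than_variants_rejected():
    with pytest.raises(ValueError, match="more variants"):
        mvmr_fit(random_mv(0, k=2, m=2))


# ---------------------------------------------------------------------------
# conditional instrument strength
# ---------------------------------------------------------------------------


def test_orthogonal_strong_instruments_have_large_q():
    # block design: each exposure has its own strong instruments
    k = 20
    bx = np.zeros((k, 2))
    bx[:10, 0] = 0.3
    bx[10:, 1] = 0.3
    sx = np.full((k, 2), 0.01)  # per-variant F = 900
    data = HarmonizedDataset.from_arrays(bx, sx, np.zeros(k), np.full(k, 0.02),
                                         exposure_ids=("a", "b"))
    q, p = instrument_strength_q(data, "a")
    from scipy.stats import chi2

    assert q > chi2.isf(0.001, k - 1)
    assert p < 0.001


def test_proportional_exposures_flag_conditional_weakness():
    rng = np.random.default_rng(4)
    bx1 = rng.uniform(0.1, 0.4, 15)
    sx = np.full((15, 2), 0.01)
    bx = np.column_stack([bx1, bx1 * 0.5])  # target is an exact multiple
    data = HarmonizedDataset.from_arrays(bx, sx, np.zeros(15), np.full(15, 0.02),
                                         exposure_ids=("a", "b"))
    q, p = instrument_strength_q(data, "b")
    assert q == pytest.approx(0.0, abs=1e-18)  # residuals vanish
    assert p == pytest.approx(1.0)


def test_strength_q_matches_projection_expectation():
    """Monte-Carlo mean of Q against its analytic noncentral-chi-square mean."""
    rng = np.random.default_rng(5)
    k = 30
    other = rng.uniform(0.1, 0.4, k)
    d = rng.normal(0, 0.05, k)  # conditional signal of the target
    se_t = np.full(k, 0.02)
    w = 1.0 / se_t**2
    # analytic: Q = ||P_perp (d + e)||^2_w with E[Q] = (k-1) + d' W P_perp d
    x = other[:, None]
    xtwx = x.T @ (x * w[:, None])
    h = x @ np.linalg.inv(xtwx) @ x.T @ np.diag(w)
    resid_d = d - h @ d
    expected = (k - 1) + float(resid_d @ (w * resid_d))
    reps = 400
    qs = np.empty(reps)
    for r in range(reps):
        target = 0.7 * other + d + rng.normal(0, se_t)
        bx = np.column_stack([target, other])
        sx = np.column_stack([se_t, np.full(k, 0.01)])
        data = HarmonizedDataset.from_arrays(bx, sx, np.zeros(k), np.full(k, 0.02),
                                             exposure_ids=("t", "o"))
        qs[r] = instrument_strength_q(data, "t")[0]
    mc_se = qs.std(ddof=1) / np.sqrt(reps)
    assert abs(qs.mean() - expected) < 3 * mc_se


def test_strength_needs_two_exposures(random_arrays_dataset):
    with pytest.raises(ValueError, match=">= 2"):
        instrument_strength_q(random_arrays_dataset(0), "exposure")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _exposure_tables():
    """Two exposures with disjoint significant variant sets of 5 each."""
    xs1, xs2, ys = [], [], []
    for j in range(10):
        sig_in_1 = j < 5
        common = dict(chrom=str(j % 22 + 1), pos=10_000_000 + j * 5_000_000, eaf=0.3)
        xs1.append(make_variant(f"rs{j}", "A", "G", beta=0.2 if sig_in_1 else 0.001,
                                pvalue=1e-10 if sig_in_1 else 0.5, **common))
        xs2.append(make_variant(f"rs{j}", "A", "G", beta=0.001 if sig_in_1 else 0.2,
                                pvalue=0.5 if sig_in_1 else 1e-10, **common))
        ys.append(make_variant(f"rs{j}", "A", "G", beta=0.05, se=0.02, pvalue=0.01,
                               **common))
    return xs1, xs2, ys


def test_disjoint_significant_sets_union_to_ten():
    xs1, xs2, ys = _exposure_tables()
    data = build_mvmr_dataset({"x1": xs1, "x2": xs2}, ys)
    assert data.n_retained == 10
    assert data.n_exposures == 2
    assert np.atleast_2d(data.beta_x).shape == (10, 2)


def test_shared_significant_variant_appears_once():
    xs1, xs2, ys = _exposure_tables()
    xs2[0] = make_variant("rs0", "A", "G", beta=0.2, pvalue=1e-9, chrom="1",
                          pos=10_000_000, eaf=0.3)
    data = build_mvmr_dataset({"x1": xs1, "x2": xs2}, ys)
    assert sorted(v.variant_id for v in data.retained) == sorted(f"rs{j}" for j in range(10))


def test_variant_missing_from_one_exposure_is_logged():
    xs1, xs2, ys = _exposure_tables()
    xs2 = [v for v in xs2 if v.variant_id != "rs1"]
    data = build_mvmr_dataset({"x1": xs1, "x2": xs2}, ys)
    assert data.n_retained == 9
    assert data.exclusion_log["absent_from_exposure"] == 1


def test_mvmr_dataset_matches_rule_replay_oracle():
    cfg = MultiSimulationConfig(n_variants=(15, 15), seed=21, palindrome_fraction=0.3,
                                exposure_ids=("a", "b"))
    (ea, eb), out, _ = simulate_multi_exposure(cfg)
    data = build_mvmr_dataset({"a": ea, "b": eb}, out, af_window=(0.4, 0.6))
    # brute-force replay: union of significant ids, then palindrome window rule
    by_id_a = {r.variant_id: r for r in ea.records}
    by_id_b = {r.variant_id: r for r in eb.records}
    by_id_y = {r.variant_id: r for r in out.records}
    expected = []
    for vid, ra in by_id_a.items():
        if min(ra.pvalue, by_id_b[vid].pvalue) >= 5e-8:
            continue
        eafs = (ra.eaf, by_id_b[vid].eaf, by_id_y[vid].eaf)
        if ra.is_palindromic and any(0.4 <= f <= 0.6 for f in eafs):
            continue
        expected.append(vid)
    assert sorted(data.variant_ids) == sorted(expected)


def test_mvmr_attenuation_under_full_mediation():
    """Effect flowing only through a mediator vanishes upon conditioning."""
    cfg = MultiSimulationConfig(
        n_variants=(30, 30), cross_effects=((0.0, 0.0), (0.5, 0.0)),
        theta=(0.0, 0.3), seed=13, palindrome_fraction=0.0,
        exposure_ids=("target", "mediator"),
    )
    (ex_t, ex_m), out, _ = simulate_multi_exposure(cfg)
    data = build_mvmr_dataset({"target": ex_t, "mediator": ex_m}, out)
    res = mvmr_fit(data)
    t = res.estimate_for("target")
    m = res.estimate_for("mediator")
    assert abs(t["beta"]) < 2 * t["se"]  # direct effect compatible with zero
    assert m["beta"] - 2 * m["se"] > 0  # mediator keeps its effect
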