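import numpy as np
import pandas as pd
import pytest

from protoncea.economics import compute_ce
from protoncea.params import TriangularRange, default_params, set_param
from protoncea.sensitivity import (
    all_ceacs, ceac, default_wtp_grid, one_way, psa_param_names, run_psa,
    sample_triangular, triangular_ppf,
)


# ----------------------------------------------------------------------
# triangular sampling

def test_degenerate_triangular_returns_mode():
    rng = np.random.default_rng(0)
    tr = TriangularRange(2.5, 2.5, 2.5)
    assert all(sample_triangular(rng, tr) == 2.5 for _ in range(10))


def test_triangular_mean_matches_closed_form():
    # mean of Triangular(0, 1, 2) is (a+b+c)/3 = 1; SE of the mean over
    # 100,000 draws is sqrt((1/6)/1e5)
    rng = np.random.default_rng(12345)
    draws = sample_triangular(rng, TriangularRange(0.0, 1.0, 2.0), size=100_000)
    se = np.sqrt((1.0 / 6.0) / 100_000)
    assert abs(draws.mean() - 1.0) < 3 * se


def test_draws_stay_inside_support():
    rng = np.random.default_rng(99)
    tr = TriangularRange(0.75, 0.85, 0.94)
    draws = sample_triangular(rng, tr, size=20_000)
    assert draws.min() >= 0.75
    assert draws.max() <= 0.94


def test_asymmetric_edge_modes():
    # mode at an endpoint must not produce NaNs or escapes
    rng = np.random.default_rng(5)
    lo = sample_triangular(rng, TriangularRange(0.0, 0.0, 1.0), size=5000)
    hi = sample_triangular(rng, TriangularRange(0.0, 1.0, 1.0), size=5000)
    assert np.all((lo >= 0) & (lo <= 1)) and np.all((hi >= 0) & (hi <= 1))
    assert lo.mean() < 0.5 < hi.mean()


# ----------------------------------------------------------------------
# tornado

def test_zero_width_range_has_zero_spread(life_table):
    p = default_params()
    p.ranges["c_hearing_aid"] = TriangularRange(2086.9, 2086.9, 2086.9)
    entries = {e.parameter: e for e in one_way(p, life_table, "EQ-5D")}
    assert entries["c_hearing_aid"].spread == pytest.approx(0.0, abs=1e-9)


def test_tornado_excludes_other_instruments_utilities(params, life_table):
    names = [e.parameter for e in one_way(params, life_table, "EQ-5D")]
    assert "u_hl_eq5d" in names
    assert "u_hl_hui3" not in names and "u_hl_sf6d" not in names


def test_discount_endpoints_order(params, life_table):
    # lower discounting favours the far-future QALY gains more than the
    # near-term cost gap, so the ICER rises with the discount rate
    lo = compute_ce(set_param(params, "discount_rate", 0.0), life_table, "EQ-5D")
    hi = compute_ce(set_param(params, "discount_rate", 0.07), life_table, "EQ-5D")
    assert lo.icer < hi.icer
    entries = {e.parameter: e for e in one_way(params, life_table, "EQ-5D")}
    e = entries["discount_rate"]
    assert e.icer_at_low == pytest.approx(lo.icer) and e.icer_at_high == pytest.approx(hi.icer)


def test_endpoint_icers_bracket_base_case(params, life_table):
    base = compute_ce(params, life_table, "EQ-5D").icer
    for e in one_way(params, life_table, "EQ-5D"):
        lo, hi = sorted([e.icer_at_low, e.icer_at_high])
        assert lo - 1e-6 <= base <= hi + 1e-6


def test_entries_sorted_by_descending_spread(params, life_table):
    spreads = [e.spread for e in one_way(params, life_table, "HUI3")]
    assert spreads == sorted(spreads, reverse=True)


# ----------------------------------------------------------------------
# PSA

def test_psa_seeded_runs_are_bitwise_identical(params, life_table):
    a = run_psa(params, life_table, n=40, seed=321)
    b = run_psa(params, life_table, n=40, seed=321)
    for idx in a.samples:
        pd.testing.assert_frame_equal(a.samples[idx], b.samples[idx])


def test_psa_degenerate_ranges_collapse_to_base_case(params, life_table):
    p = default_params()
    for name in list(psa_param_names(p)):
        base = p.ranges[name].mode
        p.ranges[name] = TriangularRange(base, base, base)
    psa = run_psa(p, life_table, n=1, seed=1)
    base_res = compute_ce(p, life_table, "EQ-5D")
    row = psa.samples["EQ-5D"].iloc[0]
    assert row["delta_cost"] == pytest.approx(base_res.delta_cost, abs=1e-9)
    assert row["delta_qaly"] == pytest.approx(base_res.delta_qaly, abs=1e-12)


def test_psa_draws_respect_supports(params, life_table):
    psa = run_psa(params, life_table, n=100, seed=7)
    for idx, df in psa.samples.items():
        for name in psa_param_names(params):
            tr = params.ranges[name]
            assert df[name].between(tr.low, tr.high).all()


def test_psa_discount_flag(params, life_table):
    with_r = run_psa(params, life_table, n=5, seed=2)
    without_r = run_psa(params, life_table, n=5, seed=2, include_discount=False)
    assert "discount_rate" in with_r.samples["EQ-5D"].columns
    assert "discount_rate" not in without_r.samples["EQ-5D"].columns


def test_psa_mean_delta_qaly_near_base(params, life_table):
    # triangular means sit close to the modes for the near-symmetric ranges,
    # so the PSA mean incremental QALY stays near the base-case value
    psa = run_psa(params, life_table, n=400, seed=11, include_discount=False)
    base = compute_ce(params, life_table, "EQ-5D").delta_qaly
    assert abs(psa.samples["EQ-5D"]["delta_qaly"].mean() - base) < 0.1


def test_psa_rejects_bad_n(params, life_table):
    with pytest.raises(ValueError):
        run_psa(params, life_table, n=0, seed=1)


# ----------------------------------------------------------------------
# CEAC

def test_ceac_zero_wtp_with_positive_cost_difference(params, life_table):
    psa = run_psa(params, life_table, n=50, seed=3)
    curve = ceac(psa.samples["EQ-5D"], np.array([0.0]))
    assert (psa.samples["EQ-5D"]["delta_cost"] > 0).all()
    assert curve.probability[0] == 0.0


def test_ceac_monotone_when_qaly_gain_nonnegative(params, life_table):
    psa = run_psa(params, life_table, n=200, seed=13)
    df = psa.pooled()
    if (df["delta_qaly"] >= 0).all():
        curve = ceac(df)
        assert np.all(np.diff(curve.probability) >= 0)


def test_ceac_empty_samples_rejected():
    with pytest.raises(ValueError):
        ceac(pd.DataFrame(columns=["delta_cost", "delta_qaly"]))


def test_wtp_grid_contains_threshold():
    assert 46_729.0 in default_wtp_grid()


def test_integrated_curve_pools_indexes_equally(params, life_table):
    psa = run_psa(params, life_table, n=60, seed=17)
    curves = all_ceacs(psa)
    pooled = np.mean(
        [curves[i].probability for i in ("EQ-5D", "HUI3", "SF-6D")], axis=0
    )
    np.testing.assert_allclose(curves["integrated"].probability, pooled, atol=1e-12)
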