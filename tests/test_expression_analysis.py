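"""Statistics pipeline: normalization invariants, filtering, dye-swap model,
empirical-Bayes moderation, BH adjustment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncarray.expression_analysis import (
    MAMatrix,
    bh_adjust,
    ebayes,
    fit_dyeswap,
    make_ma,
    net_intensity,
    normalize_between,
    normalize_within,
    pm_mm_filter,
    run_de_analysis,
)
from ncarray.hyb_simulator import TwoColorScan


def scan_from_values(array_id, f635, b635, f532, b532, names=None, ch635="case", ch532="control"):
    n = len(f635)
    names = names or [f"g{i}" for i in range(n)]
    spots = pd.DataFrame(
        {
            "Block": 1,
            "Row": 1,
            "Column": np.arange(1, n + 1),
            "ID": [f"{g}.PM.1" for g in names],
            "Name": names,
            "F635 Median": f635,
            "B635 Median": b635,
            "F532 Median": f532,
            "B532 Median": b532,
        }
    )
    return TwoColorScan(array_id, spots, {"ch635": ch635, "ch532": ch532})


def make_ma_matrix(m, a, blocks=None, names=None, array_id="arr"):
    n = len(m)
    spots = pd.DataFrame(
        {
            "Block": blocks if blocks is not None else np.ones(n, dtype=int),
            "Row": 1,
            "Column": np.arange(1, n + 1),
            "Name": names or [f"g{i}" for i in range(n)],
            "pair_role": "PM",
            "M": np.asarray(m, dtype=float),
            "A": np.asarray(a, dtype=float),
        }
    )
    return MAMatrix(array_id, spots)


# ---------------------------------------------------------------------------
# Net intensity
# ---------------------------------------------------------------------------

def test_net_intensity_subtracts_background_and_floors():
    scan = scan_from_values("a", [1000.0, 100.0], [200.0, 150.0], [500.0, 50.0], [100.0, 50.0])
    net = net_intensity(scan)
    assert list(net["net635"]) == [800.0, 0.5]  # second spot floored
    assert list(net["net532"]) == [400.0, 0.5]


def test_all_background_spot_gives_zero_m():
    scan = scan_from_values("a", [100.0], [150.0], [90.0], [120.0])
    ma = make_ma(scan)
    assert ma.spots["M"].iloc[0] == 0.0


# ---------------------------------------------------------------------------
# Within-array (print-tip) normalization
# ---------------------------------------------------------------------------

def test_print_tip_regression_residualizes_linear_trend_to_zero():
    rng = np.random.default_rng(1)
    a = np.concatenate([rng.uniform(4, 12, 200), rng.uniform(4, 12, 200)])
    blocks = np.repeat([1, 2], 200)
    m = np.where(blocks == 1, 0.7 + 0.3 * a, -1.2 - 0.1 * a)  # exact linear per block
    ma = normalize_within(make_ma_matrix(m, a, blocks))
    assert np.abs(ma.spots["M"]).max() < 1e-8
    assert np.array_equal(ma.spots["A"], a)  # A untouched


def test_opposite_block_offsets_removed_independently():
    rng = np.random.default_rng(2)
    a = rng.uniform(4, 12, 400)
    blocks = np.repeat([1, 2], 200)
    m = np.where(blocks == 1, 0.8, -0.8) + rng.normal(0, 0.05, 400)
    ma = normalize_within(make_ma_matrix(m, a, blocks))
    med = ma.spots.groupby("Block")["M"].median()
    assert np.abs(med).max() < 0.02


def test_small_blocks_fall_back_to_whole_array_fit():
    rng = np.random.default_rng(3)
    a = rng.uniform(4, 12, 110)
    blocks = np.array([1] * 100 + [2] * 10)  # block 2 below the 20-spot minimum
    m = 0.5 + 0.2 * a
    ma = normalize_within(make_ma_matrix(m, a, blocks))
    assert np.abs(ma.spots["M"]).max() < 1e-8  # whole-array fit removes the trend too


# ---------------------------------------------------------------------------
# Between-array quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalization_equalizes_sorted_a_and_is_idempotent():
    rng = np.random.default_rng(4)
    mas = [make_ma_matrix(np.zeros(50), rng.uniform(2, 14, 50), array_id=f"a{i}") for i in range(3)]
    out = normalize_between(mas)
    sorted_as = [np.sort(ma.spots["A"].to_numpy()) for ma in out]
    for s in sorted_as[1:]:
        assert np.array_equal(sorted_as[0], s)
    # reference distribution = rank-wise mean of the sorted inputs
    expected = np.mean(
        [np.sort(ma.spots["A"].to_numpy()) for ma in mas], axis=0
    )
    assert np.allclose(sorted_as[0], expected)
    # idempotent
    again = normalize_between(out)
    for before, after in zip(out, again):
        assert np.array_equal(before.spots["A"].to_numpy(), after.spots["A"].to_numpy())
    # M untouched
    for before, after in zip(mas, out):
        assert np.array_equal(before.spots["M"].to_numpy(), after.spots["M"].to_numpy())


def test_identical_a_multisets_unchanged_up_to_order():
    a = np.array([1.0, 5.0, 3.0])
    mas = [
        make_ma_matrix(np.zeros(3), a, array_id="x"),
        make_ma_matrix(np.zeros(3), a[::-1].copy(), array_id="y"),
    ]
    out = normalize_between(mas)
    assert np.array_equal(out[0].spots["A"].to_numpy(), a)
    assert np.array_equal(out[1].spots["A"].to_numpy(), a[::-1])


def test_differing_spot_counts_rejected():
    mas = [make_ma_matrix(np.zeros(4), np.arange(4.0)), make_ma_matrix(np.zeros(5), np.arange(5.0))]
    with pytest.raises(ValueError, match="spot count"):
        normalize_between(mas)


# ---------------------------------------------------------------------------
# PM > MM filter
# ---------------------------------------------------------------------------

def filter_scan(array_id, pm, mm, ch635="case", ch532="control", names=None,
                pm2=None, mm2=None):
    n = len(pm)
    names = names or [f"g{i}" for i in range(n)]
    pm2 = pm if pm2 is None else pm2
    mm2 = mm if mm2 is None else mm2
    spots = pd.DataFrame(
        {
            "Block": 1,
            "Row": np.arange(1, n + 1).repeat(2),
            "Column": np.tile([1, 2], n),
            "ID": [f"{g}.{r}.1" for g in names for r in ("PM", "MM")],
            "Name": np.repeat(names, 2),
            "F635 Median": np.column_stack([pm, mm]).ravel() + 100.0,
            "B635 Median": 100.0,
            "F532 Median": np.column_stack([pm2, mm2]).ravel() + 100.0,
            "B532 Median": 100.0,
        }
    )
    return TwoColorScan(array_id, spots, {"ch635": ch635, "ch532": ch532})


def sheet_for(scans):
    return pd.DataFrame(
        {
            "array_id": [s.array_id for s in scans],
            "ch635_condition": [s.dye_assignment["ch635"] for s in scans],
            "ch532_condition": [s.dye_assignment["ch532"] for s in scans],
            "pair_id": 1,
            "biological_replicate": 1,
        }
    )


def test_pm_equal_mm_is_filtered_out_strict_inequality():
    scans = [filter_scan("a", pm=np.array([500.0]), mm=np.array([500.0]))]
    out = pm_mm_filter(scans, sheet_for(scans))
    assert not out.loc["g0", "passed"]


def test_pm_above_mm_in_one_condition_suffices(small_experiment):
    scans, sheet, truth_table, truth = small_experiment
    out = pm_mm_filter(scans, sheet)
    candidates = set(truth_table["candidate_id"])
    kept = out.loc[out.index.isin(candidates), "passed"]
    assert kept.mean() > 0.95  # strong specific signal, kappa = 0.2


def test_probe_without_mm_is_kept_and_flagged(small_experiment):
    scans, sheet, _, _ = small_experiment
    out = pm_mm_filter(scans, sheet)
    singles = out[~out["has_mm"]]
    assert len(singles) == 48  # spike-ins + snRNA controls
    assert singles["passed"].all()


def test_null_probes_with_symmetric_noise_pass_at_about_75_percent():
    # PM and MM exchangeable -> P(PM>MM in one condition) = 1/2 per condition,
    # conditions independent -> pass rate 1 - 1/4
    rng = np.random.default_rng(6)
    n = 4000
    scans = []
    for arr, (c635, c532) in enumerate([("case", "control"), ("control", "case")]):
        # independent draws per channel, well above the net-intensity floor
        pm, mm = rng.normal(300.0, 50.0, n), rng.normal(300.0, 50.0, n)
        pm2, mm2 = rng.normal(300.0, 50.0, n), rng.normal(300.0, 50.0, n)
        scans.append(filter_scan(f"a{arr}", pm, mm, c635, c532, pm2=pm2, mm2=mm2))
    out = pm_mm_filter(scans, sheet_for(scans))
    assert out["passed"].mean() == pytest.approx(0.75, abs=0.05)


# ---------------------------------------------------------------------------
# Dye-swap linear model
# ---------------------------------------------------------------------------

def test_noise_free_fit_recovers_beta_exactly(noise_free_experiment):
    scans, sheet, truth_table, _ = noise_free_experiment
    ma_list = [make_ma(s) for s in scans]
    fit = fit_dyeswap(ma_list, sheet)
    truth = truth_table.set_index("candidate_id")["log2fc"]
    joined = fit.join(truth)
    sub = joined.dropna(subset=["log2fc"])
    assert np.allclose(sub["beta"], sub["log2fc"], atol=1e-9)


def test_relabeling_dyes_and_conditions_leaves_beta_unchanged(small_experiment):
    scans, sheet, _, _ = small_experiment
    fit = fit_dyeswap([make_ma(s) for s in scans], sheet)
    swapped = [
        TwoColorScan(
            s.array_id,
            s.spots.rename(
                columns={
                    "F635 Median": "F532 Median",
                    "B635 Median": "B532 Median",
                    "F532 Median": "F635 Median",
                    "B532 Median": "B635 Median",
                }
            ),
            {"ch635": s.dye_assignment["ch532"], "ch532": s.dye_assignment["ch635"]},
        )
        for s in scans
    ]
    fit_swapped = fit_dyeswap([make_ma(s) for s in swapped], sheet)
    assert np.allclose(fit["beta"], fit_swapped["beta"])


def test_residual_df_is_arrays_minus_one(small_experiment):
    scans, sheet, _, _ = small_experiment
    fit = fit_dyeswap([make_ma(s) for s in scans], sheet)
    assert (fit["df"] == 5.0).all()  # 3 dye-swap pairs = 6 arrays


def test_gls_dup_method_matches_average_point_estimate(small_experiment):
    scans, sheet, _, _ = small_experiment
    ma_list = [make_ma(s) for s in scans]
    avg = fit_dyeswap(ma_list, sheet, dup_method="average")
    gls = fit_dyeswap(ma_list, sheet, dup_method="gls")
    gls = gls.reindex(avg.index)
    # balanced replication: GLS point estimate equals the spot mean
    assert np.allclose(avg["beta"], gls["beta"], atol=1e-9)
    assert (gls["df"] > avg["df"]).all()  # spot-level residual df


def test_unorientable_sheet_raises():
    scan = scan_from_values("a", [100.0], [0.0], [100.0], [0.0], ch635="case", ch532="case")
    with pytest.raises(ValueError, match="same condition"):
        make_ma(scan)


# ---------------------------------------------------------------------------
# Empirical Bayes moderation
# ---------------------------------------------------------------------------

def fit_frame(beta, s2, df, v=1.0 / 6.0):
    return pd.DataFrame(
        {"beta": beta, "s2": s2, "df": float(df), "n_arrays": 6, "v": v},
        index=[f"g{i}" for i in range(len(beta))],
    )


def test_identical_variances_give_infinite_d0_and_z_statistics():
    fit = fit_frame(beta=np.linspace(-1, 1, 50), s2=np.full(50, 0.04), df=5)
    prior, out = ebayes(fit)
    assert math.isinf(prior.d0)
    z = fit["beta"] / np.sqrt(prior.s0_sq * fit["v"])
    assert np.allclose(out["t"], z)
    assert np.allclose(out["p"], 2 * stats.norm.sf(np.abs(z)))


def test_moderated_variance_lies_between_prior_and_gene_variance():
    rng = np.random.default_rng(11)
    s2 = 0.05 * rng.chisquare(5, size=300) / 5
    fit = fit_frame(beta=rng.normal(0, 0.2, 300), s2=s2, df=5)
    prior, out = ebayes(fit)
    lo = np.minimum(prior.s0_sq, s2)
    hi = np.maximum(prior.s0_sq, s2)
    assert ((out["s2_post"] >= lo - 1e-12) & (out["s2_post"] <= hi + 1e-12)).all()


def test_d0_zero_limit_recovers_ordinary_t():
    # shrink the prior out of the formula by hand: with d0 -> 0 the posterior
    # variance is the gene variance and the ordinary t-statistic results
    rng = np.random.default_rng(12)
    s2 = 0.05 * rng.chisquare(5, size=100) / 5
    beta = rng.normal(0, 0.2, 100)
    v = 1.0 / 6.0
    s2_post = (0.0 * 1.0 + 5.0 * s2) / (0.0 + 5.0)
    t = beta / np.sqrt(s2_post * v)
    assert np.allclose(t, beta / np.sqrt(s2 * v))


def test_d0_recovery_within_25_percent_on_simulated_chi2_variances():
    rng = np.random.default_rng(13)
    d0_true, s0_true, d = 4.0, 0.05, 5.0
    estimates = []
    for _ in range(200):
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=500)
        s2 = sigma2 * rng.chisquare(d, size=500) / d
        prior, _ = ebayes(fit_frame(beta=np.zeros(500), s2=s2, df=d))
        estimates.append(prior.d0)
    assert np.median(estimates) == pytest.approx(d0_true, rel=0.25)


def test_too_few_candidates_raises():
    with pytest.raises(ValueError, match="few"):
        ebayes(fit_frame(beta=np.zeros(5), s2=np.full(5, 0.1), df=5))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_hand_worked_example():
    # step-up: p_adj_(j) = min_{k>=j} m p_(k)/k -> (0.03, 0.03, 0.03)
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_degenerate_cases():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert np.allclose(bh_adjust([0.2]), [0.2])


def test_bh_monotone_and_order_preserving():
    rng = np.random.default_rng(14)
    p = rng.uniform(0, 1, 100)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    # adjusted p is a monotone non-decreasing function of raw p
    assert (np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# Full pipeline properties
# ---------------------------------------------------------------------------

def test_near_noise_free_pipeline_recovers_beta(small_panel, small_design):
    # vanishing technical noise: the full pipeline (normalization included)
    # must hand back the simulated fold changes to numerical precision.
    # (Exactly zero noise gives zero gene variances, which the moderation
    # step rejects by contract -- see test_too_few_candidates_raises.)
    from ncarray.hyb_simulator import TruthModel, simulate_experiment

    candidates = [p.probe_id for p in small_panel if p.role == "signal"]
    truth = TruthModel.generate(
        candidates, small_design.n_blocks, seed=17, kappa=0.0, nu=0.0,
        sigma_bio=0.0, sigma_dye=0.0, sigma_background=0.0, sigma_eps=1e-8,
        tip_sd=(0.0, 0.0, 0.0),
    )
    truth.delta[:] = 0.0
    truth.tip_coefs[:] = 0.0
    scans, sheet, truth_table = simulate_experiment(small_design, truth)
    de = run_de_analysis(scans, sheet)
    joined = de.join(truth_table.set_index("candidate_id"), how="inner", rsuffix="_true")
    sub = joined[joined["passed_pm_mm_filter"]]
    # robust loess ignores the few large-|M| DE spots; the interpolation
    # grid leaves at most ~1e-4 residual distortion
    assert np.abs(sub["log2fc"] - sub["log2fc_true"]).max() < 1e-3


def test_pipeline_equivariant_under_array_and_spot_permutation(small_experiment):
    scans, sheet, _, _ = small_experiment
    de = run_de_analysis(scans, sheet)
    rng = np.random.default_rng(15)
    shuffled_scans = [
        TwoColorScan(
            s.array_id,
            s.spots.sample(frac=1.0, random_state=1).reset_index(drop=True),
            s.dye_assignment,
        )
        for s in reversed(scans)
    ]
    shuffled_sheet = sheet.sample(frac=1.0, random_state=2).reset_index(drop=True)
    de2 = run_de_analysis(shuffled_scans, shuffled_sheet)
    pd.testing.assert_frame_equal(de.sort_index(), de2.sort_index())
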