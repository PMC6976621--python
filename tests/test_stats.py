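"""Measurement and inference layer: aim points, risk-sensitivity, slope
comparison, model comparison, effect sizes, power, t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reachrisk import (SubjectModel, compute_aim_points, fit_linear_quadratic,
                       generate_cohort, one_sample_t, paired_cohens_d,
                       paired_t_and_ci, relative_aims, required_sample_size,
                       risk_sensitivity, split_slopes,
                       bootstrap_permutation_slopes, optimal_aim)
from reachrisk.errors import (DegenerateDataError, InsufficientDataError,
                              ParameterError)
from reachrisk.stats import (baseline_risk_sensitivity, _paired_power,
                             window_risk_sensitivity)


def tiny_table(a_i=28.5, a_c=27.0, a_o=26.0, n_blocks=3):
    """Hand-built trial table with constant endpoints per role/session."""
    rows = []
    for blk in range(1, 6):
        for t in range(1, 11):
            rows.append(("S01", "g", "baseline", blk, t, "subject", a_i))
    for blk in range(1, n_blocks + 1):
        for t in range(1, 11):
            rows.append(("S01", "g", "competition", blk, t, "subject", a_c))
            rows.append(("S01", "g", "competition", blk, t, "opponent", a_o))
    return pd.DataFrame(rows, columns=["subject_id", "group", "session",
                                       "block", "trial", "role",
                                       "endpoint_cm"])


def two_slope_points(rng, n=88, slope_neg=0.21, slope_pos=0.63, noise=0.8,
                     xlo=-6.0, xhi=4.0):
    x = rng.uniform(xlo, xhi, n)
    y = np.where(x < 0, slope_neg * x, slope_pos * x) + rng.normal(0, noise, n)
    return x, y


class TestAimPoints:
    def test_constant_baseline(self):
        aps = compute_aim_points(tiny_table())
        assert aps.A_i.loc["S01"] == pytest.approx(28.5)

    def test_role_partition(self):
        aps = compute_aim_points(tiny_table(a_c=27.0, a_o=24.0))
        assert (aps.blocks.A_c == 27.0).all()
        assert (aps.blocks.A_o == 24.0).all()

    def test_missing_session_raises(self):
        t = tiny_table()
        with pytest.raises(InsufficientDataError):
            compute_aim_points(t[t.session != "competition"])

    def test_last50_window_on_practice_protocol(self):
        trials, _ = generate_cohort("exp1c", 1, seed=4)
        aps = compute_aim_points(trials, baseline_window="last50")
        pre = trials[(trials.role == "subject")
                     & (trials.session == "individual")]
        assert aps.A_i.loc["S01"] == pytest.approx(
            pre.endpoint_cm.tail(50).mean())


class TestRiskSensitivity:
    def test_definition(self, gf):
        assert risk_sensitivity(28.0, 1.5, gf) == pytest.approx(
            28.0 - optimal_aim(1.5, gf))

    @pytest.mark.parametrize("b", [0.9, -0.9])
    def test_recovers_generative_bias(self, b):
        model = SubjectModel(baseline_bias=b)
        trials, _ = generate_cohort("exp1b", 8, model, seed=17, bias_sd=0.0)
        rs = baseline_risk_sensitivity(trials)
        # per-subject estimate combines 50-trial mean noise (~0.31 cm) with
        # sigma-estimation noise mapped through E*(sigma) (~0.15 cm): cohort
        # SEM ~ 0.12 cm, so a 3-sigma band is ~0.36 cm
        assert rs.mean() == pytest.approx(b, abs=0.36)

    def test_null_agent_near_zero(self):
        model = SubjectModel(baseline_bias=0.0)
        trials, _ = generate_cohort("exp1b", 8, model, seed=23, bias_sd=0.0)
        rs = baseline_risk_sensitivity(trials)
        assert abs(rs.mean()) < 0.3

    def test_window_variant(self):
        trials, _ = generate_cohort("exp1b", 2, seed=3)
        rs = window_risk_sensitivity(trials, "competition", blocks=range(8, 13))
        assert len(rs) == 2 and np.isfinite(rs).all()
        # default window = last 5 blocks present = blocks 8-12 here
        auto = window_risk_sensitivity(trials, "competition")
        assert auto.equals(rs)


class TestRelativeAims:
    def test_zero_point(self):
        aps = compute_aim_points(tiny_table(a_i=27.0, a_c=27.0, a_o=27.0))
        pts = relative_aims(aps, blocks=range(2, 4))
        assert (pts.x == 0).all() and (pts.y == 0).all()

    def test_point_count_and_block_exclusion(self):
        trials, _ = generate_cohort("exp1b", 8, seed=6)
        pts = relative_aims(compute_aim_points(trials))
        assert len(pts) == 88                      # 11 blocks x 8 subjects
        assert 1 not in set(pts.block)


class TestSplitSlopes:
    def test_exact_line_both_sides(self, rng):
        x = np.concatenate([rng.uniform(-5, -0.1, 20), rng.uniform(0.1, 5, 20)])
        y = 0.5 * x + 1.0
        assert split_slopes(x, y) == pytest.approx((0.5, 0.5))

    def test_vertical_translation_invariance(self, rng):
        x, y = two_slope_points(rng)
        assert split_slopes(x, y) == pytest.approx(split_slopes(x, y + 11.3))

    def test_recovery_at_n88(self):
        rng = np.random.default_rng(42)
        x, y = two_slope_points(rng, noise=0.3)
        res = bootstrap_permutation_slopes(x, y, n_boot=2000, seed=0)
        assert res.ci_left[0] < 0.21 < res.ci_left[1]
        assert res.ci_right[0] < 0.63 < res.ci_right[1]

    def test_insufficient_side_raises(self):
        x = np.array([-3, -2, -1, -0.5, 1.0])
        with pytest.raises(InsufficientDataError):
            split_slopes(x, 0.3 * x)


class TestBootstrapPermutation:
    def test_collinear_points_are_not_significant(self, rng):
        # a single straight line carries no slope difference: the bootstrap
        # halves differ only by floating-point jitter, so the permutation p
        # must sit near 0.5 and never look significant
        x = np.concatenate([rng.uniform(-5, -0.1, 20), rng.uniform(0.1, 5, 20)])
        y = 0.5 * x + 1.0
        res = bootstrap_permutation_slopes(x, y, n_boot=500, seed=1)
        assert 0.2 < res.p_perm < 0.8
        strict = bootstrap_permutation_slopes(x, y, n_boot=500, seed=1,
                                              tie_rule="strict")
        assert strict.p_perm <= res.p_perm         # strict drops the ties

    def test_bit_reproducible_under_seed(self, rng):
        x, y = two_slope_points(rng)
        a = bootstrap_permutation_slopes(x, y, n_boot=1000, seed=99)
        b = bootstrap_permutation_slopes(x, y, n_boot=1000, seed=99)
        np.testing.assert_array_equal(a.boot_left, b.boot_left)
        assert a.p_perm == b.p_perm

    def test_cis_contain_point_estimates(self, rng):
        x, y = two_slope_points(rng)
        r = bootstrap_permutation_slopes(x, y, n_boot=2000, seed=5)
        assert r.ci_left[0] <= r.slope_left <= r.ci_left[1]
        assert r.ci_right[0] <= r.slope_right <= r.ci_right[1]

    def test_detects_two_slope_structure(self):
        # spread and slopes of the reference scatter: strong rejections
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            x, y = two_slope_points(rng, noise=0.8)
            r = bootstrap_permutation_slopes(x, y, n_boot=2000, seed=rep)
            hits += r.p_perm < 0.01
        assert hits >= 7


class TestModelComparison:
    def test_quadratic_truth_preferred(self):
        wins = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            x = rng.uniform(-6, 4, 88)
            y = 0.5 * x + 0.15 * x * x + rng.normal(0, 1.0, 88)
            f = fit_linear_quadratic(x, y)
            wins += f["quadratic"]["AICc"] < f["linear"]["AICc"]
        assert wins >= 45

    def test_pure_noise_prefers_linear(self):
        wins = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            x = rng.uniform(-6, 4, 88)
            y = rng.normal(0, 1.0, 88)
            f = fit_linear_quadratic(x, y)
            wins += f["linear"]["AICc"] < f["quadratic"]["AICc"]
        assert wins > 25

    def test_order_invariance(self, rng):
        x, y = two_slope_points(rng)
        f1 = fit_linear_quadratic(x, y)
        perm = rng.permutation(len(x))
        f2 = fit_linear_quadratic(x[perm], y[perm])
        for m in ("linear", "quadratic"):
            assert f1[m]["AIC"] == pytest.approx(f2[m]["AIC"])
            assert f1[m]["BIC"] == pytest.approx(f2[m]["BIC"])

    def test_aicc_exceeds_aic(self, rng):
        x, y = two_slope_points(rng)
        f = fit_linear_quadratic(x, y)
        for m in f.values():
            assert m["AICc"] > m["AIC"]


class TestEffectSizeAndPower:
    def test_reference_summary_statistics(self):
        d = paired_cohens_d(1.15, 0.65, -0.01, 0.70, 0.38)
        assert round(d, 2) == 1.54

    def test_equal_means_give_zero(self):
        assert paired_cohens_d(1.0, 0.5, 1.0, 0.7, 0.2) == 0.0

    def test_independent_case_matches_simulation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 0.6, 200_000)
        b = rng.normal(0.2, 0.8, 200_000)      # r = 0 by construction
        diff = a - b
        sim_d = diff.mean() / diff.std(ddof=1)
        formula = paired_cohens_d(a.mean(), a.std(ddof=1), b.mean(),
                                  b.std(ddof=1), 0.0)
        assert formula == pytest.approx(sim_d, abs=0.02)

    def test_degenerate_pairing(self):
        with pytest.raises(DegenerateDataError):
            paired_cohens_d(1.0, 0.5, 0.0, 0.5, 1.0)

    def test_required_sample_size_reference_case(self):
        assert required_sample_size(1.54, alpha=0.05, power=0.80, tails=2) == 6

    def test_power_monotone_in_n(self):
        powers = [_paired_power(1.54, n, 0.05, 2) for n in range(2, 51)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_brute_force_small_n_oracle(self):
        d = 10.0
        oracle = next(n for n in range(2, 11)
                      if _paired_power(d, n, 0.05, 2) >= 0.8)
        assert required_sample_size(d) == oracle

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            required_sample_size(-1.0)
        with pytest.raises(ParameterError):
            required_sample_size(1.0, alpha=1.5)


class TestTTests:
    def test_identical_samples(self):
        r = paired_t_and_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == 0.0 and r["p"] == 1.0 and r["ci95"] == (0.0, 0.0)

    def test_against_scipy(self, rng):
        a = rng.normal(1, 1, 15)
        b = rng.normal(0, 1, 15)
        r = paired_t_and_ci(a, b)
        t, p = sps.ttest_rel(a, b)
        assert r["t"] == pytest.approx(t) and r["p"] == pytest.approx(p)
        r1 = one_sample_t(a, mu0=0.5)
        t1, p1 = sps.ttest_1samp(a, 0.5)
        assert r1["t"] == pytest.approx(t1) and r1["p"] == pytest.approx(p1)

    def test_ci_p_duality(self, rng):
        for _ in range(50):
            a = rng.normal(rng.uniform(-1, 1), 1, 12)
            r = one_sample_t(a)
            excludes = r["ci95"][0] > 0 or r["ci95"][1] < 0
            assert excludes == (r["p"] < 0.05)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(2)
        ps = [one_sample_t(rng.normal(0, 1, 10))["p"] for _ in range(1000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_nonzero_mean_raises(self):
        with pytest.raises(DegenerateDataError):
            one_sample_t([2.0, 2.0, 2.0])
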