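import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from oracles import exact_rank_sum_p

from nodphon.stats import (
    LikelihoodRatioResult,
    bootstrap_median_diff,
    compare_groups,
    compare_models,
    fit_function_model,
    fit_logistic_mixed,
    pearson_with_ci,
    remove_outliers,
    z_score,
)
from nodphon.synthetic import simulate_binary_mixed


class TestZScore:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_mean_zero_sd_one(self, seed):
        v = np.random.default_rng(seed).lognormal(size=200)
        z = z_score(v)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            z_score(np.ones(10))


class TestRemoveOutliers:
    def test_fence_arithmetic_on_documented_example(self):
        # 1..10 plus 1000: Q1 = 3.25, Q3 = 8.75, IQR = 5.5, upper fence 36.25
        df = pd.DataFrame({"v": list(range(1, 11)) + [1000]})
        kept, removed, fences = remove_outliers(df, ["v"])
        assert fences["v"] == (pytest.approx(3.25 - 5 * 5.5), pytest.approx(8.75 + 5 * 5.5))
        assert removed["v"].tolist() == [1000]
        assert len(kept) == 10

    def test_degenerate_iqr_removes_nothing_on_ties(self):
        df = pd.DataFrame({"v": [5.0] * 8})
        kept, removed, _ = remove_outliers(df, ["v"])
        assert len(kept) == 8 and removed.empty

    def test_infinite_k_is_identity(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1e9]})
        kept, removed, _ = remove_outliers(df, ["v"], k=np.inf)
        assert len(kept) == 4 and removed.empty

    def test_joint_fences_remove_whole_rows(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6, 7, 8.0],
                           "b": [1, 2, 3, 4, 5, 6, 7, 1e6]})
        kept, removed, _ = remove_outliers(df, ["a", "b"])
        assert removed["a"].tolist() == [8.0]  # extreme on b only, fully dropped

    def test_idempotent_at_fixed_fences(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"v": np.concatenate([rng.normal(size=100), [50.0, -60.0]])})
        once, _, fences = remove_outliers(df, ["v"])
        lo, hi = fences["v"]
        assert ((once["v"] >= lo) & (once["v"] <= hi)).all()


class TestCompareGroups:
    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(a, a.copy())
        assert res.t_statistic == 0.0
        assert res.rank_sum == pytest.approx(len(a) * (2 * len(a) + 1) / 2)

    @pytest.mark.parametrize("a,b", [
        ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
        ([0.3, 2.2, 5.1, 1.7], [4.0, 0.9, 6.6]),
        ([10.0, 12.0, 9.0, 15.0], [11.0, 8.0, 14.0, 13.0]),
    ])
    def test_rank_statistics_match_exact_enumeration(self, a, b):
        res = compare_groups(np.array(a), np.array(b))
        obs, p_exact = exact_rank_sum_p(np.array(a), np.array(b))
        assert res.rank_sum == pytest.approx(obs)
        assert res.u_statistic == pytest.approx(obs - len(a) * (len(a) + 1) / 2)
        assert res.wilcoxon_p == pytest.approx(p_exact, abs=1e-12)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, size=25)
        r1, r2 = compare_groups(a, b), compare_groups(a + 7.3, b + 7.3)
        assert r1.t_statistic == pytest.approx(r2.t_statistic)
        assert r1.rank_sum == pytest.approx(r2.rank_sum)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            compare_groups(np.array([1.0]), np.array([1.0, 2.0]))

    def test_stars_thresholds(self):
        res = compare_groups(np.zeros(2) + [0, 1e-9], np.zeros(2) + [0, 1e-9])
        assert res.t_stars == ""


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, _ = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson_with_ci(x, y)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_independent_large_n_ci_covers_zero(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        r, (lo, hi) = pearson_with_ci(x, y)
        assert abs(r) < 0.1
        assert lo < 0 < hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_ci(np.ones(10), np.arange(10.0))


class TestBootstrap:
    def test_identical_groups_ci_straddles_zero(self):
        a = np.arange(30.0)
        out = bootstrap_median_diff(a, a.copy(), n_boot=500, seed=1)
        assert out["observed"] == 0.0
        lo, hi = out["ci"]
        assert lo <= 0 <= hi

    def test_degenerate_groups(self):
        out = bootstrap_median_diff(np.zeros(3), np.ones(3), n_boot=200, seed=1)
        assert out["observed"] == -1.0
        assert out["ci"] == (-1.0, -1.0)

    def test_bit_identical_for_fixed_seed(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=40), rng.normal(0.5, 1, size=35)
        r1 = bootstrap_median_diff(a, b, n_boot=300, seed=42)
        r2 = bootstrap_median_diff(a, b, n_boot=300, seed=42)
        assert r1 == r2

    def test_missing_seed_rejected_and_small_n_boot_warned(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_median_diff(np.ones(3), np.ones(3), n_boot=200)
        out = bootstrap_median_diff(np.ones(3), np.ones(3), n_boot=50, seed=1)
        assert out["warning"] == "n_boot < 100"


class TestLogisticMixed:
    def test_single_group_matches_plain_logistic_oracle(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        df = pd.DataFrame({"x1": x, "signer": "only", "is_affirmation": y})
        fit = fit_function_model(df, ["x1"])
        assert fit.sigma_u == 0.0
        # independent oracle: IRLS logistic regression, hand-rolled
        X = np.column_stack([np.ones(n), x])
        beta = np.zeros(2)
        for _ in range(25):
            p = 1 / (1 + np.exp(-X @ beta))
            W = p * (1 - p)
            beta += np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - p))
        assert fit.coef["intercept"] == pytest.approx(beta[0], abs=1e-4)
        assert fit.coef["x1"] == pytest.approx(beta[1], abs=1e-4)

    def test_matches_lme4_quadrature_reference(self, tmp_path):
        """Independent cross-check against R lme4 glmer with the same
        adaptive-quadrature order on identical data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = simulate_binary_mixed(20, 25, [0.2, 0.9], 0.7, seed=11)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(is_affirmation ~ x1 + (1|signer), data=d, family=binomial, nAGQ=25)\n"
            "cat(fixef(m)[1], fixef(m)[2],\n"
            "    attr(summary(m)$varcor$signer, 'stddev'), as.numeric(logLik(m)), sep=',')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.strip().split(",")]
        fit = fit_function_model(df, ["x1"])
        assert fit.coef["intercept"] == pytest.approx(ref[0], abs=2e-3)
        assert fit.coef["x1"] == pytest.approx(ref[1], abs=2e-3)
        assert fit.sigma_u == pytest.approx(ref[2], abs=5e-3)
        assert fit.loglik == pytest.approx(ref[3], abs=1e-2)

    def test_slope_recovery_on_simulated_data(self):
        df = simulate_binary_mixed(30, 30, [0.0, 1.0], 0.8, seed=5)
        fit = fit_function_model(df, ["x1"])
        assert fit.converged
        assert fit.coef["x1"] == pytest.approx(1.0, abs=3 * fit.se["x1"])
        assert 0.3 < fit.sigma_u < 1.5

    def test_group_effects_track_group_prevalence(self):
        df = simulate_binary_mixed(12, 60, [0.0], 1.5, seed=3)
        fit = fit_function_model(df, [])
        prevalence = df.groupby("signer")["is_affirmation"].mean()
        blups = pd.Series(fit.group_effects)
        assert np.corrcoef(prevalence[blups.index], blups)[0, 1] > 0.9


class TestCompareModels:
    def test_same_formula_gives_zero(self):
        df = simulate_binary_mixed(10, 20, [0.0, 0.5], 0.5, seed=2)
        f1 = fit_function_model(df, ["x1"])
        f2 = fit_function_model(df, ["x1"])
        res = compare_models(f1, f2)
        assert res == LikelihoodRatioResult(chi2=pytest.approx(0.0, abs=1e-4), df=0, p=1.0)

    def test_chi2_is_twice_loglik_difference(self):
        df = simulate_binary_mixed(10, 30, [0.0, 0.8], 0.5, seed=8)
        small = fit_function_model(df, [])
        large = fit_function_model(df, ["x1"])
        res = compare_models(small, large)
        assert res.chi2 == pytest.approx(2 * (large.loglik - small.loglik))
        assert res.df == 1

    def test_non_nested_rejected(self):
        df = simulate_binary_mixed(10, 20, [0.0, 0.5, 0.2], 0.5, seed=2)
        fa = fit_function_model(df, ["x1"])
        fb = fit_function_model(df, ["x2"])
        with pytest.raises(ValueError, match="nested"):
            compare_models(fa, fb)
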