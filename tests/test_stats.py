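import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from abdovar.stats import (
    CohortTable,
    choose_sensitivity_references,
    exact_logistic_binary,
    mann_whitney_test,
    multivariate_ols,
    run_correlation_analysis,
    run_predictor_analysis,
    spearman_correlation,
)
from abdovar.synthetic import CohortSimConfig, simulate_cohort_truth, truth_to_metric_table
from helpers import (
    exact_logistic_enumeration_oracle,
    mann_whitney_enumeration_oracle,
    spearman_formula,
)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_group_against_itself(self):
        res = mann_whitney_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p_value == 1.0

    def test_shift_invariance(self):
        a, b = [3.0, 7.0, 1.0, 9.0], [2.0, 8.0, 4.0]
        r1 = mann_whitney_test(a, b)
        r2 = mann_whitney_test([v + 100 for v in a], [v + 100 for v in b])
        assert r1.u_statistic == r2.u_statistic and r1.p_value == r2.p_value

    def test_identical_values_warn_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            res = mann_whitney_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
        b = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            a[0] += 1
        res = mann_whitney_test(a, b)
        assert res.p_value == pytest.approx(mann_whitney_enumeration_oracle(a, b))

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(0.5, size=15)
        res = mann_whitney_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "asymptotic"
        assert res.p_value == pytest.approx(ref.pvalue)


class TestSpearman:
    def test_known_rank_difference_example(self):
        res = spearman_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)
        assert res.rho == pytest.approx(spearman_formula([1, 2, 3, 4], [1, 3, 2, 4]))

    def test_monotone_is_one(self):
        assert spearman_correlation([1, 5, 9], [2, 4, 11]).rho == 1.0

    def test_reversal_negates_rho(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        y = [3.0, 1.0, 7.0, 2.0, 9.0]
        assert spearman_correlation(x, y).rho == pytest.approx(
            -spearman_correlation(x, y[::-1].copy() if False else [-v for v in y]).rho
        )

    def test_exact_p_for_perfect_monotone_n4(self):
        # P(|rho| = 1) over all 24 permutations = 2/24
        res = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 24)

    @pytest.mark.parametrize("seed", range(5))
    def test_rho_matches_formula_tie_free(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(8).astype(float)
        y = rng.permutation(8).astype(float)
        assert spearman_correlation(x, y).rho == pytest.approx(spearman_formula(x, y))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_correlation([1, 1, 1], [2, 3, 4])


class TestExactLogistic:
    def test_constant_covariate(self):
        res = exact_logistic_binary([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])
        assert res.coef == 0.0 and res.p_two_sided == 1.0

    def test_complete_separation_boundary(self):
        """Observed T at the maximum of the 20-point conditional support:
        one-sided exact p = 1/20."""
        res = exact_logistic_binary([0, 0, 0, 1, 1, 1], [1, 2, 3, 4, 5, 6])
        assert res.boundary
        assert res.p_one_sided == pytest.approx(0.05)
        assert np.isfinite(res.coef) and res.coef > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_enumerated_p_matches_subset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        y = np.zeros(n, int)
        y[: n // 2] = 1
        rng.shuffle(y)
        x = rng.normal(size=n)
        res = exact_logistic_binary(y, x)
        one, two = exact_logistic_enumeration_oracle(y, x)
        assert res.method == "enumeration"
        assert res.p_one_sided == pytest.approx(one)
        assert res.p_two_sided == pytest.approx(two)

    def test_monte_carlo_close_to_enumeration(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 6)
        x = rng.normal(size=12) + y
        exact = exact_logistic_binary(y, x)
        mc = exact_logistic_binary(y, x, max_enum=10, mc_samples=100_000, seed=1)
        assert mc.method == "monte-carlo"
        se = np.sqrt(exact.p_one_sided * (1 - exact.p_one_sided) / 100_000)
        assert abs(mc.p_one_sided - exact.p_one_sided) <= 3 * se + 1e-12

    def test_conditional_mle_sign_follows_effect(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=14)
        y = (x + 0.3 * rng.normal(size=14) > 0).astype(int)
        res = exact_logistic_binary(y, x)
        assert res.coef > 0


class TestOLS:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(dict(a=rng.normal(size=20), b=rng.normal(size=20)))
        y = 3.0 * X["a"] + 1.0
        fit = multivariate_ols(y, X)
        assert fit.params["a"] == pytest.approx(3.0, abs=1e-9)
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-9)

    def test_collinear_columns_named(self):
        X = pd.DataFrame(dict(a=[1.0, 2, 3, 4, 5, 6], b=[2.0, 4, 6, 8, 10, 12]))
        with pytest.raises(ValueError, match="'a' and 'b'"):
            multivariate_ols([1.0, 2, 3, 4, 5, 6], X)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(dict(a=rng.normal(size=15), b=rng.normal(size=15)))
        y = pd.Series(rng.normal(size=15))
        fit1 = multivariate_ols(y, X)
        perm = rng.permutation(15)
        fit2 = multivariate_ols(y.iloc[perm], X.iloc[perm].reset_index(drop=True))
        assert np.allclose(fit1.params.values, fit2.params.values)


def truth_cohort_table(cfg, seed):
    patients, scans = simulate_cohort_truth(cfg, seed=seed)
    frac, summ = truth_to_metric_table(cfg, patients, scans, seed=seed)
    return CohortTable.from_frames(summ, frac)


class TestCohortAnalyses:
    def test_predictor_grid_shape(self):
        table = truth_cohort_table(CohortSimConfig(), seed=0)
        out = run_predictor_analysis(table)
        assert len(out) == 12  # 4 variables x 3 metrics
        assert set(out["variable"]) == {"sex", "age_group", "ga", "feeding_tube"}

    def test_small_group_reported_not_computable(self):
        table = truth_cohort_table(CohortSimConfig(n_patients=12), seed=1)
        table.patients["ga"] = [True] + [False] * (len(table.patients) - 1)
        out = run_predictor_analysis(table)
        cell = out[(out["variable"] == "ga")].iloc[0]
        assert np.isnan(cell["p_value"]) and "2 patients" in cell["note"]

    def test_ga_effect_detected_at_spec_example_sizes(self):
        """Anaesthesia SD 80 ml vs 15 ml at 20 patients: the GA/Gas_std cell
        is significant in >= 90% of seeds."""
        cfg = CohortSimConfig(
            n_patients=20, gas_sd_ga=80.0, gas_sd_noga=15.0,
            gas_sd_lognorm_sigma=0.0, gas_trend_ml=0.0, gas_trend_sd_ml=0.0,
        )
        hits = trials = 0
        for seed in range(60):
            out = run_predictor_analysis(truth_cohort_table(cfg, seed))
            cell = out[(out["variable"] == "ga") & (out["metric"] == "gas_std_ml")]
            p = cell["p_value"].iloc[0]
            if np.isfinite(p):
                trials += 1
                hits += p < 0.05
        assert hits / trials >= 0.9

    def test_correlation_analysis_null(self):
        cfg = CohortSimConfig.null(n_patients=25)
        rhos = []
        for seed in range(5):
            out = run_correlation_analysis(truth_cohort_table(cfg, seed))
            rhos.append(
                out[out["metric"] == "surface_avg_signed_mm"]["rho"].iloc[0]
            )
        assert abs(np.mean(rhos)) < 0.2

    def test_multivariate_flags_ga_not_age(self):
        """When anaesthesia (not age itself) drives gas variability, the
        multivariate model singles out the GA coefficient."""
        from abdovar.stats import run_multivariate_analysis

        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            table = truth_cohort_table(
                CohortSimConfig(gas_sd_lognorm_sigma=0.0), seed=seed
            )
            out = run_multivariate_analysis(table).set_index("term")
            if out.loc["ga", "p_value"] < 0.05 and out.loc["age_years", "p_value"] > 0.05:
                hits += 1
        assert hits / n_seeds >= 0.6


class TestSensitivity:
    def test_reference_choice_deterministic(self):
        tps = {"A": ["planning", "week_1", "week_2"], "B": ["planning", "week_1", "week_3"]}
        assert choose_sensitivity_references(tps, 5) == choose_sensitivity_references(tps, 5)

    def test_single_cbct_patient_dropped(self):
        tps = {"A": ["planning", "week_1"], "B": ["planning", "week_1", "week_2"]}
        with pytest.warns(UserWarning, match="fewer than 2"):
            refs = choose_sensitivity_references(tps, 0)
        assert "A" not in refs and "B" in refs

    def test_reference_gas_rel_zero_by_construction(self):
        cfg = CohortSimConfig(n_patients=5)
        patients, scans = simulate_cohort_truth(cfg, seed=4)
        refs = choose_sensitivity_references(
            {pid: list(grp["timepoint"]) for pid, grp in scans.groupby("patient_id")},
            seed=1,
        )
        frac, _ = truth_to_metric_table(
            cfg, patients, scans, seed=4, reference=refs, include_planning=False
        )
        assert "planning" not in set(frac["timepoint"])
        for pid, ref_tp in refs.items():
            sub = frac[frac["patient_id"] == pid]
            assert ref_tp not in set(sub["timepoint"])  # reference row omitted
            base = scans[(scans.patient_id == pid) & (scans.timepoint == ref_tp)]["gas_ml"].iloc[0]
            expected = scans[(scans.patient_id == pid) & scans.timepoint.isin(sub.timepoint)]
            assert np.allclose(
                sub.sort_values("timepoint")["gas_rel_ml"].values,
                expected.sort_values("timepoint")["gas_ml"].values - base,
            )
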