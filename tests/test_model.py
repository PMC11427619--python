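import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tempagree as ta
from tempagree.exceptions import (
    ConfigurationError,
    DegenerateDataError,
    UndefinedInputError,
)
from tempagree.model import AgreementModel, AgreementResults

from conftest import pairs_from_differences, simulate_differences

Z95 = stats.norm.ppf(0.975)


def fitted(mu=0.0, sigma_b=0.0, sigma_w=1.0, n_participants=50, n_pairs=200):
    """Hand-assembled results object for arithmetic checks."""
    diffs, pid, time = simulate_differences(
        np.random.default_rng(0), n_participants, n_pairs // n_participants,
        mu, sigma_b, sigma_w,
    )
    model = AgreementModel(diffs, pid, time=time)
    return AgreementResults(
        model=model, bias=mu, bias_se=0.05, sigma_b=sigma_b, sigma_w=sigma_w,
        n_participants=n_participants, n_pairs=len(diffs), method="fixed",
    )


class TestFitVarianceComponents:
    def test_classical_collapse_one_pair_per_participant(self):
        rng = np.random.default_rng(3)
        diffs, pid, time = simulate_differences(rng, 80, 1, -0.4, 0.0, 0.6)
        pairs = pairs_from_differences(diffs, pid, time)
        res = ta.fit_variance_components(pairs)
        assert res.method == "classical"
        assert not res.components_identified
        assert res.bias == pytest.approx(diffs.mean(), abs=1e-12)
        assert res.sigma_total == pytest.approx(diffs.std(ddof=1), abs=1e-12)
        lo, hi, h = ta.limits_of_agreement(res)
        assert lo == pytest.approx(diffs.mean() - Z95 * diffs.std(ddof=1), abs=1e-6)
        assert hi == pytest.approx(diffs.mean() + Z95 * diffs.std(ddof=1), abs=1e-6)

    def test_matches_mixedlm_reml(self):
        """Independent oracle: statsmodels MixedLM REML on the same data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        diffs, pid, time = simulate_differences(rng, 60, 4, -0.5, 0.4, 0.3)
        pairs = pairs_from_differences(diffs, pid, time)
        res = ta.fit_variance_components(pairs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sm.MixedLM(
                pd.Series(diffs), np.ones((len(diffs), 1)), groups=pd.Series(pid)
            ).fit(reml=True)
        assert res.bias == pytest.approx(float(m.fe_params.iloc[0]), abs=1e-5)
        assert res.bias_se == pytest.approx(float(m.bse_fe.iloc[0]), abs=1e-5)
        assert res.sigma_b == pytest.approx(
            float(np.sqrt(m.cov_re.iloc[0, 0])), abs=1e-4
        )
        assert res.sigma_w == pytest.approx(float(np.sqrt(m.scale)), abs=1e-4)

    def test_parameter_recovery_single_dataset(self):
        rng = np.random.default_rng(12)
        diffs, pid, time = simulate_differences(rng, 166, 4, -0.5, 0.4, 0.3)
        res = ta.fit_variance_components(pairs_from_differences(diffs, pid, time))
        assert res.bias == pytest.approx(-0.5, abs=0.1)
        assert res.sigma_b == pytest.approx(0.4, abs=0.1)
        assert res.sigma_w == pytest.approx(0.3, abs=0.1)

    def test_boundary_sigma_b_zero_allowed(self):
        rng = np.random.default_rng(4)
        diffs, pid, time = simulate_differences(rng, 100, 4, 0.0, 0.0, 0.5)
        res = ta.fit_variance_components(pairs_from_differences(diffs, pid, time))
        assert res.sigma_b >= 0.0
        assert res.sigma_total >= res.sigma_w

    def test_identical_differences_degenerate(self):
        diffs = np.full(40, -0.5)
        pid = np.repeat([f"P{i}" for i in range(10)], 4)
        pairs = pairs_from_differences(diffs, pid, np.tile([0, 10, 20, 30], 10))
        with pytest.raises(DegenerateDataError):
            ta.fit_variance_components(pairs)

    def test_single_participant_rejected(self):
        pairs = pairs_from_differences(
            np.array([0.1, -0.2, 0.3, 0.0]), np.repeat("P1", 4),
            np.array([0, 10, 20, 30]),
        )
        with pytest.raises(DegenerateDataError):
            ta.fit_variance_components(pairs)

    def test_time_effect_fit_averages_over_time_points(self):
        rng = np.random.default_rng(8)
        diffs, pid, time = simulate_differences(rng, 80, 4, -0.5, 0.3, 0.3)
        # inject a time trend: +0.4 at the last time point
        diffs = diffs + np.where(time == 30, 0.4, 0.0)
        pairs = pairs_from_differences(diffs, pid, time)
        res = ta.fit_variance_components(pairs, include_time_effect=True)
        assert res.method == "reml+time"
        # average bias over time points: -0.5 + 0.4/4
        assert res.bias == pytest.approx(-0.4, abs=0.1)
        assert set(res.time_effect_means) == {0, 10, 20, 30}


class TestLimitsOfAgreement:
    def test_normal_quantile(self):
        res = fitted(mu=0.0, sigma_b=0.0, sigma_w=1.0)
        lo, hi, h = ta.limits_of_agreement(res, level=0.95)
        assert hi == pytest.approx(1.959964, abs=1e-6)
        assert lo == pytest.approx(-1.959964, abs=1e-6)

    def test_component_arithmetic(self):
        res = fitted(mu=-0.5, sigma_b=0.6, sigma_w=0.8)
        lo, hi, h = ta.limits_of_agreement(res)
        assert res.sigma_total == pytest.approx(1.0)
        assert h == pytest.approx(Z95 * 1.0)
        assert (lo, hi) == (pytest.approx(-0.5 - Z95), pytest.approx(-0.5 + Z95))

    def test_level_monotonicity(self):
        res = fitted(mu=0.2, sigma_b=0.3, sigma_w=0.5)
        assert res.loa_halfwidth(0.50) < res.loa_halfwidth(0.95)

    def test_invalid_level(self):
        with pytest.raises(ConfigurationError):
            fitted().loa(level=1.5)


class TestAgreementProbability:
    def test_quantile_identity(self):
        res = fitted(mu=0.0, sigma_b=0.0, sigma_w=0.5 / Z95)
        assert res.agreement_probability(0.5) == pytest.approx(0.95, abs=1e-12)

    def test_large_bias_limit(self):
        res = fitted(mu=25.0, sigma_b=0.0, sigma_w=0.5)
        assert res.agreement_probability(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_case(self):
        # mu=-0.5, sigma=0.918: Phi(1/0.918) - Phi(0)
        res = fitted(mu=-0.5, sigma_b=0.0, sigma_w=0.918)
        expected = stats.norm.cdf(1.0 / 0.918) - 0.5
        assert res.agreement_probability(0.5) == pytest.approx(expected, abs=1e-12)
        assert res.agreement_probability(0.5) == pytest.approx(0.362, abs=1e-3)

    def test_margin_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            fitted().agreement_probability(0.0)


class TestEmpiricalStatistics:
    def test_within_margin_inclusive_boundary(self):
        pairs = pairs_from_differences(
            np.array([0.2, -0.6, 0.5, 1.1]), np.array(["P1", "P2", "P3", "P4"]),
            np.zeros(4, dtype=int),
        )
        assert ta.empirical_within_margin(pairs, 0.5) == pytest.approx(0.5)

    def test_all_zero_diffs(self):
        pairs = pairs_from_differences(
            np.zeros(4), np.array(["P1", "P2", "P3", "P4"]), np.zeros(4, dtype=int)
        )
        assert ta.empirical_within_margin(pairs, 0.5) == 1.0

    def test_coverage_counting(self):
        pairs = pairs_from_differences(
            np.array([-3.0, 0.0, 3.0]), np.array(["P1", "P2", "P3"]),
            np.zeros(3, dtype=int),
        )
        assert ta.empirical_loa_coverage(pairs, -2.0, 2.0) == pytest.approx(1 / 3)
        assert ta.empirical_loa_coverage(pairs, -4.0, 4.0) == 1.0

    def test_empty_input_rejected(self):
        pairs = pairs_from_differences(
            np.array([]), np.array([], dtype=str), np.array([], dtype=int)
        )
        with pytest.raises(UndefinedInputError):
            ta.empirical_within_margin(pairs)
        with pytest.raises(UndefinedInputError):
            ta.empirical_loa_coverage(pairs, -1.0, 1.0)


class TestEquivariance:
    def test_sign_equivariance_on_swap(self, study_table):
        filtered, _ = ta.apply_plausibility_filter(study_table)
        ab = ta.pair_differences(filtered, "heat_flux", "oral")
        res_ab = ta.fit_variance_components(ab)
        res_ba = ta.fit_variance_components(ab.swapped())
        assert res_ba.bias == pytest.approx(-res_ab.bias, abs=1e-8)
        assert res_ba.sigma_b == pytest.approx(res_ab.sigma_b, abs=1e-6)
        assert res_ba.sigma_w == pytest.approx(res_ab.sigma_w, abs=1e-6)
        lo_ab, hi_ab = res_ab.loa()
        lo_ba, hi_ba = res_ba.loa()
        assert lo_ba == pytest.approx(-hi_ab, abs=1e-6)
        assert hi_ba == pytest.approx(-lo_ab, abs=1e-6)
        assert res_ba.agreement_probability(0.5) == pytest.approx(
            res_ab.agreement_probability(0.5), abs=1e-9
        )

    def test_shift_equivariance(self, study_table):
        filtered, _ = ta.apply_plausibility_filter(study_table)
        pairs = ta.pair_differences(filtered, "heat_flux", "oral")
        shifted = pairs.data.copy()
        c = 0.7
        shifted["value_a"] += c
        shifted["diff"] += c
        shifted["pair_mean"] += c / 2
        res0 = ta.fit_variance_components(pairs)
        res1 = ta.fit_variance_components(
            ta.PairedDifferenceSet("heat_flux", "oral", shifted)
        )
        assert res1.bias == pytest.approx(res0.bias + c, abs=1e-8)
        assert res1.sigma_b == pytest.approx(res0.sigma_b, abs=1e-7)
        assert res1.sigma_w == pytest.approx(res0.sigma_w, abs=1e-7)
        lo0, hi0 = res0.loa()
        lo1, hi1 = res1.loa()
        assert (lo1, hi1) == (pytest.approx(lo0 + c, abs=1e-6),
                              pytest.approx(hi0 + c, abs=1e-6))


class TestBootstrapLoa:
    def test_deterministic_given_seed(self, clean_table):
        pairs = ta.pair_differences(clean_table, "heat_flux", "oral")
        res = ta.fit_variance_components(pairs)
        b1 = res.bootstrap_loa(n_boot=200, seed=31)
        b2 = res.bootstrap_loa(n_boot=200, seed=31)
        assert b1.ci_halfwidth == b2.ci_halfwidth
        assert b1.ci_lower_bound == b2.ci_lower_bound
        assert b1.ci_upper_bound == b2.ci_upper_bound

    def test_seed_changes_interval(self, clean_table):
        pairs = ta.pair_differences(clean_table, "heat_flux", "oral")
        res = ta.fit_variance_components(pairs)
        b1 = res.bootstrap_loa(n_boot=200, seed=31)
        b2 = res.bootstrap_loa(n_boot=200, seed=32)
        assert b1.ci_halfwidth != b2.ci_halfwidth

    def test_ci_brackets_estimate(self, clean_table):
        pairs = ta.pair_differences(clean_table, "heat_flux", "oral")
        res = ta.fit_variance_components(pairs)
        b = res.bootstrap_loa(n_boot=300, seed=5)
        lo, hi = b.ci_halfwidth
        assert lo < res.loa_halfwidth() < hi

    def test_small_nboot_rejected(self, clean_table):
        pairs = ta.pair_differences(clean_table, "heat_flux", "oral")
        res = ta.fit_variance_components(pairs)
        with pytest.raises(ConfigurationError):
            res.bootstrap_loa(n_boot=50, seed=1)


class TestClusterBootstrapCorrelation:
    def test_perfect_correlation_degenerate_ci(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(36.5, 0.5, size=40)
        df = pd.DataFrame({
            "participant_id": np.repeat([f"P{i}" for i in range(10)], 4),
            "time_min": np.tile([0, 10, 20, 30], 10),
            "value_a": vals, "value_b": vals,
        })
        df["pair_mean"] = vals
        df["diff"] = 0.0
        pairs = ta.PairedDifferenceSet("a", "b", df)
        r, lo, hi, meta = ta.cluster_bootstrap_correlation(pairs, n_boot=200, seed=1)
        assert r == pytest.approx(1.0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_independence_gives_null_correlation(self):
        rng = np.random.default_rng(9)
        n_part, n_per = 150, 4
        df = pd.DataFrame({
            "participant_id": np.repeat([f"P{i:03d}" for i in range(n_part)], n_per),
            "time_min": np.tile(np.arange(n_per) * 10, n_part),
            "value_a": rng.normal(36.5, 0.5, n_part * n_per),
            "value_b": rng.normal(36.5, 0.5, n_part * n_per),
        })
        df["pair_mean"] = (df["value_a"] + df["value_b"]) / 2
        df["diff"] = df["value_a"] - df["value_b"]
        pairs = ta.PairedDifferenceSet("a", "b", df)
        r, lo, hi, meta = ta.cluster_bootstrap_correlation(pairs, n_boot=400, seed=3)
        assert abs(r) < 0.1
        assert lo < 0.0 < hi

    def test_deterministic_given_seed(self, clean_table):
        pairs = ta.pair_differences(clean_table, "heat_flux", "oral")
        out1 = ta.cluster_bootstrap_correlation(pairs, n_boot=200, seed=17)
        out2 = ta.cluster_bootstrap_correlation(pairs, n_boot=200, seed=17)
        assert out1[:3] == out2[:3]

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({
            "participant_id": ["P1", "P1", "P2", "P2"],
            "time_min": [0, 10, 0, 10],
            "value_a": [36.5] * 4,
            "value_b": [36.0, 36.2, 36.4, 36.6],
        })
        df["pair_mean"] = (df["value_a"] + df["value_b"]) / 2
        df["diff"] = df["value_a"] - df["value_b"]
        with pytest.raises(DegenerateDataError):
            ta.cluster_bootstrap_correlation(
                ta.PairedDifferenceSet("a", "b", df), n_boot=100, seed=1
            )


class TestPerTimepointAgreement:
    def test_constant_bias_across_time(self, clean_table):
        out = ta.per_timepoint_agreement(clean_table, "heat_flux", "oral")
        assert list(out["time_min"]) == [0, 10, 20, 30]
        assert out["sufficient"].all()
        # constant device bias: per-time biases scatter around the same truth
        spread = out["bias"].max() - out["bias"].min()
        assert spread < 0.5

    def test_insufficient_slice_flagged(self):
        from conftest import make_table
        rows = [("P1", "heat_flux", 0, 36.5), ("P1", "oral", 0, 36.7),
                ("P2", "heat_flux", 0, 36.4), ("P2", "oral", 0, 36.5),
                ("P3", "heat_flux", 0, 36.2), ("P3", "oral", 0, 36.8),
                ("P1", "heat_flux", 30, 36.1), ("P1", "oral", 30, 36.3)]
        out = ta.per_timepoint_agreement(make_table(rows), "heat_flux", "oral")
        by_time = out.set_index("time_min")
        assert bool(by_time.loc[0, "sufficient"])
        assert not bool(by_time.loc[30, "sufficient"])

    def test_single_time_point(self):
        from conftest import make_table
        rows = []
        rng = np.random.default_rng(1)
        for i in range(6):
            rows.append((f"P{i}", "heat_flux", 10, 36.5 + rng.normal(0, 0.3)))
            rows.append((f"P{i}", "oral", 10, 36.8 + rng.normal(0, 0.3)))
        out = ta.per_timepoint_agreement(make_table(rows), "heat_flux", "oral")
        assert len(out) == 1
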