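import numpy as np
import pandas as pd
import pytest

import tmbkit as tk
from tmbkit import landscape as L


def specimen_frame(tmb, disease="mel", **cols):
    n = len(tmb)
    base = {
        "specimen_id": [f"S{i}" for i in range(n)],
        "patient_id": [f"P{i}" for i in range(n)],
        "disease": disease,
        "age": 60.0,
        "sex": "F",
        "median_coverage": 500.0,
        "tmb": tmb,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestFilterCohort:
    def test_boundary_coverage_299_excluded(self):
        df = specimen_frame([1.0, 2.0], median_coverage=[299.0, 300.0])
        eligible, counts = tk.filter_cohort(df)
        assert list(eligible["specimen_id"]) == ["S1"]
        assert counts["low_coverage"] == 1

    def test_duplicate_patient_first_retained(self):
        df = specimen_frame([1.0, 2.0, 3.0])
        df["patient_id"] = ["P0", "P0", "P1"]
        eligible, counts = tk.filter_cohort(df)
        assert list(eligible["specimen_id"]) == ["S0", "S2"]
        assert counts["duplicate_patient"] == 1

    def test_empty_input(self):
        eligible, counts = tk.filter_cohort(specimen_frame([]))
        assert len(eligible) == 0
        assert counts == {"duplicate_patient": 0, "low_coverage": 0}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = specimen_frame(rng.uniform(0, 50, 100),
                            median_coverage=rng.uniform(250, 600, 100))
        df.loc[::7, "patient_id"] = "P0"
        once, _ = tk.filter_cohort(df)
        twice, counts = tk.filter_cohort(once)
        pd.testing.assert_frame_equal(once, twice)
        assert counts == {"duplicate_patient": 0, "low_coverage": 0}


class TestTallyPercent:
    @pytest.mark.parametrize(
        "k,n,decimals,expected",
        [
            (173, 1731, 1, 10.0),
            (39, 203, 0, 19.0),
            (858, 6348, 1, 13.5),
            (191, 92438, 1, 0.2),
            (4, 50, 1, 8.0),
        ],
    )
    def test_printed_count_pairs(self, k, n, decimals, expected):
        assert tk.tally_percent(k, n, decimals) == expected

    def test_half_away_from_zero(self):
        assert tk.tally_percent(1, 8, 0) == 13.0  # 12.5 rounds up
        assert tk.tally_percent(25, 1000, 1) == 2.5

    def test_invalid_rejected(self):
        with pytest.raises(L.LandscapeError):
            tk.tally_percent(5, 4)


class TestBinomialCI:
    def test_k0_lower_bound_zero(self):
        lo, hi = tk.binomial_ci(0, 10)
        assert lo == 0.0 and hi > 0

    def test_4_of_50_wilson_upper(self):
        lo, hi = tk.binomial_ci(4, 50)
        assert hi == pytest.approx(18.8, abs=0.05)
        assert lo == pytest.approx(3.2, abs=0.05)

    def test_full_level_degenerates(self):
        assert tk.binomial_ci(3, 10, level=1.0) == (0.0, 100.0)

    def test_contains_point_estimate(self):
        for k, n in [(0, 5), (3, 7), (7, 7), (50, 1000)]:
            lo, hi = tk.binomial_ci(k, n)
            assert lo <= 100 * k / n <= hi

    def test_k_above_n_rejected(self):
        with pytest.raises(L.LandscapeError):
            tk.binomial_ci(11, 10)

    def test_exact_method_wider_at_boundary(self):
        lo_w, hi_w = tk.binomial_ci(4, 50)
        lo_e, hi_e = tk.binomial_ci(4, 50, method="exact")
        assert hi_e >= hi_w - 1.0  # sanity: same scale
        assert lo_e < lo_w


class TestDiseaseSummary:
    def test_min_n_enforced(self):
        df = pd.concat(
            [specimen_frame(np.full(49, 5.0), disease="small"),
             specimen_frame(np.full(50, 5.0), disease="big")],
            ignore_index=True)
        out = tk.disease_summary(df, min_n=50)
        assert list(out["disease"]) == ["big"]

    def test_pct_high_and_bounds(self):
        tmb = np.r_[np.full(10, 30.0), np.full(40, 1.0)]
        out = tk.disease_summary(specimen_frame(tmb), min_n=50)
        assert out.loc[0, "pct_high"] == pytest.approx(20.0)
        assert out.loc[0, "ci_low"] <= 20.0 <= out.loc[0, "ci_high"]

    def test_zero_and_full_high(self):
        none = tk.disease_summary(specimen_frame(np.full(60, 1.0)), min_n=50)
        assert none.loc[0, "pct_high"] == 0.0 and none.loc[0, "ci_low"] == 0.0
        allh = tk.disease_summary(specimen_frame(np.full(60, 50.0)), min_n=50)
        assert allh.loc[0, "pct_high"] == 100.0
        assert allh.loc[0, "ci_high"] == 100.0

    def test_high_threshold_is_strict(self):
        out = tk.disease_summary(specimen_frame(np.full(60, 20.0)), min_n=50)
        assert out.loc[0, "pct_high"] == 0.0  # exactly 20 is not "high"

    def test_median_quartiles_match_sort_oracle(self):
        rng = np.random.default_rng(3)
        tmb = rng.gamma(2.0, 4.0, 201)
        out = tk.disease_summary(specimen_frame(tmb), min_n=50)
        srt = np.sort(tmb)
        assert out.loc[0, "median_tmb"] == pytest.approx(srt[100])
        assert out.loc[0, "q25"] == pytest.approx(np.percentile(tmb, 25))
        assert out.loc[0, "q75"] == pytest.approx(np.percentile(tmb, 75))

    def test_rounding_roundtrip(self):
        # printed percent strings recompute exactly from stored (k, n)
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(50, 3000))
            k = int(rng.integers(0, n + 1))
            printed = f"{tk.tally_percent(k, n, 1):.1f}"
            again = f"{tk.tally_percent(k, n, 1):.1f}"
            assert printed == again


class TestAgeTrend:
    def test_constructed_noiseless_fold(self):
        age = np.linspace(10, 90, 200)
        slope = np.log10(2.4) / 80
        tmb = 10 ** (0.5 + slope * age)
        df = specimen_frame(tmb)
        df["age"] = age
        trend = tk.age_trend(df, pseudo_count=1e-12)
        assert trend.fold_10_90 == pytest.approx(2.4, abs=1e-9)
        assert trend.fold(10, 90) == pytest.approx(2.4, abs=1e-9)

    def test_stochastic_recovery_n10000(self):
        cfg = tk.CohortConfig(
            n_specimens=10_000,
            disease_mix={"mel": 1.0},
            baseline_log10_tmb={"mel": (0.8, 0.3)},
            driver_prevalence={}, driver_fold_effect={},
            age_fold_per_80y=2.4, msi_high_rate=0.0, seed=42)
        truth = tk.generate_specimens(cfg)
        truth["tmb"] = truth["true_tmb"]
        trend = tk.age_trend(truth, pseudo_count=1e-12)
        assert trend.fold_10_90 == pytest.approx(2.4, abs=0.2)

    def test_zero_slope_fold_one(self):
        df = specimen_frame(np.full(100, 5.0))
        df["age"] = np.linspace(20, 80, 100)
        assert tk.age_trend(df).fold_10_90 == pytest.approx(1.0)

    def test_constant_age_rejected(self):
        df = specimen_frame(np.arange(1.0, 11.0))
        with pytest.raises(L.LandscapeError):
            tk.age_trend(df)


class TestMsiTmbCrosstab:
    def test_all_msih_high(self):
        df = specimen_frame(np.r_[np.full(5, 50.0), np.full(20, 1.0)])
        df["msi_call"] = ["MSI-H"] * 5 + ["MSS"] * 20
        ct = tk.msi_tmb_crosstab(df)
        assert ct.p_high_given_msih == 1.0
        assert ct.p_ge10_given_msih == 1.0

    def test_generator_asymmetry(self):
        # unstable specimens get a 10x TMB bump; high TMB arises without MSI
        cfg = tk.CohortConfig(n_specimens=3000, msi_high_rate=0.1, seed=6)
        truth = tk.generate_specimens(cfg)
        truth["tmb"] = truth["true_tmb"]
        truth["msi_call"] = np.where(truth["msi_truth"] == "unstable",
                                     "MSI-H", "MSS")
        ct = tk.msi_tmb_crosstab(truth)
        assert ct.p_ge10_given_msih > ct.p_msih_given_high

    def test_empty_msih_undefined(self):
        df = specimen_frame(np.full(10, 30.0))
        df["msi_call"] = "MSS"
        ct = tk.msi_tmb_crosstab(df)
        assert not ct.defined
        assert np.isnan(ct.p_high_given_msih)


class TestExplainedFraction:
    def test_worked_fraction_858_of_6348(self):
        n = 6348
        df = specimen_frame(np.full(n, 25.0))
        df["driver"] = [True] * 858 + [False] * (n - 858)
        ef = tk.explained_fraction(df, ["driver"])
        assert ef.k == 858 and ef.n == n
        assert ef.percent == 13.5

    def test_no_carriers(self):
        df = specimen_frame(np.full(30, 25.0))
        df["driver"] = False
        assert tk.explained_fraction(df, ["driver"]).percent == 0.0

    def test_all_carriers(self):
        df = specimen_frame(np.full(30, 25.0))
        df["driver"] = True
        assert tk.explained_fraction(df, ["driver"]).percent == 100.0

    def test_no_high_tmb_undefined(self):
        df = specimen_frame(np.full(30, 1.0))
        df["driver"] = True
        ef = tk.explained_fraction(df, ["driver"])
        assert not ef.defined

    def test_missing_column_rejected(self):
        df = specimen_frame(np.full(5, 25.0))
        with pytest.raises(L.LandscapeError):
            tk.explained_fraction(df, ["nope"])
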