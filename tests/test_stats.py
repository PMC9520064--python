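"""Study statistics: standardization, LMM dose-response, ICC, bootstrap,
Bland-Altman, feasibility accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import pleurastrain as ps
from pleurastrain.stats import (
    BONFERRONI_ALPHA,
    DoseResponseModel,
    ReliabilityModel,
    average_triplicates,
    bland_altman,
    bootstrap_bca,
    feasibility_ledger,
    icc_2_1,
    icc_band,
    proportion_ci_halfwidth,
    screen_parameters,
    sensitivity_subset,
    standardize,
)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 5.0, 9.0]})
        out, scales = standardize(t, ["x"])
        assert abs(out["x"].mean()) < 1e-12
        assert np.std(out["x"]) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip(self):
        t = pd.DataFrame({"x": [3.0, -1.0, 7.5]})
        out, scales = standardize(t, ["x"])
        np.testing.assert_allclose(scales["x"].inverse(out["x"]), t["x"], atol=1e-12)

    def test_constant_column_rejected_by_name(self):
        t = pd.DataFrame({"flat": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(t, ["flat"])


@pytest.fixture(scope="module")
def table():
    return ps.simulate_study(ps.SyntheticStudyDesign(n_patients=4, seed=2))


class TestAverageTriplicates:
    def test_replicates_averaged(self, table):
        out = average_triplicates(table)
        cell = table[(table["patient_id"] == "P01")
                     & (table["location"] == "R3-MCL")
                     & (table["tidal_volume_ml_kg"] == 6.0)
                     & (table["session"] == "primary")]
        row = out[(out["patient_id"] == "P01") & (out["location"] == "R3-MCL")
                  & (out["tidal_volume_ml_kg"] == 6.0)]
        assert row["response"].iloc[0] == pytest.approx(cell["response"].mean())

    def test_reliability_sessions_excluded(self, table):
        out = average_triplicates(table)
        # 4 patients x 4 locations x 4 TVs = 64 modeled cells
        assert len(out) == 64

    def test_single_replicate_passthrough(self):
        t = pd.DataFrame({
            "patient_id": ["P01"], "location": ["R3-MCL"], "side": ["right"],
            "dependence": ["nondependent"], "tidal_volume_ml_kg": [8.0],
            "observer": [1], "session": ["primary"], "replicate": [1],
            "response": [1.23], "quality_flag": ["high"],
        })
        out = average_triplicates(t)
        assert len(out) == 1 and out["response"].iloc[0] == 1.23

    def test_row_count_equals_distinct_cells(self, table):
        prim = table[table["session"] == "primary"]
        n_cells = prim.groupby(["patient_id", "location", "tidal_volume_ml_kg"]).ngroups
        assert len(average_triplicates(table)) == n_cells


class TestDoseResponse:
    def test_recovers_true_slope_within_ci(self):
        design = ps.SyntheticStudyDesign(n_patients=10, seed=42)
        res = DoseResponseModel.from_study_table(ps.simulate_study(design)).fit()
        lo, hi = res.ci_nondependent_raw
        assert lo <= design.true_slope_nondependent <= hi
        lo_d, hi_d = res.ci_dependent_raw
        assert lo_d <= design.true_slope_dependent <= hi_d
        assert res.converged

    def test_degenerate_limit_matches_ols(self):
        # no random-effect variance: the mixed model collapses to OLS
        import statsmodels.formula.api as smf

        design = ps.SyntheticStudyDesign(
            n_patients=25, sd_patient=0.0, sd_location=0.0, sd_residual=0.4, seed=7)
        model = DoseResponseModel.from_study_table(ps.simulate_study(design))
        res = model.fit()
        ols = smf.ols("y ~ tv_std + C(side) + C(dependence) + tv_std:C(dependence)",
                      data=model.data).fit()
        assert res.slope_nondependent == pytest.approx(ols.params["tv_std"], abs=0.02)
        assert res.left_effect == pytest.approx(ols.params["C(side)[T.left]"], abs=0.02)
        # estimated random-effect variances collapse toward zero
        assert res.var_patient + res.var_location < 0.15 * res.var_residual

    def test_r2_matches_hand_computed_formula(self):
        design = ps.SyntheticStudyDesign(n_patients=8, seed=3)
        model = DoseResponseModel.from_study_table(ps.simulate_study(design))
        res = model.fit()
        # recompute from scratch: fixed-effect design matrix built by hand
        d = model.data
        X = np.column_stack([
            np.ones(len(d)),
            (d["side"] == "left").to_numpy(float),
            (d["dependence"] == "dependent").to_numpy(float),
            d["tv_std"].to_numpy(),
            d["tv_std"].to_numpy() * (d["dependence"] == "dependent").to_numpy(float),
        ])
        beta = np.array([
            res.fixed_effects["Intercept"],
            res.fixed_effects["C(side)[T.left]"],
            res.fixed_effects["C(dependence)[T.dependent]"],
            res.fixed_effects["tv_std"],
            res.fixed_effects["tv_std:C(dependence)[T.dependent]"],
        ])
        var_f = np.var(X @ beta)
        total = var_f + res.var_patient + res.var_location + res.var_residual
        assert res.r2_marginal == pytest.approx(var_f / total, rel=1e-9)
        assert res.r2_conditional == pytest.approx(
            (var_f + res.var_patient + res.var_location) / total, rel=1e-9)
        assert 0 <= res.r2_marginal <= res.r2_conditional <= 1

    def test_zero_fixed_effects_give_small_marginal_r2(self):
        design = ps.SyntheticStudyDesign(
            n_patients=12, true_slope_nondependent=0.0, true_slope_dependent=0.0,
            left_offset=0.0, dependent_offset=0.0, seed=21)
        res = DoseResponseModel.from_study_table(ps.simulate_study(design)).fit()
        assert res.r2_marginal < 0.06

    def test_summary_is_one_row_per_parameter(self):
        res = DoseResponseModel.from_study_table(
            ps.simulate_study(ps.SyntheticStudyDesign(n_patients=5, seed=1))).fit()
        s = res.summary()
        assert len(s) == 1 and "r2_marginal" in s.columns

    def test_requires_two_tv_levels(self):
        t = ps.simulate_study(ps.SyntheticStudyDesign(n_patients=3, seed=0))
        t = t[t["tidal_volume_ml_kg"] == 6.0]
        with pytest.raises(ValueError):
            DoseResponseModel(t)

    def test_standardization_invariance_of_slopes(self):
        # affine rescaling of the raw response leaves standardized slopes unchanged
        table = ps.simulate_study(ps.SyntheticStudyDesign(n_patients=6, seed=13))
        res1 = DoseResponseModel.from_study_table(table).fit()
        rescaled = table.copy()
        rescaled["response"] = 3.7 * rescaled["response"] + 11.0
        res2 = DoseResponseModel.from_study_table(rescaled).fit()
        assert res1.slope_nondependent == pytest.approx(res2.slope_nondependent, rel=1e-6)


class TestScreen:
    def _fake(self, slope, p, width=0.1):
        from types import SimpleNamespace

        return SimpleNamespace(slope_nondependent=slope, p_value_tv=p,
                               ci_nondependent=(slope - width, slope + width))

    def test_bonferroni_threshold_value(self):
        assert BONFERRONI_ALPHA == pytest.approx(0.05 / 6)
        assert round(BONFERRONI_ALPHA, 3) == 0.008

    def test_no_significant_parameters(self):
        fits = {f"p{i}": self._fake(0.5, 0.5) for i in range(6)}
        report = screen_parameters(fits)
        assert not report["significant"].any()

    def test_ordering_by_absolute_slope(self):
        fits = {
            "a": self._fake(0.2, 1e-5), "b": self._fake(-0.6, 1e-5),
            "c": self._fake(0.4, 0.5),
        }
        report = screen_parameters(fits)
        sig = report[report["significant"]]
        assert list(sig["parameter"]) == ["b", "a"]  # |slope| descending
        assert report.iloc[0]["parameter"] == "b"

    def test_ci_overlap_with_top(self):
        fits = {"top": self._fake(0.9, 1e-6, width=0.05),
                "near": self._fake(0.85, 1e-6, width=0.05),
                "far": self._fake(0.2, 1e-6, width=0.05)}
        report = screen_parameters(fits).set_index("parameter")
        assert report.loc["near", "ci_overlaps_top"]
        assert not report.loc["far", "ci_overlaps_top"]


class TestICC:
    def test_identical_raters_give_one(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 3))
        icc, _ = icc_2_1(m)
        assert icc == pytest.approx(1.0)

    def test_independent_raters_give_near_zero(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (4000, 3))
        icc, _ = icc_2_1(m)
        assert abs(icc) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(4, 13), rng.integers(2, 5)
        m = rng.normal(0, 1, (n, k)) + rng.normal(0, 1.5, (n, 1))
        icc, _ = icc_2_1(m)
        # explicit two-way ANOVA decomposition
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((m - m.mean(1, keepdims=True) - m.mean(0) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        m = rng.normal(0, 1, (12, 3)) + rng.normal(0, 2, (12, 1))
        icc, ci = icc_2_1(m)
        long = pd.DataFrame({"s": np.repeat(range(12), 3),
                             "r": list(range(3)) * 12, "y": m.ravel()})
        ref = pg.intraclass_corr(long, targets="s", raters="r", ratings="y")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        np.testing.assert_allclose(ci, row["CI95"], atol=5e-3)

    def test_incomplete_matrix_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_2_1(m)

    def test_band_breakpoints(self):
        assert icc_band(0.49) == "poor"
        assert icc_band(0.5) == "moderate"
        assert icc_band(0.7499) == "moderate"
        assert icc_band(0.75) == "good"
        assert icc_band(0.8999) == "good"
        assert icc_band(0.9) == "excellent"


class TestBootstrap:
    def test_deterministic_under_seed(self):
        data = np.arange(1.0, 101.0)
        a = bootstrap_bca(np.mean, data, n_boot=500, seed=4)
        b = bootstrap_bca(np.mean, data, n_boot=500, seed=4)
        assert a == b

    def test_containment(self):
        data = np.arange(1.0, 101.0)
        lo, hi = bootstrap_bca(np.mean, data, n_boot=2000, seed=1)
        assert data.min() <= lo <= data.mean() <= hi <= data.max()

    def test_close_to_scipy_bca(self):
        rng = np.random.default_rng(7)
        data = rng.normal(10, 2, 40)
        lo, hi = bootstrap_bca(lambda d: float(np.mean(d)), data, n_boot=4000, seed=5)
        ref = sps.bootstrap((data,), np.mean, n_resamples=4000, method="BCa",
                            random_state=5)
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.1)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.1)

    def test_degenerate_distribution_collapses(self):
        data = np.full(10, 3.0)
        lo, hi = bootstrap_bca(np.mean, data, n_boot=200, seed=0)
        assert lo == hi == 3.0


class TestBlandAltman:
    def test_identical_pairs(self):
        p = np.column_stack([np.arange(5.0), np.arange(5.0)])
        out = bland_altman(p)
        assert out["bias"] == 0 and out["loa_low"] == 0 and out["loa_high"] == 0

    def test_constant_offset(self):
        x = np.arange(6.0)
        out = bland_altman(np.column_stack([x + 2.0, x]))
        assert out["bias"] == pytest.approx(2.0) and out["sd_diff"] == 0

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(2)
        p = rng.normal(0, 1, (30, 2))
        out = bland_altman(p)
        d = p[:, 0] - p[:, 1]
        assert out["bias"] == pytest.approx(d.mean())
        assert out["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones((2, 2)))


class TestReliabilityModel:
    def test_high_repeatability_gives_high_icc(self):
        design = ps.SyntheticStudyDesign(n_patients=10, sd_residual=0.05,
                                         sd_patient=1.0, sd_location=0.6, seed=6)
        table = ps.simulate_study(design)
        res = ReliabilityModel(table).fit(n_boot=300, seed=1)
        s = res.summary().set_index("session")
        for kind in ("intraobserver", "interobserver", "test-retest"):
            assert s.loc[kind, "icc"] > 0.9
            assert s.loc[kind, "band"] == "excellent"
        # Bland-Altman only for the two-session comparisons
        assert "bland_altman" not in res.sessions["intraobserver"]
        assert np.isfinite(s.loc["interobserver", "ba_bias"])

    def test_bootstrap_ci_overlaps_analytic(self):
        design = ps.SyntheticStudyDesign(n_patients=10, seed=8)
        res = ReliabilityModel(ps.simulate_study(design)).fit(n_boot=400, seed=2)
        e = res.sessions["interobserver"]
        assert e["bca_low"] < e["icc"] < e["bca_high"]


class TestSensitivitySubset:
    def test_filters_by_flag(self):
        t = ps.simulate_study(ps.SyntheticStudyDesign(n_patients=3, seed=4))
        sub = sensitivity_subset(t)
        assert (sub["quality_flag"] == "high").all()
        assert len(sub) == (t["quality_flag"] == "high").sum()

    def test_all_high_is_identity(self):
        t = ps.simulate_study(
            ps.SyntheticStudyDesign(n_patients=2, high_quality_fraction=1.0, seed=4))
        assert len(sensitivity_subset(t)) == len(t)

    def test_empty_subset_warns(self):
        t = ps.simulate_study(
            ps.SyntheticStudyDesign(n_patients=2, high_quality_fraction=0.0, seed=4))
        with pytest.warns(UserWarning, match="empty"):
            sub = sensitivity_subset(t)
        assert sub.empty


class TestFeasibility:
    def test_no_exclusions_is_hundred_percent(self):
        ledger = feasibility_ledger(100, [])
        assert ledger.computed == 100 and ledger.feasibility_pct == 100.0

    def test_negative_remainder_rejected(self):
        with pytest.raises(ValueError):
            feasibility_ledger(10, [("a", 7), ("b", 5)])

    def test_summary_tracks_remaining(self):
        ledger = feasibility_ledger(20, [("x", 5), ("y", 5)])
        s = ledger.summary()
        assert list(s["remaining"]) == [20, 15, 10]
        assert ledger.feasibility_pct == 50.0


class TestProportionCI:
    def test_half_is_widest(self):
        widths = [proportion_ci_halfwidth(p, 500) for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert max(widths) == widths[2]

    def test_sqrt_n_scaling(self):
        w1 = proportion_ci_halfwidth(0.3, 100)
        w4 = proportion_ci_halfwidth(0.3, 400)
        assert w1 == pytest.approx(2 * w4)

    def test_degenerate_p_returns_zero(self):
        assert proportion_ci_halfwidth(1.0, 50) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(p=st.floats(0.01, 0.99), n=st.integers(2, 10_000))
    def test_matches_closed_form(self, p, n):
        expected = 100 * 1.959963984540054 * np.sqrt(p * (1 - p) / n)
        assert proportion_ci_halfwidth(p, n) == pytest.approx(expected, rel=1e-9)
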