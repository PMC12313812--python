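import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from crowlaw.menzerath import (
    MenzerathParams,
    UnderdeterminedError,
    compare_models,
    fit_complex,
    fit_menzerath_nonlinear,
    fit_simple,
    likelihood_ratio_test,
    predict_curves,
)
from crowlaw.synthetic import GeneratorConfig, generate_dataset, model_frame


class TestNonlinearLaw:
    def test_pure_power_law_recovered_exactly(self):
        x = np.arange(2, 11, dtype=float)
        y = 1.0 * x**-0.5
        params = fit_menzerath_nonlinear(x, y)
        assert params.a == pytest.approx(1.0, abs=1e-10)
        assert params.b == pytest.approx(-0.5, abs=1e-10)
        assert params.c == pytest.approx(0.0, abs=1e-10)

    def test_full_law_round_trip(self):
        x = np.arange(2, 15, dtype=float)
        truth = MenzerathParams(a=2.0, b=-0.3, c=-0.05)
        params = fit_menzerath_nonlinear(x, truth.curve(x))
        assert params.a == pytest.approx(2.0, abs=1e-6)
        assert params.b == pytest.approx(-0.3, abs=1e-6)
        assert params.c == pytest.approx(-0.05, abs=1e-6)

    def test_constant_durations_give_flat_law(self):
        x = np.arange(2, 8, dtype=float)
        params = fit_menzerath_nonlinear(x, np.full_like(x, 0.7))
        assert params.b == pytest.approx(0.0, abs=1e-10)
        assert params.c == pytest.approx(0.0, abs=1e-10)
        assert params.a == pytest.approx(0.7)

    def test_too_few_distinct_lengths_refused(self):
        with pytest.raises(UnderdeterminedError):
            fit_menzerath_nonlinear([2, 2, 3, 3], [0.5, 0.5, 0.4, 0.4])

    def test_c_fixed_matches_log_scale_ols(self, rng):
        """Dropping the exponential term reduces the law to log-log OLS."""
        x = rng.integers(2, 12, size=200).astype(float)
        y = 0.4 * x**-0.45 * np.exp(rng.normal(0, 0.2, size=200))
        params = fit_menzerath_nonlinear(x, y, fix_c=True)
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        assert params.b == pytest.approx(slope, abs=1e-8)
        assert np.log(params.a) == pytest.approx(intercept, abs=1e-8)


class TestSimpleModel:
    def test_zero_variance_limit_equals_ols(self, small_frame):
        """With random effects pinned at zero the fit is exactly OLS."""
        fit = fit_simple(small_frame, force_zero_variances=True)
        lnx = np.log(small_frame["length"].astype(float))
        lny = np.log(small_frame["duration_s"])
        slope, intercept = np.polyfit(lnx, lny, 1)
        assert fit.estimates["Length"][0] == pytest.approx(slope, abs=1e-8)
        assert fit.estimates["Intercept"][0] == pytest.approx(intercept, abs=1e-8)

    def test_matches_mixedlm_reference(self):
        """Profiled-ML fitter agrees with statsmodels MixedLM.

        Uses a dataset with clearly positive variance components so both
        optimisers sit in the interior of the parameter space.
        """
        import statsmodels.formula.api as smf

        config = GeneratorConfig(
            seed=103, sequences_per_individual=30, sd_individual=0.3, sd_sequence=0.15
        )
        frame = model_frame(generate_dataset(config), segmented=False)
        fit = fit_simple(frame)
        df = frame.copy()
        df["lny"] = np.log(df["duration_s"])
        df["lnx"] = np.log(df["length"].astype(float))
        model = smf.mixedlm(
            "lny ~ lnx", df, groups="individual", re_formula="1",
            vc_formula={"seq": "0 + C(sequence_id)"},
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reference = model.fit(reml=False)
        assert fit.estimates["Length"][0] == pytest.approx(
            reference.fe_params["lnx"], abs=1e-5
        )
        assert fit.estimates["Length"][1] == pytest.approx(
            reference.bse_fe["lnx"], rel=1e-3
        )
        assert fit.loglik == pytest.approx(reference.llf, abs=1e-3)
        # the profiled fitter never finds a worse optimum
        assert fit.loglik >= reference.llf - 1e-6

    def test_no_signal_slope_interval_covers_zero(self):
        config = GeneratorConfig(
            seed=5, law=MenzerathParams(a=0.3, b=0.0), sequences_per_individual=30
        )
        frame = model_frame(generate_dataset(config), segmented=False)
        fit = fit_simple(frame)
        point, se, lo, hi = fit.estimates["Length"]
        assert lo <= 0.0 <= hi

    def test_single_individual_warns(self, small_frame):
        one = small_frame[small_frame["individual"] == small_frame["individual"].iloc[0]]
        with pytest.warns(UserWarning, match="one individual"):
            fit_simple(one)

    def test_singletons_must_be_excluded_first(self, small_frame):
        bad = small_frame.copy()
        bad.loc[bad.index[0], "length"] = 1
        with pytest.raises(ValueError, match="single-call"):
            fit_simple(bad)

    def test_wald_interval_arithmetic(self, small_frame):
        fit = fit_simple(small_frame)
        for point, se, lo, hi in fit.estimates.values():
            assert hi - lo == pytest.approx(2 * 1.959963984540054 * se, rel=1e-12)


@pytest.fixture(scope="module")
def complex_setup():
    config = GeneratorConfig(
        seed=21,
        sequences_per_individual=25,
        covariate_effects={"sex": 0.4, "length:sex": 0.3, "length:age": 0.08},
        sd_individual_slope=0.1,
    )
    frame = model_frame(generate_dataset(config), segmented=False)
    fits = {form: fit_complex(frame, form=form) for form in ("eq4", "eq5", "eq6")}
    return config, frame, fits


class TestComplexModels:
    def test_loglik_respects_nesting(self, complex_setup):
        _, _, fits = complex_setup
        assert fits["eq4"].loglik <= fits["eq5"].loglik <= fits["eq6"].loglik

    def test_interaction_model_recovers_sex_modulation(self, complex_setup):
        config, _, fits = complex_setup
        for form in ("eq5", "eq6"):
            point, se, lo, hi = fits[form].estimates["Length: Sex (M vs. F)"]
            assert lo <= 0.3 <= hi
        assert "Length: Sex (M vs. F)" not in fits["eq4"].estimates

    def test_zero_variance_covariate_dropped_with_notice(self, complex_setup):
        _, frame, _ = complex_setup
        same_sex = frame.copy()
        same_sex["sex"] = "F"
        with pytest.warns(UserWarning, match="sex"):
            fit = fit_complex(same_sex, form="eq4")
        assert "Sex (M vs. F)" not in fit.estimates

    def test_matches_lme4_reference(self, complex_setup, tmp_path):
        """The richest model agrees with lme4 on estimates, SEs and loglik."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        config, frame, fits = complex_setup
        small_cfg = GeneratorConfig(
            seed=11, sequences_per_individual=10, groups_per_population=2,
            individuals_per_group=3,
            covariate_effects={"sex": 0.4, "length:sex": 0.3},
            sd_individual_slope=0.15,
        )
        small = model_frame(generate_dataset(small_cfg), segmented=False)
        fit = fit_complex(small, form="eq6")
        df = small.copy()
        df["lny"] = np.log(df["duration_s"])
        df["lnlen"] = np.log(df["length"].astype(float))
        df["sex_m"] = (df["sex"] == "M").astype(float)
        for col in ("group_size", "age", "elo", "csi"):
            df[col] = (df[col] - df[col].mean()) / df[col].std(ddof=0)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent(f"""
            library(lme4)
            d <- read.csv("{csv}")
            m <- lmer(lny ~ lnlen*(sex_m+group_size+age+elo+csi) +
              (1|population/group/individual/sequence_id) +
              (0 + lnlen | individual), data=d, REML=FALSE,
              control=lmerControl(optimizer="bobyqa"))
            cat(as.numeric(logLik(m)), fixef(m)["lnlen"],
                sqrt(diag(vcov(m)))[2], sep="\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        llf, slope, se = map(float, out.stdout.strip().split("\n")[-3:])
        assert fit.loglik == pytest.approx(llf, abs=1e-3)
        assert fit.estimates["Length"][0] == pytest.approx(slope, abs=1e-4)
        assert fit.estimates["Length"][1] == pytest.approx(se, rel=1e-3)


class TestModelComparison:
    def test_lowest_aic_flagged_best(self, complex_setup):
        _, _, fits = complex_setup
        table = compare_models(list(fits.values()))
        assert table.loc[table["best"], "model"].tolist() == [
            table.loc[table["AIC"].idxmin(), "model"]
        ]

    def test_identical_fits_have_no_winner(self, complex_setup):
        _, _, fits = complex_setup
        table = compare_models([fits["eq4"], fits["eq4"]])
        assert (table["dAIC"] == 0).all()
        assert not table["best"].any()

    def test_lrt_statistic_nonnegative_and_consistent(self, complex_setup):
        _, _, fits = complex_setup
        stat, df, p = likelihood_ratio_test(fits["eq4"], fits["eq5"])
        assert stat >= 0
        assert df == fits["eq5"].n_params - fits["eq4"].n_params
        assert 0 <= p <= 1

    def test_lrt_refused_for_non_nested_pair(self, complex_setup):
        _, _, fits = complex_setup
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(fits["eq5"], fits["eq4"])

    def test_comparison_requires_identical_rows(self, complex_setup, small_frame):
        _, _, fits = complex_setup
        other = fit_simple(small_frame)
        with pytest.raises(ValueError, match="identical data"):
            compare_models([fits["eq4"], other])


class TestPrediction:
    def test_male_effective_slope_adds_interaction(self, complex_setup):
        _, _, fits = complex_setup
        fit = fits["eq6"]
        female = predict_curves(fit, {"sex": "F"})
        male = predict_curves(fit, {"sex": "M"})
        expected = (
            fit.estimates["Length"][0] + fit.estimates["Length: Sex (M vs. F)"][0]
        )
        assert male["effective_slope"].iloc[0] == pytest.approx(expected)
        assert female["effective_slope"].iloc[0] == pytest.approx(
            fit.estimates["Length"][0]
        )

    def test_reference_profile_is_pure_power_curve(self, complex_setup):
        _, _, fits = complex_setup
        fit = fits["eq6"]
        curve = predict_curves(fit, {})
        intercept = fit.estimates["Intercept"][0]
        slope = fit.estimates["Length"][0]
        expected = np.exp(intercept + slope * np.log(curve["length"].astype(float)))
        assert np.allclose(curve["predicted_duration"], expected)

    def test_monotone_decreasing_when_slope_negative(self, complex_setup):
        _, _, fits = complex_setup
        curve = predict_curves(fits["eq6"], {"sex": "F"})
        if curve["effective_slope"].iloc[0] < 0:
            assert curve["predicted_duration"].is_monotonic_decreasing

    def test_out_of_range_profile_warns(self, complex_setup):
        _, _, fits = complex_setup
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_curves(fits["eq6"], {"age": 1e6})
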