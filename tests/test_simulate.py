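"""Synthetic-cohort generator: calibration, exact margins, moment recovery,
covariate injection, reproducibility and file round trips."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from safref.cohort import (Cohort, CohortParseError, CohortSchemaError,
                           read_cohort, write_cohort)
from safref.reference import ReferenceTable, StratumStats
from safref.simulate import (CalibrationError, MarginalSummaries,
                             calibrate_generator, default_generator_config,
                             default_margins, generate_cohort)

from conftest import make_cohort


class TestCalibration:
    def test_mirrors_reference_verbatim(self, reference_grid):
        cfg = calibrate_generator(reference_grid, default_margins())
        assert len(cfg.stratum_params) == 14
        assert sum(p[3] for p in cfg.stratum_params) == 1997
        for s, (g, lo, hi, n, m, sd) in zip(reference_grid.strata, cfg.stratum_params):
            assert (g, lo, hi, n, m, sd) == (s.gender, s.age_low, s.age_high,
                                             s.n, s.mean_saf, s.sd_saf)

    def test_single_stratum_passthrough(self):
        ref = ReferenceTable([StratumStats("M", 20, 29, 10, 2.0, 0.4)])
        cfg = calibrate_generator(ref)
        assert cfg.stratum_params[0][3:] == (10, 2.0, 0.4)

    def test_zero_sd_rejected(self):
        ref = ReferenceTable([StratumStats("M", 20, 29, 10, 2.0, 0.0)])
        with pytest.raises(ValueError, match="SD"):
            calibrate_generator(ref)

    def test_empty_reference_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_generator(ReferenceTable([]))

    def test_female_total_reconciliation(self, reference_grid):
        cfg = calibrate_generator(reference_grid, reconcile_female_total=877)
        assert cfg.gender_total("F") == 877
        assert cfg.gender_total("M") == 1122
        f3039 = [p for p in cfg.stratum_params if p[0] == "F" and p[1] == 30][0]
        assert f3039[3] == 286  # the two unreconciled women land here

    def test_invalid_correlation_matrix_rejected(self, reference_grid):
        margins = default_margins()
        bad = margins.anthropometric_corr.copy()
        bad[0, 1] = 0.99
        with pytest.raises(ValueError, match="symmetric"):
            calibrate_generator(reference_grid, MarginalSummaries(anthropometric_corr=bad))


class TestExactMargins:
    """Categorical structure is assigned, not sampled: exact for every seed."""

    @pytest.mark.parametrize("seed", [1, 7])
    def test_counts_exact(self, default_config, seed):
        df = generate_cohort(default_config, seed=seed).df
        men, women = df[df.gender == "M"], df[df.gender == "F"]
        assert (len(men), len(women)) == (1122, 877)
        assert men.diabetes.sum() == 163 and women.diabetes.sum() == 121
        assert men.smoking.sum() == 328 and women.smoking.sum() == 64
        assert men.exercise.value_counts().to_dict() == {
            "none": 530, "1-2/month": 142, "1-2/week": 207, "3+/week": 243}
        assert (women.nationality == "Saudi").sum() == 503

    def test_stratum_counts_exact(self, default_config, cohort):
        df = cohort.df
        for g, lo, hi, n, _, _ in default_config.stratum_params:
            sub = df[(df.gender == g) & (df.age >= lo) & (df.age <= hi)]
            assert len(sub) == n


class TestMomentRecovery:
    def test_saf_means_and_sds_per_stratum(self, default_config, cohort):
        df = cohort.df
        for g, lo, hi, n, mean, sd in default_config.stratum_params:
            saf = df.loc[(df.gender == g) & (df.age >= lo) & (df.age <= hi), "saf"]
            if n >= 100:
                assert abs(saf.mean() - mean) < 3 * sd / np.sqrt(n)
                assert abs(saf.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * n)

    def test_sr_marginal(self, cohort):
        sr = cohort.df.sr
        n = len(sr)
        assert abs(sr.mean() - 9.5) < 3 * 3.0 / np.sqrt(n)
        assert abs(sr.std(ddof=1) - 3.0) < 0.25
        assert sr.min() >= 6.0

    def test_anthropometric_correlations(self, cohort):
        for sub in (cohort.men, cohort.women):
            for a, b in [("weight", "bmi"), ("weight", "waist"),
                         ("weight", "hip"), ("bmi", "waist"), ("bmi", "hip"),
                         ("waist", "hip")]:
                assert np.corrcoef(sub[a], sub[b])[0, 1] > 0.8
            assert np.corrcoef(sub.sbp, sub.dbp)[0, 1] > 0.57

    def test_subject_invariants(self, cohort):
        df = cohort.df
        assert (df.age >= 18).all() and (df.age <= 80).all()
        assert (df.saf > 0).all()
        np.testing.assert_allclose(df.bmi, df.weight / df.height**2, rtol=5e-3)
        np.testing.assert_allclose(df.whr, df.waist / df.hip, rtol=5e-3)

    def test_lognormal_option_keeps_stratum_mean(self):
        cfg = default_generator_config(saf_distribution="lognormal")
        df = generate_cohort(cfg, seed=3).df
        m = df[(df.gender == "M") & (df.age.between(30, 39))]
        assert abs(m.saf.mean() - 1.75) < 3 * 0.42 / np.sqrt(len(m))
        assert m.saf.skew() > 0  # right-skewed marginal


class TestCovariateInjection:
    """A within-stratum regression recovers each injected coefficient."""

    def test_bmi_slope_in_men(self, default_config, cohort):
        sub = cohort.df.query("gender == 'M' and 30 <= age <= 39")
        X = sm.add_constant(sub[["bmi", "diabetes"]].astype(float))
        fit = sm.OLS(sub.saf, X).fit()
        target = default_config.covariate_effects["bmi_coeff_M"]
        assert abs(fit.params["bmi"] - target) < 3 * fit.bse["bmi"]

    def test_sr_slope_in_women(self, default_config, cohort):
        sub = cohort.df.query("gender == 'F' and 30 <= age <= 39")
        X = sm.add_constant(sub[["sr", "diabetes"]].astype(float))
        fit = sm.OLS(sub.saf, X).fit()
        target = default_config.covariate_effects["sr_coeff_F"]
        assert abs(fit.params["sr"] - target) < 3 * fit.bse["sr"]

    @pytest.mark.parametrize("gender,key", [("M", "diabetes_shift_M"),
                                            ("F", "diabetes_shift_F")])
    def test_diabetes_shift(self, default_config, cohort, gender, key):
        sub = cohort.df.query("gender == @gender and 30 <= age <= 39")
        X = sm.add_constant(sub[["diabetes", "bmi", "sr"]].astype(float))
        fit = sm.OLS(sub.saf, X).fit()
        target = default_config.covariate_effects[key]
        assert abs(fit.params["diabetes"] - target) < 3 * fit.bse["diabetes"]


class TestReproducibility:
    def test_same_seed_bit_identical(self, default_config, tmp_path):
        c1 = generate_cohort(default_config, seed=11)
        c2 = generate_cohort(default_config, seed=11)
        pd.testing.assert_frame_equal(c1.df, c2.df)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(c1, p1)
        write_cohort(c2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, default_config):
        c1 = generate_cohort(default_config, seed=11)
        c2 = generate_cohort(default_config, seed=12)
        assert not c1.df.saf.equals(c2.df.saf)

    def test_seed_mandatory(self, default_config):
        with pytest.raises(ValueError, match="seed"):
            generate_cohort(default_config)


class TestCohortIO:
    def test_round_trip_identity(self, cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        a = cohort.df.reset_index(drop=True)
        b = back.df.reset_index(drop=True)
        assert list(a.columns) == list(b.columns)
        for col in a.columns:
            if a[col].dtype.kind == "f":
                np.testing.assert_array_equal(a[col].to_numpy(), b[col].to_numpy())
            else:
                assert (a[col].astype(str) == b[col].astype(str)).all()

    def test_extra_columns_preserved(self, tmp_path):
        c = make_cohort([2.0, 2.1], extra_marker=["x", "y"])
        path = tmp_path / "c.csv"
        write_cohort(c, path)
        assert list(read_cohort(path).df["extra_marker"]) == ["x", "y"]

    def test_missing_saf_column(self, cohort, tmp_path):
        path = tmp_path / "broken.csv"
        cohort.df.drop(columns=["saf"]).to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="saf"):
            read_cohort(path)

    def test_non_numeric_cell_names_row(self, tmp_path):
        c = make_cohort([2.0, 2.1])
        df = c.df.copy()
        df["saf"] = df["saf"].astype(object)
        df.loc[1, "saf"] = "oops"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortParseError, match="row 1"):
            read_cohort(path)

    def test_low_sr_row_flagged_invalid(self, tmp_path):
        with pytest.warns(UserWarning, match="SR below"):
            c = make_cohort([2.0, 2.1], sr=[9.0, 5.0])
        path = tmp_path / "lowsr.csv"
        write_cohort(c, path)
        with pytest.warns(UserWarning, match="SR below"):
            back = read_cohort(path)
        assert list(back.df["sr_valid"]) == [True, False]
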