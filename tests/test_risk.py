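"""Risk stratification: stratum assignment, boundary conventions, scheme
comparison, and the partition/monotonicity/self-consistency properties."""

import importlib.resources

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from safref.reference import ReferenceCurve
from safref.risk import (GROUP_LABELS, RiskScheme, assign_stratum, build_scheme,
                         classify, compare_schemes, read_scheme, write_scheme)

from conftest import make_cohort


def flat_curve(mean=1.5, sd=0.4, label="men"):
    return ReferenceCurve(label, mean, 0.0, sd, 0.0, age_domain=(18, 80))


@pytest.fixture
def flat_scheme():
    return build_scheme({s: flat_curve(label=s)
                         for s in ("men", "women_low_sr", "women_high_sr")})


class TestStratumAssignment:
    def test_sr_threshold_is_inclusive_low(self, flat_scheme):
        assert assign_stratum("F", 10.0, flat_scheme) == "women_low_sr"
        assert assign_stratum("F", 10.1, flat_scheme) == "women_high_sr"

    def test_men_ignore_sr(self, flat_scheme):
        assert assign_stratum("M", 25.0, flat_scheme) == "men"
        assert assign_stratum("M", None, flat_scheme) == "men"

    def test_woman_without_sr_unassignable(self, flat_scheme):
        with pytest.raises(ValueError, match="reflectance"):
            assign_stratum("F", float("nan"), flat_scheme)


class TestSchemeConstruction:
    def test_flat_boundaries(self, flat_scheme):
        assert flat_scheme.boundary("men", 0, 30) == pytest.approx(1.9)
        assert flat_scheme.boundary("men", 1, 77) == pytest.approx(2.3)

    def test_non_increasing_multipliers_rejected(self):
        curves = {s: flat_curve(label=s)
                  for s in ("men", "women_low_sr", "women_high_sr")}
        with pytest.raises(ValueError, match="increasing"):
            build_scheme(curves, multipliers=[2, 1])

    def test_missing_stratum_rejected(self):
        with pytest.raises(ValueError, match="women_high_sr"):
            build_scheme({"men": flat_curve(), "women_low_sr": flat_curve()})

    def test_yaml_round_trip(self, flat_scheme, tmp_path):
        path = tmp_path / "scheme.yaml"
        write_scheme(flat_scheme, path)
        back = read_scheme(path)
        assert back.multipliers == flat_scheme.multipliers
        for s in flat_scheme.strata:
            assert back.strata[s].mean_intercept == flat_scheme.strata[s].mean_intercept

    def test_packaged_conventional_placeholder_loads(self):
        path = importlib.resources.files("safref.data").joinpath(
            "conventional_scheme_synthetic.yaml")
        scheme = read_scheme(str(path))
        assert "placeholder" in scheme.name


class TestClassification:
    """Boundary ties escalate: [b1, b2) is group 1, [b2, ∞) is group 2+."""

    @pytest.mark.parametrize("saf,expected", [
        (1.89, "0"),      # just under b1 = 1.9
        (1.90, "1"),      # exactly b1 → escalates
        (2.29, "1"),
        (2.30, "2+"),     # exactly b2 → escalates
        (2.80, "2+"),
    ])
    def test_boundary_convention(self, flat_scheme, saf, expected):
        subject = {"id": "x", "gender": "M", "sr": 9.0, "age": 40, "saf": saf}
        assert classify(subject, flat_scheme).group == expected

    def test_non_finite_saf_rejected(self, flat_scheme):
        subject = {"id": "x", "gender": "M", "sr": 9.0, "age": 40,
                   "saf": float("nan")}
        with pytest.raises(ValueError, match="non-finite"):
            classify(subject, flat_scheme)

    def test_out_of_domain_age_warns_but_classifies(self):
        curve = {s: ReferenceCurve(s, 1.5, 0.0, 0.4, 0.0, age_domain=(18, 60))
                 for s in ("men", "women_low_sr", "women_high_sr")}
        scheme = build_scheme(curve)
        subject = {"id": "x", "gender": "M", "sr": 9.0, "age": 75, "saf": 1.0}
        with pytest.warns(UserWarning, match="extrapolation"):
            assert classify(subject, scheme).group == "0"

    def test_partition_over_cohort(self, flat_scheme, cohort):
        asg = classify(cohort, flat_scheme)
        assert len(asg) == len(cohort)
        assert asg.group.value_counts().sum() == len(cohort)

    @given(saf=st.floats(0.1, 6.0), delta=st.floats(0.0, 2.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_group_monotone_in_saf(self, saf, delta):
        scheme = build_scheme({s: flat_curve(label=s)
                               for s in ("men", "women_low_sr", "women_high_sr")})
        base = {"id": "x", "gender": "F", "sr": 12.0, "age": 50}
        g1 = classify({**base, "saf": saf}, scheme).group
        g2 = classify({**base, "saf": saf + delta}, scheme).group
        assert GROUP_LABELS.index(g2) >= GROUP_LABELS.index(g1)

    def test_self_consistency_normal_cohort(self):
        """Classifying 50,000 normal SAF values against the curves that
        generated them reproduces the Φ(1)/Φ(2) tail masses."""
        n = 50_000
        rng = np.random.default_rng(0)
        curve = ReferenceCurve("men", 1.2, 0.016, 0.30, 0.002, age_domain=(18, 80))
        scheme = build_scheme({"men": curve, "women_low_sr": curve,
                               "women_high_sr": curve})
        ages = rng.integers(18, 81, n)
        saf = curve.mean_at(ages) + curve.sd_at(ages) * rng.standard_normal(n)
        saf = np.maximum(saf, 1e-6)   # positivity; deep inside group 0 anyway
        df = pd.DataFrame({"id": [f"S{i}" for i in range(n)], "gender": "M",
                           "sr": 9.0, "age": ages, "saf": saf})
        groups = classify(_pad(df), scheme).group
        frac = groups.value_counts(normalize=True)
        expected = {"0": stats.norm.cdf(1),
                    "1": stats.norm.cdf(2) - stats.norm.cdf(1),
                    "2+": 1 - stats.norm.cdf(2)}
        for grp, p in expected.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frac[grp] - p) < 3 * se


def _pad(df):
    """Fill the remaining mandatory columns so a bare (age, saf) frame can be
    classified through the Cohort container."""
    from safref.cohort import Cohort, validate_cohort
    out = df.assign(nationality="x", height=1.7, weight=80.0,
                    bmi=80.0 / 1.7**2, waist=100.0, hip=105.0,
                    whr=100.0 / 105.0, sbp=120.0, dbp=80.0, diabetes=False,
                    hypertension=False, smoking=False, exercise="none")
    validate_cohort(out)
    return Cohort(df=out)


class TestSchemeComparison:
    def test_all_low_saf_is_all_group_zero(self, flat_scheme):
        c = make_cohort([1.0, 1.1, 1.2], age=[30, 40, 50])
        dist, _ = compare_schemes(c, [flat_scheme])
        men = dist[dist.stratum == "men"].set_index("group")
        assert men.loc["0", "percent"] == 100.0
        assert men.loc["1", "count"] == 0 and men.loc["2+", "count"] == 0

    def test_percentages_sum_to_100(self, flat_scheme, cohort):
        dist, _ = compare_schemes(cohort, [flat_scheme])
        sums = dist.groupby(["scheme", "stratum"])["percent"].sum()
        assert np.allclose(sums, 100.0)

    def test_identical_schemes_migrate_diagonally(self, flat_scheme, cohort):
        other = build_scheme(dict(flat_scheme.strata), name="copy")
        _, mig = compare_schemes(cohort, [flat_scheme, other])
        tab = mig[("proposed", "copy")].to_numpy()
        assert tab.sum() == len(cohort)
        assert np.all(tab == np.diag(np.diag(tab)))

    def test_global_shift_never_demotes(self, flat_scheme, cohort):
        before = classify(cohort, flat_scheme).group.map(GROUP_LABELS.index)
        shifted = make_cohort(cohort.df.saf + 0.3,
                              gender=list(cohort.df.gender),
                              age=list(cohort.df.age),
                              sr=list(cohort.df.sr))
        after = classify(shifted, flat_scheme).group.map(GROUP_LABELS.index)
        assert (after.to_numpy() >= before.to_numpy()).all()
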