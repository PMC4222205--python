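"""Derived traits, variance components, heritability, CV_G, region test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qstdiv.quantgen import (
    bootstrap_heritability_ci,
    cv_g,
    derive_traits,
    fit_nested_varcomp,
    heritability,
    percent_contributions,
    region_f_test,
)
from qstdiv.synthetic_data import SimTraitConfig, simulate_traits


def balanced_ems_oracle(df, trait="y"):
    """Closed-form Henderson estimators for a balanced 4-level design.

    Independent of the package's moment solver: works directly from the
    balanced expected-mean-squares ladder.
    """
    n = df.groupby("family")[trait].count().iloc[0]
    f = df.groupby("population")["family"].nunique().iloc[0]
    p = df.groupby("region")["population"].nunique().iloc[0]
    grand = df[trait].mean()
    reg_means = df.groupby("region")[trait].mean()
    pop_means = df.groupby("population")[trait].mean()
    fam_means = df.groupby("family")[trait].mean()
    pop_parent = df.groupby("population")["region"].first()
    fam_parent = df.groupby("family")["population"].first()
    r = len(reg_means)
    ms_r = n * f * p * ((reg_means - grand) ** 2).sum() / (r - 1)
    ms_p = n * f * ((pop_means - reg_means[pop_parent].to_numpy()) ** 2).sum() / (
        r * (p - 1)
    )
    ms_f = n * ((fam_means - pop_means[fam_parent].to_numpy()) ** 2).sum() / (
        r * p * (f - 1)
    )
    resid = df[trait] - fam_means[df["family"]].to_numpy()
    ms_e = (resid**2).sum() / (r * p * f * (n - 1))
    v_e = ms_e
    v_f = (ms_f - ms_e) / n
    v_p = (ms_p - ms_f) / (n * f)
    v_r = (ms_r - ms_p) / (n * f * p)
    return v_r, v_p, v_f, v_e


class TestDeriveTraits:
    def test_cone_volume_and_log(self):
        df = pd.DataFrame({"RosD": [6.0], "RosH": [4.0]})
        out = derive_traits(df)
        assert out["RosV"].iloc[0] == pytest.approx(12 * math.pi, abs=1e-12)
        assert out["logRosV"].iloc[0] == pytest.approx(
            math.log10(12 * math.pi), abs=1e-9
        )

    def test_wue_mean_of_ratios(self):
        df = pd.DataFrame(
            {"A1": [1.2, 2.0], "E1": [1.0, 1.0], "A2": [1.2, 4.0],
             "E2": [1.0, 2.0], "A3": [1.2, 0.0], "E3": [1.0, 0.0]}
        )
        out = derive_traits(df)
        assert out["WUE"].iloc[0] == pytest.approx(1.2)
        # E = 0 measurement dropped, mean over the remaining two
        assert out["WUE"].iloc[1] == pytest.approx(2.0)

    def test_zero_height_gives_zero_volume_missing_log(self):
        out = derive_traits(pd.DataFrame({"RosD": [6.0], "RosH": [0.0]}))
        assert out["RosV"].iloc[0] == 0.0
        assert np.isnan(out["logRosV"].iloc[0])

    def test_existing_columns_not_overwritten(self):
        df = pd.DataFrame({"RosD": [6.0], "RosH": [4.0], "RosV": [1.0]})
        out = derive_traits(df)
        assert out["RosV"].iloc[0] == 1.0


class TestNestedVarcomp:
    def test_constant_data_gives_zero_components(self):
        df = pd.DataFrame(
            {
                "region": ["R1", "R1", "R2", "R2"] * 2,
                "population": ["P1", "P1", "P2", "P2"] * 2,
                "family": ["F1", "F2", "F3", "F4"] * 2,
                "y": 5.0,
            }
        )
        vc = fit_nested_varcomp(df, "y")
        assert all(v == 0 for v in vc.components.values())
        assert vc.converged

    def test_reml_matches_independent_balanced_oracle(self, balanced_traits):
        vc = fit_nested_varcomp(balanced_traits, "y", method="reml")
        oracle = balanced_ems_oracle(balanced_traits)
        for name, truth in zip(vc.names, oracle):
            assert vc.components[name] == pytest.approx(truth, abs=1e-6)

    def test_ems_matches_independent_balanced_oracle(self, balanced_traits):
        vc = fit_nested_varcomp(balanced_traits, "y", method="ems")
        oracle = balanced_ems_oracle(balanced_traits)
        for name, truth in zip(vc.names, oracle):
            assert vc.raw[name] == pytest.approx(truth, abs=1e-10)

    def test_single_group_level_rejected(self):
        df = pd.DataFrame(
            {"population": ["P1"] * 4, "family": ["F1", "F1", "F2", "F2"],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="population"):
            fit_nested_varcomp(df, "y", levels=("population", "family"))

    def test_heritability_affine_invariance(self, balanced_traits):
        df = balanced_traits.copy()
        h0 = heritability(fit_nested_varcomp(df, "y", method="ems"))
        df["y"] = 7.3 * df["y"] - 2.0
        h1 = heritability(fit_nested_varcomp(df, "y", method="ems"))
        assert h1 == pytest.approx(h0, abs=1e-10)


class TestHeritabilityAndCVG:
    @pytest.mark.parametrize(
        "v_f,v_e,expected",
        [(0.017, 0.011, 0.61), (0.050, 0.021, 0.70), (0.0, 0.011, 0.0)],
    )
    def test_point_values(self, v_f, v_e, expected):
        assert round(heritability(v_f, v_e), 2) == expected

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability(0.0, 0.0)

    @pytest.mark.parametrize(
        "v_f,mean,expected",
        [(0.017, 0.6532, 20.0), (1.879, 5.5915, 24.5), (0.0, 1.0, 0.0)],
    )
    def test_cv_g_values(self, v_f, mean, expected):
        assert round(cv_g(v_f, mean), 1) == expected

    def test_cv_g_requires_positive_mean(self):
        with pytest.raises(ValueError, match="positive"):
            cv_g(0.1, 0.0)

    @given(
        v_f=st.floats(1e-6, 10.0), mean=st.floats(0.01, 100.0),
        a=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_cv_g_multiplicative_invariance(self, v_f, mean, a):
        # rescaling y -> a*y scales V_F by a^2 and the mean by a
        assert cv_g(v_f * a**2, mean * a) == pytest.approx(
            cv_g(v_f, mean), rel=1e-9
        )


class TestPercentContributions:
    def test_examples(self):
        assert percent_contributions(
            {"a": 1, "b": 1, "c": 1, "d": 1}
        ) == {"a": 25, "b": 25, "c": 25, "d": 25}
        got = percent_contributions({"a": 2, "b": 0, "c": 1, "d": 1})
        assert [got[k] for k in "abcd"] == [50, 0, 25, 25]

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6).filter(sum))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_hundred(self, vals):
        got = percent_contributions({str(i): v for i, v in enumerate(vals)})
        assert sum(got.values()) == pytest.approx(100.0, abs=1e-6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_contributions({"a": 0.0, "b": 0.0})


class TestBootstrap:
    def test_zero_family_variance_gives_degenerate_ci(self):
        # every family shows the same two values: between-family variance
        # is zero in every resample, so the percentile CI collapses to 0
        df = pd.DataFrame(
            {
                "population": ["P1"] * 8 + ["P2"] * 8,
                "family": [f"F{i}" for i in range(8) for _ in range(2)],
                "y": [0.0, 1.0] * 8,
            }
        )
        est = bootstrap_heritability_ci(
            df, "y", n_boot=100, seed=0, levels=("population", "family")
        )
        assert est.ci == (0.0, 0.0)

    def test_reproducible_for_seed(self, balanced_traits):
        kw = dict(n_boot=50, seed=123, point_method="ems")
        a = bootstrap_heritability_ci(balanced_traits, "y", **kw)
        b = bootstrap_heritability_ci(balanced_traits, "y", **kw)
        assert a.ci == b.ci
        assert np.array_equal(a.boot_values, b.boot_values)

    def test_ci_brackets_truth_on_calibrated_simulation(self):
        cfg = SimTraitConfig(
            n_regions=1, pops_per_region=(1,), families_per_pop=50,
            reps_per_family=6, variance_components=(0, 0, 0.015, 0.010),
            seed=77,
        )
        est = bootstrap_heritability_ci(
            simulate_traits(cfg), "trait", n_boot=500, seed=1,
            levels=("family",), point_method="ems",
        )
        assert est.ci[0] < 0.6 < est.ci[1]


class TestRegionFTest:
    def test_degrees_of_freedom_ten_pops_two_regions(self):
        cfg = SimTraitConfig(pops_per_region=(3, 7), seed=0)
        res = region_f_test(simulate_traits(cfg), "trait")
        assert (res.df_num, res.df_den) == (1, 8)

    def test_p_goes_to_zero_without_noise(self):
        df = pd.DataFrame(
            {
                "region": ["R1"] * 8 + ["R2"] * 8,
                "population": ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4,
                "family": [f"F{i // 2}" for i in range(16)],
                "y": [0.0] * 8 + [1.0] * 8,
            }
        )
        res = region_f_test(df, "y")
        assert res.p < 1e-10

    def test_single_population_per_region_rejected(self):
        df = pd.DataFrame(
            {"region": ["R1", "R1", "R2", "R2"],
             "population": ["P1", "P1", "P2", "P2"],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="2 populations"):
            region_f_test(df, "y")
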