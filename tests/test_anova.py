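import numpy as np
import pandas as pd
import pytest

from lickstruct import (
    Comparison,
    DesignError,
    DesignSpec,
    MixedAnova,
    ValidationError,
    bonferroni_pairwise,
    mixed_anova,
    unpaired_t,
)
from .conftest import balanced_mixed_dataset
from .oracles import glm_f, glm_projection_anova

SPEC_2x2 = DesignSpec(unit="unit", between="group", within=("w1",), response="y")
SPEC_2x6x2 = DesignSpec(unit="unit", between="group", within=("w1", "w2"),
                        response="y")


class TestAgainstProjectionOracle:
    @pytest.mark.parametrize("within_levels, spec, n", [
        ((2,), SPEC_2x2, 16),
        ((6, 2), SPEC_2x6x2, 8),
    ])
    def test_strata_match_glm_projections(self, rng, within_levels, spec, n):
        for _ in range(10):
            df = balanced_mixed_dataset(rng, n_per_group=n,
                                        within_levels=within_levels)
            res = MixedAnova(df, spec).fit()
            oracle = glm_projection_anova(df, "unit", "group",
                                          tuple(spec.within), "y")
            tab = res.anova_table
            checks = [("group", "A"), ("subjects(within groups)", "S"),
                      ("w1", "B"), ("group x w1", "AB")]
            if len(within_levels) == 2:
                checks += [("w1 x subjects(within groups)", "BS"),
                           ("w2", "C"), ("group x w2", "AC"),
                           ("w2 x subjects(within groups)", "CS"),
                           ("w1 x w2", "BC"), ("group x w1 x w2", "ABC")]
            for row, term in checks:
                assert tab.loc[row, "SS"] == pytest.approx(
                    oracle[term]["ss"], abs=1e-8), (row, term)
                assert tab.loc[row, "df"] == oracle[term]["df"]
            assert res.f_statistic("group") == pytest.approx(
                glm_f(oracle, "A", "S"), abs=1e-8)

    def test_reported_df_match_study_designs(self, rng):
        # the 2 x (2) sucrose design on 16 mice per group: F_{1,30}
        df = balanced_mixed_dataset(rng, n_per_group=16, within_levels=(2,))
        res = MixedAnova(df, SPEC_2x2).fit()
        assert res.anova_table.loc["group", "df"] == 1
        assert res.anova_table.loc["subjects(within groups)", "df"] == 30
        # the 2 x (6 x 2) voluntary-interaction design on 8 cages per group:
        # F_{1,14} for the between effect
        df = balanced_mixed_dataset(rng, n_per_group=8, within_levels=(6, 2))
        res = MixedAnova(df, SPEC_2x6x2).fit()
        assert res.anova_table.loc["group", "df"] == 1
        assert res.anova_table.loc["subjects(within groups)", "df"] == 14


class TestDegenerateInputs:
    def test_all_equal_observations_give_zero_f(self, rng):
        df = balanced_mixed_dataset(rng, 4, (2,))
        df["y"] = 3.0
        res = MixedAnova(df, SPEC_2x2).fit()
        for eff in ("group", "w1", "group x w1"):
            assert res.f_statistic(eff) == 0.0
            assert res.p_value(eff) == 1.0

    def test_identical_within_difference_zero_interaction(self, rng):
        df = balanced_mixed_dataset(rng, 6, (2,))
        # impose y(l1) = y(l0) + 2 for every unit: interaction variance vanishes
        wide = df.pivot_table(index=["unit", "group"], columns="w1", values="y")
        wide["l1"] = wide["l0"] + 2.0
        long = wide.reset_index().melt(id_vars=["unit", "group"],
                                       value_vars=["l0", "l1"],
                                       var_name="w1", value_name="y")
        res = MixedAnova(long, SPEC_2x2).fit()
        assert res.f_statistic("group x w1") == 0.0

    def test_one_way_reduction_equals_t_squared(self, rng):
        df = balanced_mixed_dataset(rng, 12, ())
        spec = DesignSpec(unit="unit", between="group", within=(), response="y")
        res = MixedAnova(df, spec).fit()
        x = df.loc[df.group == "g1", "y"].to_numpy()
        y = df.loc[df.group == "g2", "y"].to_numpy()
        t = unpaired_t(x, y)
        assert res.f_statistic("group") == pytest.approx(t.value ** 2, rel=1e-10)
        assert res.p_value("group") == pytest.approx(t.p, rel=1e-10)


class TestInvariances:
    def test_ss_decomposition_identity(self, rng):
        for within in [(2,), (6, 2)]:
            df = balanced_mixed_dataset(rng, 6, within)
            spec = SPEC_2x2 if within == (2,) else SPEC_2x6x2
            tab = MixedAnova(df, spec).fit().anova_table
            total = ((df["y"] - df["y"].mean()) ** 2).sum()
            assert tab["SS"].sum() == pytest.approx(total, abs=1e-8)
            assert tab["df"].sum() == len(df) - 1

    def test_f_invariant_under_affine_response_transform(self, rng):
        df = balanced_mixed_dataset(rng, 8, (2,))
        res1 = MixedAnova(df, SPEC_2x2).fit()
        df2 = df.assign(y=-2.5 * df["y"] + 7.0)
        res2 = MixedAnova(df2, SPEC_2x2).fit()
        for eff in ("group", "w1", "group x w1"):
            assert res1.f_statistic(eff) == pytest.approx(
                res2.f_statistic(eff), rel=1e-10)

    def test_log_transform_scaling_leaves_f_unchanged(self, rng):
        # multiplying the raw response by a constant is a location shift after
        # log: every F (the interaction in particular) is unchanged
        df = balanced_mixed_dataset(rng, 8, (2,))
        df["y"] = np.exp(df["y"])  # make positive
        spec = DesignSpec(unit="unit", between="group", within=("w1",),
                          response="y", transform="log")
        res1 = MixedAnova(df, spec).fit()
        res2 = MixedAnova(df.assign(y=17.3 * df["y"]), spec).fit()
        for eff in ("w1", "group x w1"):
            assert res1.f_statistic(eff) == pytest.approx(
                res2.f_statistic(eff), rel=1e-10)

    def test_cross_check_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = balanced_mixed_dataset(rng, 10, (2,))
        res = MixedAnova(df, SPEC_2x2).fit()
        pg = pingouin.mixed_anova(data=df, dv="y", within="w1", subject="unit",
                                  between="group")
        pg = pg.set_index("Source")
        assert res.f_statistic("group") == pytest.approx(
            float(pg.loc["group", "F"]), rel=1e-8)
        assert res.f_statistic("w1") == pytest.approx(
            float(pg.loc["w1", "F"]), rel=1e-8)
        assert res.f_statistic("group x w1") == pytest.approx(
            float(pg.loc["Interaction", "F"]), rel=1e-8)


class TestDesignRejection:
    def test_unbalanced_groups_named(self, rng):
        df = balanced_mixed_dataset(rng, 4, (2,))
        df = df[~((df.unit == "u1"))]
        with pytest.raises(DesignError, match="unbalanced"):
            MixedAnova(df, SPEC_2x2)

    def test_missing_within_cell_reported(self, rng):
        df = balanced_mixed_dataset(rng, 4, (2,))
        df = df.drop(df[(df.unit == "u1") & (df.w1 == "l1")].index)
        df = df.drop(df[(df.unit == "u5") & (df.w1 == "l1")].index)  # keep balance of units
        with pytest.raises(DesignError):
            MixedAnova(df, SPEC_2x2)

    def test_nonfinite_response_rejected(self, rng):
        df = balanced_mixed_dataset(rng, 4, (2,))
        df.loc[0, "y"] = np.nan
        with pytest.raises(ValidationError):
            MixedAnova(df, SPEC_2x2)


class TestBonferroni:
    def test_adjustment_multiplies_and_caps(self, rng):
        df = balanced_mixed_dataset(rng, 10, (2,))
        fam2 = [
            Comparison("group", where={"w1": "l0"}),
            Comparison("group", where={"w1": "l1"}),
        ]
        res = bonferroni_pairwise(df, SPEC_2x2, fam2)
        for r in res:
            assert r.adjusted_p == pytest.approx(min(1.0, 2 * r.p))
            assert r.adjusted_p >= r.p
        fam1 = [Comparison("group", where={"w1": "l0"})]
        solo = bonferroni_pairwise(df, SPEC_2x2, fam1)[0]
        assert solo.adjusted_p == pytest.approx(solo.p)

    def test_cap_at_one(self, rng):
        # three copies of a null comparison: adjusted p capped at 1
        df = balanced_mixed_dataset(rng, 10, (2,), effects=False)
        fam = [Comparison("group", where={"w1": "l0"})] * 3
        res = bonferroni_pairwise(df, SPEC_2x2, fam)
        assert all(r.adjusted_p <= 1.0 for r in res)

    def test_within_factor_comparison_is_paired(self, rng):
        df = balanced_mixed_dataset(rng, 10, (2,))
        r = bonferroni_pairwise(df, SPEC_2x2, [Comparison("w1")])[0]
        # paired t over all 20 units -> df 19
        assert r.df == 19

    def test_between_factor_comparison_is_unpaired(self, rng):
        df = balanced_mixed_dataset(rng, 10, (2,))
        r = bonferroni_pairwise(
            df, SPEC_2x2, [Comparison("group", where={"w1": "l0"})])[0]
        assert r.df == 18  # 10 + 10 - 2

    def test_unknown_level_rejected(self, rng):
        df = balanced_mixed_dataset(rng, 4, (2,))
        with pytest.raises(ValidationError):
            bonferroni_pairwise(df, SPEC_2x2,
                                [Comparison("group", levels=("g1", "nope"))])
        with pytest.raises(ValidationError):
            bonferroni_pairwise(df, SPEC_2x2, [])


def test_assumption_checks_report_but_never_switch(rng, caplog):
    from lickstruct import assumption_checks
    df = balanced_mixed_dataset(rng, 10, (2,))
    # heavy-tailed contamination in one cell to trip Shapiro-Wilk
    idx = df[(df.group == "g1") & (df.w1 == "l0")].index
    df.loc[idx[:3], "y"] += 40.0
    with caplog.at_level("WARNING"):
        rep = assumption_checks(df, SPEC_2x2)
    assert set(rep["check"]) == {"shapiro", "levene"}
    assert ((rep["p"] >= 0) & (rep["p"] <= 1)).all()
    assert "unchanged" in caplog.text
    # the ANOVA itself still runs identically on the same data
    MixedAnova(df, SPEC_2x2).fit()


def test_summary_renders_table(rng):
    df = balanced_mixed_dataset(rng, 4, (2,))
    text = mixed_anova(df, SPEC_2x2).summary()
    assert "group x w1" in text and "F" in text
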