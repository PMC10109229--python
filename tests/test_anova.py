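import numpy as np
import pandas as pd
import pytest

from acutewell.anova import (bonferroni_posthoc, build_results_table,
                             cohens_d_paired, derive_subgroup_factors,
                             direction_arrow, mixed_anova,
                             significance_stars, subgroup_anova)
from acutewell.errors import AnalysisError
from oracles import split_plot_oracle

EFFECTS = ["group", "subject(group)", "period", "period:group", "residual"]


def _wide(groups, Y):
    df = pd.DataFrame(np.asarray(Y, dtype=float),
                      columns=["B", "W", "R1", "R2"])
    df["group"] = groups
    return df


def _random_design(rng, balanced=False):
    sizes = ([8, 8, 8] if balanced
             else rng.integers(2, 17, size=3))
    groups = np.repeat(["high", "medium", "low"], sizes)
    Y = (rng.normal(size=(len(groups), 1))          # subject effects
         + rng.normal(size=(len(groups), 4)))
    return groups, Y


class TestMixedAnova:
    def test_matches_projection_oracle_on_random_designs(self):
        """SS of every stratum equals explicit nested least squares, 1e-8 rel."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            groups, Y = _random_design(rng)
            res = mixed_anova(_wide(groups, Y))
            oracle = split_plot_oracle(groups, Y)
            for eff in EFFECTS:
                got = res.table.loc[eff, "SS"]
                assert got == pytest.approx(oracle[eff], rel=1e-8, abs=1e-10)

    def test_matches_pingouin_on_balanced_design(self):
        """F and p of all three effects agree with an independent package."""
        import pingouin as pg
        rng = np.random.default_rng(22)
        groups, Y = _random_design(rng, balanced=True)
        df = _wide(groups, Y)
        res = mixed_anova(df)
        long = df.reset_index().melt(id_vars=["index", "group"],
                                     var_name="period", value_name="y")
        ref = pg.mixed_anova(data=long, dv="y", within="period",
                             subject="index", between="group").set_index("Source")
        for ours, theirs in [("group", "group"), ("period", "period"),
                             ("period:group", "Interaction")]:
            assert res.table.loc[ours, "F"] == pytest.approx(
                ref.loc[theirs, "F"], rel=1e-9)
            assert res.table.loc[ours, "p"] == pytest.approx(
                ref.loc[theirs, "p_unc"], rel=1e-9)

    def test_ss_conservation(self):
        """The five strata partition the total SS exactly."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            groups, Y = _random_design(rng)
            res = mixed_anova(_wide(groups, Y))
            total = float(((Y - Y.mean()) ** 2).sum())
            assert res.table["SS"].sum() == pytest.approx(total, rel=1e-10)

    def test_design_degrees_of_freedom(self):
        rng = np.random.default_rng(24)
        groups, Y = _random_design(rng)
        res = mixed_anova(_wide(groups, Y))
        N = len(groups)
        assert res.table.loc["period", "df"] == 3
        assert res.table.loc["group", "df"] == 2
        assert res.table.loc["period:group", "df"] == 6
        assert res.table.loc["subject(group)", "df"] == N - 3
        assert res.table.loc["residual", "df"] == (N - 3) * 3

    def test_constant_input_reports_missing_f(self):
        df = _wide(np.repeat(["a", "b"], 3), np.ones((6, 4)) * 5.0)
        res = mixed_anova(df)
        assert res.table.loc["period", "SS"] == pytest.approx(0.0)
        assert res.table.loc["period:group", "SS"] == pytest.approx(0.0)
        assert np.isnan(res.table.loc["period", "F"])
        assert any("zero-variance" in d for d in res.diagnostics)

    def test_undersized_group_aborts_with_diagnostic(self):
        df = _wide(["a", "a", "b"], np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(AnalysisError, match="<2 complete cases"):
            mixed_anova(df)

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(25)
        groups, Y = _random_design(rng)
        res = mixed_anova(_wide(groups, Y), greenhouse_geisser=True)
        assert 1.0 / 3.0 <= res.gg_epsilon <= 1.0


class TestPosthoc:
    def test_bonferroni_multiplies_and_clamps(self):
        rng = np.random.default_rng(30)
        df = _wide(np.repeat(["a", "b"], 20), rng.normal(size=(40, 4)))
        ph = bonferroni_posthoc(df).set_index("pair")
        for pair in ("B & W", "B & R1", "B & R2"):
            unc = ph.loc[pair, "p_uncorrected"]
            assert ph.loc[pair, "p_bonferroni"] == pytest.approx(
                min(1.0, 6 * unc))
            assert ph.loc[pair, "p_bonferroni"] >= unc

    def test_identical_period_means_give_p_one_and_d_zero(self):
        base = np.arange(10, dtype=float)
        Y = np.column_stack([base, base[::-1], base, base[::-1]])
        df = _wide(np.repeat(["a", "b"], 5), Y)
        ph = bonferroni_posthoc(df, pairs=[("B", "R1")]).set_index("pair")
        # B and R1 are identical columns -> zero differences -> missing p
        assert np.isnan(ph.loc["B & R1", "p_uncorrected"])
        ph2 = bonferroni_posthoc(df, pairs=[("B", "W")]).set_index("pair")
        assert ph2.loc["B & W", "p_uncorrected"] == pytest.approx(1.0)
        assert ph2.loc["B & W", "cohens_d"] == pytest.approx(0.0)

    def test_direction_matches_sign_of_mean_difference(self):
        rng = np.random.default_rng(31)
        Y = rng.normal(size=(30, 4))
        Y[:, 1] += 1.0
        df = _wide(np.repeat(["a", "b"], 15), Y)
        ph = bonferroni_posthoc(df).set_index("pair")
        assert ph.loc["B & W", "direction"] == "increase"
        assert np.sign(ph.loc["B & W", "cohens_d"]) == 1.0


class TestCohensD:
    def test_zero_mean_differences(self):
        assert cohens_d_paired([0.0, 0.0], [1.0, -1.0]) == 0.0

    def test_constant_differences_raise(self):
        with pytest.raises(AnalysisError, match="zero SD"):
            cohens_d_paired([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_mean_over_sd_definition(self):
        rng = np.random.default_rng(32)
        x1, x2 = rng.normal(size=50), rng.normal(size=50) + 0.4
        diff = x2 - x1
        assert cohens_d_paired(x1, x2) == pytest.approx(
            diff.mean() / diff.std(ddof=1))


class TestSubgroupFactors:
    def _profiles(self):
        return pd.DataFrame({
            "participant_id": ["p1", "p2", "p3", "p4"],
            "age": [59, 60, 45, 72],
            "gender": ["man", "woman", "woman", "man"],
            "income_level": ["median", "unspecified", "above_median",
                             "below_median"],
        })

    def _aggregates(self):
        return pd.DataFrame({
            "participant_id": ["p1", "p2", "p3", "p4"],
            "indicator": "mood",
            "period": "B",
            "work_mean": 1.0, "free_mean": 1.0,
            "weighted_mean": [0.0, 1.0, 2.0, 3.0],
        })

    def _exposure(self):
        return pd.DataFrame({"participant_id": ["p1", "p2", "p3", "p4"],
                             "group": ["medium", "high", "medium", "low"]})

    def test_age_split_at_59_60(self):
        f = derive_subgroup_factors(self._profiles(), self._aggregates(),
                                    "mood", self._exposure()).set_index(
                                        "participant_id")
        assert f.loc["p1", "age_group"] == "younger"
        assert f.loc["p2", "age_group"] == "older"

    def test_baseline_median_tie_is_at_or_above(self):
        f = derive_subgroup_factors(self._profiles(), self._aggregates(),
                                    "mood", self._exposure()).set_index(
                                        "participant_id")
        # median of [0,1,2,3] = 1.5; p3 (2.0) above, p1 (0.0) below
        assert f.loc["p3", "baseline_level"] == "at_or_above_median"
        assert f.loc["p1", "baseline_level"] == "below_median"

    def test_unspecified_income_becomes_missing(self):
        f = derive_subgroup_factors(self._profiles(), self._aggregates(),
                                    "mood", self._exposure()).set_index(
                                        "participant_id")
        assert pd.isna(f.loc["p2", "income_level"])

    def test_low_exposure_excluded(self):
        f = derive_subgroup_factors(self._profiles(), self._aggregates(),
                                    "mood", self._exposure())
        assert "p4" not in set(f["participant_id"])


def _subgroup_data(rng, n=240, gender_effect=0.0):
    factors = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)],
        "exposure": rng.choice(["medium", "high"], n, p=[0.75, 0.25]),
        "age_group": rng.choice(["younger", "older"], n),
        "gender": rng.choice(["man", "woman"], n),
        "income_level": rng.choice(["above_median", "median", "below_median"],
                                   n, p=[0.5, 0.2, 0.3]),
        "baseline_level": rng.choice(["below_median", "at_or_above_median"], n),
    })
    delta = rng.normal(0, 1, n) + gender_effect * (factors["gender"] == "woman")
    deltas = pd.DataFrame({"participant_id": factors["participant_id"],
                           "delta": delta})
    return deltas, factors


class TestSubgroupAnova:
    def test_constant_deltas_give_zero_factor_ss(self):
        rng = np.random.default_rng(40)
        deltas, factors = _subgroup_data(rng)
        deltas["delta"] = 1.25
        res = subgroup_anova(deltas, factors)
        for f in ("exposure", "age_group", "gender", "income_level",
                  "baseline_level"):
            assert res.table.loc[f, "SS"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_type3(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        rng = np.random.default_rng(41)
        deltas, factors = _subgroup_data(rng, gender_effect=0.5)
        res = subgroup_anova(deltas, factors)
        m = factors.copy()
        m["delta"] = deltas["delta"].to_numpy()
        fit = smf.ols("delta ~ C(exposure, Sum) + C(age_group, Sum) "
                      "+ C(gender, Sum) + C(income_level, Sum) "
                      "+ C(baseline_level, Sum)", data=m).fit()
        ref = anova_lm(fit, typ=3)
        for f, tag in [("exposure", "C(exposure, Sum)"),
                       ("gender", "C(gender, Sum)"),
                       ("income_level", "C(income_level, Sum)")]:
            assert res.table.loc[f, "SS"] == pytest.approx(
                ref.loc[tag, "sum_sq"], rel=1e-9)
            assert res.table.loc[f, "p"] == pytest.approx(
                ref.loc[tag, "PR(>F)"], rel=1e-9)

    def test_known_gender_effect_recovered(self):
        """A 0.5 SD gender gap is detected and its size estimated within 25%."""
        sig, gaps = 0, []
        for seed in range(10):
            rng = np.random.default_rng(50 + seed)
            deltas, factors = _subgroup_data(rng, n=600, gender_effect=0.5)
            res = subgroup_anova(deltas, factors)
            sig += res.table.loc["gender", "p"] < 0.05
            am = res.adjusted_means["gender"]
            gaps.append(am["woman"] - am["man"])
        assert sig >= 9
        assert abs(np.mean(gaps) - 0.5) < 0.125

    def test_balanced_design_equals_sequential_ss(self):
        """On a fully crossed balanced design Type-III and sequential agree."""
        levels = [("medium", "high"), ("younger", "older"), ("man", "woman"),
                  ("above_median", "median", "below_median"),
                  ("below_median", "at_or_above_median")]
        rows = []
        i = 0
        for a in levels[0]:
            for b in levels[1]:
                for c in levels[2]:
                    for d in levels[3]:
                        for e in levels[4]:
                            for _ in range(2):
                                rows.append((f"p{i}", a, b, c, d, e))
                                i += 1
        factors = pd.DataFrame(rows, columns=["participant_id", "exposure",
                                              "age_group", "gender",
                                              "income_level", "baseline_level"])
        rng = np.random.default_rng(60)
        y = rng.normal(size=len(factors))
        deltas = pd.DataFrame({"participant_id": factors["participant_id"],
                               "delta": y})
        res = subgroup_anova(deltas, factors)
        # sequential SS via nested one-hot projections (independent route)
        from numpy.linalg import lstsq

        def onehot(vals):
            u = sorted(set(vals))
            return np.eye(len(u))[[u.index(v) for v in vals]]

        X = np.ones((len(y), 1))
        rss_prev = float(((y - y.mean()) ** 2).sum())
        for f in ("exposure", "age_group", "gender", "income_level",
                  "baseline_level"):
            X = np.hstack([X, onehot(factors[f])])
            beta, *_ = lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            assert res.table.loc[f, "SS"] == pytest.approx(rss_prev - rss,
                                                           rel=1e-8, abs=1e-10)
            rss_prev = rss

    def test_single_level_factor_dropped_not_fatal(self):
        rng = np.random.default_rng(42)
        deltas, factors = _subgroup_data(rng)
        factors["gender"] = "woman"
        res = subgroup_anova(deltas, factors)
        assert "gender" in res.dropped_factors
        assert "gender" not in res.table.index


class TestResultsTable:
    @pytest.mark.parametrize("p, stars", [
        (0.0004, "***"), (0.004, "**"), (0.03, "*"), (0.2, ""),
    ])
    def test_significance_stars(self, p, stars):
        assert significance_stars(p) == stars

    def test_direction_arrows(self):
        assert direction_arrow(+1.0) == "↑"
        assert direction_arrow(-1.0) == "↓"

    def test_table_carries_pair_columns_and_arrows(self):
        rng = np.random.default_rng(43)
        Y = rng.normal(size=(60, 4))
        Y[:, 1] += 2.0   # strong W increase
        df = _wide(np.repeat(["high", "medium", "low"], 20), Y)
        mixed = {"stress": mixed_anova(df)}
        ph = {"stress": bonferroni_posthoc(df)}
        table = build_results_table(mixed, ph)
        row = table.iloc[0]
        assert row["B_W_p"] < 0.001
        assert row["B_W_stars"] == "***"
        assert row["B_W_arrow"] == "↑"
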