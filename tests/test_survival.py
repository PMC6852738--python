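"""Unit tests for the PFS survival-analysis layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apoptosim.survival import (
    ConvergenceError,
    chi_square_association,
    cox_multivariate,
    cox_univariate,
    km_fit,
    log_rank,
    median_split,
)
from apoptosim.synthetic import OutcomeSpec, generate_outcomes


def _records(times, events, group, **extra) -> pd.DataFrame:
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(times))],
        "pfs_months": times, "event": events, "group": group,
    })
    for k, v in extra.items():
        df[k] = v
    return df


def _planted_cohort(n, hr, seed, p_resistant=0.3, window=36.0):
    rng = np.random.default_rng(seed)
    classes = np.where(rng.random(n) < p_resistant, "resistant", "sensitive")
    cl = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                       "history": "newly_diagnosed", "apoptosis_class": classes})
    out = generate_outcomes(cl, OutcomeSpec(hazard_ratio=hr, seed=seed,
                                            censor_window_months=window),
                            covariate_mode=False)
    return out.merge(cl[["sample_id", "apoptosis_class"]], on="sample_id")


class TestMedianSplit:
    def test_even_no_ties_halves(self):
        lab = median_split(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(lab) == ["<=median", "<=median", ">median", ">median"]

    def test_ties_at_median_go_low(self):
        lab = median_split(pd.Series([5.0, 5.0, 5.0, 9.0]))
        assert list(lab) == ["<=median"] * 3 + [">median"]

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_hand_computed_curve_and_median(self):
        rec = _records([2.0, 4.0, 6.0], [1, 1, 1], "all")
        curve = km_fit(rec, "group")["all"]
        surv_at = dict(zip(curve.times, curve.survival))
        assert surv_at[2.0] == pytest.approx(2 / 3)
        assert surv_at[4.0] == pytest.approx(1 / 3)
        assert surv_at[6.0] == pytest.approx(0.0)
        assert curve.median == pytest.approx(4.0)
        assert curve.n_events == 3

    def test_no_censoring_matches_empirical_survival(self, rng):
        t = rng.exponential(10.0, size=50)
        rec = _records(t, np.ones(50, dtype=int), "all")
        curve = km_fit(rec, "group")["all"]
        emp = [(t > u).mean() for u in curve.times]
        np.testing.assert_allclose(curve.survival, emp, atol=1e-12)

    def test_all_censored_median_not_reached(self):
        rec = _records([3.0, 5.0, 8.0], [0, 0, 0], "all")
        curve = km_fit(rec, "group")["all"]
        assert np.all(curve.survival == 1.0)
        assert not curve.median_reached

    def test_median_ci_brackets_median(self):
        df = _planted_cohort(120, 1.0, seed=5)
        curve = km_fit(df, "apoptosis_class")["sensitive"]
        lo, hi = curve.median_ci
        assert lo <= curve.median <= hi


class TestLogRank:
    def test_identical_groups_p_one(self):
        base = _records([2.0, 4.0, 6.0, 8.0], [1, 1, 0, 1], "a")
        dup = base.assign(group="b", sample_id=[f"t{i}" for i in range(4)])
        p = log_rank(pd.concat([base, dup], ignore_index=True), "group")
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            log_rank(_records([1.0, 2.0], [1, 1], "a"), "group")

    def test_separated_groups_match_hand_computed_statistic(self):
        """All of group a fails before any of group b; compare with a direct
        observed-minus-expected summation over event times."""
        ta, tb = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        rec = _records(ta + tb, [1] * 6, ["a"] * 3 + ["b"] * 3)
        # hypergeometric O-E and variance accumulated at each distinct event time
        times = sorted(ta + tb)
        o_minus_e, var = 0.0, 0.0
        for t in times:
            n_at_risk = sum(1 for x in ta + tb if x >= t)
            na = sum(1 for x in ta if x >= t)
            d = 1
            o = 1 if t in ta else 0
            e = d * na / n_at_risk
            o_minus_e += o - e
            if n_at_risk > 1:
                var += d * (na / n_at_risk) * (1 - na / n_at_risk) \
                    * (n_at_risk - d) / (n_at_risk - 1)
        expected_p = stats.chi2.sf(o_minus_e ** 2 / var, df=1)
        assert log_rank(rec, "group") == pytest.approx(expected_p, rel=1e-6)


class TestCox:
    def test_identical_distributions_hr_near_one(self):
        base = _records([2.0, 3.0, 5.0, 7.0, 11.0, 13.0], [1, 1, 0, 1, 1, 0], "a")
        dup = base.assign(group="b", sample_id=[f"t{i}" for i in range(6)])
        fit = cox_univariate(pd.concat([base, dup], ignore_index=True), "group",
                             reference="a")
        assert fit.hazard_ratio() == pytest.approx(1.0, abs=1e-6)

    def test_recovers_planted_hazard_ratio(self):
        df = _planted_cohort(800, hr=5.0, seed=11)
        fit = cox_univariate(df, "apoptosis_class", reference="sensitive")
        assert 4.0 < fit.hazard_ratio("resistant") < 6.25
        assert fit.lrt_p < 1e-6

    def test_invariant_to_row_order_and_ids(self):
        df = _planted_cohort(200, hr=3.0, seed=2)
        fit1 = cox_univariate(df, "apoptosis_class", reference="sensitive")
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        shuffled["sample_id"] = [f"z{i}" for i in range(len(shuffled))]
        fit2 = cox_univariate(shuffled, "apoptosis_class", reference="sensitive")
        assert fit1.hazard_ratio() == pytest.approx(fit2.hazard_ratio(), rel=1e-8)
        assert fit1.lrt_p == pytest.approx(fit2.lrt_p, rel=1e-6)

    def test_continuous_predictor(self):
        rng = np.random.default_rng(3)
        n = 300
        age = rng.uniform(20, 80, n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.03 * (age - 50))))
        df = pd.DataFrame({"sample_id": range(n), "pfs_months": t,
                           "event": 1, "age_years": age})
        fit = cox_univariate(df, "age_years")
        assert np.log(fit.hazard_ratio()) == pytest.approx(0.03, abs=0.01)

    def test_lrt_agrees_with_log_rank_asymptotically(self):
        # modest effect keeps both p-values in a regime where the two
        # asymptotically equivalent tests are numerically comparable
        df = _planted_cohort(1000, hr=1.2, seed=17)
        fit = cox_univariate(df, "apoptosis_class", reference="sensitive")
        p_lr = log_rank(df, "apoptosis_class")
        assert abs(np.log10(fit.lrt_p) - np.log10(p_lr)) < 0.2

    def test_unadjusted_and_adjusted_agree_without_confounding(self):
        df = _planted_cohort(500, hr=3.0, seed=23)
        rng = np.random.default_rng(23)
        df["age_years"] = rng.uniform(30, 75, len(df))
        df["mgmt"] = rng.choice(["methylated", "unmethylated"], len(df))
        crude = cox_univariate(df, "apoptosis_class", reference="sensitive")
        adj = cox_multivariate(df, "apoptosis_class",
                               adjusters=("age_years", "mgmt"),
                               reference="sensitive")
        row = crude.table.iloc[0]
        assert row["ci_low"] < adj.hazard_ratio("resistant") < row["ci_high"]

    def test_confounder_adjustment_removes_bias(self):
        """A covariate driving both class and hazard biases the crude HR; the
        adjusted HR returns to the null truth."""
        rng = np.random.default_rng(31)
        n = 1500
        z = rng.random(n) < 0.5
        resistant = rng.random(n) < np.where(z, 0.8, 0.2)
        rate = 0.05 * np.exp(1.2 * z)  # hazard depends on z only
        t = rng.exponential(1.0 / rate)
        df = pd.DataFrame({
            "sample_id": range(n), "pfs_months": t, "event": 1,
            "apoptosis_class": np.where(resistant, "resistant", "sensitive"),
            "confounder": np.where(z, "high", "low"),
        })
        crude = cox_univariate(df, "apoptosis_class", reference="sensitive")
        adj = cox_multivariate(df, "apoptosis_class", adjusters=("confounder",),
                               reference="sensitive")
        assert crude.hazard_ratio("resistant") > 1.5  # biased away from null
        assert adj.hazard_ratio("resistant") == pytest.approx(1.0, abs=0.2)

    def test_missing_covariates_dropped_per_model(self):
        df = _planted_cohort(100, hr=2.0, seed=7)
        df["mgmt"] = (["missing"] * 10
                      + ["methylated", "unmethylated"] * 45)
        fit = cox_multivariate(df, "apoptosis_class", adjusters=("mgmt",),
                               reference="sensitive")
        assert fit.n_used == 90

    def test_complete_separation_flagged(self):
        df = _records([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [1] * 3 + [0] * 3,
                      ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ConvergenceError):
            cox_univariate(df, "group", reference="b")


class TestChiSquare:
    def test_independent_table_p_one(self):
        cls = pd.Series(["r"] * 20 + ["s"] * 20)
        hist = pd.Series((["new"] * 10 + ["rec"] * 10) * 2)
        res = chi_square_association(cls, hist)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        cls = pd.Series(["r"] * 20 + ["s"] * 20)
        hist = pd.Series(["new"] * 20 + ["rec"] * 20)
        res = chi_square_association(cls, hist)
        assert res.statistic == pytest.approx(40.0)
        assert res.p_value < 1e-9
        assert res.p_value_yates > res.p_value  # correction is conservative

    def test_single_level_margin_rejected(self):
        # one observed class level collapses a margin of the 2x2 table
        with pytest.raises(ValueError, match="margin"):
            chi_square_association(pd.Series(["r", "r"]),
                                   pd.Series(["new", "rec"]))
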