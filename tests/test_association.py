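"""2x2 machinery, logistic fits, selection rule and the dependent
permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdsinfer import (
    ContingencyTable2x2,
    RespondentRecord,
    Variable,
    VariableCatalogue,
    build_forest,
    crosstab,
    dependent_permutation_test,
    logistic_fit,
    multiple_overdose_model,
    odds_ratio_wald,
    records_to_frame,
    select_multivariable,
)

from conftest import make_records

XY_CAT = VariableCatalogue([Variable("x"), Variable("y")], outcome="y")


def records_from_table(a, b, c, d):
    """Respondent records realizing exact 2x2 counts (x = exposure)."""
    rows = ([(1, 1)] * a) + ([(1, 0)] * b) + ([(0, 1)] * c) + ([(0, 0)] * d)
    return [RespondentRecord(f"r{i}", None, 5, {"x": x, "y": y}, y)
            for i, (x, y) in enumerate(rows)]


class TestCrosstab:
    def test_reconstructed_hcv_table(self):
        recs = records_from_table(79, 26, 155, 270)
        table = crosstab(recs, "x", "y", XY_CAT)
        assert table.as_tuple() == (79, 26, 155, 270)

    def test_all_outcome_negative(self):
        recs = records_from_table(0, 7, 0, 13)
        assert crosstab(recs, "x", "y", XY_CAT).as_tuple() == (0, 7, 0, 13)

    def test_exposure_swap_symmetry(self):
        table = ContingencyTable2x2(5, 7, 11, 13)
        assert table.swapped_exposure().as_tuple() == (11, 13, 5, 7)

    def test_missing_values_excluded_and_counted(self):
        recs = records_from_table(3, 2, 4, 1)
        recs[0].covariates["y"] = None
        table = crosstab(recs, "x", "y", XY_CAT)
        assert table.n == 9


class TestOddsRatioWald:
    @pytest.mark.parametrize("cells,or2,ci2", [
        ((79, 26, 155, 270), 5.29, (3.26, 8.60)),
        ((165, 141, 68, 158), 2.72, (1.89, 3.91)),
    ])
    def test_reconstructed_study_tables(self, cells, or2, ci2):
        res = odds_ratio_wald(ContingencyTable2x2(*cells))
        assert round(res.or_, 2) == or2
        assert (round(res.ci[0], 2), round(res.ci[1], 2)) == ci2

    def test_null_table_symmetric_ci(self):
        res = odds_ratio_wald(ContingencyTable2x2(10, 10, 10, 10))
        assert res.or_ == pytest.approx(1.0)
        assert res.ci[0] * res.ci[1] == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_cell_continuity_corrected_and_flagged(self):
        res = odds_ratio_wald(ContingencyTable2x2(0, 10, 5, 5))
        assert res.continuity_corrected
        assert res.or_ == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_double_zero_diagonal_undefined(self):
        res = odds_ratio_wald(ContingencyTable2x2(0, 10, 5, 0))
        assert res.undefined and res.or_ is None

    def test_transposed_table_same_or(self):
        t = ContingencyTable2x2(8, 3, 5, 9)
        tt = ContingencyTable2x2(8, 5, 3, 9)  # exposure <-> outcome swap
        assert odds_ratio_wald(t).or_ == pytest.approx(
            odds_ratio_wald(tt).or_)


class TestLogisticFit:
    def test_single_binary_predictor_matches_cross_product_or(self):
        recs = records_from_table(79, 26, 155, 270)
        fit = logistic_fit(recs, "y", ["x"], XY_CAT)
        or_ = odds_ratio_wald(ContingencyTable2x2(79, 26, 155, 270)).or_
        assert float(fit.aor["x"]) == pytest.approx(or_, rel=1e-6)
        assert round(float(fit.aor["x"]), 2) == 5.29

    def test_simulated_coefficients_recovered(self):
        rng = np.random.default_rng(12)
        x = rng.random(5000) < 0.5
        logit = -1.0 + 0.7 * x
        y = rng.random(5000) < 1 / (1 + np.exp(-logit))
        frame = pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(5000)],
            "recruiter_id": [None] * 5000, "degree": 5.0,
            "x": x.astype(float), "y": y.astype(float)})
        fit = logistic_fit(frame, "y", ["x"], XY_CAT)
        assert abs(float(fit.params["const"]) + 1.0) < 0.1
        assert abs(float(fit.params["x"]) - 0.7) < 0.1

    def test_constant_outcome_rejected(self):
        recs = records_from_table(5, 0, 7, 0)
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(recs, "y", ["x"], XY_CAT)

    def test_categorical_reference_contrast(self):
        cat = VariableCatalogue([
            Variable("g", kind="categorical", levels=("lo", "mid", "hi"),
                     reference="mid"), Variable("y")], outcome="y")
        rng = np.random.default_rng(13)
        g = rng.choice(["lo", "mid", "hi"], 600)
        y = (rng.random(600) < np.where(g == "hi", 0.6, 0.3)).astype(float)
        frame = pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(600)],
            "recruiter_id": [None] * 600, "degree": 4.0, "g": g, "y": y})
        fit = logistic_fit(frame, "y", ["g"], cat)
        assert set(fit.params.index) == {"const", "g[lo]", "g[hi]"}
        assert float(fit.aor["g[hi]"]) > 1.5


TABLE_SHAPED_PVALUES = [
    ("age", "24_29", 0.10),
    ("gender", "female", 0.27),
    ("race_ethnicity", "white_nonhispanic", 1e-5),
    ("race_ethnicity", "nonwhite_nonhispanic", 0.53),
    ("income_growing_up", "le_50k", 0.42),
    ("income_growing_up", "gt_100k", 0.005),
    ("income_growing_up", "dont_know_missing", 0.01),
    ("education", "hs_grad_ged", 0.02),
    ("education", "beyond_hs", 0.35),
    ("ever_homeless", "1", 1e-5),
    ("hcv_positive", "1", 1e-5),
    ("benzo_regular", "1", 1e-5),
    ("po_regular", "1", 0.81),
    ("heroin_regular", "1", 1e-5),
    ("heroin_injection_regular", "1", 1e-5),
    ("po_injection_regular", "1", 1e-5),
    ("nonsterile_syringe", "1", 1e-5),
    ("drug_binging", "1", 0.001),
]


class TestSelectMultivariable:
    def test_study_shaped_pvalues_select_eleven_variables(self):
        selected = select_multivariable(TABLE_SHAPED_PVALUES, 0.05)
        assert selected == [
            "race_ethnicity", "income_growing_up", "education",
            "ever_homeless", "hcv_positive", "benzo_regular",
            "heroin_regular", "heroin_injection_regular",
            "po_injection_regular", "nonsterile_syringe", "drug_binging"]
        assert "age" not in selected and "gender" not in selected

    def test_all_nonsignificant_selects_nothing(self):
        assert select_multivariable([("a", "1", 1.0), ("b", "1", 1.0)]) == []

    def test_threshold_one_selects_everything(self):
        assert select_multivariable(
            [("a", "1", 0.9), ("b", "1", 0.5)], threshold=1.0) == ["a", "b"]

    def test_boundary_comparator(self):
        res = [("a", "1", 0.05)]
        assert select_multivariable(res, 0.05, "le") == ["a"]
        assert select_multivariable(res, 0.05, "lt") == []


def exact_iid_null_p(x, y):
    """Exhaustive enumeration of the iid Bernoulli null (non-constant
    vectors) for the continuity-corrected |ln OR| statistic."""
    def stat(xv):
        a = int(np.sum((xv == 1) & (y == 1)))
        b = int(np.sum((xv == 1) & (y == 0)))
        c = int(np.sum((xv == 0) & (y == 1)))
        d = int(np.sum((xv == 0) & (y == 0)))
        cells = np.array([a, b, c, d], float)
        if (cells == 0).any():
            cells += 0.5
        return abs(np.log(cells[0] * cells[3] / (cells[1] * cells[2])))

    n = len(x)
    t_obs = stat(x)
    phat = x.mean()
    num = den = 0.0
    for bits in itertools.product([0, 1], repeat=n):
        xv = np.array(bits)
        k = xv.sum()
        if k in (0, n):
            continue
        w = phat ** k * (1 - phat) ** (n - k)
        den += w
        if stat(xv) >= t_obs - 1e-12:
            num += w
    return num / den


class TestDependentPermutationTest:
    def test_matches_exhaustive_iid_enumeration_on_toy(
            self, toy_chain_records):
        recs, forest, x, y = toy_chain_records
        p_exact = exact_iid_null_p(x, y)
        phat = x.mean()
        iid_rows = np.array([[1 - phat, phat], [1 - phat, phat]])
        res = dependent_permutation_test(
            recs, forest, "x", "y", XY_CAT, r_replicates=9999,
            rng=np.random.default_rng(14), transition=iid_rows)
        assert abs(res.p - p_exact) < 0.02

    def test_null_statistic_gives_p_one(self):
        x = np.array([1, 1, 0, 0] * 5)
        y = np.array([1, 0, 1, 0] * 5)  # OR exactly 1
        parents = [None if i < 4 else i - 4 for i in range(20)]
        recs = make_records(x, y, parents)
        res = dependent_permutation_test(
            recs, build_forest(recs), "x", "y", XY_CAT, r_replicates=999,
            rng=np.random.default_rng(15))
        assert res.t_obs == pytest.approx(0.0)
        assert res.p >= 1.0 - 1 / 1000

    def test_invariant_to_id_relabelling_within_mc_error(self):
        rng = np.random.default_rng(16)
        x = (rng.random(60) < 0.5).astype(int)
        y = (rng.random(60) < 0.4).astype(int)
        parents = [None if i < 6 else (i - 6) // 2 for i in range(60)]
        recs = make_records(x, y, parents)
        forest = build_forest(recs)
        r = 4999
        p1 = dependent_permutation_test(
            recs, forest, "x", "y", XY_CAT, r_replicates=r,
            rng=np.random.default_rng(17)).p
        relabel = {f"r{i}": f"z{99 - i}" for i in range(60)}
        recs2 = [RespondentRecord(
            relabel[r_.respondent_id],
            None if r_.recruiter_id is None else relabel[r_.recruiter_id],
            r_.degree, dict(r_.covariates), r_.outcome) for r_ in recs]
        p2 = dependent_permutation_test(
            recs2, build_forest(recs2), "x", "y", XY_CAT, r_replicates=r,
            rng=np.random.default_rng(18)).p
        mc_se = np.sqrt(p1 * (1 - p1) / r)
        assert abs(p1 - p2) < 4 * mc_se + 2 / r

    def test_constant_correlate_rejected(self):
        recs = make_records(np.ones(12, int), np.arange(12) % 2,
                            [None] + list(range(11)))
        with pytest.raises(ValueError, match="constant"):
            dependent_permutation_test(recs, build_forest(recs), "x", "y",
                                       XY_CAT, r_replicates=199)

    def test_too_few_replicates_rejected(self, toy_chain_records):
        recs, forest, _, _ = toy_chain_records
        with pytest.raises(ValueError):
            dependent_permutation_test(recs, forest, "x", "y", XY_CAT,
                                       r_replicates=50)

    def test_p_values_uniform_under_iid_null(self):
        """Kolmogorov-Smirnov check of null p-value uniformity."""
        n = 150
        parents = [None if i < 10 else (i - 10) // 2 for i in range(n)]
        recs = make_records(np.zeros(n, int), np.zeros(n, int), parents)
        forest = build_forest(recs)
        frame = records_to_frame(recs, XY_CAT)
        rng = np.random.default_rng(19)
        ps = []
        for _ in range(500):
            frame["x"] = (rng.random(n) < 0.5).astype(float)
            frame["y"] = (rng.random(n) < 0.4).astype(float)
            ps.append(dependent_permutation_test(
                frame, forest, "x", "y", XY_CAT, r_replicates=199,
                rng=rng).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestMultipleOverdoseModel:
    def make_frame(self, n, rng, beta=1.2):
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.4).astype(float)
        x3 = (rng.random(n) < 0.5).astype(float)
        logit = -0.8 + beta * x1 + beta * x2
        rep = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(n)],
            "recruiter_id": [None] * n, "degree": 5.0,
            "x1": x1, "x2": x2, "x3": x3, "repeat": rep})

    CAT = VariableCatalogue(
        [Variable("x1"), Variable("x2"), Variable("x3"), Variable("repeat")])

    def test_pathway_runs_end_to_end(self):
        frame = self.make_frame(300, np.random.default_rng(20))
        out = multiple_overdose_model(frame, "repeat", self.CAT,
                                      correlates=["x1", "x2", "x3"])
        assert out["n_subsample"] == 300
        assert out["multivariable"] is not None

    def test_constant_recoded_outcome_rejected(self):
        frame = self.make_frame(100, np.random.default_rng(21))
        frame["repeat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            multiple_overdose_model(frame, "repeat", self.CAT,
                                    correlates=["x1"])

    def test_true_drivers_recovered_with_power(self):
        """The two real predictors reach p<0.05 in >=80% of replicates."""
        rng = np.random.default_rng(22)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            frame = self.make_frame(1000, rng, beta=0.8)
            out = multiple_overdose_model(
                frame, "repeat", self.CAT, correlates=["x1", "x2", "x3"],
                comparator="lt")
            if {"x1", "x2"} <= set(out["selected"]):
                hits += 1
        assert hits / n_rep >= 0.8
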