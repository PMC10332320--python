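"""Successive-sampling weights, proportions, bootstrap SE, N-sensitivity."""

import numpy as np
import pandas as pd
import pytest

from rdsinfer import (
    RespondentRecord,
    SSConfig,
    Variable,
    VariableCatalogue,
    build_forest,
    records_to_frame,
    sensitivity_to_N,
    ss_bootstrap_se,
    ss_proportion,
    ss_weights,
)

CAT = VariableCatalogue([Variable("a")])


class TestSsWeights:
    @pytest.mark.parametrize("n_pop", [500, 5000])
    def test_equal_degrees_give_equal_weights(self, n_pop):
        res = ss_weights(np.full(80, 6.0),
                         SSConfig(N=n_pop, n_inner_simulations=100),
                         rng=np.random.default_rng(1))
        assert np.allclose(res.weights, 1 / 80)
        assert res.converged

    def test_census_boundary_all_inclusion_probabilities_one(self):
        res = ss_weights([1, 2, 3, 4, 5],
                         SSConfig(N=5, n_inner_simulations=100),
                         rng=np.random.default_rng(2))
        assert np.allclose(res.pi_by_class, 1.0)
        assert np.allclose(res.weights, 0.2)
        assert res.near_census

    def test_near_census_flagged_and_runs(self):
        res = ss_weights([2, 4, 6, 8], SSConfig(N=5, n_inner_simulations=100),
                         rng=np.random.default_rng(3))
        assert res.near_census

    def test_weights_monotone_nonincreasing_in_degree(self, study_bundle):
        frame = records_to_frame(study_bundle.records, study_bundle.catalogue)
        deg = frame["degree"].dropna().to_numpy()
        res = ss_weights(deg, SSConfig(N=15000, n_inner_simulations=200,
                                       max_iterations=4),
                         rng=np.random.default_rng(4))
        order = np.argsort(deg)
        w_sorted = res.weights[order]
        assert (np.diff(w_sorted) <= 1e-12).all()

    def test_invalid_degrees_rejected(self):
        with pytest.raises(ValueError):
            ss_weights([3.0, np.nan, 2.0], SSConfig(N=100))
        with pytest.raises(ValueError):
            ss_weights([0.0, 2.0], SSConfig(N=100))
        with pytest.raises(ValueError):
            ss_weights(np.arange(1, 60, dtype=float), SSConfig(N=50))


class TestSsProportion:
    def make_frame(self):
        return pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(6)],
            "recruiter_id": [None] * 6,
            "degree": [2.0, 3.0, 4.0, 2.0, 6.0, 3.0],
            "a": [1.0, 0.0, 1.0, np.nan, 0.0, 1.0],
        })

    def test_equal_weights_recover_sample_proportion(self):
        frame = self.make_frame()
        w = np.full(6, 1 / 6)
        assert ss_proportion(frame, "a", 1, w) == pytest.approx(3 / 5)

    def test_levels_sum_to_one(self):
        frame = self.make_frame()
        w = np.array([0.3, 0.1, 0.2, 0.1, 0.2, 0.1])
        total = (ss_proportion(frame, "a", 1, w)
                 + ss_proportion(frame, "a", 0, w))
        assert total == pytest.approx(1.0)

    def test_respondent_missing_on_variable_is_irrelevant(self):
        frame = self.make_frame()
        w = np.array([0.3, 0.1, 0.2, 0.1, 0.2, 0.1])
        p_all = ss_proportion(frame, "a", 1, w)
        sub = frame[frame["a"].notna()].reset_index(drop=True)
        p_sub = ss_proportion(sub, "a", 1, w[frame["a"].notna().to_numpy()])
        assert p_all == pytest.approx(p_sub)

    def test_degenerate_single_weight(self):
        frame = self.make_frame()
        w = np.array([1.0, 0, 0, 0, 0, 0])
        assert ss_proportion(frame, "a", 1, w) == pytest.approx(1.0)

    def test_all_missing_rejected(self):
        frame = self.make_frame()
        frame["a"] = np.nan
        with pytest.raises(ValueError):
            ss_proportion(frame, "a", 1, np.full(6, 1 / 6))


class TestBootstrapSe:
    def make_sample(self):
        recs = []
        rng = np.random.default_rng(5)
        for s in range(6):
            recs.append(RespondentRecord(
                f"s{s}", None, int(rng.integers(1, 9)), {"a": 1}))
            for c in range(3):
                recs.append(RespondentRecord(
                    f"c{s}{c}", f"s{s}", int(rng.integers(1, 9)), {"a": 1}))
        return recs, build_forest(recs)

    def test_constant_variable_has_zero_se(self):
        recs, forest = self.make_sample()
        se = ss_bootstrap_se(
            recs, forest, "a", 1,
            SSConfig(N=500, n_inner_simulations=60, max_iterations=2, B=20),
            CAT, rng=np.random.default_rng(6))
        assert se == pytest.approx(0.0)

    def test_too_few_replicates_rejected(self):
        recs, forest = self.make_sample()
        with pytest.raises(ValueError):
            ss_bootstrap_se(recs, forest, "a", 1,
                            SSConfig(N=500, B=1), CAT)

    def test_single_tree_warns(self):
        recs = [RespondentRecord("s", None, 3, {"a": 1}),
                RespondentRecord("c", "s", 5, {"a": 0}),
                RespondentRecord("d", "s", 2, {"a": 1})]
        forest = build_forest(recs)
        with pytest.warns(UserWarning, match="single-tree"):
            ss_bootstrap_se(recs, forest, "a", 1,
                            SSConfig(N=100, n_inner_simulations=50,
                                     max_iterations=2, B=10),
                            CAT, rng=np.random.default_rng(7))


class TestSensitivityToN:
    def test_equal_degrees_invariant_across_N(self):
        frame = pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(40)],
            "recruiter_id": [None] * 40,
            "degree": np.full(40, 5.0),
            "a": (np.arange(40) % 3 == 0).astype(float),
        })
        out = sensitivity_to_N(frame, "a", 1, [100, 1000, 10000],
                               SSConfig(n_inner_simulations=80,
                                        max_iterations=2),
                               rng=np.random.default_rng(8))
        assert out.attrs["max_spread"] == pytest.approx(0.0)

    def test_near_census_grid_point_flagged(self):
        frame = pd.DataFrame({
            "respondent_id": ["r0", "r1", "r2"],
            "recruiter_id": [None] * 3,
            "degree": [2.0, 4.0, 8.0],
            "a": [1.0, 0.0, 1.0],
        })
        out = sensitivity_to_N(frame, "a", 1, [3, 400],
                               SSConfig(n_inner_simulations=80,
                                        max_iterations=2),
                               rng=np.random.default_rng(9))
        assert bool(out.loc[out["N"] == 3, "near_census"].iloc[0])
        assert not bool(out.loc[out["N"] == 400, "near_census"].iloc[0])

    def test_study_fixture_estimates_insensitive_to_working_N(
            self, study_bundle):
        frame = records_to_frame(study_bundle.records, study_bundle.catalogue)
        deg = frame["degree"].to_numpy()
        deg = np.where(np.isnan(deg), np.nanmedian(deg), deg)
        out = sensitivity_to_N(
            frame, "ever_overdose", 1, [10000, 15000, 30000],
            SSConfig(n_inner_simulations=300, max_iterations=4),
            degrees=deg, rng=np.random.default_rng(10))
        assert out.attrs["max_spread"] < 0.02
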