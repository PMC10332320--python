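"""Ground-truth generator: degree/homophily control and RDS recruitment."""

import numpy as np
import pytest

from rdsinfer import (
    OutcomeModel,
    PopulationSpec,
    RDSSampleSpec,
    TraitSpec,
    edge_concordance,
    generate_population,
    simulate_rds,
    study_shaped_fixture,
)


class TestGeneratePopulation:
    def test_no_homophily_matches_independence_concordance(self):
        spec = PopulationSpec(population_size=4000, traits=(
            TraitSpec("t", prevalence=0.3),), random_seed=3)
        world = generate_population(spec)
        c0 = 0.3 ** 2 + 0.7 ** 2
        assert abs(edge_concordance(world.edges, world.traits["t"]) - c0) < 0.02

    def test_null_outcome_model_gives_half_prevalence(self):
        spec = PopulationSpec(
            population_size=4000, traits=(TraitSpec("t", prevalence=0.4),),
            outcome_model=OutcomeModel(intercept=0.0, coef={}), random_seed=4)
        world = generate_population(spec)
        assert abs(world.outcome.mean() - 0.5) < 0.03

    def test_realized_degrees_positive_no_self_or_multi_edges(self):
        spec = PopulationSpec(population_size=2000, random_seed=5)
        world = generate_population(spec)
        assert world.degrees.min() >= 1
        assert (world.edges[:, 0] != world.edges[:, 1]).all()
        assert len(np.unique(world.edges, axis=0)) == len(world.edges)

    def test_homophily_monotone_in_weight(self):
        concs = []
        for h in (0.0, 0.5, 1.5, 4.0):
            spec = PopulationSpec(population_size=3000, traits=(
                TraitSpec("t", prevalence=0.5, homophily=h),), random_seed=6)
            world = generate_population(spec)
            concs.append(edge_concordance(world.edges, world.traits["t"]))
        assert all(b > a for a, b in zip(concs, concs[1:]))

    def test_hcv_prevalence_emulation_target(self, study_bundle):
        # the survey's antibody-positive share is the fixture's target
        assert abs(study_bundle.world.realized_prevalence["hcv_positive"]
                   - 0.196) < 0.01

    def test_identical_seeds_identical_worlds(self):
        spec = PopulationSpec(population_size=1500, traits=(
            TraitSpec("t", prevalence=0.4, homophily=1.0),), random_seed=11)
        w1, w2 = generate_population(spec), generate_population(spec)
        assert np.array_equal(w1.edges, w2.edges)
        assert np.array_equal(w1.traits["t"], w2.traits["t"])


@pytest.fixture(scope="module")
def world():
    return generate_population(PopulationSpec(
        population_size=2000,
        traits=(TraitSpec("t", prevalence=0.3, homophily=0.8),),
        random_seed=7))


class TestSimulateRds:

    def test_zero_acceptance_returns_exactly_the_seeds(self, world):
        sample = simulate_rds(world, RDSSampleSpec(
            n_target=100, n_seeds=15, referral_acceptance=0.0, random_seed=1))
        assert len(sample.records) == 15
        assert sample.truth["exhausted"]
        assert all(r.recruiter_id is None for r in sample.records)

    def test_no_respondent_sampled_twice_and_coupon_limit_held(self, world):
        sample = simulate_rds(world, RDSSampleSpec(
            n_target=300, n_seeds=10, random_seed=2))
        ids = [r.respondent_id for r in sample.records]
        assert len(set(ids)) == len(ids)
        assert len(set(sample.truth["nodes"])) == len(sample.truth["nodes"])
        assert all(len(k) <= 3 for k in sample.forest.children.values())

    def test_reseeding_flagged_when_chains_die(self, world):
        sample = simulate_rds(world, RDSSampleSpec(
            n_target=60, n_seeds=5, referral_acceptance=0.05,
            reseed_on_exhaustion=True, random_seed=3))
        assert len(sample.records) == 60
        assert sample.truth["reseeds"] > 0

    def test_identical_seeds_identical_samples(self, world):
        spec = RDSSampleSpec(n_target=150, n_seeds=10, random_seed=9)
        s1, s2 = simulate_rds(world, spec), simulate_rds(world, spec)
        assert s1.records == s2.records


class TestStudyShapedFixture:
    def test_sample_size_and_seed_count(self, study_bundle):
        assert len(study_bundle.records) == 539
        assert len(study_bundle.forest.roots) == 20

    def test_outcome_prevalence_near_study_value(self, study_bundle):
        vals = np.array([r.outcome for r in study_bundle.records], dtype=float)
        assert abs(np.nanmean(vals) - 0.439) < 0.03

    def test_population_outcome_prevalence_calibrated(self, study_bundle):
        assert abs(study_bundle.world.realized_prevalence["__outcome__"]
                   - 0.439) <= 1e-3

    def test_degree_missingness_applied(self, study_bundle):
        frac = np.mean([r.degree is None for r in study_bundle.records])
        assert 0.05 < frac < 0.18


def test_covariate_dependent_missingness_tilts_rates():
    spec = PopulationSpec(
        population_size=4000,
        traits=(TraitSpec("t", prevalence=0.5),),
        missing_degree_rate=0.2, missing_degree_covariate="t",
        missing_degree_odds=3.0, random_seed=21)
    world = generate_population(spec)
    sample = simulate_rds(world, RDSSampleSpec(
        n_target=1500, n_seeds=20, random_seed=22))
    miss = np.array([r.degree is None for r in sample.records])
    flag = np.array([r.covariates["t"] == 1 for r in sample.records])
    rate1 = miss[flag].mean()
    rate0 = miss[~flag].mean()
    assert rate1 > 2 * rate0
    assert abs(miss.mean() - 0.2) < 0.05
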