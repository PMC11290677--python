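import itertools
import math

import numpy as np
import pandas as pd
import pytest

from surveyopt import (
    Combination,
    Community,
    CostModel,
    EnumerationCapError,
    OptimizerConfig,
    SampleMatrix,
    alpha,
    beta_bias,
    beta_pair,
    expected_alpha_proportion,
    optim_alpha_exhaustive,
    optim_alpha_nested,
    optim_beta,
    planted_optimum_scenario,
    simulate_survey,
    star_tree,
    true_alpha,
)
from surveyopt.optimizer import _AlphaEngine, _BetaEngine

from conftest import toy_samples


# ---------------------------------------------------------------------------
# independent brute-force oracles (set arithmetic + direct diversity calls)


def _site_subset_unions(data, site, comb):
    per_method = []
    for m, n in comb.counts.items():
        samples = data.sample_species(site, m)
        per_method.append(
            [frozenset().union(*rows) if rows else frozenset() for rows in itertools.combinations(samples, n)]
        )
    return [
        frozenset().union(*parts) if parts else frozenset()
        for parts in itertools.product(*per_method)
    ]


def brute_alpha_expectation(comb, data, tree):
    props = []
    for site in data.sites:
        true = alpha(data.pooled_community(site), tree)
        unions = _site_subset_unions(data, site, comb)
        props.append(np.mean([alpha(Community(u), tree) / true for u in unions]))
    return float(np.mean(props))


def brute_beta_bias(comb, data, tree):
    pooled = [data.pooled_community(s) for s in data.sites]
    pairs = list(itertools.combinations(range(len(pooled)), 2))
    true = {p: beta_pair(pooled[p[0]], pooled[p[1]], tree) for p in pairs}
    per_site = [_site_subset_unions(data, s, comb) for s in data.sites]
    biases = []
    for assignment in itertools.product(*per_site):
        comms = [Community(u) for u in assignment]
        devs = []
        for p in pairs:
            sampled = beta_pair(comms[p[0]], comms[p[1]], tree)
            devs.extend(abs(s - t) for s, t in zip(sampled, true[p]))
        biases.append(np.mean(devs))
    return float(np.mean(biases))


@pytest.fixture
def abcde_tree():
    return star_tree(list("abcde"))


@pytest.fixture
def two_site_survey():
    return toy_samples(
        [
            ("s1", "site1", "A", ["a", "b"]),
            ("s2", "site1", "A", ["b"]),
            ("s3", "site1", "B", ["c"]),
            ("s4", "site1", "B", ["c", "d"]),
            ("s5", "site2", "A", ["a"]),
            ("s6", "site2", "A", ["a", "e"]),
            ("s7", "site2", "B", ["d", "e"]),
            ("s8", "site2", "B", ["d"]),
        ]
    )


class TestSampleMatrix:
    def test_duplicate_sample_species_rejected(self):
        frame = pd.DataFrame(
            [("s1", "x", "A", "a", 1), ("s1", "x", "A", "a", 2)],
            columns=["sample_id", "site", "method", "species", "abundance"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            SampleMatrix(frame)

    def test_negative_abundance_rejected(self):
        frame = pd.DataFrame(
            [("s1", "x", "A", "a", -1)],
            columns=["sample_id", "site", "method", "species", "abundance"],
        )
        with pytest.raises(ValueError, match="negative"):
            SampleMatrix(frame)

    def test_conflicting_sample_tags_rejected(self):
        frame = pd.DataFrame(
            [("s1", "x", "A", "a", 1), ("s1", "y", "A", "b", 1)],
            columns=["sample_id", "site", "method", "species", "abundance"],
        )
        with pytest.raises(ValueError, match="more than one"):
            SampleMatrix(frame)

    def test_max_combination_minimum_over_sites(self, two_site_survey):
        assert two_site_survey.max_combination().counts == {"A": 2, "B": 2}


class TestTrueAlpha:
    def test_pooled_site_diversity(self, two_method_survey, abcde_tree):
        # pooled site1 community is {a..e} on a unit star tree
        assert true_alpha(two_method_survey, "site1", abcde_tree) == pytest.approx(5.0)

    def test_agrees_with_manual_pooling(self, two_site_survey, abcde_tree):
        manual = Community({"a", "b", "c", "d"})
        assert true_alpha(two_site_survey, "site1", abcde_tree) == pytest.approx(
            alpha(manual, abcde_tree)
        )

    def test_unknown_site_rejected(self, two_method_survey, abcde_tree):
        with pytest.raises(KeyError):
            true_alpha(two_method_survey, "nowhere", abcde_tree)


class TestExpectedAlphaProportion:
    def test_complete_allocation_reaches_one(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0)
        comb = two_site_survey.max_combination()
        assert expected_alpha_proportion(comb, two_site_survey, abcde_tree, cfg) == pytest.approx(1.0)

    def test_empty_allocation_zero(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0)
        comb = Combination({"A": 0, "B": 0})
        assert expected_alpha_proportion(comb, two_site_survey, abcde_tree, cfg) == 0.0

    def test_oversized_allocation_rejected(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0)
        with pytest.raises(ValueError, match="available"):
            expected_alpha_proportion(Combination({"A": 3}), two_site_survey, abcde_tree, cfg)

    @pytest.mark.parametrize("na,nb", [(1, 0), (1, 1), (2, 1), (0, 2)])
    def test_exact_mode_matches_brute_force(self, two_site_survey, abcde_tree, na, nb):
        cfg = OptimizerConfig(runs=10, seed=0, exact_threshold=100)
        comb = Combination({"A": na, "B": nb})
        got = expected_alpha_proportion(comb, two_site_survey, abcde_tree, cfg)
        assert got == pytest.approx(brute_alpha_expectation(comb, two_site_survey, abcde_tree))

    def test_monte_carlo_within_three_se_of_exact(self, two_site_survey, abcde_tree):
        comb = Combination({"A": 1, "B": 1})
        exact = brute_alpha_expectation(comb, two_site_survey, abcde_tree)
        cfg = OptimizerConfig(runs=4000, seed=7, exact_threshold=0)
        mean, se = _AlphaEngine(two_site_survey, abcde_tree, cfg).score(comb)
        assert abs(mean - exact) <= 3 * se + 1e-12


class TestOptimAlphaExhaustive:
    def test_single_method_takes_all_affordable(self, abcde_tree):
        data = toy_samples(
            [
                ("s1", "site1", "A", ["a"]),
                ("s2", "site1", "A", ["a", "b"]),
                ("s3", "site1", "A", ["c"]),
            ]
        )
        cfg = OptimizerConfig(runs=50, seed=0)
        res = optim_alpha_exhaustive(data, abcde_tree, CostModel.uniform(["A"]), cfg)
        costs = [e.cost for e in res.entries]
        assert costs == sorted(set(costs))
        for e in res.entries:
            assert e.combination["A"] == int(e.cost)  # unit variable cost
        values = [e.value for e in res.entries]
        assert values == sorted(values)

    def test_matches_brute_force_winner_per_cost(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0, exact_threshold=1000)
        cm = CostModel.uniform(["A", "B"])
        res = optim_alpha_exhaustive(two_site_survey, abcde_tree, cm, cfg)
        for entry in res.entries:
            n = int(entry.cost)
            best = max(
                (
                    brute_alpha_expectation(Combination({"A": a, "B": n - a}), two_site_survey, abcde_tree)
                    for a in range(max(0, n - 2), min(2, n) + 1)
                ),
                default=0.0,
            )
            assert entry.value == pytest.approx(best)

    def test_empty_pool_equals_unconstrained(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=20, seed=1)
        cm = CostModel.uniform(["A", "B"])
        r1 = optim_alpha_exhaustive(two_site_survey, abcde_tree, cm, cfg, pool=None)
        r2 = optim_alpha_exhaustive(two_site_survey, abcde_tree, cm, cfg, pool=Combination({}))
        pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())

    def test_pool_constrains_candidates(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=20, seed=1)
        cm = CostModel.uniform(["A", "B"])
        res = optim_alpha_exhaustive(
            two_site_survey, abcde_tree, cm, cfg, pool=Combination({"B": 1})
        )
        assert (res.evaluated["B"] >= 1).all()

    def test_enumeration_cap(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=5, seed=0, enumeration_cap=3)
        with pytest.raises(EnumerationCapError, match="nested"):
            optim_alpha_exhaustive(two_site_survey, abcde_tree, CostModel.uniform(["A", "B"]), cfg)

    def test_deterministic_given_seed(self, two_site_survey, abcde_tree):
        cm = CostModel.uniform(["A", "B"])
        frames = [
            optim_alpha_exhaustive(
                two_site_survey, abcde_tree, cm, OptimizerConfig(runs=64, seed=5, exact_threshold=0)
            ).to_frame()
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(frames[0], frames[1])


class TestOptimAlphaNested:
    def test_single_method_sequence(self, abcde_tree):
        data = toy_samples(
            [("s1", "site1", "A", ["a"]), ("s2", "site1", "A", ["b"])]
        )
        cfg = OptimizerConfig(runs=10, seed=0)
        res = optim_alpha_nested(data, abcde_tree, CostModel.uniform(["A"]), cfg)
        assert [e.method_added for e in res.entries[1:]] == ["A", "A"]

    def test_accumulation_monotone_and_complete(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=200, seed=3, exact_threshold=0)  # force Monte Carlo
        res = optim_alpha_nested(two_site_survey, abcde_tree, CostModel.uniform(["A", "B"]), cfg)
        values = [e.value for e in res.entries]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0)

    def test_greedy_never_beats_exhaustive(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0, exact_threshold=1000)
        cm = CostModel.uniform(["A", "B"])
        exh = {e.cost: e.value for e in optim_alpha_exhaustive(two_site_survey, abcde_tree, cm, cfg).entries}
        nested = optim_alpha_nested(two_site_survey, abcde_tree, cm, cfg)
        for e in nested.entries:
            assert e.value <= exh[e.cost] + 1e-12

    def test_too_many_steps_rejected(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0)
        with pytest.raises(ValueError, match="remaining"):
            optim_alpha_nested(
                two_site_survey, abcde_tree, CostModel.uniform(["A", "B"]), cfg, steps=99
            )


class TestPlantedScenario:
    def test_recovers_planted_optimum(self):
        cfg, expected = planted_optimum_scenario(budget=2, seed=42)
        survey = simulate_survey(cfg)
        ocfg = OptimizerConfig(runs=200, seed=42)
        res = optim_alpha_exhaustive(
            survey.samples, survey.tree, CostModel.uniform(survey.samples.methods), ocfg
        )
        assert res.best(budget=2).combination.counts == expected.counts

    def test_first_greedy_pick_covers_large_clade(self):
        cfg, _ = planted_optimum_scenario(budget=2, seed=11)
        survey = simulate_survey(cfg)
        ocfg = OptimizerConfig(runs=200, seed=11)
        res = optim_alpha_nested(
            survey.samples, survey.tree, CostModel.uniform(survey.samples.methods), ocfg, steps=1
        )
        # method_a exclusively detects the clade carrying 75% of tree length
        assert res.entries[1].method_added == "method_a"


class TestRandomProtocolEnvelope:
    def test_envelope_brackets_effort_extremes(self, two_site_survey, abcde_tree):
        from surveyopt import random_protocol_envelope

        cfg = OptimizerConfig(runs=50, seed=0)
        env = random_protocol_envelope(
            two_site_survey, abcde_tree, CostModel.uniform(["A", "B"]), cfg, n_random=30
        )
        assert list(env["effort"]) == [0, 1, 2, 3, 4]
        assert (env["lower"] <= env["median"]).all()
        assert (env["median"] <= env["upper"]).all()
        assert env.loc[0, "upper"] == pytest.approx(0.0)
        assert env.loc[4, "lower"] == pytest.approx(1.0)  # complete sampling

    def test_optimized_curve_at_least_median_random(self, two_site_survey, abcde_tree):
        from surveyopt import random_protocol_envelope

        cfg = OptimizerConfig(runs=50, seed=1)
        cm = CostModel.uniform(["A", "B"])
        env = random_protocol_envelope(two_site_survey, abcde_tree, cm, cfg, n_random=30)
        res = optim_alpha_exhaustive(two_site_survey, abcde_tree, cm, cfg)
        for e in res.entries:
            assert e.value >= env.loc[int(e.cost), "median"] - 1e-9


class TestBetaBias:
    def test_complete_allocation_no_bias(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=20, seed=0)
        comb = two_site_survey.max_combination()
        assert beta_bias(comb, two_site_survey, abcde_tree, cfg) == pytest.approx(0.0)

    def test_identical_sites_bias_is_mean_sampled_beta(self, abcde_tree):
        data = toy_samples(
            [
                ("s1", "site1", "A", ["a", "b"]),
                ("s2", "site1", "A", ["c"]),
                ("s3", "site2", "A", ["a", "b"]),
                ("s4", "site2", "A", ["c"]),
            ]
        )
        cfg = OptimizerConfig(runs=50, seed=1)
        bias = beta_bias(Combination({"A": 1}), data, abcde_tree, cfg)
        assert bias >= 0.0
        assert bias == pytest.approx(brute_beta_bias(Combination({"A": 1}), data, abcde_tree))

    def test_single_site_rejected(self, two_method_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0)
        with pytest.raises(ValueError, match="2 sites"):
            beta_bias(Combination({"A": 1}), two_method_survey, abcde_tree, cfg)

    def test_exact_matches_brute_force(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0, exact_threshold=10_000)
        comb = Combination({"A": 1, "B": 1})
        got = beta_bias(comb, two_site_survey, abcde_tree, cfg)
        assert got == pytest.approx(brute_beta_bias(comb, two_site_survey, abcde_tree))

    def test_monte_carlo_within_three_se_of_exact(self, two_site_survey, abcde_tree):
        comb = Combination({"A": 1, "B": 1})
        exact = brute_beta_bias(comb, two_site_survey, abcde_tree)
        cfg = OptimizerConfig(runs=4000, seed=9, exact_threshold=0)
        mean, se = _BetaEngine(two_site_survey, abcde_tree, cfg).score(comb)
        assert abs(mean - exact) <= 3 * se + 1e-12


class TestOptimBeta:
    def test_full_combination_reaches_efficiency_one(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=20, seed=0)
        cm = CostModel.uniform(["A", "B"])
        res = optim_beta(two_site_survey, abcde_tree, cm, cfg)
        assert res.entries[-1].value == pytest.approx(1.0)
        for e in res.entries:
            assert -1e-12 <= e.value <= 1 + 1e-12

    def test_matches_brute_force_winner_per_cost(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=10, seed=0, exact_threshold=10_000)
        cm = CostModel.uniform(["A", "B"])
        res = optim_beta(two_site_survey, abcde_tree, cm, cfg)
        for entry in res.entries:
            n = int(entry.cost)
            best = min(
                (
                    brute_beta_bias(Combination({"A": a, "B": n - a}), two_site_survey, abcde_tree)
                    for a in range(max(0, n - 2), min(2, n) + 1)
                ),
                default=0.0,
            )
            assert entry.value == pytest.approx(1.0 - best)

    def test_nested_mode_runs(self, two_site_survey, abcde_tree):
        cfg = OptimizerConfig(runs=30, seed=2)
        res = optim_beta(
            two_site_survey, abcde_tree, CostModel.uniform(["A", "B"]), cfg, mode="nested", steps=2
        )
        assert len(res.entries) == 3
        assert res.mode == "nested"
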