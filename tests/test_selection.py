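import itertools
import math

import numpy as np
import pytest

from episelect import (
    CoverageState,
    Experiment,
    ExperimentSet,
    SelectionConfig,
    SimilarityContainer,
    brute_force_optimum,
    facility_location_value,
    greedy_select,
    marginal_gain,
    mixture_objective_value,
)
from episelect.synthetic import generate_block_similarity
from tests.conftest import random_similarity

PHI3 = SimilarityContainer(
    np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]]),
    ExperimentSet([Experiment("B1", "A1"), Experiment("B1", "A2"), Experiment("B2", "A1")]),
)


class TestFacilityLocationValue:
    def test_hand_computed_column_maxima(self):
        assert facility_location_value([0], PHI3) == pytest.approx(1.7)
        assert facility_location_value([0, 2], PHI3) == pytest.approx(2.5)

    def test_empty_set_is_zero(self):
        assert facility_location_value([], PHI3) == 0.0

    def test_all_ones_matrix_saturates_at_ground_size(self):
        n = 77
        exps = ExperimentSet([Experiment("B", f"A{i}") for i in range(n)])
        sim = SimilarityContainer(np.ones((n, n)), exps)
        for X in ([0], [3, 9], list(range(n))):
            assert facility_location_value(X, sim) == pytest.approx(n)

    def test_unknown_member_rejected(self):
        with pytest.raises(ValueError):
            facility_location_value([5], PHI3)

    def test_weights_scale_coverage(self):
        w = np.array([2.0, 1.0, 1.0])
        assert facility_location_value([0], PHI3, w) == pytest.approx(2 * 1.7)


class TestMixtureObjective:
    def test_shared_assay_penalty_squares_counts(self):
        # experiments 0 and 2 share assay A1: ||a||^2 = 4; 0 and 1 span
        # two assays: 1 + 1 = 2
        cfg = SelectionConfig(lambda_a=1.0)
        fl = facility_location_value([0, 2], PHI3)
        assert mixture_objective_value([0, 2], PHI3, config=cfg) == pytest.approx(
            fl + 4.0 + 0.0
        )
        fl2 = facility_location_value([0, 1], PHI3)
        assert mixture_objective_value([0, 1], PHI3, config=cfg) == pytest.approx(
            fl2 + 2.0
        )

    def test_zero_lambdas_reduce_to_facility_location(self):
        cfg = SelectionConfig(lambda_a=0.0, lambda_b=0.0)
        for X in ([], [0], [0, 1, 2]):
            assert mixture_objective_value(X, PHI3, config=cfg) == pytest.approx(
                facility_location_value(X, PHI3)
            )

    def test_count_term_gain_is_2a_plus_1(self):
        # adding a third same-assay experiment to a count of 2 gains
        # (2+1)^2 - 2^2 = 5 in the count term
        n = 3
        exps = ExperimentSet([Experiment(f"B{i}", "A") for i in range(n)])
        sim = SimilarityContainer(np.eye(n), exps)
        cfg = SelectionConfig(lambda_a=1.0)
        two = mixture_objective_value([0, 1], sim, config=cfg)
        three = mixture_objective_value([0, 1, 2], sim, config=cfg)
        assert (three - two) == pytest.approx(1.0 + 5.0)  # coverage 1 + counts 5

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(lambda_a=-0.1)


class TestMarginalGain:
    def test_empty_state_gain_is_weighted_row_sum(self):
        state = CoverageState(PHI3)
        assert state.gain(0) == pytest.approx(PHI3.values[0].sum())

    def test_duplicate_candidate_has_zero_gain(self):
        sim = random_similarity(6, seed=0)
        state = CoverageState(sim)
        state.add(2)
        assert state.gain(2) == pytest.approx(0.0, abs=1e-12)

    def test_already_selected_rejected(self):
        state = CoverageState(PHI3)
        state.add(0)
        with pytest.raises(ValueError):
            marginal_gain(0, state)

    @pytest.mark.parametrize("lambda_a,lambda_b", [(0.0, 0.0), (0.7, 0.3)])
    def test_matches_from_scratch_difference(self, lambda_a, lambda_b):
        """Incremental gains equal objective differences recomputed from
        scratch on a random 8x8 instance."""
        sim = random_similarity(8, seed=11)
        cfg = SelectionConfig(lambda_a=lambda_a, lambda_b=lambda_b)
        rng = np.random.default_rng(5)
        w = rng.uniform(0.2, 2.0, 8)
        state = CoverageState(sim, w, cfg)
        chosen: list[int] = []
        for x in [3, 0, 6, 2]:
            before = mixture_objective_value(chosen, sim, w, cfg)
            after = mixture_objective_value(chosen + [x], sim, w, cfg)
            assert state.gain(x) == pytest.approx(after - before, abs=1e-9)
            state.add(x)
            chosen.append(x)


class TestGreedySelect:
    def test_k0_returns_seeded_baseline(self):
        sim = random_similarity(6, seed=1)
        res = greedy_select(sim, SelectionConfig(k=0), seeds=[1, 4])
        assert len(res.selected) == 0
        assert res.seeds.tolist() == [1, 4]

    def test_two_block_matrix_selects_one_per_block(self):
        sim = generate_block_similarity([4, 4], within=0.9, between=0.1)
        res = greedy_select(sim, SelectionConfig(k=2))
        blocks = {sim.experiments[i].assay for i in res.indices}
        assert blocks == {"block0", "block1"}
        best, _ = brute_force_optimum(sim, k=2)
        assert {sim.experiments[i].assay for i in best} == {"block0", "block1"}

    def test_lazy_requires_zero_lambdas(self):
        sim = random_similarity(6, seed=2)
        with pytest.raises(ValueError, match="lazy"):
            greedy_select(sim, SelectionConfig(k=2, lambda_a=0.5, engine="lazy"))

    def test_k_exceeding_candidates_rejected(self):
        sim = random_similarity(4, seed=3)
        with pytest.raises(ValueError, match="exceeds"):
            greedy_select(sim, SelectionConfig(k=4), seeds=[0])

    def test_duplicate_seeds_rejected(self):
        sim = random_similarity(4, seed=3)
        with pytest.raises(ValueError, match="duplicate"):
            greedy_select(sim, SelectionConfig(k=1), seeds=[0, 0])

    def test_seeds_excluded_from_ranking(self):
        sim = random_similarity(10, seed=4)
        res = greedy_select(sim, SelectionConfig(k=5), seeds=[0, 1, 2])
        assert not set(res.indices) & {0, 1, 2}
        assert len(set(res.indices.tolist())) == 5

    def test_monotone_objective_for_nonnegative_weights(self):
        sim = random_similarity(12, seed=5)
        rng = np.random.default_rng(6)
        w = rng.uniform(0.0, 3.0, 12)
        res = greedy_select(sim, SelectionConfig(k=12), w=w)
        assert (np.diff(res.objectives) >= -1e-12).all()
        assert (res.gains >= -1e-12).all()

    def test_candidate_similar_to_seed_gets_near_zero_gain(self):
        # duplicate rows: candidate 1 is a copy of seed 0
        m = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]])
        exps = ExperimentSet([Experiment(f"B{i}", "A") for i in range(3)])
        sim = SimilarityContainer(m, exps)
        state = CoverageState(sim)
        state.add(0)
        assert state.gain(1) == pytest.approx(0.0, abs=1e-12)
        assert state.gain(2) > 0.5


class TestEngineEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_lazy_equals_naive_with_weights_and_seeds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        sim = random_similarity(n, seed=seed + 100)
        w = rng.uniform(0.1, 3.0, n)
        seeds = rng.choice(n, size=rng.integers(0, 3), replace=False)
        k = int(rng.integers(1, n - len(seeds) + 1))
        naive = greedy_select(sim, SelectionConfig(k=k, engine="naive"), seeds, w)
        lazy = greedy_select(sim, SelectionConfig(k=k, engine="lazy"), seeds, w)
        assert naive.indices.tolist() == lazy.indices.tolist()
        assert np.allclose(naive.objectives, lazy.objectives, atol=1e-9)


class TestSubmodularityAndApproximation:
    def test_diminishing_returns_on_random_instances(self):
        """lambda = 0: gain at a subset A is never below the gain at any
        superset B, for random nested pairs."""
        rng = np.random.default_rng(42)
        for trial in range(50):
            n = int(rng.integers(4, 11))
            sim = random_similarity(n, seed=1000 + trial)
            w = rng.uniform(0.0, 2.0, n)
            perm = rng.permutation(n)
            cut_a = int(rng.integers(0, n - 1))
            cut_b = int(rng.integers(cut_a, n - 1))
            A, B = perm[:cut_a], perm[:cut_b]
            x = int(perm[-1])
            gain_a = facility_location_value(
                list(A) + [x], sim, w
            ) - facility_location_value(A, sim, w)
            gain_b = facility_location_value(
                list(B) + [x], sim, w
            ) - facility_location_value(B, sim, w)
            assert gain_a >= gain_b - 1e-9

    def test_supermodular_count_term_grows(self):
        # the concentration term violates diminishing returns by design
        n = 4
        exps = ExperimentSet([Experiment(f"B{i}", "A") for i in range(n)])
        sim = SimilarityContainer(np.eye(n), exps)
        cfg = SelectionConfig(lambda_a=1.0)
        d_small = mixture_objective_value([0, 1], sim, config=cfg) - \
            mixture_objective_value([0], sim, config=cfg)
        d_large = mixture_objective_value([0, 1, 2], sim, config=cfg) - \
            mixture_objective_value([0, 1], sim, config=cfg)
        assert d_large > d_small


class TestBruteForce:
    def test_single_element_ground_set(self):
        sim = random_similarity(1, seed=0)
        best, value = brute_force_optimum(sim, k=1)
        assert best == (0,)
        assert value == pytest.approx(1.0)

    def test_all_ones_returns_lexicographically_first_pair(self):
        exps = ExperimentSet([Experiment(f"B{i}", "A") for i in range(4)])
        sim = SimilarityContainer(np.ones((4, 4)), exps)
        best, value = brute_force_optimum(sim, k=2)
        assert best == (0, 1)
        assert value == pytest.approx(4.0)

    def test_budget_exceeded(self):
        sim = random_similarity(40, seed=0)
        with pytest.raises(ValueError, match="budget"):
            brute_force_optimum(sim, k=20, budget=10**4)

    def test_matches_independent_enumeration(self):
        """Second, independent enumeration over a random 10x10 instance."""
        sim = random_similarity(10, seed=77)
        best, value = brute_force_optimum(sim, k=3)
        expected = max(
            (
                float(sim.values[list(s)].max(axis=0).sum()),
                tuple(sorted(s)),
            )
            for s in itertools.combinations(range(10), 3)
        )
        assert value == pytest.approx(expected[0])
        assert facility_location_value(best, sim) == pytest.approx(expected[0])


def test_greedy_respects_1_minus_1_over_e_bound():
    """Greedy value is at least (1 - 1/e) of the brute-force optimum on
    random instances (spot check; the full sweep runs in acceptance)."""
    bound = 1 - math.exp(-1)
    rng = np.random.default_rng(0)
    for trial in range(20):
        n = int(rng.integers(4, 13))
        k = int(rng.integers(1, 5))
        k = min(k, n)
        sim = random_similarity(n, seed=5000 + trial)
        res = greedy_select(sim, SelectionConfig(k=k, engine="lazy"))
        _, opt = brute_force_optimum(sim, k=k)
        assert res.objectives[-1] >= bound * opt - 1e-9
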