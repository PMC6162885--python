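"""Pareto machinery, scalarization, neighbourhood enumeration, local search
and the restart loop, with brute-force oracles for dominance and the front."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paretoprimer.matching import Evaluator, ScoreVector
from paretoprimer.optimize import (
    ArchiveEntry,
    SearchConfig,
    UserInputError,
    Weights,
    archive_jaccard,
    dominates,
    local_search,
    multi_objective_search,
    neighborhood,
    pareto_front,
    sample_weights,
    scalarize,
    select_initial,
    weighted_score,
)
from paretoprimer.seqcore import PrimerSetPair
from paretoprimer._io import CandidateRecord

from conftest import FWD_A, REV, make_two_variant_refset

score_st = st.tuples(
    st.integers(0, 10), st.integers(0, 4), st.integers(0, 4)
).map(lambda t: ScoreVector(float(t[0]), t[1] / 4.0, t[1], t[2] / 4.0))


def oracle_front_mask(scores: list[ScoreVector]) -> list[bool]:
    """O(n^2) all-pairs dominance oracle, vectorized over numpy arrays."""
    arr = np.array([[s.e, s.c_fraction, s.m] for s in scores])
    n = len(arr)
    better_eq = (
        (arr[:, None, 0] >= arr[None, :, 0])
        & (arr[:, None, 1] >= arr[None, :, 1])
        & (arr[:, None, 2] <= arr[None, :, 2])
    )
    differs = (arr[:, None, :] != arr[None, :, :]).any(axis=2)
    dominated = (better_eq & differs).any(axis=0)
    return [not d for d in dominated]


class TestDominance:
    def test_strictly_better_dominates(self):
        assert dominates(ScoreVector(10, 0.9, 4, 0.2), ScoreVector(9, 0.8, 3, 0.3))

    def test_identical_vectors_do_not_dominate(self):
        a = ScoreVector(10, 0.9, 4, 0.2)
        assert not dominates(a, a)

    def test_incomparable_pair(self):
        a, b = ScoreVector(10, 0.7, 2, 0.2), ScoreVector(9, 0.9, 4, 0.3)
        assert not dominates(a, b) and not dominates(b, a)

    def test_better_in_one_equal_elsewhere_dominates(self):
        a, b = ScoreVector(10, 0.9, 4, 0.2), ScoreVector(10, 0.9, 4, 0.3)
        assert dominates(a, b) and not dominates(b, a)

    @settings(derandomize=True, max_examples=100)
    @given(score_st, score_st, score_st)
    def test_irreflexive_and_transitive(self, a, b, c):
        assert not dominates(a, a)
        if dominates(a, b) and dominates(b, c):
            assert dominates(a, c)


class TestParetoFront:
    def _entries(self, scores):
        pair = PrimerSetPair.of(["ACGTAACGTACGTACGT"], ["TACGTACGTACGTTACG"])
        return [ArchiveEntry(pair, s) for s in scores]

    def test_single_entry_is_its_own_front(self):
        entries = self._entries([ScoreVector(5, 0.5, 2, 0.5)])
        assert pareto_front(entries) == entries

    def test_chain_collapses_to_best(self):
        v1 = ScoreVector(1, 0.1, 1, 0.9)
        v2 = ScoreVector(5, 0.5, 2, 0.5)
        v3 = ScoreVector(9, 0.9, 3, 0.1)
        front = pareto_front(self._entries([v1, v2, v3]))
        assert [e.score for e in front] == [v3]

    def test_duplicate_scores_kept_once_first_occurrence(self):
        s = ScoreVector(5, 0.5, 2, 0.5)
        entries = [
            ArchiveEntry(PrimerSetPair.of([p], ["TACGTACGTACGTTACG"]), s)
            for p in ("ACGTAACGTACGTACGT", "CCGTAACGTACGTACGT")
        ]
        front = pareto_front(entries)
        assert front == [entries[0]]

    def test_empty_archive_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(score_st, min_size=1, max_size=120))
    def test_matches_all_pairs_oracle_and_is_idempotent(self, scores):
        entries = self._entries(scores)
        front = pareto_front(entries)
        mask = oracle_front_mask(scores)
        expected_keys = []
        seen = set()
        for keep, s in zip(mask, scores):
            if keep and s.key not in seen:
                seen.add(s.key)
                expected_keys.append(s.key)
        assert sorted(e.score.key for e in front) == sorted(expected_keys)
        assert pareto_front(front) == front


class TestWeights:
    def test_simplex_invariants_and_determinism(self):
        rng = np.random.default_rng(42)
        draws = [sample_weights(rng) for _ in range(200)]
        for w in draws:
            assert w.e >= 0 and w.c >= 0 and w.m >= 0
            assert w.e + w.c + w.m == pytest.approx(1.0, abs=1e-12)
        rng2 = np.random.default_rng(42)
        assert [sample_weights(rng2) for _ in range(200)] == draws

    def test_componentwise_mean_is_one_third(self):
        rng = np.random.default_rng(7)
        draws = np.array([[*(w.e, w.c, w.m)] for w in (sample_weights(rng) for _ in range(10000))])
        assert np.allclose(draws.mean(axis=0), 1 / 3, atol=0.02)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            Weights(0.5, 0.6, -0.1)
        with pytest.raises(ValueError):
            Weights(0.5, 0.4, 0.2)


class TestScalarization:
    def test_pure_efficiency(self):
        assert scalarize(ScoreVector(10, 0.0, 0, 5.0), Weights(1, 0, 0)) == 1.0

    def test_pure_bias_with_clamp(self):
        assert scalarize(ScoreVector(0, 0.0, 0, 0.0), Weights(0, 0, 1)) == 1.0
        assert scalarize(ScoreVector(0, 0.0, 0, 1.7), Weights(0, 0, 1)) == 0.0

    def test_hand_arithmetic(self):
        sv = ScoreVector(9, 0.6, 3, 0.25)
        w = Weights(1 / 3, 1 / 3, 1 / 3)
        assert scalarize(sv, w) == pytest.approx((0.9 + 0.6 + 0.75) / 3)


class TestNeighborhood:
    def _pair(self, fwd="ACGTAACGTACGTACGTA", rev="TACGTACGTACGTTACGT"):
        return PrimerSetPair.of([fwd], [rev])

    def test_full_count_for_18mer(self):
        neigh = neighborhood(self._pair(), 0, 15, 25)
        assert len(neigh) == 3 * 18 + 8 + 2

    def test_removals_blocked_at_minimum_length(self):
        pair = self._pair(fwd="ACGTAACGTACGTAC")  # 15-mer at the lower bound
        neigh = neighborhood(pair, 0, 15, 25)
        assert len(neigh) == 3 * 15 + 8
        assert all(len(n.forward[0]) >= 15 for n in neigh)

    def test_additions_blocked_at_maximum_length(self):
        fwd = "ACGTAACGTACGTACGTA" + "CCGGATT"  # 25-mer at the upper bound
        neigh = neighborhood(self._pair(fwd=fwd), 0, 15, 25)
        assert len(neigh) == 3 * 25 + 2

    def test_each_neighbour_is_one_edit_away(self):
        pair = self._pair()
        for n in neighborhood(pair, 1, 15, 25):
            assert n.forward == pair.forward
            assert len(n.reverse) == 1
            a, b = pair.reverse[0], n.reverse[0]
            assert a != b and abs(len(a) - len(b)) <= 1

    def test_invalid_index_rejected(self):
        with pytest.raises(IndexError):
            neighborhood(self._pair(), 2)


@pytest.fixture(scope="module")
def evaluator():
    return Evaluator(make_two_variant_refset())


class TestLocalSearch:

    def test_repairs_planted_variant_and_raises_coverage(self, evaluator):
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800)
        start = PrimerSetPair.of([FWD_A], [REV])
        assert evaluator.score(start).c_fraction == 0.5
        weights = Weights(0.2, 0.6, 0.2)
        result = local_search(start, weights, evaluator, cfg)
        assert evaluator.score(result).c_fraction == 1.0
        assert weighted_score(result, weights, evaluator) >= weighted_score(
            start, weights, evaluator
        )

    def test_result_is_a_verified_local_optimum(self, evaluator):
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800)
        start = PrimerSetPair.of([FWD_A], [REV])
        weights = Weights(0.4, 0.4, 0.2)
        result = local_search(start, weights, evaluator, cfg)
        best = weighted_score(result, weights, evaluator)
        for index in range(len(result)):
            for cand in neighborhood(result, index, cfg.move_len_min, cfg.move_len_max):
                assert weighted_score(cand, weights, evaluator) <= best

    def test_local_optimum_returned_unchanged(self, evaluator):
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800)
        weights = Weights(0.2, 0.6, 0.2)
        start = PrimerSetPair.of([FWD_A], [REV])
        opt = local_search(start, weights, evaluator, cfg)
        assert local_search(opt, weights, evaluator, cfg) == opt


class TestSelectInitial:
    def _records(self):
        return [
            CandidateRecord("good", FWD_A, REV, "Bacteria", None),
            CandidateRecord("short16", "CCTACGGGAGGCAGCA", REV, "Bacteria", None),
            CandidateRecord("archaeal", FWD_A, REV, "Archaea", None),
            CandidateRecord("wrong_len", FWD_A, REV, "Bacteria", 650),
            CandidateRecord("untagged", FWD_A, REV, None, 707),
        ]

    def test_filters(self):
        evaluator = Evaluator(make_two_variant_refset())
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800)
        archive = select_initial(self._records(), evaluator, cfg)
        kept = {e.provenance for e in archive}
        assert kept == {"initial"}
        # 16-nt primer, Archaea domain and out-of-range metadata are excluded;
        # the untagged duplicate is kept
        assert len(archive) == 2

    def test_all_filtered_raises_user_error(self):
        evaluator = Evaluator(make_two_variant_refset())
        cfg = SearchConfig(amplicon_min=100, amplicon_max=200)
        with pytest.raises(UserInputError, match="widen"):
            select_initial(self._records(), evaluator, cfg)

    def test_degenerate_candidate_expands(self):
        evaluator = Evaluator(make_two_variant_refset())
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800)
        # H in the forward, R and Y in the reverse: 3 x 4 expansion
        cand = CandidateRecord(
            "degen", FWD_A[:-1] + "H", REV[:-2] + "RY", "Universal", 707
        )
        archive = select_initial([cand], evaluator, cfg)
        assert len(archive[0].pair.forward) == 3
        assert len(archive[0].pair.reverse) == 4


class TestMultiObjectiveSearch:
    def test_zero_restarts_returns_initial_archive(self):
        evaluator = Evaluator(make_two_variant_refset())
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800, n_restarts=0, seed=1)
        start = PrimerSetPair.of([FWD_A], [REV])
        init = [ArchiveEntry(start, evaluator.score(start), "initial")]
        assert multi_objective_search(cfg, evaluator, init) == init

    def test_same_seed_same_archive(self):
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800, n_restarts=4, seed=9)
        start = PrimerSetPair.of([FWD_A], [REV])
        runs = []
        for _ in range(2):
            evaluator = Evaluator(make_two_variant_refset())
            init = [ArchiveEntry(start, evaluator.score(start), "initial")]
            runs.append(multi_objective_search(cfg, evaluator, init))
        assert runs[0] == runs[1]

    def test_archive_grows_by_one_per_restart(self):
        evaluator = Evaluator(make_two_variant_refset())
        cfg = SearchConfig(amplicon_min=700, amplicon_max=800, n_restarts=5, seed=2)
        start = PrimerSetPair.of([FWD_A], [REV])
        init = [ArchiveEntry(start, evaluator.score(start), "initial")]
        archive = multi_objective_search(cfg, evaluator, init)
        assert len(archive) == len(init) + 5
        assert [e.restart for e in archive[1:]] == [1, 2, 3, 4, 5]


class TestArchiveJaccard:
    def _pairs(self, *names):
        return [PrimerSetPair.of([n], ["TACGTACGTACGTTACG"]) for n in names]

    def test_identical_lists(self):
        pairs = self._pairs("ACGTAACGTACGTACGT", "CCGTAACGTACGTACGT")
        assert archive_jaccard(pairs, list(reversed(pairs))) == 1.0

    def test_disjoint_lists(self):
        a = self._pairs("ACGTAACGTACGTACGT", "CCGTAACGTACGTACGT")
        b = self._pairs("GCGTAACGTACGTACGT", "TCGTAACGTACGTACGT", "AAGTAACGTACGTACGT")
        assert archive_jaccard(a, b) == 0.0

    def test_one_common_of_three(self):
        x, y, z = self._pairs(
            "ACGTAACGTACGTACGT", "CCGTAACGTACGTACGT", "GCGTAACGTACGTACGT"
        )
        assert archive_jaccard([x, y], [y, z]) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        assert archive_jaccard([], []) == 1.0
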