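"""Markov-chain outcomes: fundamental matrix, longevity, LRO, occupancy, first passage."""

import numpy as np
import pytest

import lifemix as lm
from lifemix.outcomes import SingularChainError

from conftest import geometric_chain

# Published per-group fundamental matrices (expected years in row-stage given
# column-stage), computed by the original analysis from the same vital rates;
# inputs are printed to 2 decimals, hence the 0.05 comparison tolerance.
PUBLISHED_N = {
    "UH-1": [[10.00, 0, 0, 0],
             [9.03, 9.30, 7.90, 6.66],
             [2.75, 2.54, 3.61, 2.20],
             [1.69, 1.63, 1.92, 3.35]],
    "UH-2": [[11.21, 0, 0, 0],
             [1.28, 13.08, 11.03, 9.92],
             [0.37, 3.32, 4.26, 2.91],
             [0.54, 5.31, 4.93, 5.81]],
    "UH-3": [[6.25, 0, 0, 0],
             [8.49, 8.49, 7.19, 6.45],
             [0.19, 0.19, 1.60, 0.54],
             [0.43, 0.43, 0.81, 2.11]],
}


class TestFundamentalMatrix:
    @pytest.mark.parametrize("label", ["UH-1", "UH-2", "UH-3"])
    def test_reproduces_published_matrices(self, fulmar, label):
        N = lm.fundamental_matrix(fulmar.chain(label).U, label)
        np.testing.assert_allclose(N, PUBLISHED_N[label], atol=0.05)

    def test_geometric_closed_form(self):
        N = lm.fundamental_matrix(geometric_chain(0.5))
        assert N[0, 0] == pytest.approx(2.0)

    def test_diagonal_at_least_one_and_pb_never_reentered(self, fulmar):
        for chain in fulmar.chains:
            N = lm.fundamental_matrix(chain.U)
            assert np.all(np.diag(N) >= 1.0)
            assert np.all(N[0, 1:] == 0)
            assert np.all(N >= 0)

    def test_no_absorption_raises_naming_group(self):
        immortal = lm.StageVitalRates(sigma=[1] * 4, beta=[0.5] * 4, gamma=[0.5] * 4,
                                      label="immortal")
        with pytest.raises(SingularChainError, match="immortal"):
            lm.fundamental_matrix(lm.build_transient_matrix(immortal), "immortal")


class TestOccupancyVariance:
    def test_geometric_variance_closed_form(self):
        # time in a state with return probability p is geometric: var p/(1-p)^2
        p = 0.5
        N = lm.fundamental_matrix(geometric_chain(p))
        V = lm.occupancy_variance(N)
        assert V[0, 0] == pytest.approx(p / (1 - p) ** 2)

    def test_deterministic_single_visit_has_zero_variance(self):
        V = lm.occupancy_variance(lm.fundamental_matrix(np.zeros((4, 4))))
        np.testing.assert_allclose(V, 0.0, atol=1e-12)

    def test_nonnegative(self, fulmar):
        for chain in fulmar.chains:
            V = lm.occupancy_variance(lm.fundamental_matrix(chain.U))
            assert np.all(V >= 0)


class TestLongevity:
    @pytest.mark.parametrize("label,mean_pb", [("UH-1", 23.47), ("UH-2", 13.40), ("UH-3", 15.36)])
    def test_life_expectancy_at_fledging(self, fulmar, label, mean_pb):
        mom = lm.longevity_moments(fulmar.chain(label).U, label)
        assert mom.for_stage("PB")[0] == pytest.approx(mean_pb, abs=0.05)
        assert np.all(mom.prob_event == 1.0)

    def test_immediate_death_chain(self):
        mom = lm.longevity_moments(np.zeros((1, 1)))
        assert mom.mean[0] == pytest.approx(1.0)
        assert mom.variance[0] == pytest.approx(0.0)

    def test_variance_matches_geometric(self):
        p = 0.5
        mom = lm.longevity_moments(geometric_chain(p))
        assert mom.variance[0] == pytest.approx(p / (1 - p) ** 2)


class TestLRO:
    @pytest.mark.parametrize("label,lro_pb", [("UH-1", 9.03), ("UH-2", 1.28), ("UH-3", 8.49)])
    def test_expected_lifetime_reproduction(self, fulmar, label, lro_pb):
        mom = lm.expected_lro(fulmar.chain(label).U, label)
        assert mom.for_stage("PB")[0] == pytest.approx(lro_pb, abs=0.05)

    def test_zero_success_means_no_future_lro(self):
        """With gamma = 0 the S stage is never entered again, so future
        reproduction is zero; the S start itself still counts its current
        (already successful) season, per the occupancy convention."""
        r = lm.StageVitalRates(sigma=[0.9] * 4, beta=[0.5] * 4, gamma=[0.0] * 4)
        mom = lm.expected_lro(lm.build_transient_matrix(r))
        np.testing.assert_allclose(mom.mean, [0.0, 1.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(mom.variance, 0.0, atol=1e-12)


class TestOccupancyProportions:
    def test_whole_life_shares(self, fulmar):
        p2 = lm.occupancy_proportions(fulmar.chain("UH-2").U, "PB")
        assert p2[0] == pytest.approx(0.84, abs=0.02)
        p3 = lm.occupancy_proportions(fulmar.chain("UH-3").U, "PB")
        assert p3[1] == pytest.approx(0.55, abs=0.02)

    def test_adult_life_share_from_recruitment_distribution(self, fulmar):
        chain = fulmar.chain("UH-3")
        p = lm.occupancy_proportions(chain.U, lm.recruitment_start(chain))
        assert p[1] == pytest.approx(0.93, abs=0.02)

    def test_shares_sum_to_one(self, fulmar):
        for chain in fulmar.chains:
            for start in lm.STAGES:
                assert lm.occupancy_proportions(chain.U, start).sum() == pytest.approx(1.0)


class TestFirstPassage:
    def test_recruitment_probability_and_age(self, fulmar):
        res2 = lm.first_passage(fulmar.chain("UH-2").U, None,
                                lm.FirstPassageSpec(target=("S", "F")))
        m, v, p = res2.for_stage("PB")
        assert p == pytest.approx(0.10, abs=0.01)
        assert m == pytest.approx(11.2, abs=0.1)
        res3 = lm.first_passage(fulmar.chain("UH-3").U, None,
                                lm.FirstPassageSpec(target=("S", "F")))
        # closed form: sigma_PB = 1 so age at recruitment is geometric, 1/beta_PB
        assert res3.for_stage("PB")[0] == pytest.approx(1 / 0.16)

    def test_first_success_lets_failure_be_a_detour(self, fulmar):
        res1 = lm.first_passage(fulmar.chain("UH-1").U, None,
                                lm.FirstPassageSpec(target=("S",)))
        m, _, p = res1.for_stage("PB")
        assert p == pytest.approx(0.97, abs=0.01)
        assert m == pytest.approx(10.3, abs=0.1)

    def test_conditional_chain_is_consistent(self, fulmar):
        """Conditioned transient columns are substochastic and the event is certain."""
        U = fulmar.chain("UH-1").U
        tgt = np.array([1, 2])
        Umod = U.copy()
        Umod[tgt, :] = 0.0
        event = U[tgt, :].sum(axis=0)
        Nmod = np.linalg.solve(np.eye(4) - Umod, np.eye(4))
        b = event @ Nmod
        Uc = Umod * b[:, None] / b[None, :]
        assert np.all(Uc.sum(axis=0) <= 1 + 1e-12)
        # conditional absorption into the event state is 1 by construction
        ec = event / b
        Nc = np.linalg.solve(np.eye(4) - Uc, np.eye(4))
        np.testing.assert_allclose(ec @ Nc, 1.0, atol=1e-10)

    def test_unreachable_event_is_flagged_not_nan(self, fulmar):
        # the pre-breeder stage is never re-entered: no path from any adult stage
        res = lm.first_passage(fulmar.chain("UH-1").U, None,
                               lm.FirstPassageSpec(target=("PB",), start="S"))
        for st in ("S", "F", "NB"):
            m, v, p = res.for_stage(st)
            j = lm.STAGES.index(st)
            assert p == 0.0 and res.no_path[j]
            assert not np.isnan(m) and not np.isnan(v)

    def test_all_stage_target_degenerates_to_one_step(self):
        r = lm.StageVitalRates(sigma=[1.0] * 4, beta=[0.5] * 4, gamma=[0.5] * 4)
        res = lm.first_passage(lm.build_transient_matrix(r), None,
                               lm.FirstPassageSpec(target=("PB", "S", "F", "NB")))
        m, v, p = res.for_stage("PB")
        assert p == pytest.approx(1.0)
        assert m == pytest.approx(1.0)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            lm.FirstPassageSpec(target=())


class TestBreedingInterval:
    # conditional time to the next successful breeding from each adult stage
    @pytest.mark.parametrize("label,stage,expected", [
        ("UH-1", "S", 1.4), ("UH-2", "S", 1.6), ("UH-3", "S", 1.1),
        ("UH-1", "F", 1.9), ("UH-2", "F", 1.9), ("UH-3", "F", 1.8),
        ("UH-1", "NB", 2.6), ("UH-2", "NB", 2.2), ("UH-3", "NB", 2.2),
    ])
    def test_intervals_match_published_values(self, fulmar, label, stage, expected):
        chain = fulmar.chain(label)
        mean, _, _ = lm.breeding_interval(chain.U, chain.M, stage)
        assert mean == pytest.approx(expected, abs=0.1)

    def test_certain_immediate_breeding_gives_unit_interval(self):
        r = lm.StageVitalRates(sigma=[1.0] * 4, beta=[1.0] * 4, gamma=[1.0] * 4)
        U = lm.build_transient_matrix(r)
        mean, var, prob = lm.breeding_interval(U, None, "S")
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(0.0, abs=1e-12)
        assert prob == pytest.approx(1.0)

    def test_rejects_pre_breeder_start(self, fulmar):
        chain = fulmar.chain("UH-1")
        with pytest.raises(ValueError, match="adult"):
            lm.breeding_interval(chain.U, chain.M, "PB")
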