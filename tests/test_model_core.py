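"""Round mechanics: hand-traced examples and brute-force recomputation."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import chisquare

from riskgame import (
    ParamError,
    Params,
    Strategy,
    apply_central_punishment,
    apply_contributions,
    apply_peer_punishment,
    initialize_population,
    make_fixture,
    partition_into_subgroups,
    play_round,
    resolve_risk,
    validate_params,
)

C, CP, PP, D = Strategy.C, Strategy.CP, Strategy.PP, Strategy.D


def subgroup(*counts):
    """Strategy codes for one subgroup given (n_C, n_CP, n_PP, n_D)."""
    return np.repeat(np.arange(4, dtype=np.int8), counts)


def brute_force_round(labels, p):
    """Per-member oracle for one subgroup: plain-Python reapplication of the
    round rules, independent of the vectorised implementation."""
    n_cp = labels.count("CP")
    n_pp = labels.count("PP")
    n_d = labels.count("D")
    total = p.u * (len(labels) - n_d)
    inst = p.w1 * n_cp >= p.w
    success = total >= p.U
    out = []
    for s in labels:
        bal = p.m
        if s != "D":
            bal -= p.u
        if s == "CP":
            bal -= p.w1
        if s == "PP":
            bal -= p.w2 * n_d
        if s == "D":
            if inst:
                bal -= p.t1
            bal -= p.t2 * n_pp
        out.append(bal if success else 0.0)
    return out, total, inst, success


class TestValidateParams:
    def test_defaults_are_valid(self):
        p = Params(t1=5.0, t2=2.5, U=25.0)
        assert validate_params(p) is p

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"N": 100, "a": 7, "n": 10}, "N"),
            ({"t2": 1.0, "w2": 2.0}, "w2"),
            ({"beta": 0.0}, "beta"),
            ({"beta": 1.5}, "beta"),
            ({"alpha": -0.1}, "alpha"),
            ({"u": 11.0}, "u"),
            ({"t1": -1.0}, "t1"),
            ({"stable_window": 5000}, "stable_window"),
            ({"strategy_set": ("C",)}, "strategy_set"),
            ({"strategy_set": ("C", "X")}, "strategy_set"),
        ],
    )
    def test_violations_name_the_field(self, kwargs, field):
        with pytest.raises(ParamError, match=field):
            validate_params(Params(**kwargs))


class TestInitialization:
    def test_restricted_support(self, rng):
        p = Params(strategy_set=("C", "D"))
        state = initialize_population(p, rng)
        assert set(np.unique(state.strategies)) <= {int(C), int(D)}
        assert np.all(state.resources == 0.0) and state.round_index == 0

    def test_deterministic_under_seed(self):
        p = Params()
        s1 = initialize_population(p, np.random.default_rng(7)).strategies
        s2 = initialize_population(p, np.random.default_rng(7)).strategies
        assert np.array_equal(s1, s2)

    def test_uniform_assignment(self):
        # pooled counts over many initialisations are uniform across the four
        # strategies (expectation N/4 each)
        rng = np.random.default_rng(42)
        p = Params()
        totals = np.zeros(4)
        for _ in range(1000):
            totals += np.bincount(initialize_population(p, rng).strategies, minlength=4)
        assert chisquare(totals).pvalue > 1e-3


class TestPartition:
    def test_blocks_partition_population(self, rng):
        p = Params()
        asg = partition_into_subgroups(p, rng)
        assert asg.membership.shape == (10, 10)
        assert np.array_equal(np.sort(asg.membership.reshape(-1)), np.arange(100))

    def test_single_block_when_population_equals_subgroup(self, rng):
        p = Params(N=10, a=1, n=10)
        asg = partition_into_subgroups(p, rng)
        assert sorted(asg.membership[0]) == list(range(10))

    def test_deterministic_under_seed(self):
        p = Params()
        m1 = partition_into_subgroups(p, np.random.default_rng(3)).membership
        m2 = partition_into_subgroups(p, np.random.default_rng(3)).membership
        assert np.array_equal(m1, m2)


class TestStageOperations:
    def test_contributions_mixed_subgroup(self):
        p = Params()
        bal, total = apply_contributions(subgroup(3, 2, 2, 3), p)
        assert total == 35.0
        assert np.array_equal(bal, [5, 5, 5, 5, 5, 5, 5, 10, 10, 10])

    def test_contributions_all_defect_and_all_collaborate(self):
        p = Params()
        bal, total = apply_contributions(np.full(10, int(D), np.int8), p)
        assert total == 0.0 and np.all(bal == 10.0)
        _, total = apply_contributions(np.full(10, int(C), np.int8), p)
        assert total == 50.0

    def test_central_punishment_threshold_met(self):
        p = Params(t1=5.0)
        strat = subgroup(0, 2, 0, 3)
        bal, _ = apply_contributions(strat, p)
        bal, inst, loss, cost = apply_central_punishment(bal, strat, p)
        assert inst and loss == 15.0 and cost == 4.0
        assert np.array_equal(bal, [3, 3, 5, 5, 5])

    def test_central_punishment_underfunded_cost_still_sunk(self):
        p = Params(t1=5.0)
        strat = subgroup(0, 1, 0, 4)
        bal, _ = apply_contributions(strat, p)
        bal, inst, loss, cost = apply_central_punishment(bal, strat, p)
        assert not inst and loss == 0.0 and cost == 2.0
        assert np.array_equal(bal, [3, 10, 10, 10, 10])

    def test_central_punishment_no_targets(self):
        p = Params(t1=5.0)
        strat = subgroup(0, 3, 0, 0)
        bal, _ = apply_contributions(strat, p)
        _, inst, loss, cost = apply_central_punishment(bal, strat, p)
        assert inst and loss == 0.0 and cost == 6.0

    def test_peer_punishment_many_to_many(self):
        p = Params(t2=2.0, w2=1.0)
        strat = subgroup(0, 0, 3, 2)
        bal, _ = apply_contributions(strat, p)
        bal, loss, cost = apply_peer_punishment(bal, strat, p)
        assert loss == 12.0 and cost == 6.0
        # each PP pays w2 per D (2), each D loses t2 per PP (6)
        assert np.array_equal(bal, [3, 3, 3, 4, 4])

    def test_peer_punishment_absent_without_punishers(self):
        p = Params(t2=2.0)
        strat = subgroup(0, 0, 0, 5)
        bal, _ = apply_contributions(strat, p)
        out, loss, cost = apply_peer_punishment(bal, strat, p)
        assert loss == 0.0 and cost == 0.0 and np.array_equal(out, bal)

    def test_peer_punishment_single_act(self):
        p = Params(t2=6.5, w2=1.0)
        strat = subgroup(0, 0, 1, 1)
        bal, _ = apply_contributions(strat, p)
        bal, loss, cost = apply_peer_punishment(bal, strat, p)
        assert bal[0] == 10 - 5 - 1 and bal[1] == 10 - 6.5

    def test_risk_threshold_is_inclusive(self):
        p = Params(U=15.0)
        strat = subgroup(3, 0, 0, 7)
        bal, total = apply_contributions(strat, p)
        success, out = resolve_risk(bal, total, p)
        assert success and np.array_equal(out, bal)
        success, _ = resolve_risk(*apply_contributions(subgroup(7, 0, 0, 3), Params(U=35.0)), p=Params(U=35.0))
        assert success

    def test_risk_failure_zeroes_everyone(self):
        p = Params(U=15.0)
        strat = subgroup(2, 0, 0, 8)
        bal, total = apply_contributions(strat, p)
        success, out = resolve_risk(bal, total, p)
        assert not success and np.all(out == 0.0)
        # the subgroup forfeits all n*m endowed units
        assert bal.sum() == p.n * p.m - total  # kept resources pre-failure
        assert out.sum() == 0.0


class TestPlayRound:
    def test_hand_traced_mixed_subgroup(self):
        # one subgroup (3C, 2CP, 2PP, 3D) at t1=5, t2=2, U=35: total
        # contribution 35 -> success; C=5, CP=3, PP=2 (pays w2 per D), D=1
        # (central 5 + peer 2*2)
        p = Params(N=10, a=1, n=10, t1=5.0, t2=2.0, U=35.0)
        state, asg = make_fixture([(3, 2, 2, 3)], p)
        state, ledger = play_round(state, asg, p)
        assert ledger.success[0] and ledger.institution_established[0]
        assert ledger.total_contribution[0] == 35.0
        assert ledger.central_loss[0] == 15.0 and ledger.central_cost[0] == 4.0
        assert ledger.peer_loss[0] == 12.0 and ledger.peer_cost[0] == 6.0
        expected = [5, 5, 5, 3, 3, 2, 2, 1, 1, 1]
        assert np.allclose(state.resources, expected)

    def test_all_defectors_fail(self):
        p = Params(N=10, a=1, n=10, U=15.0)
        state, asg = make_fixture([(0, 0, 0, 10)], p)
        state, ledger = play_round(state, asg, p)
        assert not ledger.success[0]
        assert np.all(state.resources == 0.0)

    def test_pure_and_deterministic(self, rng):
        p = Params()
        state = initialize_population(p, rng)
        asg = partition_into_subgroups(p, rng)
        out1, led1 = play_round(state, asg, p)
        out2, led2 = play_round(state, asg, p)
        assert np.array_equal(out1.resources, out2.resources)
        assert np.array_equal(led1.success, led2.success)

    def test_matches_brute_force_on_random_subgroups(self):
        # vectorised mechanics vs the per-member oracle on 1000 random
        # subgroups over a grid of punishment intensities and thresholds
        rng = np.random.default_rng(99)
        names = ["C", "CP", "PP", "D"]
        for _ in range(1000):
            p = Params(
                N=10,
                a=1,
                n=10,
                t1=float(rng.choice([0.0, 2.0, 5.0, 9.5])),
                t2=float(rng.choice([1.0, 2.5, 6.5])),
                w2=1.0,
                U=float(rng.choice([15.0, 25.0, 35.0])),
            )
            counts = rng.multinomial(10, [0.25] * 4)
            state, asg = make_fixture([tuple(counts)], p)
            labels = [names[s] for s in state.strategies]
            state, ledger = play_round(state, asg, p)
            exp_bal, exp_total, exp_inst, exp_success = brute_force_round(labels, p)
            assert np.allclose(state.resources, exp_bal)
            assert ledger.total_contribution[0] == exp_total
            assert bool(ledger.institution_established[0]) == exp_inst
            assert bool(ledger.success[0]) == exp_success
            # ledger identities
            n_pp, n_d = labels.count("PP"), labels.count("D")
            assert ledger.peer_loss[0] == p.t2 * n_pp * n_d
            assert ledger.peer_cost[0] == p.w2 * n_pp * n_d
            assert ledger.central_loss[0] == p.t1 * n_d * exp_inst
            assert ledger.central_cost[0] == p.w1 * labels.count("CP")
            if not exp_success:
                assert state.resources.sum() == 0.0
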