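"""Consistency checkers: toy-network behaviour, completeness, soundness."""

import numpy as np
import pytest

from metnet import (
    build_network,
    cmc_check,
    fastcc,
    flip_reactions,
    fva_check,
    lp2_feasibility_check,
    lp3_max_flux_sum,
    lp7_maximize_active,
    scale_bounds,
)

from .conftest import blocked_by_direct_lp, raw_net, to_cobra

EPS = 1e-4


def rid_set(net, idx):
    return {net.reaction_ids[i] for i in idx}


class TestLP2:
    def test_false_positive_on_blocked_reversible_dead_end(self, fig1):
        # the two irreversible copies of A<->B cancel; the test wrongly
        # reports the network consistent
        assert lp2_feasibility_check(fig1, EPS) is True
        assert len(fva_check(fig1, EPS).blocked) == 1

    def test_feasible_chain(self, chain3):
        assert lp2_feasibility_check(chain3, EPS) is True

    def test_dead_end_infeasible(self, dead_end):
        assert lp2_feasibility_check(dead_end, EPS) is False


class TestLP3:
    def test_sum_objective_prefers_long_pathway(self, fig1):
        # with per-reaction caps at eps, routing through A->C->D collects
        # 3.5x eps vs 2.5x eps for the direct route; A->D stays at zero
        sol = lp3_max_flux_sum(fig1, range(6), EPS)
        assert sol.optimal
        iAD = fig1.reaction_index("r5_A_D")
        iAC = fig1.reaction_index("r3_A_C")
        assert sol.v[iAC] >= 0.99 * EPS
        assert abs(sol.v[iAD]) < 0.01 * EPS
        assert sol.objective == pytest.approx(3.5 * EPS, rel=1e-6)

    def test_blocked_singleton_has_zero_optimum(self, fig1):
        sol = lp3_max_flux_sum(fig1, [fig1.reaction_index("r2_A_B")], EPS)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_chain_objective_reaches_cap_sum(self, chain3):
        sol = lp3_max_flux_sum(chain3, range(3), EPS)
        assert sol.objective == pytest.approx(3 * EPS, rel=1e-6)

    def test_empty_set_rejected(self, fig1):
        with pytest.raises(ValueError):
            lp3_max_flux_sum(fig1, [], EPS)


class TestLP7:
    def test_single_run_activates_all_unblocked(self, fig1):
        sol = lp7_maximize_active(fig1, range(6), EPS)
        active = {i for i in range(6) if sol.v[i] >= 0.99 * EPS}
        assert rid_set(fig1, active) == set(fig1.reaction_ids) - {"r2_A_B"}

    def test_blocked_dead_end_objective_zero(self, dead_end):
        sol = lp7_maximize_active(dead_end, [0], EPS)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_certifies_at_least_as_many_as_sum_objective(self, seed):
        net = raw_net(seed, m=10, n=20)
        J = net.irreversible.tolist()
        if not J:
            pytest.skip("no irreversible reactions drawn")
        v7 = lp7_maximize_active(net, J, EPS).v
        v3 = lp3_max_flux_sum(net, J, EPS).v
        n7 = sum(v7[i] >= 0.99 * EPS for i in J)
        n3 = sum(v3[i] >= 0.99 * EPS for i in J)
        assert n7 >= n3


class TestCMC:
    def test_two_iterations_needed_on_toy_network(self, fig1):
        res = cmc_check(fig1, EPS)
        assert rid_set(fig1, res.blocked) == {"r2_A_B"}
        first = res.trace[0][1]
        second = res.trace[1][1]
        iAD = fig1.reaction_index("r5_A_D")
        assert iAD not in first          # sum objective leaves A->D at zero
        assert iAD in second             # certified only by the second LP
        assert rid_set(fig1, first) == {"r1_src_2A", "r3_A_C",
                                        "r4_C_D", "r6_D_snk"}

    def test_consistent_chain_certified_in_one_lp(self, chain3):
        res = cmc_check(chain3, EPS)
        assert res.blocked == frozenset()
        assert res.trace[0][1] == frozenset({0, 1, 2})

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_direct_lp_oracle_on_random_networks(self, seed):
        net = raw_net(seed, m=10, n=20)
        assert cmc_check(net, EPS).blocked == blocked_by_direct_lp(net)


class TestFastcc:
    def test_one_lp_certifies_toy_consistent_part(self, fig1):
        res = fastcc(fig1, EPS)
        assert rid_set(fig1, res.blocked) == {"r2_A_B"}
        assert len(res.trace[0][1]) == 5 and res.trace[0][0] == 1

    def test_idempotent_on_own_consistent_part(self, fig1_consistent):
        res = fastcc(fig1_consistent, EPS)
        assert res.blocked == frozenset()

    def test_lp_ordering_on_toy_network(self, fig1):
        assert (fastcc(fig1, EPS).lp_calls
                <= cmc_check(fig1, EPS).lp_calls
                <= fva_check(fig1, EPS).lp_calls)

    @pytest.mark.parametrize("seed", range(1, 26))
    def test_partition_matches_fva_on_random_networks(self, seed):
        net = raw_net(seed, m=12, n=24)
        f = fastcc(net, EPS)
        v = fva_check(net, EPS)
        assert f.blocked == v.blocked
        assert f.consistent == v.consistent

    @pytest.mark.parametrize("seed", [2, 5, 8])
    def test_matches_cobrapy_fastcc(self, seed):
        """Independent implementation + solver stack (cobrapy over GLPK)."""
        from cobra.flux_analysis import fastcc as cobra_fastcc

        net = raw_net(seed, m=10, n=20)
        kept = {r.id for r in cobra_fastcc(to_cobra(net), flux_threshold=EPS,
                                           zero_cutoff=0.99 * EPS).reactions}
        assert rid_set(net, fastcc(net, EPS).consistent) == kept

    def test_witnesses_are_modes(self, fig1):
        res = fastcc(fig1, EPS)
        S = fig1.dense_S()
        for i in res.consistent:
            w = res.witnesses[i]
            assert abs(w[i]) >= 0.99 * EPS * (1 - 1e-9)
            assert np.abs(S @ w).max() < 1e-7
            assert (w >= fig1.lb - 1e-7).all() and (w <= fig1.ub + 1e-7).all()


class TestFVA:
    def test_toy_network_blocked_set(self, fig1):
        res = fva_check(fig1, EPS)
        assert rid_set(fig1, res.blocked) == {"r2_A_B"}
        assert res.lp_calls <= 2 * fig1.n_reactions

    def test_empty_model(self):
        res = fva_check(build_network([], []), EPS)
        assert res.lp_calls == 0
        assert res.consistent == res.blocked == frozenset()

    def test_vertex_enumeration_agreement_on_three_reaction_net(self, chain3):
        # the feasible polytope of the chain is {v: v0=v1=v2 in [0,10]};
        # every vertex has either full or empty support
        res = fva_check(chain3, EPS)
        assert res.blocked == frozenset()
        # append a dead-end column: its polytope coordinate is always zero
        net = build_network(
            ["A", "B", "C"],
            [("in_A", {"A": 1.0}, 0.0, 10.0),
             ("A_B", {"A": -1.0, "B": 1.0}, 0.0, 10.0),
             ("out_B", {"B": -1.0}, 0.0, 10.0),
             ("A_C", {"A": -1.0, "C": 1.0}, 0.0, 10.0)])
        assert rid_set(net, fva_check(net, EPS).blocked) == {"A_C"}


class TestPartitionInvariances:
    @pytest.mark.parametrize("seed", [1, 6, 10])
    def test_blocked_set_invariant_under_bound_scaling(self, seed):
        net = raw_net(seed, m=10, n=20)
        base = fva_check(net, EPS).blocked
        assert fva_check(scale_bounds(net, 7.3), EPS).blocked == base

    @pytest.mark.parametrize("seed", [1, 6, 10])
    def test_blocked_set_invariant_under_reversible_flips(self, seed):
        net = raw_net(seed, m=10, n=20)
        rev = net.reversible.tolist()
        if not rev:
            pytest.skip("no reversible reactions drawn")
        flipped = flip_reactions(net, rev[::2])
        assert fva_check(flipped, EPS).blocked == fva_check(net, EPS).blocked

    def test_zero_locked_bounds_blocked_without_lp(self):
        net = build_network(
            ["A"],
            [("in_A", {"A": 1.0}, 0.0, 10.0),
             ("out_A", {"A": -1.0}, 0.0, 10.0),
             ("locked", {"A": -1.0}, 0.0, 0.0)])
        res = fva_check(net, EPS)
        assert 2 in res.blocked
        assert res.lp_calls <= 2  # no LP spent on the locked column
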