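"""Fermi imitation, asymmetric payoff evaluation, synchronous stepping."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from herdsim import (
    DynamicsParams,
    GameParams,
    HerdingParams,
    build_lattice,
    compute_payoffs,
    effective_payoffs,
    fermi_probability,
    from_networkx,
    synchronous_step,
)
from herdsim.strategies import HC, HD, NHC, NHD, VARIANT_SETS

GP = GameParams(S=-1.0, T=0.0)
HP = HerdingParams(tau=1.0)


class TestFermi:
    def test_equal_payoffs_give_half(self):
        assert fermi_probability(0.0, beta=5.0) == 0.5

    def test_unit_difference_at_beta_5(self):
        assert fermi_probability(1.0, beta=5.0) == pytest.approx(1 / (1 + math.exp(-5)), rel=1e-12)

    @given(x=st.floats(-50, 50), beta=st.floats(0.01, 20))
    @settings(max_examples=50, deadline=None)
    def test_logistic_identity(self, x, beta):
        assert fermi_probability(x, beta) + fermi_probability(-x, beta) == pytest.approx(1.0)

    def test_overflow_safe_and_open_interval(self):
        lo = fermi_probability(-1e9, beta=5.0)
        hi = fermi_probability(1e9, beta=5.0)
        assert 0.0 < lo < hi < 1.0

    def test_monotone_in_model_payoff(self):
        diffs = np.linspace(-4, 4, 81)
        p = fermi_probability(diffs, beta=5.0)
        assert np.all(np.diff(p) > 0)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            fermi_probability(0.0, beta=0.0)


class TestEffectivePayoffs:
    def setup_method(self):
        self.net = from_networkx(nx.path_graph(3))
        self.state = np.array([HC, NHD, NHC], dtype=np.int8)
        self.pv = compute_payoffs(self.state, self.net, GP, HP)

    def test_herding_focal_discounts_both_sides(self):
        pi, pj = effective_payoffs(0, 1, self.pv, self.state, "four_strategy", self.net)
        assert pi == self.pv.raw[0] - self.pv.herding_cost[0]
        assert pj == self.pv.raw[1] - self.pv.herding_cost[1]

    def test_non_herding_focal_uses_raw_payoffs(self):
        # focal 2 is NHC: raw on both sides even though the model may herd
        pi, pj = effective_payoffs(2, 1, self.pv, self.state, "four_strategy", self.net)
        assert (pi, pj) == (self.pv.raw[2], self.pv.raw[1])

    def test_plain_variant_never_discounts(self):
        pi, pj = effective_payoffs(0, 1, self.pv, self.state, "pairwise_plain", self.net)
        assert (pi, pj) == (self.pv.raw[0], self.pv.raw[1])

    def test_zero_tau_collapses_to_plain(self):
        pv0 = compute_payoffs(self.state, self.net, GP, HerdingParams(tau=0.0))
        for variant in VARIANT_SETS:
            assert effective_payoffs(0, 1, pv0, self.state, variant, self.net) == (
                pv0.raw[0],
                pv0.raw[1],
            )

    def test_non_adjacent_pair_rejected(self):
        with pytest.raises(ValueError, match="not adjacent"):
            effective_payoffs(0, 2, self.pv, self.state, "four_strategy", self.net)


class TestSynchronousStep:
    def test_homogeneous_state_absorbing_without_mutation(self):
        net = build_lattice(4, 4)
        for variant, fill in [("pairwise_plain", NHC), ("pairwise_herding", HC), ("four_strategy", HD)]:
            state = np.full(16, fill, dtype=np.int8)
            dp = DynamicsParams(beta=5.0, mu=0.0, variant=variant)
            out = synchronous_step(state, net, GP, HP, dp, np.random.default_rng(0))
            assert np.array_equal(out, state)

    def test_full_mutation_uniform_over_strategy_set(self):
        net = build_lattice(10, 10)
        dp = DynamicsParams(beta=5.0, mu=1.0, variant="four_strategy")
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        state = np.full(100, HC, dtype=np.int8)
        for _ in range(200):
            state = synchronous_step(state, net, GP, HP, dp, rng)
            counts += np.bincount(state, minlength=4)
        assert chisquare(counts).pvalue > 1e-4

    def test_strategy_set_closure(self, rng):
        net = build_lattice(5, 5)
        for variant, strat_set in VARIANT_SETS.items():
            state = rng.choice(strat_set, size=25).astype(np.int8)
            dp = DynamicsParams(beta=5.0, mu=0.2, variant=variant)
            for _ in range(20):
                state = synchronous_step(state, net, GP, HP, dp, rng)
                assert set(np.unique(state)) <= set(strat_set)

    def test_seed_determinism(self):
        net = build_lattice(6, 6)
        state = np.random.default_rng(1).choice([HC, HD, NHC, NHD], size=36).astype(np.int8)
        dp = DynamicsParams()
        a = synchronous_step(state, net, GP, HP, dp, np.random.default_rng(9))
        b = synchronous_step(state, net, GP, HP, dp, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_matched_seed_tau_zero_collapse(self):
        """With tau=0 the uniform herding-cost game is the plain game up to
        the trait label: identical seeds give identical action sequences."""
        net = build_lattice(6, 6)
        rng_init = np.random.default_rng(2)
        actions = rng_init.integers(0, 2, size=36).astype(np.int8)
        hp0 = HerdingParams(tau=0.0)
        state_h = actions.copy()          # HC/HD encode actions 0/1
        state_p = (actions + 2).astype(np.int8)  # NHC/NHD
        for seed in range(3):
            sh = synchronous_step(state_h, net, GP, hp0,
                                  DynamicsParams(variant="pairwise_herding"),
                                  np.random.default_rng(seed))
            sp = synchronous_step(state_p, net, GP, hp0,
                                  DynamicsParams(variant="pairwise_plain"),
                                  np.random.default_rng(seed))
            assert np.array_equal(sh & 1, sp & 1)

    def test_empty_network_rejected(self):
        import scipy.sparse as sp

        from herdsim.networks import Network

        with pytest.raises(ValueError):
            Network(node_count=0, kind="custom", adjacency=sp.csr_array((0, 0)))


def brute_force_step(state, net, gp, hp, dp, seed):
    """Straight-line scalar re-implementation of one synchronous step,
    consuming the documented four-draw randomness contract."""
    n = net.node_count
    rng = np.random.default_rng(seed)
    u_mut = rng.random(n)
    mut_pick = rng.integers(0, dp.strategy_set.size, size=n)
    u_nb = rng.random(n)
    u_imit = rng.random(n)

    M = {(0, 0): 1.0, (0, 1): gp.S, (1, 0): gp.T, (1, 1): 0.0}
    raw, cost = np.zeros(n), np.zeros(n)
    for i in range(n):
        nbrs = list(net.neighbors(i))
        raw[i] = sum(M[(int(state[i]) & 1, int(state[j]) & 1)] for j in nbrs)
        if nbrs:
            r = sum((int(state[j]) & 1) != (int(state[i]) & 1) for j in nbrs) / len(nbrs)
            cost[i] = hp.tau * (len(nbrs) / net.mean_degree) * r

    new = state.copy()
    for i in range(n):
        nbrs = list(net.neighbors(i))
        j = nbrs[min(int(u_nb[i] * len(nbrs)), len(nbrs) - 1)]
        if u_mut[i] < dp.mu:
            new[i] = dp.strategy_set[mut_pick[i]]
            continue
        if dp.variant == "pairwise_plain":
            discount = False
        elif dp.variant == "pairwise_herding":
            discount = True
        else:
            discount = int(state[i]) < 2
        pi = raw[i] - cost[i] * discount
        pj = raw[j] - cost[j] * discount
        p = 1.0 / (1.0 + math.exp(-dp.beta * (pj - pi)))
        if u_imit[i] < p:
            new[i] = state[j]
    return new


@pytest.mark.parametrize("variant", ["pairwise_plain", "pairwise_herding", "four_strategy"])
def test_step_matches_brute_force_oracle(variant):
    g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 4), (1, 3)])
    net = from_networkx(g)
    state = np.array([HC, NHD, HD, NHC, HC], dtype=np.int8)
    if variant != "four_strategy":
        state = np.asarray(VARIANT_SETS[variant])[state & 1]
    dp = DynamicsParams(beta=5.0, mu=0.1, variant=variant)
    for seed in range(20):
        expected = brute_force_step(state, net, GP, HP, dp, seed)
        got = synchronous_step(state, net, GP, HP, dp, np.random.default_rng(seed))
        assert np.array_equal(got, expected), f"seed {seed}"
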