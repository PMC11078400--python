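import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acctrait import (
    BACKGROUND,
    CONSERVED,
    ACCELERATED,
    TransitionParams,
    LatentStates,
    PhiHyperPriors,
    build_phi,
    backward_messages,
    sample_states,
    update_phi,
    RateMultipliers,
    VarianceParams,
    BranchMatrices,
)
from acctrait.latent_states import transition_counts, state_posteriors_exact, ROOT_PRIOR
from conftest import make_element
from oracles import enumerate_state_posterior


class TestBuildPhi:
    def test_half_half_matrix(self):
        phi = build_phi(0.5, 0.5, 0.5)
        np.testing.assert_allclose(
            phi, [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.5, 0.5]]
        )

    @given(
        a=st.floats(0.01, 0.99), b=st.floats(0.01, 0.99), c=st.floats(0.01, 0.99)
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_stochastic_and_structural_zeros(self, a, b, c):
        phi = build_phi(a, b, c)
        np.testing.assert_allclose(phi.sum(axis=1), 1.0, atol=1e-12)
        assert phi[0, 2] == 0.0  # background never jumps straight to accelerated
        assert phi[1, 0] == 0.0 and phi[2, 0] == 0.0  # no return to background

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_boundary_values_rejected(self, bad):
        with pytest.raises(ValueError):
            build_phi(bad, 0.5, 0.5)


def _message_setup(tree, jc, rng, S=1):
    el = make_element(tree, jc, rng, S=S)
    rates = RateMultipliers(r2=0.2, r3=2.0)
    vp = VarianceParams(sigma2=1.0, beta2=0.5, beta3=2.0)
    tp = TransitionParams(a=0.3, b=0.4, c=0.5)
    m = BranchMatrices(tree, jc)
    m.update(rates)
    return el, rates, vp, tp, m


class TestBackwardMessages:
    def test_leaf_message_is_emission_only(self, tree2, jc):
        rng = np.random.default_rng(0)
        el, rates, vp, tp, m = _message_setup(tree2, jc, rng, S=2)
        msg = backward_messages(el, rates, vp, tp, tree2, m)
        for leaf in range(2):
            for k in range(3):
                seq = sum(
                    m.logP5[leaf, k][el.X[tree2.parent[leaf], s], el.X[leaf, s]]
                    for s in range(2)
                )
                d = el.y[leaf] - el.y[tree2.parent[leaf]]
                var = tree2.branch_length[leaf] * vp.v[k]
                trait = -0.5 * (math.log(2 * math.pi * var) + d * d / var)
                assert msg[leaf, k] == pytest.approx(seq + trait, rel=1e-10)

    def test_state_distribution_matches_brute_force(self, tree2, jc):
        rng = np.random.default_rng(1)
        el, rates, vp, tp, m = _message_setup(tree2, jc, rng, S=1)
        brute = enumerate_state_posterior(el, rates, vp, tp, tree2, jc)
        # exact per-node marginals from the messages
        msg = backward_messages(el, rates, vp, tp, tree2, m)
        marg = state_posteriors_exact(msg, tp, tree2)
        for node in range(tree2.n_nodes):
            for k in range(3):
                expected = sum(p for zz, p in brute.items() if zz[node] == k)
                assert marg[node, k] == pytest.approx(expected, abs=1e-10)

    def test_equal_multipliers_collapse_emissions(self, tree4, jc):
        rng = np.random.default_rng(2)
        el = make_element(tree4, jc, rng, S=2)
        rates = RateMultipliers(r2=1.0, r3=1.0)
        vp = VarianceParams(sigma2=1.0, beta2=1.0, beta3=1.0)
        tp = TransitionParams(a=0.3, b=0.4, c=0.5)
        m = BranchMatrices(tree4, jc)
        m.update(rates)
        msg = backward_messages(el, rates, vp, tp, tree4, m)
        # leaves: emission identical across states
        for leaf in range(4):
            assert msg[leaf, 0] == pytest.approx(msg[leaf, 1], rel=1e-12)
            assert msg[leaf, 1] == pytest.approx(msg[leaf, 2], rel=1e-12)


class TestSampleStates:
    def test_root_never_accelerated(self, tree4, jc):
        rng = np.random.default_rng(3)
        el, rates, vp, tp, m = _message_setup(tree4, jc, rng)
        msg = backward_messages(el, rates, vp, tp, tree4, m)
        for _ in range(500):
            z = sample_states(msg, tp, tree4, rng)
            assert z[tree4.root] != ACCELERATED

    def test_frequencies_match_brute_force(self, tree2, jc):
        rng = np.random.default_rng(4)
        el, rates, vp, tp, m = _message_setup(tree2, jc, rng, S=1)
        brute = enumerate_state_posterior(el, rates, vp, tp, tree2, jc)
        msg = backward_messages(el, rates, vp, tp, tree2, m)
        n = 100_000
        counts: dict[tuple, int] = {}
        for _ in range(n):
            z = tuple(int(v) for v in sample_states(msg, tp, tree2, rng))
            counts[z] = counts.get(z, 0) + 1
        for zz, p in brute.items():
            freq = counts.get(zz, 0) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3.5 * se + 1e-9, (zz, freq, p)

    def test_no_conservation_limit(self, tree4, jc):
        """c -> 0 with a background root: every node stays background."""
        rng = np.random.default_rng(5)
        el, rates, vp, _, m = _message_setup(tree4, jc, rng)
        tp = TransitionParams(a=0.5, b=0.5, c=1e-12)
        msg = backward_messages(el, rates, vp, tp, tree4, m)
        for _ in range(200):
            z = sample_states(msg, tp, tree4, rng, root_prior=np.array([1.0, 0.0, 0.0]))
            assert (z == BACKGROUND).all()

    def test_structural_zeros_never_violated(self, tree4, jc):
        rng = np.random.default_rng(6)
        el, rates, vp, tp, m = _message_setup(tree4, jc, rng)
        msg = backward_messages(el, rates, vp, tp, tree4, m)
        for _ in range(2000):
            z = sample_states(msg, tp, tree4, rng)
            LatentStates(z=z).validate(tree4)


class TestUpdatePhi:
    def test_counts(self, tree4):
        z = np.array([1, 1, 2, 2, 1, 2, 1], dtype=np.int8)
        counts = transition_counts(z, tree4)
        assert counts.sum() == tree4.n_edges

    def test_posterior_parameters_via_long_run_mean(self, tree4):
        """c | z ~ Beta(1 + n12, 1 + n11): check the empirical mean."""
        rng = np.random.default_rng(7)
        # craft z with known background transitions: root bg, children mixed
        z = np.zeros(7, dtype=np.int8)
        z[[0, 1]] = CONSERVED  # two leaves conserved under node 4
        z[4] = CONSERVED
        counts = transition_counts(z, tree4)
        n12, n11 = counts[0, 1], counts[0, 0]
        draws = [update_phi(z, tree4, PhiHyperPriors(), rng).c for _ in range(20_000)]
        expected = (1 + n12) / (2 + n12 + n11)
        assert np.mean(draws) == pytest.approx(expected, abs=0.01)

    def test_all_background_gives_prior_for_a_b(self, tree4):
        rng = np.random.default_rng(8)
        z = np.zeros(7, dtype=np.int8)
        a = [update_phi(z, tree4, PhiHyperPriors(), rng).a for _ in range(20_000)]
        b = [update_phi(z, tree4, PhiHyperPriors(), rng).b for _ in range(20_000)]
        # Beta(1,1) has mean 1/2, variance 1/12
        assert np.mean(a) == pytest.approx(0.5, abs=0.01)
        assert np.var(b) == pytest.approx(1 / 12, abs=0.01)

    def test_forbidden_transition_raises(self, tree4):
        z = np.zeros(7, dtype=np.int8)
        z[6] = CONSERVED  # root conserved
        z[[4, 5]] = BACKGROUND  # children back to background: forbidden
        with pytest.raises(RuntimeError, match="zero prior probability"):
            update_phi(z, tree4, PhiHyperPriors(), np.random.default_rng(0))


class TestGibbsSelfConsistency:
    def test_forward_vs_successive_conditional_state_frequencies(self, tree4, jc):
        """Alternating sim-data / sample-z leaves the prior law of z invariant."""
        from acctrait.simulator import sim_z, sim_X, sim_y

        rng = np.random.default_rng(9)
        tp = TransitionParams(a=0.3, b=0.4, c=0.5)
        rates = RateMultipliers(r2=0.2, r3=2.0)
        vp = VarianceParams(sigma2=1.0, beta2=0.5, beta3=2.0)
        m = BranchMatrices(tree4, jc)
        m.update(rates)
        n = 4000
        fwd = np.zeros((tree4.n_nodes, 3))
        suc = np.zeros((tree4.n_nodes, 3))
        # forward: z ~ prior
        for _ in range(n):
            z = sim_z(tree4, tp, rng)
            fwd[np.arange(tree4.n_nodes), z] += 1
        # successive-conditional: z ~ prior, then (X, y) | z, then z | X, y
        z = sim_z(tree4, tp, rng)
        for _ in range(n):
            X = sim_X(tree4, z, rates, jc, 3, rng)
            y = sim_y(tree4, z, vp, rng)
            el = make_element(tree4, jc, rng, S=3, X_leaves=X[:4], y_leaves=y[:4])
            el.X[:] = X
            el.y[:] = y
            msg = backward_messages(el, rates, vp, tp, tree4, m)
            z = sample_states(msg, tp, tree4, rng)
            suc[np.arange(tree4.n_nodes), z] += 1
        fwd /= n
        suc /= n
        se = np.sqrt(np.maximum(fwd * (1 - fwd), 1e-4) / n)
        assert np.all(np.abs(fwd - suc) <= 5 * se + 0.01)
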