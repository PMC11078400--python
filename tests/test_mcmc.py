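import math

import numpy as np
import pytest

from acctrait import (
    make_full_binary_tree,
    jukes_cantor,
    RateMultipliers,
    VarianceParams,
    TransitionParams,
    BranchMatrices,
    TraitPriors,
    LatentStates,
    RunConfig,
    ChainState,
    gibbs_sweep,
    run_chains,
    gelman_rubin,
    log_joint,
)
from acctrait.latent_states import PhiHyperPriors, transition_counts, ROOT_PRIOR
from acctrait.mcmc import (
    RatePriors,
    step4_update_rates,
    init_chain_state,
    complete_data_seq_loglik,
    run_chain,
)
from acctrait.trait_model import trait_log_joint
from acctrait.element_io import MISSING
from acctrait.simulator import sim_z, sim_X, sim_y
from conftest import make_element


def _sweep_args(tree, jc):
    return dict(
        config=RunConfig(n_iter=1, n_chains=1, step1_inner=50),
        trait_priors=TraitPriors(),
        rate_priors=RatePriors(),
        phi_priors=PhiHyperPriors(),
    )


class TestGibbsSweep:
    def test_invariants_hold_after_sweeps(self, tree4, jc):
        rng = np.random.default_rng(0)
        el = make_element(tree4, jc, rng, S=5)
        state = init_chain_state(el, tree4, jc, rng)
        m = BranchMatrices(tree4, jc)
        args = _sweep_args(tree4, jc)
        for _ in range(20):
            gibbs_sweep(state, tree4, jc, m, rng=rng, **args)
            assert math.isfinite(state.log_joint)
            assert state.rates.r2 > 0 and state.rates.r3 > 0
            assert state.vp.sigma2 > 0
            LatentStates(z=state.z).validate(tree4)
            assert 0 < state.tp.a < 1 and 0 < state.tp.b < 1 and 0 < state.tp.c < 1

    def test_fixed_seed_reproducible(self, tree4, jc):
        traj = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            el = make_element(tree4, jc, np.random.default_rng(5), S=5)
            df = run_chain(el, tree4, jc, RunConfig(n_iter=30, n_chains=1, step1_inner=50), rng)
            traj.append(df[["log_beta_ratio", "r2", "a", "log_joint"]].to_numpy())
        np.testing.assert_array_equal(traj[0], traj[1])

    def test_prior_recovery_with_no_data(self, tree4, jc):
        """All alignment columns missing, no observed traits: marginals = priors."""
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        el = make_element(tree4, jc, rng, S=2)
        el.X[:4] = MISSING
        el.observed_trait[:] = False
        state = init_chain_state(el, tree4, jc, rng)
        m = BranchMatrices(tree4, jc)
        args = _sweep_args(tree4, jc)
        args["config"] = RunConfig(n_iter=1, n_chains=1, step1_inner=20, param_step_sd=0.8)
        r2s, cs = [], []
        for i in range(12_000):
            gibbs_sweep(state, tree4, jc, m, rng=rng, compute_log_joint=False, **args)
            if i >= 2000:
                r2s.append(state.rates.r2)
                if i % 5 == 0:
                    cs.append(state.tp.c)
        # c is a conjugate Beta draw each sweep: nearly independent, KS-testable
        ks_c = sps.kstest(cs, sps.uniform.cdf)
        assert ks_c.pvalue > 0.01
        # r2 moves by one Metropolis step per sweep (autocorrelated):
        # compare moments against Gamma(5, 0.04) with an IACT-inflated s.e.
        r2s = np.asarray(r2s)
        assert np.mean(r2s) == pytest.approx(0.2, abs=0.02)
        assert np.var(r2s) == pytest.approx(5 * 0.04 ** 2, rel=0.25)


class TestStep4:
    def test_prior_recovery_when_state_absent(self, tree4, jc):
        """z all-background: r2, r3 have no data and sample from their Gammas."""
        rng = np.random.default_rng(2)
        el = make_element(tree4, jc, rng, S=4)
        z = np.zeros(7, dtype=np.int8)
        rates = RateMultipliers(r2=0.2, r3=2.0)
        draws = []
        for _ in range(20_000):
            rates, _ = step4_update_rates(el, z, rates, tree4, jc, RatePriors(), rng)
            draws.append((rates.r2, rates.r3))
        r2, r3 = np.array(draws[2000:]).T
        assert np.mean(r2) == pytest.approx(0.2, rel=0.05)   # Gamma(5, .04)
        assert np.mean(r3) == pytest.approx(2.0, rel=0.05)   # Gamma(10, .2)
        assert np.var(r2) == pytest.approx(5 * 0.04 ** 2, rel=0.15)

    def test_acceptance_monotone_in_step_size(self, tree4, jc):
        rng = np.random.default_rng(3)
        el = make_element(tree4, jc, rng, S=30)
        z = np.ones(7, dtype=np.int8)
        accs = []
        for sd in (0.05, 0.5, 2.0):
            r = RateMultipliers(r2=0.2, r3=2.0)
            acc = 0
            rng2 = np.random.default_rng(4)
            for _ in range(600):
                r, a = step4_update_rates(el, z, r, tree4, jc, RatePriors(), rng2, step_sd=sd)
                acc += a["r2"]
            accs.append(acc)
        assert accs[0] > accs[1] > accs[2]


class TestLogJoint:
    def test_matches_direct_factor_product(self, tree2, jc):
        rng = np.random.default_rng(5)
        el = make_element(tree2, jc, rng, S=2)
        state = init_chain_state(el, tree2, jc, rng)
        m = BranchMatrices(tree2, jc)
        m.update(state.rates)
        got = log_joint(state, tree2, jc, m, TraitPriors(), RatePriors())
        # independent recomputation, factor by factor
        expected = 0.0
        r = state.rates.as_array
        from acctrait.substitution_model import branch_transition_matrix

        for j in range(2):
            P = branch_transition_matrix(jc, float(r[state.z[j]]), float(tree2.branch_length[j]))
            for s in range(2):
                expected += math.log(P[state.element.X[2, s], state.element.X[j, s]])
        for s in range(2):
            expected += math.log(jc.pi[state.element.X[2, s]])
        expected += trait_log_joint(state.element.y, state.z, state.vp, tree2, TraitPriors())
        phi = state.tp.phi
        for j in range(2):
            expected += math.log(phi[state.z[2], state.z[j]])
        expected += math.log(ROOT_PRIOR[state.z[2]])
        rp = RatePriors()
        expected += rp.logpdf_r2(state.rates.r2) + rp.logpdf_r3(state.rates.r3)
        from scipy import stats as sps

        expected += sps.norm.logpdf(math.log(state.vp.sigma2), scale=math.sqrt(2))
        expected += sps.norm.logpdf(math.log(state.vp.beta2))
        expected += sps.norm.logpdf(math.log(state.vp.beta3))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_locality_of_ancestral_perturbation(self, tree4, jc):
        rng = np.random.default_rng(6)
        el = make_element(tree4, jc, rng, S=3)
        state = init_chain_state(el, tree4, jc, rng)
        m = BranchMatrices(tree4, jc)
        m.update(state.rates)
        base = complete_data_seq_loglik(state.element, state.z, tree4, m)
        node = 4  # internal, non-root
        old = state.element.X[node, 0]
        state.element.X[node, 0] = (old + 1) % 4
        changed = complete_data_seq_loglik(state.element, state.z, tree4, m)
        # only the three branch terms touching `node` can change
        assert changed != base
        state.element.X[node, 0] = old
        assert complete_data_seq_loglik(state.element, state.z, tree4, m) == pytest.approx(base)


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((3, 5000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_inflate(self):
        rng = np.random.default_rng(8)
        chains = rng.standard_normal((2, 2000))
        chains[1] += 3.0
        assert gelman_rubin(chains) > 1.5

    def test_agrees_with_arviz_classic_formula(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        chains = rng.standard_normal((4, 1000)) + rng.standard_normal((4, 1))
        ours = gelman_rubin(chains, split=True)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0), method="split").x.values) \
            if hasattr(az.rhat(chains), "x") else float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, abs=0.02)


class TestGewekeSelfConsistency:
    def test_forward_vs_gibbs_coupled_moments(self, tree4, jc):
        """Alternating one Gibbs sweep with re-simulating the data from the
        current parameters leaves the prior law of the parameters invariant:
        moments from that chain match plain prior draws within MC error."""
        from acctrait.simulator import draw_prior_params, sim_z, sim_X, sim_y
        from acctrait.trait_model import TraitPriors

        rng = np.random.default_rng(20)
        S = 10
        n = 4000

        def record(tp, rates, vp):
            return (
                rates.r2, vp.sigma2, math.log(vp.beta2), math.log(vp.beta3),
                tp.a, tp.b, tp.c,
            )

        fwd = np.array([record(*draw_prior_params(rng)) for _ in range(n)])

        el = make_element(tree4, jc, rng, S=S)
        state = init_chain_state(el, tree4, jc, rng)
        m = BranchMatrices(tree4, jc)
        args = dict(
            config=RunConfig(n_iter=1, n_chains=1, step1_inner=30, param_step_sd=0.8),
            trait_priors=TraitPriors(),
            rate_priors=RatePriors(),
            phi_priors=PhiHyperPriors(),
        )
        suc = np.empty((n, 7))
        for i in range(n):
            # data | current state
            z = sim_z(tree4, state.tp, rng)
            state.z = z
            state.element.X[:] = sim_X(tree4, z, state.rates, jc, S, rng)
            state.element.y[:] = sim_y(tree4, z, state.vp, rng)
            # state | data (one sweep)
            gibbs_sweep(state, tree4, jc, m, rng=rng, compute_log_joint=False, **args)
            suc[i] = record(state.tp, state.rates, state.vp)
        # compare means with an autocorrelation-inflated standard error
        for k in range(7):
            se = math.sqrt(fwd[:, k].var() / n + 8 * suc[:, k].var() / n)
            assert abs(fwd[:, k].mean() - suc[:, k].mean()) <= 5 * se + 0.02, k


class TestRunChains:
    def test_default_config_matches_standard_operating_point(self):
        cfg = RunConfig()
        assert cfg.n_iter == 10_000
        assert cfg.n_chains == 3
        assert cfg.rhat_threshold == 1.01

    def test_summary_schema_and_finiteness(self, tree4, jc):
        rng = np.random.default_rng(10)
        el = make_element(tree4, jc, rng, S=6)
        cfg = RunConfig(n_iter=120, n_chains=2, step1_inner=50, seed=11)
        out = run_chains(el, tree4, jc, cfg, log_joint_every=10)
        s = out["summary"]
        assert s["n_post_samples"] == 2 * 60
        assert set(s["rhat"]) == set(
            ["log_sigma2", "log_beta2", "log_beta3", "log_beta_ratio",
             "r2", "r3", "a", "b", "c"]
        )
        assert all(math.isfinite(v) for v in s["medians"].values())
        for k in ("step1_param_accept", "step1_trait_accept"):
            assert 0.05 < s["acceptance"][k] < 0.95
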