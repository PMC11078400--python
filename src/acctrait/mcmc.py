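"""Gibbs sampler orchestration, multi-chain runs and convergence diagnostics.

One sweep executes, in order:

1. Metropolis block on (sigma2, beta2, beta3) and latent trait values
   (default 500 inner iterations, 60% parameter moves).
2. Pruning over the observed leaf alignment followed by exact forward
   sampling of ancestral nucleotides.
3. Tips-to-root messages combining sequence and trait emissions, followed by
   exact root-to-tips sampling of per-branch conservation states.
4. Metropolis random-walk updates of the rate multipliers r2, r3 against the
   complete-data sequence likelihood and their Gamma priors.
5. Conjugate Beta updates of the state-transition probabilities (a, b, c).

Multiple chains start from independent prior draws; convergence is screened
with the classic split-chain Gelman-Rubin statistic (threshold 1.01 by
default, mirroring common practice for this model family).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .treeio import Phylogeny, NeutralModel
from .element_io import ElementData, initialize_latent
from .substitution_model import (
    RateMultipliers,
    BranchMatrices,
    branch_transition_matrix,
    prune_partials,
    sample_ancestral_nucleotides,
)
from .trait_model import VarianceParams, TraitPriors, trait_log_joint, step1_update_trait
from .latent_states import (
    TransitionParams,
    PhiHyperPriors,
    ROOT_PRIOR,
    backward_messages,
    sample_states,
    update_phi,
    transition_counts,
    BACKGROUND,
)
from .simulator import draw_prior_params, sim_z, R2_GAMMA, R3_GAMMA

MONITORED = [
    "log_sigma2", "log_beta2", "log_beta3", "log_beta_ratio",
    "r2", "r3", "a", "b", "c", "log_joint",
]


@dataclass
class RatePriors:
    """Shape-scale Gamma priors on the rate multipliers r2 (conserved) and r3."""

    r2_shape: float = R2_GAMMA[0]
    r2_scale: float = R2_GAMMA[1]
    r3_shape: float = R3_GAMMA[0]
    r3_scale: float = R3_GAMMA[1]

    def logpdf_r2(self, r: float) -> float:
        return _gamma_logpdf(r, self.r2_shape, self.r2_scale)

    def logpdf_r3(self, r: float) -> float:
        return _gamma_logpdf(r, self.r3_shape, self.r3_scale)


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return (shape - 1.0) * math.log(x) - x / scale - shape * math.log(scale) - math.lgamma(shape)


_LOG2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x: float, var: float) -> float:
    return -0.5 * (_LOG2PI + math.log(var) + x * x / var)


@dataclass
class RunConfig:
    """Sampler settings; defaults follow the method's standard operating point."""

    n_iter: int = 10_000
    n_chains: int = 3
    burn_in_fraction: float = 0.5
    thin: int = 1
    step1_inner: int = 500
    step1_mix: float = 0.6
    param_step_sd: float = 0.3
    trait_step_scale: float = 0.5
    rate_step_sd: float = 0.3
    rhat_threshold: float = 1.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_chains < 1 or not (0 <= self.burn_in_fraction < 1):
            raise ValueError("invalid run configuration")


@dataclass
class ChainState:
    """Full state of one chain: data with latent fill-ins plus all parameters."""

    element: ElementData
    z: np.ndarray
    rates: RateMultipliers
    vp: VarianceParams
    tp: TransitionParams
    log_joint: float = math.nan
    iteration: int = 0


def complete_data_seq_loglik(
    element: ElementData, z: np.ndarray, tree: Phylogeny, matrices: BranchMatrices
) -> float:
    """Log likelihood of the filled-in X: sum of branch transition log probs.

    MISSING leaf entries contribute zero via the padded 5x5 log matrices
    (their emission marginalizes to one).
    """
    X = element.X
    jj = np.delete(np.arange(tree.n_nodes), tree.root)
    Xp = X[tree.parent[jj]].astype(np.intp)
    Xc = X[jj].astype(np.intp)
    kk = z[jj].astype(np.intp)
    return float(matrices.logP5[jj[:, None], kk[:, None], Xp, Xc].sum())


def _state_transition_histograms(
    element: ElementData, z: np.ndarray, tree: Phylogeny, state: int
) -> dict[float, np.ndarray]:
    """Per distinct branch length, the 5x5 parent->child nucleotide counts
    over edges currently in ``state``."""
    X = element.X
    jj = np.where((z == state) & (np.arange(tree.n_nodes) != tree.root))[0]
    out: dict[float, np.ndarray] = {}
    if len(jj) == 0:
        return out
    idx = 5 * X[tree.parent[jj]].astype(np.intp) + X[jj].astype(np.intp)  # (E_k, S)
    ts = tree.branch_length[jj]
    for t in np.unique(ts):
        sel = ts == t
        out[float(t)] = np.bincount(idx[sel].ravel(), minlength=25).reshape(5, 5).astype(float)
    return out


def _seq_loglik_at_rate(
    hists: dict[float, np.ndarray], rate: float, model: NeutralModel
) -> float:
    total = 0.0
    for t, hist in hists.items():
        P = branch_transition_matrix(model, rate, t)
        logP5 = np.zeros((5, 5))
        with np.errstate(divide="ignore"):
            logP5[:4, :4] = np.log(P)
        total += float((hist * logP5).sum())
    return total


def step4_update_rates(
    element: ElementData,
    z: np.ndarray,
    rates: RateMultipliers,
    tree: Phylogeny,
    model: NeutralModel,
    rate_priors: RatePriors,
    rng: np.random.Generator,
    step_sd: float = 0.3,
) -> tuple[RateMultipliers, dict[str, int]]:
    """One Metropolis step each on log r2 and log r3.

    The target is the complete-data sequence likelihood of the edges in the
    corresponding state times the Gamma prior (with the log-scale random
    walk's Jacobian).  A rate with no edges in its state is sampled against
    its prior alone.
    """
    acc = {"r2": 0, "r3": 0}
    new = {"r2": rates.r2, "r3": rates.r3}
    for name, state, logprior in (
        ("r2", 1, rate_priors.logpdf_r2),
        ("r3", 2, rate_priors.logpdf_r3),
    ):
        cur = new[name]
        hists = _state_transition_histograms(element, z, tree, state)
        prop = cur * math.exp(step_sd * rng.standard_normal())
        ll_cur = _seq_loglik_at_rate(hists, cur, model) if hists else 0.0
        ll_prop = _seq_loglik_at_rate(hists, prop, model) if hists else 0.0
        # Jacobian of the log-scale walk: + log(prop) - log(cur)
        ratio = (
            ll_prop - ll_cur
            + logprior(prop) - logprior(cur)
            + math.log(prop) - math.log(cur)
        )
        if math.log(rng.random()) < ratio:
            new[name] = prop
            acc[name] = 1
    return RateMultipliers(r2=new["r2"], r3=new["r3"]), acc


def log_joint(
    state: ChainState,
    tree: Phylogeny,
    model: NeutralModel,
    matrices: BranchMatrices,
    trait_priors: TraitPriors,
    rate_priors: RatePriors,
) -> float:
    """Log of the full joint density (up to constants) at the current state."""
    element = state.element
    seq = complete_data_seq_loglik(element, state.z, tree, matrices)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi)
    seq += float(logpi[element.X[tree.root].astype(np.intp)].sum())

    trait = trait_log_joint(element.y, state.z, state.vp, tree, trait_priors)

    counts = transition_counts(state.z, tree)
    with np.errstate(divide="ignore"):
        log_phi = np.log(state.tp.phi)
        states_term = float((counts * np.where(counts > 0, log_phi, 0.0)).sum())
        root_term = math.log(ROOT_PRIOR[state.z[tree.root]])

    ls = math.log(state.vp.sigma2)
    l2 = math.log(state.vp.beta2)
    l3 = math.log(state.vp.beta3)
    priors = (
        rate_priors.logpdf_r2(state.rates.r2)
        + rate_priors.logpdf_r3(state.rates.r3)
        + _norm_logpdf(ls, trait_priors.log_sigma2_var)
        + _norm_logpdf(l2, trait_priors.log_beta_var)
        + _norm_logpdf(l3, trait_priors.log_beta_var)
        # Beta(1,1) densities for a, b, c are 0 on the log scale
    )
    return float(seq + trait + states_term + root_term + priors)


def gibbs_sweep(
    state: ChainState,
    tree: Phylogeny,
    model: NeutralModel,
    matrices: BranchMatrices,
    config: RunConfig,
    rng: np.random.Generator,
    trait_priors: TraitPriors,
    rate_priors: RatePriors,
    phi_priors: PhiHyperPriors,
    compute_log_joint: bool = True,
) -> dict[str, float]:
    """Execute one full sweep (steps 1-5) in place; returns acceptance info."""
    element = state.element

    state.vp, acc1 = step1_update_trait(
        element, state.z, state.vp, tree, trait_priors, rng,
        n_inner=config.step1_inner, mix=config.step1_mix,
        param_step_sd=config.param_step_sd, trait_step_scale=config.trait_step_scale,
    )

    matrices.update(state.rates)
    partials, _ = prune_partials(element, state.z, tree, matrices)
    sample_ancestral_nucleotides(element, partials, state.z, tree, model, matrices, rng)

    msg = backward_messages(element, state.rates, state.vp, state.tp, tree, matrices)
    state.z = sample_states(msg, state.tp, tree, rng)

    state.rates, acc4 = step4_update_rates(
        element, state.z, state.rates, tree, model, rate_priors, rng,
        step_sd=config.rate_step_sd,
    )
    matrices.update(state.rates)

    state.tp = update_phi(state.z, tree, phi_priors, rng)
    state.iteration += 1
    if compute_log_joint:
        state.log_joint = log_joint(state, tree, model, matrices, trait_priors, rate_priors)
    return {
        "step1_param_accept": acc1["param_accept"],
        "step1_trait_accept": acc1["trait_accept"],
        "r2_accept": float(acc4["r2"]),
        "r3_accept": float(acc4["r3"]),
    }


def init_chain_state(
    element: ElementData,
    tree: Phylogeny,
    model: NeutralModel,
    rng: np.random.Generator,
) -> ChainState:
    """Overdispersed start: all parameters drawn from their priors, latent data
    re-initialized, states drawn from the prior Markov process."""
    element = copy.deepcopy(element)
    initialize_latent(element, tree, model, rng)
    tp, rates, vp = draw_prior_params(rng)
    z = sim_z(tree, tp, rng)
    return ChainState(element=element, z=z, rates=rates, vp=vp, tp=tp)


def run_chain(
    element: ElementData,
    tree: Phylogeny,
    model: NeutralModel,
    config: RunConfig,
    rng: np.random.Generator,
    log_joint_every: int = 1,
) -> pd.DataFrame:
    """Run a single chain; returns the per-iteration trace of monitored scalars."""
    trait_priors = TraitPriors()
    rate_priors = RatePriors()
    phi_priors = PhiHyperPriors()
    state = init_chain_state(element, tree, model, rng)
    matrices = BranchMatrices(tree, model)
    rows = np.empty((config.n_iter, len(MONITORED) + 4))
    for it in range(config.n_iter):
        acc = gibbs_sweep(
            state, tree, model, matrices, config, rng,
            trait_priors, rate_priors, phi_priors,
            compute_log_joint=(it % log_joint_every == 0),
        )
        rows[it] = [
            math.log(state.vp.sigma2), math.log(state.vp.beta2), math.log(state.vp.beta3),
            state.vp.log_beta_ratio, state.rates.r2, state.rates.r3,
            state.tp.a, state.tp.b, state.tp.c, state.log_joint,
            acc["step1_param_accept"], acc["step1_trait_accept"],
            acc["r2_accept"], acc["r3_accept"],
        ]
    cols = MONITORED + ["step1_param_accept", "step1_trait_accept", "r2_accept", "r3_accept"]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "iteration", np.arange(config.n_iter))
    return df


def gelman_rubin(chains: np.ndarray, split: bool = True) -> float:
    """Classic (split-chain) Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half so the
    statistic is sensitive to within-chain drift even with few chains.
    """
    chains = np.asarray(chains, dtype=float)
    if split:
        n = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :n], chains[:, n: 2 * n]], axis=0)
    m, n = chains.shape
    if n < 2:
        return math.nan
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else math.inf
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


def rank_normalized_rhat(chains: np.ndarray) -> float:
    """Split R-hat on rank-normalized draws (robust to heavy tails)."""
    flat = np.asarray(chains, dtype=float)
    ranks = sps.rankdata(flat.reshape(-1)).reshape(flat.shape)
    zscores = sps.norm.ppf((ranks - 0.375) / (flat.size + 0.25))
    return gelman_rubin(zscores, split=True)


def run_chains(
    element: ElementData,
    tree: Phylogeny,
    model: NeutralModel,
    config: RunConfig,
    log_joint_every: int = 1,
) -> dict:
    """Run ``config.n_chains`` independent chains and summarize.

    Returns a dict with the per-chain traces, pooled post-burn-in samples,
    per-scalar split Gelman-Rubin statistics (classic drives the convergence
    flag; the rank-normalized variant is reported alongside), posterior
    medians and 10th/90th percentiles, and mean acceptance rates.
    """
    ss = np.random.SeedSequence(config.seed)
    traces = [
        run_chain(element, tree, model, config, np.random.default_rng(child), log_joint_every)
        for child in ss.spawn(config.n_chains)
    ]
    burn = int(config.n_iter * config.burn_in_fraction)
    post = [t.iloc[burn::config.thin] for t in traces]

    rhat: dict[str, float] = {}
    rhat_rank: dict[str, float] = {}
    for name in MONITORED:
        if name == "log_joint":
            continue
        arr = np.stack([p[name].to_numpy() for p in post])
        rhat[name] = gelman_rubin(arr)
        rhat_rank[name] = rank_normalized_rhat(arr)
    rhat_max = max(rhat.values())
    pooled = pd.concat(post, ignore_index=True)

    summary = {
        "n_chains": config.n_chains,
        "n_iter": config.n_iter,
        "n_post_samples": len(pooled),
        "rhat": rhat,
        "rhat_rank_normalized": rhat_rank,
        "rhat_max": float(rhat_max),
        "converged": bool(rhat_max < config.rhat_threshold),
        "medians": {k: float(pooled[k].median()) for k in MONITORED},
        "q10": {k: float(pooled[k].quantile(0.10)) for k in MONITORED},
        "q90": {k: float(pooled[k].quantile(0.90)) for k in MONITORED},
        "acceptance": {
            k: float(pooled[k].mean())
            for k in ["step1_param_accept", "step1_trait_accept", "r2_accept", "r3_accept"]
        },
        "seed": config.seed,
    }
    return {"traces": traces, "pooled": pooled, "summary": summary}
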