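"""The conservation-state Markov process on the tree.

Each branch carries a latent state: background (0), conserved (1) or
accelerated (2) — reported to users as 1/2/3.  States follow a root-to-tip
Markov chain with transition matrix::

    Phi = [[1-c,  c,   0 ],
           [ 0,  1-a,  a ],
           [ 0,   b,  1-b]]

whose structural zeros forbid returning to background and jumping directly
from background to accelerated.  The root state is background or conserved
with probability 0.5 each (never accelerated).  Conditional on filled-in
sequences and traits, states are resampled exactly: a tips-to-root pass
accumulates log messages combining sequence and trait emissions with child
messages, then a root-to-tips pass draws each state from its conditional.
The (a, b, c) entries get conjugate Beta updates from transition counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .treeio import Phylogeny, NeutralModel
from .element_io import ElementData, MISSING
from .substitution_model import BranchMatrices, RateMultipliers
from .trait_model import VarianceParams, _LOG2PI

BACKGROUND, CONSERVED, ACCELERATED = 0, 1, 2
ROOT_PRIOR = np.array([0.5, 0.5, 0.0])


def build_phi(a: float, b: float, c: float) -> np.ndarray:
    """Root-to-tip state transition matrix from (a, b, c) in (0,1)^3."""
    for name, val in (("a", a), ("b", b), ("c", c)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"transition parameter {name}={val} must lie strictly in (0, 1)")
    return np.array([
        [1.0 - c, c, 0.0],
        [0.0, 1.0 - a, a],
        [0.0, b, 1.0 - b],
    ])


@dataclass
class TransitionParams:
    """State-transition probabilities: a (cons->accel), b (accel->cons), c (bg->cons)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        build_phi(self.a, self.b, self.c)  # domain check

    @property
    def phi(self) -> np.ndarray:
        return build_phi(self.a, self.b, self.c)

    @property
    def log_phi(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.phi)


@dataclass
class PhiHyperPriors:
    """Beta pseudo-counts shared by a, b and c; Beta(1,1) is the uniform prior."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Beta pseudo-counts must be positive")


@dataclass
class LatentStates:
    """Per-node conservation states (root included) plus the root-state prior."""

    z: np.ndarray
    root_prior: np.ndarray = field(default_factory=lambda: ROOT_PRIOR.copy())

    def validate(self, tree: Phylogeny) -> None:
        if self.z[tree.root] == ACCELERATED and self.root_prior[ACCELERATED] == 0.0:
            raise ValueError("root in accelerated state has zero prior probability")
        par = tree.parent
        for j in range(tree.n_nodes):
            if j == tree.root:
                continue
            zi, zj = self.z[par[j]], self.z[j]
            if zj == BACKGROUND and zi != BACKGROUND:
                raise ValueError(f"forbidden return to background on edge above node {j}")
            if zi == BACKGROUND and zj == ACCELERATED:
                raise ValueError(f"forbidden background->accelerated jump above node {j}")


def backward_messages(
    element: ElementData,
    rates: RateMultipliers,
    vp: VarianceParams,
    tp: TransitionParams,
    tree: Phylogeny,
    matrices: BranchMatrices,
) -> np.ndarray:
    """Tips-to-root log messages for state resampling.

    ``msg[i, k]`` is the log joint density of all sequence and trait emissions
    in the subtree rooted at node ``i`` (with ancestral X and y filled in,
    child states marginalized), given that the branch above ``i`` is in state
    ``k``: the per-site log transition probabilities of the branch above
    ``i``, plus the trait displacement density, plus log-sum-exp mixing of
    the children's messages through Phi.  The root row combines the children
    only (the root's own nucleotide and trait priors do not depend on its
    state and cancel in the conditional).
    """
    N = tree.n_nodes
    X = element.X
    y = element.y
    v = vp.v
    emis = np.zeros((N, 3))
    root = tree.root

    non_root = np.arange(N) != root
    par = tree.parent
    # Sequence emissions: gather log P_k[x_parent, x_child] summed over sites.
    # logP5 carries zero rows/cols at the MISSING code, so gaps contribute 0.
    jj = np.where(non_root)[0]
    Xp = X[par[jj]].astype(np.intp)
    Xc = X[jj].astype(np.intp)
    for k in range(3):
        emis[jj, k] = matrices.logP5[jj[:, None], k, Xp, Xc].sum(axis=1)
    # Trait emissions.
    t = tree.branch_length[non_root]
    d = y[non_root] - y[par[non_root]]
    var = t[:, None] * v[None, :]
    emis[non_root] += -0.5 * (_LOG2PI + np.log(var) + (d * d)[:, None] / var)

    log_phi = tp.log_phi
    msg = np.zeros((N, 3))
    msg[: tree.n_leaves] = emis[: tree.n_leaves]
    for nodes in tree.pruning_levels[1:]:
        c0 = tree.children[nodes, 0]
        c1 = tree.children[nodes, 1]
        A = _lse_mix(log_phi, msg[c0])
        B = _lse_mix(log_phi, msg[c1])
        msg[nodes] = emis[nodes] + A + B
    return msg


def _lse_mix(log_phi: np.ndarray, child_msg: np.ndarray) -> np.ndarray:
    """Row-wise log sum_k' exp(log_phi[k, k'] + child_msg[:, k']); (n, 3) out."""
    M = log_phi[None, :, :] + child_msg[:, None, :]
    mx = M.max(axis=2)
    # structural zeros give -inf columns; exp(-inf - mx) underflows to 0 safely
    return mx + np.log(np.exp(M - mx[:, :, None]).sum(axis=2))


def sample_states(
    msg: np.ndarray,
    tp: TransitionParams,
    tree: Phylogeny,
    rng: np.random.Generator,
    root_prior: np.ndarray = ROOT_PRIOR,
) -> np.ndarray:
    """Root-to-tips exact conditional draw of all conservation states."""
    z = np.zeros(tree.n_nodes, dtype=np.int8)
    root = tree.root
    with np.errstate(divide="ignore"):
        logw = np.log(root_prior) + msg[root]
    z[root] = _draw_log(logw[None, :], rng)[0]
    log_phi = tp.log_phi
    for nodes in tree.preorder_levels[1:]:
        logw = log_phi[z[tree.parent[nodes]]] + msg[nodes]  # (n, 3)
        z[nodes] = _draw_log(logw, rng)
    return z


def _draw_log(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise exact categorical draws from unnormalized log weights (n, 3)."""
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    cdf = np.cumsum(w, axis=1)
    u = rng.random(len(w)) * cdf[:, -1]
    return (u[:, None] >= cdf).sum(axis=1).astype(np.int8)


def state_posteriors_exact(
    msg: np.ndarray,
    tp: TransitionParams,
    tree: Phylogeny,
    root_prior: np.ndarray = ROOT_PRIOR,
) -> np.ndarray:
    """Exact per-node marginal state posteriors implied by the messages.

    Outside-in marginalization companion to :func:`sample_states`; used for
    reporting and as an internal cross-check of the sampler.
    """
    N = tree.n_nodes
    root = tree.root
    log_phi = tp.log_phi
    logpost = np.full((N, 3), -np.inf)
    with np.errstate(divide="ignore"):
        lw = np.log(root_prior) + msg[root]
    logpost[root] = lw - logsumexp(lw)
    for node in tree.preorder:
        if node == root:
            continue
        pa = tree.parent[node]
        # sum over parent state of P(z_pa | data above) x conditional of child
        cond = log_phi + msg[node][None, :]
        cond = cond - logsumexp(cond, axis=1, keepdims=True)
        logpost[node] = logsumexp(logpost[pa][:, None] + cond, axis=0)
    return np.exp(logpost)


def transition_counts(z: np.ndarray, tree: Phylogeny) -> np.ndarray:
    """3x3 parent->child state transition counts over all edges."""
    non_root = np.arange(tree.n_nodes) != tree.root
    zi = z[tree.parent[non_root]]
    zj = z[non_root]
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (zi, zj), 1)
    return counts


def update_phi(
    z: np.ndarray,
    tree: Phylogeny,
    hp: PhiHyperPriors,
    rng: np.random.Generator,
) -> TransitionParams:
    """Conjugate Beta draw of (a, b, c) from parent->child transition counts."""
    counts = transition_counts(z, tree)
    forbidden = counts[1, 0] + counts[2, 0] + counts[0, 2]
    if forbidden:
        raise RuntimeError(
            "state assignment contains transitions with zero prior probability"
        )
    c = rng.beta(hp.alpha + counts[0, 1], hp.beta + counts[0, 0])
    a = rng.beta(hp.alpha + counts[1, 2], hp.beta + counts[1, 1])
    b = rng.beta(hp.alpha + counts[2, 1], hp.beta + counts[2, 2])
    eps = 1e-12
    clip = lambda x: min(max(x, eps), 1.0 - eps)
    return TransitionParams(a=clip(a), b=clip(b), c=clip(c))
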