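"""Brownian-motion trait model with per-state variance multipliers.

A trait diffuses along the tree with displacement variance ``t_j * v_{z_j}``
on the branch above node ``j``, where ``v = (sigma2, beta2*sigma2,
beta3*sigma2)`` by conservation state.  The root value has a Normal(0, 1)
prior.  This module evaluates the trait part of the joint density and runs
the Metropolis-within-Gibbs block that updates (sigma2, beta2, beta3) and
the latent trait values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .treeio import Phylogeny
from .element_io import ElementData

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class VarianceParams:
    """Trait variance rate sigma2 and state multipliers beta2, beta3.

    Per-state variance per unit branch length is ``(sigma2, beta2*sigma2,
    beta3*sigma2)`` for background/conserved/accelerated.
    """

    sigma2: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0 and self.beta2 > 0 and self.beta3 > 0):
            raise ValueError("sigma2, beta2, beta3 must all be strictly positive")

    @property
    def v(self) -> np.ndarray:
        return np.array([self.sigma2, self.beta2 * self.sigma2, self.beta3 * self.sigma2])

    @property
    def log_beta_ratio(self) -> float:
        return math.log(self.beta3 / self.beta2)


@dataclass
class TraitPriors:
    """Priors for the trait block.  Second parameter of every Normal is a VARIANCE."""

    root_mean: float = 0.0
    root_var: float = 1.0
    log_sigma2_var: float = 2.0
    log_beta_var: float = 1.0

    def __post_init__(self) -> None:
        if not (self.root_var > 0 and self.log_sigma2_var > 0 and self.log_beta_var > 0):
            raise ValueError("prior variances must be positive")

    def log_prior(self, vp: VarianceParams) -> float:
        """Log prior density of (log sigma2, log beta2, log beta3) at vp."""
        ls, l2, l3 = math.log(vp.sigma2), math.log(vp.beta2), math.log(vp.beta3)
        return (
            _normal_logpdf(ls, 0.0, self.log_sigma2_var)
            + _normal_logpdf(l2, 0.0, self.log_beta_var)
            + _normal_logpdf(l3, 0.0, self.log_beta_var)
        )


def _normal_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (_LOG2PI + math.log(var) + (x - mean) ** 2 / var)


def trait_branch_logdensity(y_child: float, y_parent: float, t: float, v_state: float) -> float:
    """Log Normal(y_child; y_parent, t * v_state) — one branch displacement."""
    return _normal_logpdf(y_child, y_parent, t * v_state)


def trait_log_joint(
    y: np.ndarray,
    z: np.ndarray,
    vp: VarianceParams,
    tree: Phylogeny,
    priors: TraitPriors,
) -> float:
    """Trait factor of the joint density: all branch displacements + root prior."""
    root = tree.root
    nodes = np.arange(tree.n_nodes) != root
    par = tree.parent[nodes]
    d = y[nodes] - y[par]
    var = tree.branch_length[nodes] * vp.v[z[nodes]]
    branch_term = -0.5 * np.sum(_LOG2PI + np.log(var) + d * d / var)
    return float(branch_term + _normal_logpdf(y[root], priors.root_mean, priors.root_var))


class _TraitSuffStats:
    """Per-state sufficient statistics of the branch displacements.

    With edges grouped by state, the trait log joint is
    ``sum_k [-n_k/2 log v_k - sse_k / (2 v_k)] + const(y, t)``, where
    ``sse_k = sum d_j^2 / t_j`` over edges in state k.  Parameter proposals
    are then O(1); latent-y proposals touch only the incident edges.
    """

    def __init__(self, y: np.ndarray, z: np.ndarray, tree: Phylogeny):
        self.tree = tree
        self.z = z
        self.y = y
        self.n = np.zeros(3)
        self.sse = np.zeros(3)
        root = tree.root
        for j in range(tree.n_nodes):
            if j == root:
                continue
            d = y[j] - y[tree.parent[j]]
            self.n[z[j]] += 1.0
            self.sse[z[j]] += d * d / tree.branch_length[j]

    def loglik_v(self, v: np.ndarray) -> float:
        """State-dependent part of the trait log joint (up to y,t-only constants)."""
        return float(np.sum(-0.5 * self.n * np.log(v) - 0.5 * self.sse / v))

    def edge_delta(self, j: int, y_child: float, y_parent: float) -> float:
        return (y_child - y_parent) ** 2 / self.tree.branch_length[j]


def step1_update_trait(
    element: ElementData,
    z: np.ndarray,
    vp: VarianceParams,
    tree: Phylogeny,
    priors: TraitPriors,
    rng: np.random.Generator,
    n_inner: int = 500,
    mix: float = 0.6,
    param_step_sd: float = 0.3,
    trait_step_scale: float = 0.5,
) -> tuple[VarianceParams, dict[str, float]]:
    """Metropolis block updating (sigma2, beta2, beta3) and latent trait values.

    Runs ``n_inner`` inner Metropolis iterations.  Each iteration flips an
    independent Bernoulli(``mix``) coin: on success it proposes a Gaussian
    random-walk move on one of (log sigma2, log beta2, log beta3) chosen
    uniformly; otherwise it perturbs one latent trait entry (an internal node
    or a leaf with unobserved trait) chosen uniformly.  The latent-y step
    s.d. is ``trait_step_scale * sqrt(median branch length * sigma2)``.
    Updates ``element.y`` in place and returns the new variance parameters
    plus acceptance statistics.
    """
    y = element.y
    root = tree.root
    latent = element.latent_trait_nodes(tree)
    n_latent = len(latent)
    parent = tree.parent
    blen = tree.branch_length
    children_of = tree.children_lists
    med_t = float(np.median(np.delete(blen, root)))

    # Per-state sufficient statistics: edge counts and sum of d^2 / t.
    zl = z.tolist()
    n_k = [0.0, 0.0, 0.0]
    sse = [0.0, 0.0, 0.0]
    for j in range(tree.n_nodes):
        if j == root:
            continue
        d = y[j] - y[parent[j]]
        n_k[zl[j]] += 1.0
        sse[zl[j]] += d * d / blen[j]

    lp = [math.log(vp.sigma2), math.log(vp.beta2), math.log(vp.beta3)]
    prior_vars = (priors.log_sigma2_var, priors.log_beta_var, priors.log_beta_var)
    log = math.log
    exp = math.exp

    def v_of(p: list[float]) -> tuple[float, float, float]:
        s2 = exp(p[0])
        return (s2, exp(p[1]) * s2, exp(p[2]) * s2)

    def loglik(v: tuple[float, float, float]) -> float:
        return (
            -0.5 * (n_k[0] * log(v[0]) + sse[0] / v[0])
            - 0.5 * (n_k[1] * log(v[1]) + sse[1] / v[1])
            - 0.5 * (n_k[2] * log(v[2]) + sse[2] / v[2])
        )

    v_cur = v_of(lp)
    loglik_cur = loglik(v_cur)

    # Pre-generate all randomness for the inner loop.
    coins = rng.random(n_inner) < mix
    normals = rng.standard_normal(n_inner)
    uniforms = rng.random(n_inner)
    which_param = rng.integers(3, size=n_inner)
    which_node = latent[rng.integers(n_latent, size=n_inner)] if n_latent else None

    yl = y.tolist()
    accept = {"param": 0, "param_tries": 0, "trait": 0, "trait_tries": 0}

    for i in range(n_inner):
        if coins[i] or n_latent == 0:
            accept["param_tries"] += 1
            w = which_param[i]
            old = lp[w]
            lp[w] = old + param_step_sd * normals[i]
            v_prop = v_of(lp)
            loglik_prop = loglik(v_prop)
            dprior = (old * old - lp[w] * lp[w]) / (2.0 * prior_vars[w])
            if log(uniforms[i]) < loglik_prop - loglik_cur + dprior:
                v_cur = v_prop
                loglik_cur = loglik_prop
                accept["param"] += 1
            else:
                lp[w] = old
        else:
            accept["trait_tries"] += 1
            node = which_node[i]
            step_sd = trait_step_scale * math.sqrt(med_t * exp(lp[0]))
            y_old = yl[node]
            y_new = y_old + step_sd * normals[i]
            delta_ll = 0.0
            d0 = d1 = d2 = 0.0
            if node == root:
                delta_ll += (y_old * y_old - y_new * y_new) / (2.0 * priors.root_var)
            else:
                k = zl[node]
                yp = yl[parent[node]]
                dd = ((y_new - yp) ** 2 - (y_old - yp) ** 2) / blen[node]
                if k == 0:
                    d0 += dd
                elif k == 1:
                    d1 += dd
                else:
                    d2 += dd
            for c in children_of[node]:
                k = zl[c]
                yc = yl[c]
                dd = ((yc - y_new) ** 2 - (yc - y_old) ** 2) / blen[c]
                if k == 0:
                    d0 += dd
                elif k == 1:
                    d1 += dd
                else:
                    d2 += dd
            delta_ll -= 0.5 * (d0 / v_cur[0] + d1 / v_cur[1] + d2 / v_cur[2])
            if log(uniforms[i]) < delta_ll:
                yl[node] = y_new
                sse[0] += d0
                sse[1] += d1
                sse[2] += d2
                loglik_cur = loglik(v_cur)
                accept["trait"] += 1

    y[:] = yl
    new_vp = VarianceParams(sigma2=exp(lp[0]), beta2=exp(lp[1]), beta3=exp(lp[2]))
    rates = {
        "param_accept": accept["param"] / max(accept["param_tries"], 1),
        "trait_accept": accept["trait"] / max(accept["trait_tries"], 1),
        **{k: float(v) for k, v in accept.items()},
    }
    return new_vp, rates
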