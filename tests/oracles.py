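"""Independent brute-force oracles for small instances.

Everything here enumerates latent configurations directly (no pruning, no
message passing) and is only feasible on trees with a handful of nodes; the
main code paths are checked against these on tiny fixtures.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from acctrait.element_io import MISSING
from acctrait.latent_states import ROOT_PRIOR
from acctrait.substitution_model import branch_transition_matrix


def enumerate_seq_likelihood(X_leaves, z, rates, tree, model):
    """Marginal likelihood of the leaf data at each site by enumerating all
    ancestral nucleotide assignments.  Returns an array of per-site likelihoods."""
    L, S = X_leaves.shape
    N = tree.n_nodes
    r = rates.as_array
    P = {
        j: branch_transition_matrix(model, float(r[z[j]]), float(tree.branch_length[j]))
        for j in range(N)
        if j != tree.root
    }
    internals = list(range(L, N))
    out = np.zeros(S)
    for s in range(S):
        total = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            x = np.zeros(N, dtype=int)
            x[:L] = X_leaves[:, s]
            x[L:] = assign
            p = model.pi[x[tree.root]]
            for j in range(N):
                if j == tree.root:
                    continue
                if x[j] == MISSING:
                    continue  # missing leaf: sum over its state of P(.->b) = 1
                p *= P[j][x[tree.parent[j]], x[j]]
            total += p
        out[s] = total
    return out


def enumerate_ancestral_posterior(X_leaves, z, rates, tree, model, node):
    """Posterior P(nucleotide at ``node`` | leaf data) for a 1-site element,
    by enumerating every ancestral assignment."""
    L = X_leaves.shape[0]
    N = tree.n_nodes
    r = rates.as_array
    P = {
        j: branch_transition_matrix(model, float(r[z[j]]), float(tree.branch_length[j]))
        for j in range(N)
        if j != tree.root
    }
    internals = list(range(L, N))
    post = np.zeros(4)
    for assign in itertools.product(range(4), repeat=len(internals)):
        x = np.zeros(N, dtype=int)
        x[:L] = X_leaves[:, 0]
        x[L:] = assign
        p = model.pi[x[tree.root]]
        for j in range(N):
            if j == tree.root or x[j] == MISSING:
                continue
            p *= P[j][x[tree.parent[j]], x[j]]
        post[x[node]] += p
    return post / post.sum()


def enumerate_state_posterior(element, rates, vp, tp, tree, model):
    """Joint posterior over all per-node conservation states given filled-in
    X and y, by enumerating every reachable z assignment.

    Returns a dict mapping state tuples (over all nodes, root included) to
    probabilities.
    """
    N = tree.n_nodes
    phi = tp.phi
    r = rates.as_array
    v = vp.v
    X, y = element.X, element.y
    weights: dict[tuple, float] = {}
    for assign in itertools.product(range(3), repeat=N):
        z = np.array(assign, dtype=int)
        p = ROOT_PRIOR[z[tree.root]]
        if p == 0:
            continue
        for j in range(N):
            if j == tree.root:
                continue
            p *= phi[z[tree.parent[j]], z[j]]
            if p == 0:
                break
            t = float(tree.branch_length[j])
            P = branch_transition_matrix(model, float(r[z[j]]), t)
            for s in range(element.n_sites):
                if X[j, s] == MISSING:
                    continue
                p *= P[X[tree.parent[j], s], X[j, s]]
            var = t * v[z[j]]
            d = y[j] - y[tree.parent[j]]
            p *= math.exp(-0.5 * (math.log(2 * math.pi * var) + d * d / var))
        if p > 0:
            weights[tuple(assign)] = p
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


def bm_tip_moments(tree, z, vp, root_var=1.0):
    """Exact mean-zero covariance matrix of the leaf trait values under the
    state-modulated Brownian motion (shared-path variance accumulation)."""
    N = tree.n_nodes
    v = vp.v
    # variance accumulated along the path root -> node
    path_var = np.zeros(N)
    for node in tree.preorder:
        if node == tree.root:
            path_var[node] = root_var
        else:
            path_var[node] = (
                path_var[tree.parent[node]] + tree.branch_length[node] * v[z[node]]
            )
    L = tree.n_leaves
    # ancestor sets
    ancestors = []
    for leaf in range(L):
        anc = set()
        n = leaf
        while n != -1:
            anc.add(n)
            n = int(tree.parent[n])
        ancestors.append(anc)
    cov = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            shared = ancestors[i] & ancestors[j]
            mrca = max(shared, key=lambda n: path_var[n])
            cov[i, j] = path_var[mrca]
    return cov
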