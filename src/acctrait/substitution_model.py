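"""State-modulated nucleotide substitution process.

The neutral rate matrix Q is scaled per branch by the rate multiplier of the
branch's conservation state, ``r = (1, r2, r3)``, giving transition matrices
``P = expm(Q * r_k * t_j)``.  This module provides those matrices (cached per
distinct ``r_k * t_j``), Felsenstein's pruning recursion over the observed
leaf rows, and exact forward (root-to-tips) sampling of ancestral
nucleotides from their joint conditional distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .treeio import Phylogeny, NeutralModel
from .element_io import ElementData, MISSING


@dataclass
class RateMultipliers:
    """Per-state substitution rate multipliers; the background rate is fixed at 1."""

    r2: float
    r3: float

    def __post_init__(self) -> None:
        if not (self.r2 > 0 and self.r3 > 0):
            raise ValueError("rate multipliers must be strictly positive")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([1.0, self.r2, self.r3])


def branch_transition_matrix(model: NeutralModel, rate: float, t: float) -> np.ndarray:
    """``expm(Q * rate * t)``: nucleotide transition probabilities on one branch."""
    if not (rate > 0 and t > 0):
        raise ValueError("rate and branch length must be > 0")
    P = expm(model.Q * (rate * t))
    if not np.all(np.isfinite(P)):
        raise FloatingPointError(f"non-finite transition matrix for rate={rate}, t={t}")
    drift = np.max(np.abs(P.sum(axis=1) - 1.0))
    if drift > 1e-12:
        P = P / P.sum(axis=1, keepdims=True)
    np.clip(P, 0.0, None, out=P)
    return P


class BranchMatrices:
    """Per-branch, per-state transition matrices for the current rate multipliers.

    Matrix exponentials are computed once per distinct scaled distance
    ``r_k * t_j`` and cached; the cache is rebuilt whenever (r2, r3) change.
    ``P[j, k]`` and ``logP5[j, k]`` address the edge above node ``j`` in
    conservation state ``k`` (0-based).  ``logP5`` is 5x5 with zero rows and
    columns for the MISSING code so emission terms can be gathered without
    masking.
    """

    def __init__(self, tree: Phylogeny, model: NeutralModel):
        self.tree = tree
        self.model = model
        self._rates: tuple[float, float] | None = None
        self._expm_cache: dict[float, np.ndarray] = {}
        N = tree.n_nodes
        self.P = np.zeros((N, 3, 4, 4))
        self.logP5 = np.zeros((N, 3, 5, 5))

    def update(self, rates: RateMultipliers) -> None:
        key = (rates.r2, rates.r3)
        if key == self._rates:
            return
        self._rates = key
        r = rates.as_array
        tree = self.tree
        jj = np.delete(np.arange(tree.n_nodes), tree.root)
        dist = tree.branch_length[jj, None] * r[None, :]  # (E, 3)
        uniq, inv = np.unique(dist, return_inverse=True)
        stack = np.empty((len(uniq), 4, 4))
        for u, d in enumerate(uniq):
            P = self._expm_cache.get(float(d))
            if P is None:
                P = branch_transition_matrix(self.model, 1.0, float(d))
                self._expm_cache[float(d)] = P
            stack[u] = P
        with np.errstate(divide="ignore"):
            log_stack = np.log(stack)
        idx = inv.reshape(dist.shape)
        self.P[jj] = stack[idx]
        self.logP5[jj[:, None], np.arange(3)[None, :], :4, :4] = log_stack[idx]
        if len(self._expm_cache) > 8192:
            self._expm_cache.clear()

    def matrix(self, node: int, state: int) -> np.ndarray:
        """Transition matrix for the edge above ``node`` given 0-based state."""
        return self.P[node, state]


def leaf_partials(X_row: np.ndarray) -> np.ndarray:
    """Indicator emission vectors for one leaf: (4, S); all-ones where MISSING."""
    S = X_row.shape[0]
    out = np.zeros((4, S))
    obs = X_row != MISSING
    out[:, ~obs] = 1.0
    out[X_row[obs], np.nonzero(obs)[0]] = 1.0
    return out


def prune_partials(
    element: ElementData,
    z: np.ndarray,
    tree: Phylogeny,
    matrices: BranchMatrices,
) -> tuple[np.ndarray, np.ndarray]:
    """Felsenstein pruning over observed leaf rows, conditional on z and r.

    Returns ``(partials, logscale)``: ``partials[i, x, s]`` is the scaled
    likelihood of the leaf data below node ``i`` given nucleotide ``x`` at
    ``i``; the true log partial is ``log partials[i, x, s] + logscale[i, s]``.
    Per-node, per-site rescaling keeps values in floating range.
    """
    N, S = tree.n_nodes, element.n_sites
    L = tree.n_leaves
    partials = np.empty((N, 4, S))
    logscale = np.zeros((N, S))
    Xl = element.X[:L]
    obs = Xl != MISSING
    partials[:L] = np.where(
        obs[:, None, :],
        (Xl[:, None, :] == np.arange(4)[None, :, None]).astype(float),
        1.0,
    )
    for nodes in tree.pruning_levels[1:]:
        c0 = tree.children[nodes, 0]
        c1 = tree.children[nodes, 1]
        M0 = np.einsum("nij,njs->nis", matrices.P[c0, z[c0]], partials[c0])
        M1 = np.einsum("nij,njs->nis", matrices.P[c1, z[c1]], partials[c1])
        acc = M0 * M1
        mx = acc.max(axis=1)  # (n, S); all-MISSING subtrees rescale by 1
        acc /= mx[:, None, :]
        partials[nodes] = acc
        logscale[nodes] = logscale[c0] + logscale[c1] + np.log(mx)
    return partials, logscale


def sequence_log_likelihood(
    partials: np.ndarray, logscale: np.ndarray, tree: Phylogeny, model: NeutralModel
) -> float:
    """Total log likelihood of the leaf alignment: sum over sites at the root."""
    root = tree.root
    site_lik = model.pi @ partials[root]
    return float(np.sum(np.log(site_lik) + logscale[root]))


def sample_ancestral_nucleotides(
    element: ElementData,
    partials: np.ndarray,
    z: np.ndarray,
    tree: Phylogeny,
    model: NeutralModel,
    matrices: BranchMatrices,
    rng: np.random.Generator,
) -> None:
    """Draw all ancestral rows of X from their exact joint conditional, in place.

    Root sites are drawn proportional to ``pi_x * partial(root, x, s)``; every
    other internal node is drawn root-to-tips proportional to
    ``partial(j, x, s) * P_j[x_parent, x]``.
    """
    root = tree.root
    w = partials[root] * model.pi[:, None]  # (4, S)
    element.X[root] = _categorical_per_site(w[None, :, :], rng)[0]
    for level in tree.preorder_levels[1:]:
        nodes = level[level >= tree.n_leaves]
        if len(nodes) == 0:
            continue
        pstates = element.X[tree.parent[nodes]].astype(np.intp)  # (n, S)
        Pn = matrices.P[nodes, z[nodes]]  # (n, 4, 4)
        rows = Pn[np.arange(len(nodes))[:, None], pstates]  # (n, S, 4)
        w = partials[nodes] * np.swapaxes(rows, 1, 2)  # (n, 4, S)
        element.X[nodes] = _categorical_per_site(w, rng)


def _categorical_per_site(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw along axis 1 of an (n, 4, S) weight array."""
    cdf = np.cumsum(w, axis=1)
    total = cdf[:, -1, :]
    if np.any(total <= 0) or not np.all(np.isfinite(total)):
        raise FloatingPointError("zero or non-finite total probability in ancestral sampling")
    u = rng.random(total.shape) * total
    return (u[:, None, :] >= cdf).sum(axis=1).astype(np.int8)
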