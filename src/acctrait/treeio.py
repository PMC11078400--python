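"""Rooted phylogenies and neutral substitution models.

Node indexing convention used throughout the package
---------------------------------------------------
Leaves are numbered ``0 .. L-1`` in the order they are encountered in the
Newick string; internal nodes are numbered in postorder completion order
from ``L``; the root is always ``N - 1`` where ``N = 2L - 1``.  Per-branch
quantities (branch length, conservation state, rate multiplier, trait
displacement) are attached to the edge *above* a node and indexed by the
child node id; the root carries no edge quantities.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import dendropy

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"


class TreeValidationError(ValueError):
    """Raised when a tree violates the model's structural requirements."""


class ModelValidationError(ValueError):
    """Raised when a neutral substitution model is inconsistent."""


@dataclass
class Phylogeny:
    """A rooted, strictly bifurcating phylogeny with branch lengths.

    Attributes
    ----------
    n_leaves:
        Number of leaf species ``L``.
    parent:
        ``(N,)`` int array; ``parent[root] == -1``.
    children:
        ``(N, 2)`` int array; ``-1`` entries for leaves.
    branch_length:
        ``(N,)`` float array of edge lengths above each node, in expected
        substitutions per site under the neutral model; ``nan`` at the root.
    leaf_labels:
        Species names for nodes ``0 .. L-1``.
    postorder:
        All ``N`` node ids with every child before its parent.
    """

    n_leaves: int
    parent: np.ndarray
    children: np.ndarray
    branch_length: np.ndarray
    leaf_labels: list[str]
    postorder: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    @cached_property
    def pruning_levels(self) -> list[np.ndarray]:
        """Nodes grouped by height (leaves first); every group's children lie
        in earlier groups, so tips-to-root passes can be vectorized per group."""
        height = np.zeros(self.n_nodes, dtype=np.int64)
        for node in self.postorder:
            c0, c1 = self.children[node]
            if c0 != -1:
                height[node] = max(height[c0], height[c1]) + 1
        return [np.where(height == h)[0] for h in range(height.max() + 1)]

    @cached_property
    def children_lists(self) -> list[list[int]]:
        """Children of each node as plain lists (empty for leaves)."""
        return [
            [int(c) for c in self.children[n] if c != -1] for n in range(self.n_nodes)
        ]

    @cached_property
    def preorder_levels(self) -> list[np.ndarray]:
        """Nodes grouped by depth from the root, for root-to-tips passes."""
        depth = np.zeros(self.n_nodes, dtype=np.int64)
        for node in self.preorder:
            if node != self.root:
                depth[node] = depth[self.parent[node]] + 1
        return [np.where(depth == d)[0] for d in range(depth.max() + 1)]

    def leaf_index(self, label: str) -> int:
        return self.leaf_labels.index(label)

    def validate(self) -> None:
        N = self.n_nodes
        if self.parent.shape != (N,) or self.children.shape != (N, 2):
            raise TreeValidationError("parent/children arrays have wrong shape")
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise TreeValidationError("exactly one root expected, at node N-1")
        non_root = np.arange(N) != self.root
        if not np.all(self.branch_length[non_root] > 0):
            bad = np.where(non_root & ~(self.branch_length > 0))[0]
            raise TreeValidationError(f"non-positive branch length above node(s) {bad.tolist()}")
        if len(set(self.leaf_labels)) != self.n_leaves or "" in self.leaf_labels:
            raise TreeValidationError("leaf labels must be unique and non-empty")
        seen = np.zeros(N, dtype=bool)
        for node in self.postorder:
            if seen[node]:
                raise TreeValidationError("postorder repeats a node")
            c0, c1 = self.children[node]
            if (c0 == -1) != (c1 == -1):
                raise TreeValidationError(f"node {node} has exactly one child (not bifurcating)")
            if c0 != -1 and not (seen[c0] and seen[c1]):
                raise TreeValidationError("postorder violates child-before-parent")
            seen[node] = True
        if not seen.all():
            raise TreeValidationError("postorder does not cover all nodes")

    def to_newick(self) -> str:
        """Serialize back to a Newick string (round-trips through parse_newick)."""

        def fmt(node: int) -> str:
            if self.is_leaf(node):
                body = self.leaf_labels[node]
            else:
                c0, c1 = self.children[node]
                body = f"({fmt(c0)},{fmt(c1)})"
            if node == self.root:
                return body
            return f"{body}:{self.branch_length[node]:.10g}"

        return fmt(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    root = tree.seed_node
    for nd in tree.preorder_node_iter():
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            where = nd.taxon.label if nd.taxon else ("root" if nd is root else "internal node")
            raise TreeValidationError(
                f"tree is not strictly bifurcating at {where} ({len(kids)} children)"
            )
        if nd is not root and nd.edge.length is None:
            where = nd.taxon.label if nd.taxon else "an internal node"
            raise TreeValidationError(f"missing branch length above {where}")

    leaves = [nd for nd in tree.leaf_node_iter()]
    # Leaf order: order of appearance in the Newick string == preorder of leaves.
    leaf_order = [nd for nd in tree.preorder_node_iter() if nd.is_leaf()]
    L = len(leaves)
    N = 2 * L - 1
    ids: dict[int, int] = {}
    for i, nd in enumerate(leaf_order):
        ids[id(nd)] = i
    nxt = L
    for nd in tree.postorder_node_iter():
        if not nd.is_leaf():
            ids[id(nd)] = nxt
            nxt += 1
    assert nxt == N and ids[id(root)] == N - 1

    parent = np.full(N, -1, dtype=np.int64)
    children = np.full((N, 2), -1, dtype=np.int64)
    blen = np.full(N, np.nan)
    labels = [""] * L
    post = []
    for nd in tree.postorder_node_iter():
        i = ids[id(nd)]
        post.append(i)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeValidationError("leaf without a label")
            labels[i] = nd.taxon.label
        else:
            c = [ids[id(k)] for k in nd.child_nodes()]
            children[i] = c
            for k in c:
                parent[k] = i
        if nd is not root:
            blen[i] = nd.edge.length

    phy = Phylogeny(L, parent, children, blen, labels, np.asarray(post))
    phy.validate()
    return phy


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted bifurcating Newick tree with branch lengths.

    Quoted labels and square-bracket comments are accepted; internal labels
    (e.g. bootstrap values) are ignored.  Polytomies, a trifurcating root and
    missing branch lengths raise :class:`TreeValidationError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(tree)


def make_full_binary_tree(depth: int, branch_length: float) -> Phylogeny:
    """Balanced ultrametric binary tree with ``2**depth`` leaves.

    Every branch has the same length, so each root-to-tip path sums to
    ``depth * branch_length``.  Leaves are named ``t1 .. t2^depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not branch_length > 0:
        raise ValueError("branch_length must be > 0")
    L = 2 ** depth
    N = 2 * L - 1
    parent = np.full(N, -1, dtype=np.int64)
    children = np.full((N, 2), -1, dtype=np.int64)

    # Build bottom-up: level d has 2**d nodes; leaves are level `depth`.
    level = list(range(L))  # leaf ids in left-to-right order
    nxt = L
    while len(level) > 1:
        new_level = []
        for a, b in zip(level[::2], level[1::2]):
            children[nxt] = (a, b)
            parent[a] = nxt
            parent[b] = nxt
            new_level.append(nxt)
            nxt += 1
        level = new_level

    # Renumber internals to postorder-completion order from L.
    order: list[int] = []

    def collect(node: int) -> None:
        c0, c1 = children[node]
        if c0 != -1:
            collect(c0)
            collect(c1)
        order.append(node)

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, N + 100))
    try:
        collect(N - 1)
        remap = np.arange(N)
        pos = L
        for node in order:
            if node >= L:
                remap[node] = pos
                pos += 1
        parent2 = np.full(N, -1, dtype=np.int64)
        children2 = np.full((N, 2), -1, dtype=np.int64)
        for i in range(N):
            j = remap[i]
            if parent[i] != -1:
                parent2[j] = remap[parent[i]]
            if children[i, 0] != -1:
                children2[j] = remap[children[i]]
        post2 = np.asarray([remap[n] for n in order])
    finally:
        sys.setrecursionlimit(old_limit)

    blen = np.full(N, branch_length)
    blen[N - 1] = np.nan
    labels = [f"t{i + 1}" for i in range(L)]
    phy = Phylogeny(L, parent2, children2, blen, labels, post2)
    phy.validate()
    return phy


@dataclass
class NeutralModel:
    """Background nucleotide substitution process: rate matrix Q and stationary pi.

    Nucleotide order is A, C, G, T.  Rows of Q sum to zero and pi is a
    probability vector satisfying ``pi @ Q = 0`` (stationarity).
    """

    Q: np.ndarray
    pi: np.ndarray

    def validate(self) -> None:
        Q, pi = self.Q, self.pi
        if Q.shape != (4, 4):
            raise ModelValidationError("Q must be 4x4")
        off = Q[~np.eye(4, dtype=bool)]
        if np.any(off < 0):
            raise ModelValidationError("off-diagonal entries of Q must be >= 0")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8:
            raise ModelValidationError("rows of Q must sum to 0 (tol 1e-8)")
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ModelValidationError("pi must be a length-4 vector of positive entries")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ModelValidationError("pi must sum to 1 (tol 1e-8)")
        if np.max(np.abs(pi @ Q)) > 1e-6:
            raise ModelValidationError("pi Q = 0 violated (tol 1e-6): pi is not stationary for Q")


def jukes_cantor() -> NeutralModel:
    """Jukes-Cantor model with total rate 1 (all off-diagonals 1/3, uniform pi)."""
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    return NeutralModel(Q, np.full(4, 0.25))


def _finalize_model(Q: np.ndarray, pi: np.ndarray) -> NeutralModel:
    if Q.shape != (4, 4):
        raise ModelValidationError(f"rate matrix must be 4x4, got {Q.shape}")
    off = Q[~np.eye(4, dtype=bool)]
    if np.any(off < 0):
        raise ModelValidationError("negative off-diagonal rate")
    rowsum = Q.sum(axis=1)
    if np.max(np.abs(rowsum)) > 1e-8:
        logger.warning(
            "rate-matrix rows do not sum to 0 (max |sum| = %.3g); resetting diagonals",
            np.max(np.abs(rowsum)),
        )
        Q = Q.copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
    if abs(pi.sum() - 1.0) > 1e-3:
        raise ModelValidationError(f"background frequencies sum to {pi.sum():.4f}, not ~1")
    pi = pi / pi.sum()
    model = NeutralModel(Q, pi)
    model.validate()
    return model


def parse_neutral_model(text: str) -> NeutralModel:
    """Parse a neutral model from phyloFit ".mod" text or a plain-text fallback.

    The ".mod" dialect is recognized by its ``BACKGROUND:`` and ``RATE_MAT:``
    lines.  The fallback format is five whitespace-delimited rows: one row of
    4 stationary frequencies followed by the 4 rows of the rate matrix.
    Diagonals are reset to minus the off-diagonal row sum (with a logged
    warning) if rows do not sum to zero.
    """
    if "RATE_MAT" in text or "BACKGROUND" in text:
        pi = None
        rows: list[list[float]] = []
        in_mat = False
        for line in io.StringIO(text):
            line = line.strip()
            if not line:
                continue
            if line.upper().startswith("BACKGROUND:"):
                pi = np.array([float(v) for v in line.split(":", 1)[1].split()])
                in_mat = False
            elif line.upper().startswith("RATE_MAT:"):
                in_mat = True
                rest = line.split(":", 1)[1].split()
                if rest:
                    rows.append([float(v) for v in rest])
            elif in_mat:
                try:
                    rows.append([float(v) for v in line.split()])
                except ValueError:
                    in_mat = False
            # other .mod lines (ALPHABET, ORDER, SUBST_MOD, TREE...) ignored
        if pi is None:
            raise ModelValidationError("mod file lacks a BACKGROUND line")
        if len(rows) != 4 or any(len(r) != 4 for r in rows):
            raise ModelValidationError("RATE_MAT must contain a 4x4 matrix")
        return _finalize_model(np.array(rows), pi)

    values = [line.split() for line in text.strip().splitlines() if line.strip()]
    if len(values) != 5:
        raise ModelValidationError(
            "plain-text model must have 5 rows: frequencies then 4 rate-matrix rows"
        )
    pi = np.array([float(v) for v in values[0]])
    Q = np.array([[float(v) for v in row] for row in values[1:]])
    return _finalize_model(Q, pi)
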