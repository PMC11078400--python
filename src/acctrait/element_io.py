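"""Loading one conserved element: alignment plus trait vector, matched to a tree.

The data container :class:`ElementData` holds both the observed leaf data and
the latent ancestral rows that the sampler fills in: row ``i`` of ``X`` is the
(possibly partly MISSING) sequence at node ``i`` and ``y[i]`` the trait value,
for all ``N`` nodes of the phylogeny.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .treeio import Phylogeny, NeutralModel

# Nucleotide codes in X: 0=A 1=C 2=G 3=T, 4=MISSING.
MISSING = 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ElementData:
    """Alignment matrix and trait vector over all nodes of a phylogeny.

    ``X`` is ``(N, S)`` int8; rows ``0..L-1`` are observed leaf sequences
    (gaps and ambiguity codes mapped to MISSING), rows ``L..N-1`` are latent
    ancestral sequences.  ``y`` is length ``N``; entries for leaves with
    ``observed_trait`` True are data, all others are latent.
    """

    X: np.ndarray
    y: np.ndarray
    observed_trait: np.ndarray  # (L,) bool
    element_id: str = "element"

    @property
    def n_sites(self) -> int:
        return self.X.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    def latent_trait_nodes(self, tree: Phylogeny) -> np.ndarray:
        """Node ids whose trait value is latent: internals plus unobserved leaves."""
        L = tree.n_leaves
        unobs = np.where(~self.observed_trait)[0]
        return np.concatenate([unobs, np.arange(L, tree.n_nodes)])


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes; gaps/ambiguity codes become MISSING."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _CODE.get(ch, MISSING)
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("ACGT-"[c] for c in codes)


def _parse_trait_table(text: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for ln, line in enumerate(io.StringIO(text), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"trait table line {ln}: expected two columns, got {len(parts)}")
        name, raw = parts
        try:
            val = float(raw)
        except ValueError:
            if ln == 1:  # header row
                continue
            raise ValueError(f"trait table line {ln}: non-numeric value {raw!r}")
        if name in values:
            raise ValueError(f"duplicate species {name!r} in trait table")
        values[name] = val
    return values


def initialize_latent(
    element: ElementData,
    tree: Phylogeny,
    model: NeutralModel,
    rng: np.random.Generator,
) -> None:
    """Fill latent rows of X (draws from pi) and latent y entries (descendant means).

    Ancestral nucleotides start as independent draws from the stationary
    distribution; latent traits start at the mean of their observed descendant
    leaves (overdispersed-but-plausible starts for multi-chain diagnostics).
    Leaves without an observed trait are treated like internal nodes.
    """
    L, N, S = tree.n_leaves, tree.n_nodes, element.n_sites
    element.X[L:] = rng.choice(4, size=(N - L, S), p=model.pi).astype(np.int8)

    obs_mean = float(np.mean(element.y[:L][element.observed_trait])) if element.observed_trait.any() else 0.0
    desc_sum = np.zeros(N)
    desc_n = np.zeros(N)
    desc_sum[:L][element.observed_trait] = element.y[:L][element.observed_trait]
    desc_n[:L][element.observed_trait] = 1.0
    for node in tree.postorder:
        c0, c1 = tree.children[node]
        if c0 != -1:
            desc_sum[node] = desc_sum[c0] + desc_sum[c1]
            desc_n[node] = desc_n[c0] + desc_n[c1]
    for node in element.latent_trait_nodes(tree):
        element.y[node] = desc_sum[node] / desc_n[node] if desc_n[node] > 0 else obs_mean


def load_element(
    fasta_text: str,
    trait_text: str,
    tree: Phylogeny,
    model: NeutralModel,
    seed: int | np.random.Generator = 0,
    element_id: str = "element",
) -> ElementData:
    """Load an aligned element (FASTA) and a trait table, matched to ``tree``.

    Species names must match leaf labels exactly (case-sensitive).  Species
    present in the tree but absent from the trait table are flagged as having
    an unobserved trait and their value is treated as latent.  All-gap columns
    are retained (they contribute likelihood one).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise ValueError("empty FASTA input")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species in alignment: {dupes}")
    unknown = sorted(set(names) - set(tree.leaf_labels))
    if unknown:
        raise ValueError(f"alignment species not in tree: {unknown}")
    absent = sorted(set(tree.leaf_labels) - set(names))
    if absent:
        raise ValueError(f"tree species missing from alignment: {absent}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    S = lengths.pop()
    if S < 1:
        raise ValueError("alignment has zero columns")

    L, N = tree.n_leaves, tree.n_nodes
    X = np.full((N, S), MISSING, dtype=np.int8)
    for rec in records:
        X[tree.leaf_index(rec.id)] = encode_sequence(str(rec.seq))

    traits = _parse_trait_table(trait_text)
    unknown = sorted(set(traits) - set(tree.leaf_labels))
    if unknown:
        raise ValueError(f"trait-table species not in tree: {unknown}")
    y = np.zeros(N)
    observed = np.zeros(L, dtype=bool)
    for name, val in traits.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite trait value for {name!r}")
        idx = tree.leaf_index(name)
        y[idx] = val
        observed[idx] = True

    element = ElementData(X=X, y=y, observed_trait=observed, element_id=element_id)
    initialize_latent(element, tree, model, rng)
    return element


def write_fasta(X_leaves: np.ndarray, labels: list[str]) -> str:
    """Serialize leaf rows of an alignment to FASTA text."""
    chunks = []
    for label, row in zip(labels, X_leaves):
        chunks.append(f">{label}\n{decode_sequence(row)}\n")
    return "".join(chunks)


def write_trait_table(values: np.ndarray, labels: list[str]) -> str:
    """Serialize leaf trait values to a two-column tab-separated table."""
    return "".join(f"{label}\t{value:.10g}\n" for label, value in zip(labels, values))
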