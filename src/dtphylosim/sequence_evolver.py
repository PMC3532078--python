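"""Root-sequence generation and Markov propagation down the tree.

Sites evolve independently with no rate variation: the root sequence is
drawn i.i.d. from the model's root distribution, and each edge replaces a
parent state by a child state drawn from the corresponding row of the
edge's substitution matrix.  The fixed orders (root distribution, then one
matrix per edge in pre-order, then the root sequence, then pre-order
propagation with children in Newick order) make a run bit-reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_sampler import SubstitutionMatrix, sample_matrix
from .models import ModelSpec, RootDistribution, sample_root_distribution
from .tree_io import Tree, edges_in_output_order

__all__ = [
    "Alignment",
    "SimulationRecord",
    "BASES",
    "sample_root_sequence",
    "evolve_sequence",
    "simulate_alignment",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclass
class Alignment:
    """Leaf-name -> DNA sequence map; all sequences of equal length."""

    sequences: dict[str, str]
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        for name, seq in self.sequences.items():
            if len(seq) != self.length:
                raise ValueError(
                    f"sequence {name!r} has length {len(seq)}, expected {self.length}"
                )

    def names(self) -> list[str]:
        return list(self.sequences)


@dataclass
class SimulationRecord:
    """Every parameter of one simulation, in canonical edge order."""

    model: str
    tree_text: str
    root_distribution: RootDistribution
    edge_matrices: list[tuple[str, SubstitutionMatrix]]
    seed: int | None = None
    internal_sequences: dict[str, str] | None = None  # only with keep_internal


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"sequence contains a non-ACGT character: {exc}") from exc


def sample_root_sequence(pi: RootDistribution, L: int, rng: np.random.Generator) -> str:
    """L characters drawn i.i.d. from the root distribution."""
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    codes = rng.choice(4, size=L, p=pi.as_array()).astype(np.uint8)
    return _codes_to_str(codes)


def _evolve_codes(
    parent: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    child = np.empty_like(parent)
    for state in range(4):  # fixed state order keeps RNG consumption reproducible
        idx = np.nonzero(parent == state)[0]
        if idx.size:
            child[idx] = rng.choice(4, size=idx.size, p=P[state]).astype(np.uint8)
    return child


def evolve_sequence(parent_seq: str, P, rng: np.random.Generator) -> str:
    """Evolve a sequence one edge: each site's child state ~ row P[parent state]."""
    entries = P.entries if isinstance(P, SubstitutionMatrix) else np.asarray(P, float)
    return _codes_to_str(_evolve_codes(_str_to_codes(parent_seq), entries, rng))


def simulate_alignment(
    tree: Tree,
    model: ModelSpec,
    L: int,
    rng: np.random.Generator,
    *,
    seed: int | None = None,
    keep_internal: bool = False,
) -> tuple[Alignment, SimulationRecord]:
    """Simulate an alignment of length ``L`` on ``tree`` under ``model``.

    One substitution matrix is drawn per edge (pre-order), the root sequence
    from the model's root distribution, and every node receives the evolved
    sequence of its parent.  Only leaf sequences enter the alignment;
    ``keep_internal`` additionally stores the internal-node sequences
    (keyed by node label) on the returned record, for debugging.

    Returns the alignment together with a :class:`SimulationRecord` holding
    the root distribution and the per-edge matrices in canonical output
    order (terminal edges first, then internal edges top-down).
    """
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    pi = sample_root_distribution(model, rng)

    matrices: dict[int, SubstitutionMatrix] = {}
    for node in tree.preorder():
        for child in node.children:
            edge = tree.edge_above(child)
            matrices[id(child)] = sample_matrix(model, edge.length, rng)

    root_codes = _str_to_codes(sample_root_sequence(pi, L, rng))
    leaf_seqs: dict[str, str] = {}
    internal_seqs: dict[str, str] = {}

    def descend(node, codes) -> None:
        if node.is_leaf:
            leaf_seqs[node.name] = _codes_to_str(codes)
            return
        if keep_internal:
            internal_seqs[tree.node_label(node)] = _codes_to_str(codes)
        for child in node.children:
            descend(child, _evolve_codes(codes, matrices[id(child)].entries, rng))

    descend(tree.root, root_codes)

    ordered = {name: leaf_seqs[name] for name in tree.leaf_names()}
    aln = Alignment(sequences=ordered, length=L)
    record = SimulationRecord(
        model=model.name,
        tree_text=tree.newick,
        root_distribution=pi,
        edge_matrices=[
            (tree.edge_label(e), matrices[id(e.child)])
            for e in edges_in_output_order(tree)
        ],
        seed=seed,
        internal_sequences=internal_seqs if keep_internal else None,
    )
    return aln, record
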