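"""The five discrete-time substitution model classes.

Each model is a symbolic 4x4 pattern of parameter labels over the alphabet
(A, C, G, T): cells sharing a label must hold equal probabilities, rows sum
to one, and entries are nonnegative.  No rate-matrix (exponential) structure
is imposed — the stochastic matrix itself is the parameter.

Patterns::

    JC69          K80           K81           SSM           GMM
    a b b b       a b c b       a b c d       a b c d       a b c d
    b a b b       b a b c       b a d c       e f g h       e f g h
    b b a b       c b a b       c d a b       h g f e       i j k l
    b b b a       b c b a       d c b a       d c b a       m n o p

Transitions (A<->G, C<->T) carry parameter ``c`` in K80/K81.  JC69, K80 and
K81 matrices are symmetric, hence doubly stochastic, and fix the uniform
distribution; SSM and GMM need not fix any distribution, which is what makes
nonstationary simulation possible.

Each model also carries its *allowable row permutations*: the permutations
of (A, C, G, T) applied to the rows of a matrix that map the model's
pattern onto itself up to a relabelling of parameters.  These are the only
moves available for converting a sampled matrix to diagonal-largest-in-
column (DLC) form without leaving the model class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

__all__ = [
    "ModelSpec",
    "RootDistribution",
    "MODEL_NAMES",
    "get_model",
    "allowable_permutations",
    "sample_root_distribution",
    "conforms_to_pattern",
]

_PATTERNS: dict[str, tuple[str, str, str, str]] = {
    "JC69": ("abbb", "babb", "bbab", "bbba"),
    "K80": ("abcb", "babc", "cbab", "bcba"),
    "K81": ("abcd", "badc", "cdab", "dcba"),
    "SSM": ("abcd", "efgh", "hgfe", "dcba"),
    "GMM": ("abcd", "efgh", "ijkl", "mnop"),
}

_FREE_PARAMS = {"JC69": 1, "K80": 2, "K81": 3, "SSM": 6, "GMM": 12}

Permutation = tuple[int, int, int, int]
IDENTITY: Permutation = (0, 1, 2, 3)


@dataclass(frozen=True)
class ModelSpec:
    """A model class: its pattern, parameter count and row-permutation group."""

    name: str
    pattern: tuple[str, str, str, str]
    free_params: int
    perm_group: frozenset[Permutation]

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class RootDistribution:
    """Base distribution at the root, over (A, C, G, T)."""

    pi: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.pi, dtype=float)
        if arr.shape != (4,) or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError("root distribution must be 4 nonnegative numbers summing to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)


def _canonical(pattern: tuple[str, ...]) -> str:
    """Relabel a pattern by first occurrence so equal partitions compare equal."""
    mapping: dict[str, str] = {}
    out = []
    for row in pattern:
        for lab in row:
            if lab not in mapping:
                mapping[lab] = chr(ord("a") + len(mapping))
            out.append(mapping[lab])
    return "".join(out)


def _pattern_preserving_permutations(
    pattern: tuple[str, str, str, str]
) -> frozenset[Permutation]:
    """Brute-force symbolic check of all 24 row permutations of the pattern.

    sigma preserves the pattern iff the row-permuted symbolic matrix has the
    same partition of cells into equal-label classes (relabelling allowed).
    The check is symbolic on purpose: a numeric check on one random matrix
    can be fooled by accidental coincidences.
    """
    ref = _canonical(pattern)
    keep = []
    for sigma in permutations(range(4)):
        permuted = tuple(pattern[sigma[i]] for i in range(4))
        if _canonical(permuted) == ref:
            keep.append(sigma)
    return frozenset(keep)


_MODELS: dict[str, ModelSpec] = {
    name: ModelSpec(
        name=name,
        pattern=pat,
        free_params=_FREE_PARAMS[name],
        perm_group=_pattern_preserving_permutations(pat),
    )
    for name, pat in _PATTERNS.items()
}

MODEL_NAMES: tuple[str, ...] = tuple(n.lower() for n in _MODELS)


def get_model(name: str) -> ModelSpec:
    """Look up a model by name (case-insensitive)."""
    key = name.strip().upper()
    if key not in _MODELS:
        raise ValueError(
            f"unknown model {name!r}; valid models are: {', '.join(MODEL_NAMES)}"
        )
    return _MODELS[key]


def allowable_permutations(model: ModelSpec) -> frozenset[Permutation]:
    """Row permutations that keep a matrix inside the model class.

    JC69 admits only the identity; K80 the order-2 group {id, (AG)(CT)};
    K81 and SSM the Klein four-group of double transpositions; GMM all of
    S4.  All are recomputed here symbolically rather than hard-coded.
    """
    return model.perm_group


def sample_root_distribution(model: ModelSpec, rng: np.random.Generator) -> RootDistribution:
    """Draw a root distribution from the model's family.

    JC69/K80/K81 matrices are doubly stochastic, so the uniform distribution
    is the only stationary choice and is returned deterministically.  SSM
    requires strand symmetry pi_A = pi_T, pi_C = pi_G: we draw
    pi_A uniformly on (0, 1/2).  GMM draws from the flat Dirichlet on the
    3-simplex.
    """
    if model.name in ("JC69", "K80", "K81"):
        return RootDistribution((0.25, 0.25, 0.25, 0.25))
    if model.name == "SSM":
        p = rng.uniform(0.0, 0.5)
        return RootDistribution((p, 0.5 - p, 0.5 - p, p))
    pi = rng.dirichlet(np.ones(4))
    pi = pi / pi.sum()
    return RootDistribution(tuple(pi))


def conforms_to_pattern(entries: np.ndarray, model: ModelSpec, tol: float = 1e-12) -> bool:
    """True iff cells sharing a pattern label are numerically equal within tol."""
    P = np.asarray(entries, dtype=float)
    if P.shape != (4, 4):
        return False
    groups: dict[str, list[float]] = {}
    for i in range(4):
        for j in range(4):
            groups.setdefault(model.pattern[i][j], []).append(P[i, j])
    return all(max(v) - min(v) <= tol for v in groups.values())
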