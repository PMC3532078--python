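"""Empirical pairwise joints and log-det (paralinear) distances.

These estimators close the loop on a simulation: the paralinear distance of
the joint base-pair frequency matrix of two leaves is additive along the
path between them, and under the doubly stochastic models (JC69/K80/K81,
uniform root) it equals the sum of the log-det branch lengths, so branch
lengths written into the matrices can be recovered from the simulated data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix_sampler import SubstitutionMatrix
from .sequence_evolver import BASES, Alignment

__all__ = [
    "PairJoint",
    "empirical_joint",
    "paralinear_distance",
    "logdet_branch_length",
]

_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class PairJoint:
    """4x4 site-pattern counts for an ordered leaf pair (rows: u, cols: v)."""

    counts: np.ndarray
    total: int

    def frequencies(self) -> np.ndarray:
        return self.counts / self.total


def empirical_joint(aln: Alignment, u: str, v: str) -> PairJoint:
    """Count joint site patterns between leaves ``u`` and ``v``."""
    if u == v:
        raise ValueError("the two leaves must be distinct")
    for name in (u, v):
        if name not in aln.sequences:
            raise KeyError(f"leaf {name!r} not in alignment")
    su = np.array([_CODE[b] for b in aln.sequences[u]])
    sv = np.array([_CODE[b] for b in aln.sequences[v]])
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (su, sv), 1)
    return PairJoint(counts=counts, total=aln.length)


def paralinear_distance(J: PairJoint) -> float:
    """Paralinear (log-det) distance of a pairwise joint distribution.

    With F the relative-frequency matrix and f, g its row and column
    marginals,

        d = -1/4 * [ ln |det F| - 1/2 * ln( prod(f) * prod(g) ) ].

    The absolute value guards against tiny negative determinants produced
    by sampling noise at short alignments.  Additive along paths; equals
    the sum of per-edge log-det branch lengths when all marginals are
    uniform (the stationary JC69/K80/K81 case), but not in general under
    the nonstationary models.
    """
    F = J.frequencies()
    f = F.sum(axis=1)
    g = F.sum(axis=0)
    if (f <= 0).any() or (g <= 0).any():
        raise ValueError(
            "a base is absent at one of the leaves; the paralinear distance "
            "is undefined (try a longer alignment)"
        )
    det = np.linalg.det(F)
    if det == 0:
        raise ValueError(
            "singular joint frequency matrix; the paralinear distance is "
            "undefined (try a longer alignment)"
        )
    return -0.25 * (math.log(abs(det)) - 0.5 * (np.log(f).sum() + np.log(g).sum()))


def logdet_branch_length(P) -> float:
    """The branch length -1/4 ln det of a substitution matrix."""
    E = P.entries if isinstance(P, SubstitutionMatrix) else np.asarray(P, float)
    sign, logabs = np.linalg.slogdet(E)
    if sign <= 0:
        raise ValueError("determinant must be positive for a log-det length")
    return -0.25 * logabs
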