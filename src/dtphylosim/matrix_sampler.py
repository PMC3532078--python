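"""Random stochastic matrices with a prescribed log-det branch length.

The branch length of an edge under the discrete-time models is

    l = -1/4 * ln det(P),

so a requested length ``l`` pins the determinant of the edge matrix to
``D = exp(-4 l)``.  Each sampler below draws a random row-stochastic matrix
of its model's shape whose determinant equals ``D`` (to numerical
precision), then the matrix is converted to DLC (diagonal largest in
column) form by an allowable row permutation so that the emitted parameters
are identifiable from the leaf distribution.

Samplers
--------
JC69
    Closed form.  With ``e = exp(-4 l / 3)`` the diagonal is
    ``a = (1 + 3 e) / 4`` and the off-diagonal ``b = (1 - e) / 4``; the
    eigenvalues are (1, e, e, e), so det = exp(-4 l) exactly and the matrix
    is always DLC.
K80 / K81
    Eigenvalue parameterisation.  K81 matrices are simultaneously
    diagonalised by the Hadamard basis with non-unit eigenvalues
    (x, y, z) = (a+b-c-d, a-b+c-d, a-b-c+d) and det = x*y*z.  We draw
    x ~ U(D, 1), y ~ U(D/x, 1), set z = D/(x*y), and reject draws with a
    negative entry.  K80 is the sub-family with a double eigenvalue:
    x ~ U(sqrt(D), 1), y = D/x^2.  Positive eigenvalues make the diagonal
    strictly dominant, so these matrices are DLC by construction.
SSM / GMM
    Identity-mixture bisection.  Draw a random matrix M of the model's
    shape (Dirichlet rows); if det(M) >= D redraw; otherwise the path
    P(s) = (1-s) I + s M stays inside the (convex) shape class, and
    f(s) = det P(s) falls continuously from 1 to det(M) < D, so a crossing
    f(s*) = D exists.  We take the first crossing (a grid scan at step
    1/1000 followed by bisection), which favours diagonally dominant, hence
    DLC-friendly, matrices.

All samplers share the 1000-trial restart cap: shape rejections, failed
DLC conversions and (for GMM) determinant-sign flips under an odd
permutation all consume trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import IDENTITY, ModelSpec, conforms_to_pattern, get_model

__all__ = [
    "SubstitutionMatrix",
    "TrialBudgetExceededError",
    "branch_to_det",
    "sample_jc69",
    "sample_k80",
    "sample_k81",
    "sample_mixture",
    "is_dlc",
    "make_dlc",
    "sample_matrix",
]

DEFAULT_MAX_TRIALS = 1000
LENGTH_TOL = 1e-9  # |(-1/4) ln det P - l| guaranteed for every emitted matrix


class TrialBudgetExceededError(RuntimeError):
    """The sampler could not produce a valid DLC matrix within the trial cap."""


@dataclass
class SubstitutionMatrix:
    """A 4x4 row-stochastic matrix attached to an edge.

    Rows index the parent state, columns the child state, both in
    (A, C, G, T) order.  ``trials`` records how many sampling attempts the
    matrix took (diagnostic only).
    """

    entries: np.ndarray
    model: ModelSpec
    branch_length: float
    trials: int = 1

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if (self.entries < -1e-15).any():
            raise ValueError("substitution matrix entries must be nonnegative")
        if np.abs(self.entries.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("substitution matrix rows must sum to 1")

    @property
    def logdet_length(self) -> float:
        """-1/4 ln det of the stored entries."""
        sign, logabs = np.linalg.slogdet(self.entries)
        if sign <= 0:
            raise ValueError("matrix determinant is not positive")
        return -0.25 * logabs


def branch_to_det(l: float) -> float:
    """Target determinant D = exp(-4 l) for a branch of length ``l``."""
    if not (l > 0) or not math.isfinite(l):
        raise ValueError(f"branch length must be positive and finite, got {l!r}")
    return math.exp(-4.0 * l)


# ---------------------------------------------------------------------------
# per-model draws (single attempt; None signals a shape rejection)


def _jc69_entries(l: float) -> np.ndarray:
    e = math.exp(-4.0 * l / 3.0)
    a = (1.0 + 3.0 * e) / 4.0
    b = (1.0 - e) / 4.0
    return np.full((4, 4), b) + np.eye(4) * (a - b)


def _k81_entries_from_eigs(x: float, y: float, z: float) -> np.ndarray | None:
    a = (1.0 + x + y + z) / 4.0
    b = (1.0 + x - y - z) / 4.0
    c = (1.0 - x + y - z) / 4.0
    d = (1.0 - x - y + z) / 4.0
    if min(a, b, c, d) < 0.0:
        return None
    return np.array(
        [[a, b, c, d], [b, a, d, c], [c, d, a, b], [d, c, b, a]], dtype=float
    )


def _try_k81(l: float, rng: np.random.Generator) -> np.ndarray | None:
    D = branch_to_det(l)
    x = rng.uniform(D, 1.0)
    y = rng.uniform(D / x, 1.0)
    z = D / (x * y)
    return _k81_entries_from_eigs(x, y, z)


def _try_k80(l: float, rng: np.random.Generator) -> np.ndarray | None:
    D = branch_to_det(l)
    x = rng.uniform(math.sqrt(D), 1.0)
    y = D / (x * x)
    # eigenvalues (x, x, y); build entries directly so the two transversion
    # cells share the exact same float
    a = (1.0 + 2.0 * x + y) / 4.0
    b = (1.0 - y) / 4.0
    c = (1.0 - 2.0 * x + y) / 4.0
    if min(a, b, c) < 0.0:
        return None
    return np.array(
        [[a, b, c, b], [b, a, b, c], [c, b, a, b], [b, c, b, a]], dtype=float
    )


def _draw_shape_matrix(model: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    """A random matrix of the model's shape with flat-Dirichlet rows."""
    if model.name == "GMM":
        return rng.dirichlet(np.ones(4), size=4)
    if model.name == "SSM":
        r1 = rng.dirichlet(np.ones(4))
        r2 = rng.dirichlet(np.ones(4))
        return np.array([r1, r2, r2[::-1], r1[::-1]], dtype=float)
    raise ValueError(f"mixture draw undefined for model {model.name}")


_GRID = np.linspace(0.001, 1.0, 1000)
_EYE = np.eye(4)


def _mix(M: np.ndarray, s: float) -> np.ndarray:
    return (1.0 - s) * _EYE + s * M


def _first_crossing(M: np.ndarray, D: float) -> float:
    """Smallest s with det((1-s)I + sM) = D, located by grid scan + bisection."""
    mats = (1.0 - _GRID)[:, None, None] * _EYE + _GRID[:, None, None] * M
    dets = np.linalg.det(mats)
    below = dets <= D
    k = int(np.argmax(below))  # first grid point at or below D; exists: dets[-1] < D
    a = 0.0 if k == 0 else _GRID[k - 1]
    b = _GRID[k]
    fa, fb = (1.0 if k == 0 else dets[k - 1]), dets[k]
    for _ in range(200):
        if b - a <= 1e-17:
            break
        m = 0.5 * (a + b)
        fm = float(np.linalg.det(_mix(M, m)))
        if fm > D:
            a, fa = m, fm
        else:
            b, fb = m, fm
    return b if abs(fb - D) <= abs(fa - D) else a


def _try_mixture(model: ModelSpec, l: float, rng: np.random.Generator) -> np.ndarray | None:
    D = branch_to_det(l)
    M = _draw_shape_matrix(model, rng)
    if np.linalg.det(M) >= D:
        return None  # determinant already too large: a convex path to I cannot cross D
    s = _first_crossing(M, D)
    return _mix(M, s)


_TRY = {
    "K80": _try_k80,
    "K81": _try_k81,
    "SSM": _try_mixture,
    "GMM": _try_mixture,
}


def _draw_entries(model: ModelSpec, l: float, rng: np.random.Generator) -> np.ndarray | None:
    if model.name == "JC69":
        return _jc69_entries(l)
    fn = _TRY[model.name]
    if model.name in ("SSM", "GMM"):
        return fn(model, l, rng)
    return fn(l, rng)


# ---------------------------------------------------------------------------
# public per-model samplers


def sample_jc69(l: float) -> SubstitutionMatrix:
    """The (unique) JC69 matrix of branch length ``l``; deterministic and DLC."""
    branch_to_det(l)  # validates l
    return SubstitutionMatrix(_jc69_entries(l), get_model("jc69"), l)


def _sample_rejecting(
    name: str, l: float, rng: np.random.Generator, max_trials: int
) -> SubstitutionMatrix:
    model = get_model(name)
    for trial in range(1, max_trials + 1):
        entries = _draw_entries(model, l, rng)
        if entries is not None:
            return SubstitutionMatrix(entries, model, l, trials=trial)
    raise TrialBudgetExceededError(
        f"{name} sampler rejected {max_trials} consecutive draws at length {l}"
    )


def sample_k81(
    l: float, rng: np.random.Generator, max_trials: int = DEFAULT_MAX_TRIALS
) -> SubstitutionMatrix:
    """A random K81 matrix with det = exp(-4 l); DLC by positive eigenvalues."""
    return _sample_rejecting("K81", l, rng, max_trials)


def sample_k80(
    l: float, rng: np.random.Generator, max_trials: int = DEFAULT_MAX_TRIALS
) -> SubstitutionMatrix:
    """A random K80 matrix with det = exp(-4 l); DLC by positive eigenvalues."""
    return _sample_rejecting("K80", l, rng, max_trials)


def sample_mixture(
    model: ModelSpec, l: float, rng: np.random.Generator, max_trials: int = DEFAULT_MAX_TRIALS
) -> SubstitutionMatrix:
    """A random SSM or GMM matrix with det = exp(-4 l) (not necessarily DLC)."""
    if model.name not in ("SSM", "GMM"):
        raise ValueError("sample_mixture handles only SSM and GMM")
    return _sample_rejecting(model.name, l, rng, max_trials)


# ---------------------------------------------------------------------------
# DLC


def _as_entries(P) -> np.ndarray:
    if isinstance(P, SubstitutionMatrix):
        return P.entries
    return np.asarray(P, dtype=float)


def is_dlc(P) -> bool:
    """Strict diagonal-largest-in-column: ties disqualify.

    DLC matrices are the identifiable representatives of a model's
    permutation orbit; strictness matters because a tie already breaks the
    uniqueness of the parameter set producing a given leaf distribution.
    """
    E = _as_entries(P)
    for j in range(4):
        col = E[:, j]
        if any(col[i] >= col[j] for i in range(4) if i != j):
            return False
    return True


def make_dlc(P, model: ModelSpec):
    """Convert a matrix to DLC form by an allowable row permutation.

    Returns the input unchanged if already DLC, otherwise the first
    row-permuted copy (over the model's permutation group, in lexicographic
    order) that is DLC; ``None`` if no allowable permutation achieves DLC,
    so the caller can resample.  The permuted matrix keeps the model's
    shape because the group was chosen to preserve the pattern.
    """
    E = _as_entries(P)
    if is_dlc(E):
        return P
    for sigma in sorted(model.perm_group):
        if sigma == IDENTITY:
            continue
        candidate = E[list(sigma), :]
        if is_dlc(candidate):
            if isinstance(P, SubstitutionMatrix):
                return SubstitutionMatrix(
                    candidate, model, P.branch_length, trials=P.trials
                )
            return candidate
    return None


def sample_matrix(
    model: ModelSpec,
    l: float,
    rng: np.random.Generator,
    max_trials: int = DEFAULT_MAX_TRIALS,
) -> SubstitutionMatrix:
    """A DLC matrix of the model's shape with -1/4 ln det = ``l``.

    Dispatches to the model's sampler and applies the DLC conversion,
    retrying on any failure up to ``max_trials`` attempts.  A zero length
    (only reachable when zero-length branches were explicitly allowed at
    parse time) yields the identity matrix.

    Raises
    ------
    TrialBudgetExceededError
        After ``max_trials`` failed attempts; simulations then require a
        re-start (a different seed or tree).
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    if l == 0.0:
        return SubstitutionMatrix(np.eye(4), model, 0.0)
    branch_to_det(l)  # validate l before looping
    for trial in range(1, max_trials + 1):
        entries = _draw_entries(model, l, rng)
        if entries is None:
            continue
        converted = make_dlc(entries, model)
        if converted is None:
            continue
        # An odd permutation (possible for SSM and GMM) flips the determinant
        # sign and silently destroys the branch-length contract; treat it
        # as a failed trial.
        sign, logabs = np.linalg.slogdet(converted)
        if sign <= 0 or abs(-0.25 * logabs - l) > LENGTH_TOL:
            continue
        return SubstitutionMatrix(converted, model, l, trials=trial)
    raise TrialBudgetExceededError(
        f"no DLC {model.name} matrix of branch length {l} found in "
        f"{max_trials} trials; simulations require a re-start"
    )
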