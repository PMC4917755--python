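"""Uniqueness bounds for cosparse recovery and their brute-force oracles.

How many linear measurements guarantee a unique ``l``-cosparse solution of
``y = M x``?  For an analysis operator in *general position* (every ``n`` of
its ``p`` rows linearly independent) the answers are closed-form:

* cosupport exactly known:  ``m ≥ n − l``;
* only the cosparsity known: ``m ≥ n + p − 2l``;
* cosupport known up to a small error set (``|Λ₀| = l₀`` containing the true
  cosupport of size ``l``): ``m ≥ n + l₀ − 2l`` — interpolating between the
  two cases above as ``l₀`` moves from ``l`` to ``p``.

The 2-D finite-difference operator is *not* in general position: its rows
are highly dependent, and the dimension of the cosparse subspace
``W_Λ = Null(Ω_Λ)`` is instead a graph quantity.  Viewing the (non-periodic,
horizontal+vertical) difference rows as edges of the grid graph, a
cosupport ``Λ`` constrains connected pixels to share a value, so

    dim W_Λ = |V| − |V(Λ)| + J(Λ),

where ``V(Λ)`` is the set of vertices touched by an edge in ``Λ`` and
``J(Λ)`` counts connected components of the subgraph ``(V(Λ), Λ)``.  The
grid graph here intentionally differs from the periodic four-direction
operator used for reconstruction: the dimension formula is stated for the
plain horizontal+vertical difference operator on the open grid.

A numerical-rank (SVD) null-space oracle validates both routes on small
instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GridCosupportGraph",
    "min_measurements_known",
    "min_measurements_unknown",
    "min_measurements_prior",
    "fd_subspace_dimension",
    "brute_force_nullspace_dim",
]

Edge = Tuple[int, int]


def _clamp(value: int, n: int) -> int:
    return int(min(max(value, 0), n))


def min_measurements_known(n: int, l: int) -> int:
    """Minimum measurements with exactly known cosupport: ``n − l``."""
    if not 0 <= l <= n:
        raise ValueError(f"l must lie in [0, n={n}], got {l}")
    return n - l


def min_measurements_unknown(n: int, p: int, l: int) -> int:
    """Minimum measurements knowing only the cosparsity: ``n + p − 2l``.

    Requires ``n ≤ p`` (redundant analysis operator); the result is clamped
    to ``[0, n]`` (a bound above ``n`` is vacuous and below 0 meaningless).
    """
    if p < n:
        raise ValueError(f"expected a redundant operator (p >= n), got p={p} < n={n}")
    if not 0 <= l <= p:
        raise ValueError(f"l must lie in [0, p={p}], got {l}")
    return _clamp(n + p - 2 * l, n)


def min_measurements_prior(n: int, l0: int, l: int) -> int:
    """Minimum measurements with an inexact cosupport prior: ``n + l₀ − 2l``.

    ``Λ₀`` (``|Λ₀| = l₀``) is a superset estimate of the true cosupport
    (``|Λ| = l``, ``Λ = Λ₀ ∖ Λ'``), so ``l ≤ l₀`` is required.  Clamped to
    ``[0, n]``.  Limits: ``l₀ = l`` recovers the exactly-known bound
    ``n − l``; ``l₀ = p`` recovers the no-prior bound ``n + p − 2l``.
    """
    if l > l0:
        raise ValueError(
            f"the true cosupport (l={l}) cannot exceed the prior (l0={l0})"
        )
    if l < 0:
        raise ValueError("l must be non-negative")
    return _clamp(n + l0 - 2 * l, n)


@dataclass(frozen=True)
class GridCosupportGraph:
    """A cosupport as an edge set over the 4-neighbour grid graph.

    Vertices are pixels of a ``rows × cols`` grid (flat row-major indices);
    admissible edges connect horizontally or vertically adjacent pixels
    (non-periodic).  Each edge is one finite-difference row known to vanish.
    """

    shape: Tuple[int, int]
    edges: FrozenSet[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        rows, cols = self.shape
        n = rows * cols
        norm = set()
        for a, b in self.edges:
            a, b = int(a), int(b)
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a}, {b}) references a vertex outside the grid")
            ra, ca = divmod(a, cols)
            rb, cb = divmod(b, cols)
            if abs(ra - rb) + abs(ca - cb) != 1:
                raise ValueError(
                    f"edge ({a}, {b}) does not connect 4-neighbour grid cells"
                )
            norm.add((min(a, b), max(a, b)))
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n(self) -> int:
        return self.shape[0] * self.shape[1]

    def touched_vertices(self) -> FrozenSet[int]:
        """``V(Λ)``: vertices covered by at least one edge."""
        return frozenset(v for e in self.edges for v in e)

    def num_components(self) -> int:
        """``J(Λ)``: connected components of the subgraph ``(V(Λ), Λ)``."""
        touched = sorted(self.touched_vertices())
        if not touched:
            return 0
        remap = {v: i for i, v in enumerate(touched)}
        rows = [remap[a] for a, b in self.edges]
        cols = [remap[b] for a, b in self.edges]
        graph = coo_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(touched), len(touched)),
        )
        ncomp, _ = connected_components(graph, directed=False)
        return int(ncomp)

    def all_edges(self) -> FrozenSet[Edge]:
        """Every admissible horizontal+vertical edge of the grid."""
        rows, cols = self.shape
        out = set()
        for r in range(rows):
            for c in range(cols):
                v = r * cols + c
                if c + 1 < cols:
                    out.add((v, v + 1))
                if r + 1 < rows:
                    out.add((v, v + cols))
        return frozenset(out)

    def difference_rows(self) -> np.ndarray:
        """Dense ``|Λ| × n`` matrix of the edge difference rows."""
        mat = np.zeros((len(self.edges), self.n))
        for i, (a, b) in enumerate(sorted(self.edges)):
            mat[i, a] = 1.0
            mat[i, b] = -1.0
        return mat


def fd_subspace_dimension(graph: GridCosupportGraph) -> int:
    """``dim W_Λ = |V| − |V(Λ)| + J(Λ)`` for a grid cosupport edge set."""
    return graph.n - len(graph.touched_vertices()) + graph.num_components()


def brute_force_nullspace_dim(
    rows: np.ndarray, lam: Iterable[int] | None = None, tol: float = 1e-9
) -> int:
    """Null-space dimension of the ``Λ``-restricted row matrix, by SVD.

    ``rows`` is an explicit ``p × n`` analysis matrix with ``n ≤ 64``;
    ``lam`` selects the cosupport rows (all rows when omitted).  Returns
    ``n − rank`` with singular values below ``tol`` treated as zero.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("rows must be a 2-D matrix")
    n = rows.shape[1]
    if n > 64:
        raise ValueError(f"brute-force oracle limited to n <= 64, got n={n}")
    sub = rows if lam is None else rows[np.asarray(sorted(lam), dtype=np.intp)]
    if sub.shape[0] == 0:
        return n
    svals = np.linalg.svd(sub, compute_uv=False)
    return int(n - np.count_nonzero(svals > tol))
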