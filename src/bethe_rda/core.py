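"""Domain types and tree combinatorics for the automaton on the 3-regular lattice.

The lattice is an infinite cycle-free graph in which every vertex has the
same degree ``k`` (coordination number); only ``k = 3`` is supported.  Cells
are empty or occupied; occupied cells form *clusters*, empty cells form
*empty clusters*.  Empty cells are classified by their number of occupied
neighbours:

====  =========  ==================================================
type  occupied   effect of occupying the cell
      neighbours
====  =========  ==================================================
C0    0          creates a new cluster ("creating" cell)
C1    1          enlarges the adjacent cluster ("enlarging" cell)
C2    2          merges two clusters
C3    3          merges three clusters
====  =========  ==================================================

This module holds the parameter/state containers, the exact composition of
an empty cluster in terms of cell types, and the change of variables between
the per-type empty-cell counts ``x0..x3`` and the aggregate quantities
``{rho, n0, n1_0, nhat0}``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

from .errors import DomainError, NoAdmissibleState

__all__ = [
    "ModelParams",
    "SteadyState",
    "EmptyClusterComposition",
    "perimeter",
    "empty_cluster_composition",
    "aggregates_from_x",
    "empty_cluster_means",
]


def perimeter(i: int, k: int = 3) -> int:
    """Number of empty cells adjacent to an occupied cluster of size ``i``.

    On a cycle-free ``k``-regular lattice a cluster of ``i`` cells has exactly
    ``i*(k - 2) + 2`` neighbouring cells (provable by induction on ``i``).

    Parameters
    ----------
    i : cluster size, ``i >= 1``.
    k : coordination number, ``k >= 2``.
    """
    if i < 1:
        raise DomainError(f"cluster size must be >= 1, got {i}")
    if k < 2:
        raise DomainError(f"coordination number must be >= 2, got {k}")
    return i * (k - 2) + 2


@dataclass(frozen=True)
class EmptyClusterComposition:
    """Cell-type census of an empty cluster of size ``i`` on the 3-regular tree.

    ``j`` is the number of creating (C0) cells.  For ``i >= 2`` the census is
    fully determined by ``(i, j)``: ``j + 2`` cells of C2-type,
    ``i - 2j - 2`` enlarging cells and no C3 cells.  The single cell of an
    ``i = 1`` empty cluster is C3-type (all three neighbours occupied).
    """

    i: int
    j: int
    n_creating: int
    n_enlarging: int
    n_C2: int
    n_C3: int

    def total(self) -> int:
        return self.n_creating + self.n_enlarging + self.n_C2 + self.n_C3


def empty_cluster_composition(i: int, j: int) -> EmptyClusterComposition:
    """Exact composition of an empty ``i``-cluster with ``j`` creating cells.

    Valid index range for ``i >= 2`` is ``0 <= j <= floor(i/2) - 1``.
    ``i = 1`` is the special isolated-cell case and requires ``j = 0``.
    """
    if i < 1:
        raise DomainError(f"empty-cluster size must be >= 1, got {i}")
    if i == 1:
        if j != 0:
            raise DomainError("a size-1 empty cluster has no creating cells")
        return EmptyClusterComposition(i=1, j=0, n_creating=0, n_enlarging=0,
                                       n_C2=0, n_C3=1)
    jmax = i // 2 - 1
    if not 0 <= j <= jmax:
        raise DomainError(
            f"creating-cell count j={j} out of range [0, {jmax}] for i={i}")
    return EmptyClusterComposition(
        i=i, j=j,
        n_creating=j,
        n_enlarging=i - 2 * j - 2,
        n_C2=j + 2,
        n_C3=0,
    )


def _as_mu_callable(mu) -> Callable[[int], float]:
    if callable(mu):
        return mu
    if isinstance(mu, Mapping):
        table = dict(mu)

        def lookup(i: int) -> float:
            try:
                return table[i]
            except KeyError:
                raise DomainError(f"mu not defined for cluster size {i}")
        return lookup
    raise DomainError("mu must be a callable i -> probability or a mapping")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the automaton on the 3-regular lattice.

    ``c0..c3`` are the occupation probabilities for the four empty-cell types.
    The avalanche law is either the solvable one-parameter family
    ``mu_i = delta / i`` (give ``delta``) or a general ``mu`` (mapping or
    callable ``i -> probability``); exactly one of the two must be supplied.
    ``N`` is the reference cell count used when reporting table-scale counts.
    """

    c0: float
    c1: float
    c2: float
    c3: float
    delta: float | None = None
    mu: Callable[[int], float] | Mapping[int, float] | None = None
    N: float = 1e6
    k: int = 3

    def __post_init__(self):
        if self.k != 3:
            raise DomainError(f"only coordination number k=3 is supported, got {self.k}")
        for name in ("c0", "c1", "c2", "c3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name}={v} outside [0, 1]")
        if (self.delta is None) == (self.mu is None):
            raise DomainError("give exactly one of delta or mu")
        if self.delta is not None and not 0.0 < self.delta < 1.0:
            raise DomainError(f"delta={self.delta} outside (0, 1)")
        # necessary condition for a stationary state: creating must be able to
        # outweigh merging (c0 > min{c2, c3})
        if not self.c0 > min(self.c2, self.c3):
            raise DomainError(
                f"c0={self.c0} must exceed min(c2, c3)={min(self.c2, self.c3)}")
        if self.N <= 0:
            raise DomainError("N must be positive")

    @property
    def cs(self) -> tuple[float, float, float, float]:
        return (self.c0, self.c1, self.c2, self.c3)

    @property
    def is_special(self) -> bool:
        """True for the solvable avalanche law mu_i = delta / i."""
        return self.delta is not None

    def mu_of(self, i: int) -> float:
        """Avalanche probability for a cluster of size ``i``."""
        if i < 1:
            raise DomainError(f"cluster size must be >= 1, got {i}")
        if self.delta is not None:
            return self.delta / i
        return _as_mu_callable(self.mu)(i)

    def with_delta(self, delta: float) -> "ModelParams":
        return ModelParams(self.c0, self.c1, self.c2, self.c3,
                           delta=delta, N=self.N, k=self.k)


_STATE_FIELDS = ("rho", "n", "n0", "n1_0", "x0", "x1", "x2", "x3", "T", "Y")


@dataclass(frozen=True)
class SteadyState:
    """Stationary-state aggregates at reference scale ``N``.

    All counts (``n``, ``n0``, ``n1_0``, ``x0..x3``) are per ``N`` cells;
    ``rho`` is the occupied fraction, ``T`` the mean probability that an
    empty cell next to another empty cell becomes occupied in a step, and
    ``Y`` the per-cluster merging rate ``(c1 x1 + 2 c2 x2 + 3 c3 x3)/n``.
    """

    rho: float
    n: float
    n0: float
    n1_0: float
    x0: float
    x1: float
    x2: float
    x3: float
    T: float
    Y: float
    N: float = 1e6

    @property
    def nhat0(self) -> float:
        """Total creating-cell count (alias of x0)."""
        return self.x0

    @property
    def xs(self) -> tuple[float, float, float, float]:
        return (self.x0, self.x1, self.x2, self.x3)

    def x_fractions(self) -> tuple[float, float, float, float]:
        """Empty-cell type shares ``x_i / ((1 - rho) N)``."""
        empty = (1.0 - self.rho) * self.N
        return tuple(x / empty for x in self.xs)

    def rescaled(self, N: float) -> "SteadyState":
        """Same per-cell state expressed at a different reference scale."""
        f = N / self.N
        return SteadyState(rho=self.rho, n=self.n * f, n0=self.n0 * f,
                           n1_0=self.n1_0 * f, x0=self.x0 * f, x1=self.x1 * f,
                           x2=self.x2 * f, x3=self.x3 * f, T=self.T, Y=self.Y,
                           N=N)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in _STATE_FIELDS}
        d["N"] = self.N
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SteadyState":
        return cls(**{k: d[k] for k in _STATE_FIELDS}, N=d.get("N", 1e6))


def aggregates_from_x(x0: float, x1: float, x2: float, x3: float,
                      N: float = 1e6) -> dict:
    """Aggregate quantities implied by the per-type empty-cell counts.

    Returns ``{rho, n0, n1_0, nhat0}`` where ``rho = 1 - sum(x)/N``,
    ``n1_0 = x3``, ``nhat0 = x0`` and ``n0 = (x2 + 2 x3 - x0)/2``.

    Raises
    ------
    NoAdmissibleState
        If empty cells are present but ``x2 <= x0`` — such counts cannot
        come from a valid configuration (they would imply ``n0 <= n1_0``
        with equality violated, i.e. a negative number of size->=2 empty
        clusters).
    """
    xs = (x0, x1, x2, x3)
    if any(x < 0 for x in xs):
        raise DomainError(f"negative empty-cell count in {xs}")
    total = math.fsum(xs)
    if total > N * (1 + 1e-12):
        raise DomainError(f"sum(x)={total} exceeds N={N}")
    if total == 0:
        return {"rho": 1.0, "n0": 0.0, "n1_0": 0.0, "nhat0": 0.0}
    if x2 <= x0:
        raise NoAdmissibleState("x2 <= x0",
                                f"x2={x2}, x0={x0} violates strict admissibility")
    return {
        "rho": 1.0 - total / N,
        "n0": 0.5 * (x2 + 2.0 * x3 - x0),
        "n1_0": x3,
        "nhat0": x0,
    }


def x_from_aggregates(rho: float, n0: float, n1_0: float, nhat0: float,
                      N: float = 1e6) -> tuple[float, float, float, float]:
    """Inverse change of variables: ``{rho, n0, n1_0, nhat0} -> {x0..x3}``."""
    x0 = nhat0
    x3 = n1_0
    x2 = nhat0 + 2.0 * n0 - 2.0 * n1_0
    x1 = (1.0 - rho) * N - 2.0 * nhat0 - 2.0 * n0 + n1_0
    return (x0, x1, x2, x3)


def empty_cluster_means(state: SteadyState, N: float | None = None) -> dict:
    """Mean empty-cluster sizes ``<i0>`` and ``<i0>_{2+}`` (size >= 2 only).

    ``<i0> = (1 - rho) N / n0``; excluding the size-1 clusters,
    ``<i0>_{2+} = (<i0> n0 - n1_0) / (n0 - n1_0)``.
    """
    N = state.N if N is None else N
    scale = N / state.N
    n0 = state.n0 * scale
    n1_0 = state.n1_0 * scale
    if n0 <= 0:
        raise DomainError("state has no empty clusters")
    mean_i0 = (1.0 - state.rho) * N / n0
    if n0 == n1_0:
        raise DomainError("all empty clusters are of size 1; <i0>_2+ undefined")
    mean_2plus = (mean_i0 * n0 - n1_0) / (n0 - n1_0)
    return {"mean_i0": mean_i0, "mean_i0_2plus": mean_2plus}
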