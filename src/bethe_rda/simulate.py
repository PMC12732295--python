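"""Monte-Carlo realization of the automaton on finite 3-regular lattices.

The infinite cycle-free lattice is approximated either by a uniformly
random 3-regular graph (boundary-free and locally tree-like — the default
for quantitative comparison with the mean-field solution) or by a finite
ball of the actual tree ("cayley-ball", used for the exact per-snapshot
combinatorial checks, with boundary clusters excluded).

Update rule per time step: one cell is chosen uniformly.  If it is
occupied, the whole cluster containing it (size ``i``) is emptied with
probability ``mu_i``; if it is empty with ``t`` occupied neighbours, it
becomes occupied with probability ``c_t``; otherwise nothing changes.
Random draws per step, in fixed order: (1) the cell index, (2) a single
uniform accept/reject variate.

Occupied clusters are tracked with an incremental union-find: clusters
only ever merge (occupation) or disappear whole (avalanche), never split,
so removal just resets the member cells.  A full breadth-first recount is
available as the correctness oracle.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import ModelParams, empty_cluster_composition
from .errors import DomainError, NonStationaryWarning

__all__ = [
    "SimConfig",
    "SimResult",
    "Lattice",
    "SimState",
    "build_lattice",
    "step",
    "run",
    "snapshot",
    "snapshot_composition",
]

_OBSERVABLES = ("rho", "n", "n0", "n1_0", "x0", "x1", "x2", "x3")


@dataclass(frozen=True)
class Lattice:
    """Adjacency structure; ``interior`` marks degree-3 vertices."""

    mode: str
    n_cells: int
    adj: tuple
    interior: np.ndarray

    @property
    def n_interior(self) -> int:
        return int(self.interior.sum())


def cayley_ball_size(radius: int) -> int:
    """Cells in a radius-``radius`` ball of the 3-regular tree."""
    return 1 + 3 * (2 ** radius - 1)


def build_lattice(mode: str, n_cells: int, seed: int | None = None) -> Lattice:
    """Construct a finite 3-regular lattice.

    ``random-regular``: uniform random 3-regular graph (``n_cells`` even,
    >= 4); every vertex has degree exactly 3 and is interior.
    ``cayley-ball``: the ball of radius r around a root of the infinite
    tree; requires ``n_cells == 1 + 3 (2**r - 1)``.  Leaves have degree 1
    and are marked non-interior.
    """
    if mode == "random-regular":
        if n_cells % 2 or n_cells < 4:
            raise DomainError("random-regular needs an even n_cells >= 4")
        import networkx as nx
        g = nx.random_regular_graph(3, n_cells, seed=seed)
        adj = tuple(tuple(g.neighbors(v)) for v in range(n_cells))
        interior = np.ones(n_cells, dtype=bool)
        return Lattice(mode=mode, n_cells=n_cells, adj=adj, interior=interior)
    if mode == "cayley-ball":
        r = 0
        while cayley_ball_size(r) < n_cells:
            r += 1
        if cayley_ball_size(r) != n_cells:
            raise DomainError(
                f"cayley-ball needs n_cells of the form 1 + 3(2^r - 1); "
                f"got {n_cells} (nearest: {cayley_ball_size(r)})")
        nbrs = [[] for _ in range(n_cells)]
        nxt = 1
        frontier = [0]
        for depth in range(r):
            newf = []
            for v in frontier:
                kids = 3 if v == 0 else 2
                for _ in range(kids):
                    nbrs[v].append(nxt)
                    nbrs[nxt].append(v)
                    newf.append(nxt)
                    nxt += 1
            frontier = newf
        adj = tuple(tuple(a) for a in nbrs)
        interior = np.array([len(a) == 3 for a in adj])
        return Lattice(mode=mode, n_cells=n_cells, adj=adj, interior=interior)
    raise DomainError(f"unknown lattice mode {mode!r}")


@dataclass
class SimConfig:
    lattice_mode: str
    n_cells: int
    params: ModelParams
    burn_in: int | None = None          # default: 50 sweeps
    n_samples: int = 200
    sample_interval: int | None = None  # default: 1 sweep
    seed: int = 0
    n_batches: int = 20

    def __post_init__(self):
        if self.n_cells < 100:
            raise DomainError("n_cells must be >= 100")
        if self.burn_in is None:
            self.burn_in = 50 * self.n_cells
        if self.sample_interval is None:
            self.sample_interval = self.n_cells
        if self.burn_in < self.n_cells:
            raise DomainError("burn_in must cover at least one sweep")
        if self.sample_interval < 1:
            raise DomainError("sample_interval must be >= 1")


@dataclass
class SimResult:
    """Time-averaged per-cell observables with batch-means standard errors."""

    means: dict
    se: dict
    samples: dict = field(repr=False)
    histogram: dict = field(repr=False)      # cluster size -> mean count/cell
    n_samples: int = 0
    stationary: bool = True


class SimState:
    """Mutable lattice state with incremental occupied-cluster tracking."""

    def __init__(self, lattice: Lattice, rng: np.random.Generator):
        self.lattice = lattice
        self.rng = rng
        n = lattice.n_cells
        self.occupied = bytearray(n)
        self.parent = [-1] * n       # -1 marks empty cells
        self.csize = [0] * n         # cluster size, valid at roots
        self.n_clusters = 0
        self.n_occupied = 0

    # -- union-find ---------------------------------------------------------
    def find(self, v: int) -> int:
        parent = self.parent
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def cluster_size(self, v: int) -> int:
        return self.csize[self.find(v)]

    def _occupy(self, c: int):
        parent, csize = self.parent, self.csize
        parent[c] = c
        csize[c] = 1
        self.n_clusters += 1
        self.n_occupied += 1
        occupied = self.occupied
        for nb in self.lattice.adj[c]:
            if occupied[nb]:
                ra, rb = self.find(c), self.find(nb)
                if ra != rb:
                    if csize[ra] < csize[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    csize[ra] += csize[rb]
                    self.n_clusters -= 1
        occupied[c] = 1

    def _avalanche(self, c: int):
        """Remove the whole occupied cluster containing ``c`` (BFS)."""
        occupied, parent, adj = self.occupied, self.parent, self.lattice.adj
        stack = [c]
        occupied[c] = 0
        removed = 1
        while stack:
            v = stack.pop()
            parent[v] = -1
            for nb in adj[v]:
                if occupied[nb]:
                    occupied[nb] = 0
                    removed += 1
                    stack.append(nb)
        self.n_clusters -= 1
        self.n_occupied -= removed

    # -- dynamics -----------------------------------------------------------
    def advance(self, params: ModelParams, n_steps: int):
        """Run ``n_steps`` update steps (tight loop, batched randomness)."""
        occupied, adj = self.occupied, self.lattice.adj
        cs = params.cs
        delta = params.delta
        mu_of = None if delta is not None else params.mu_of
        n = self.lattice.n_cells
        rng = self.rng
        done = 0
        while done < n_steps:
            chunk = min(n_steps - done, 1 << 16)
            cells = rng.integers(0, n, size=chunk)
            us = rng.random(chunk)
            for idx in range(chunk):
                c = int(cells[idx])
                u = us[idx]
                if occupied[c]:
                    size = self.csize[self.find(c)]
                    mu = delta / size if delta is not None else mu_of(size)
                    if u < mu:
                        self._avalanche(c)
                else:
                    t = (occupied[adj[c][0]] + occupied[adj[c][1]]
                         + occupied[adj[c][2]]) if len(adj[c]) == 3 else sum(
                             occupied[nb] for nb in adj[c])
                    if u < cs[t]:
                        self._occupy(c)
            done += chunk

    # -- oracle recount -----------------------------------------------------
    def recount_clusters(self) -> dict[int, int]:
        """Breadth-first recount of occupied clusters: size histogram.

        Independent of the union-find bookkeeping; used as its oracle.
        """
        occupied, adj = self.occupied, self.lattice.adj
        seen = bytearray(self.lattice.n_cells)
        hist: Counter = Counter()
        for v in range(self.lattice.n_cells):
            if occupied[v] and not seen[v]:
                size = 0
                stack = [v]
                seen[v] = 1
                while stack:
                    w = stack.pop()
                    size += 1
                    for nb in adj[w]:
                        if occupied[nb] and not seen[nb]:
                            seen[nb] = 1
                            stack.append(nb)
                hist[size] += 1
        return dict(hist)


def step(state: SimState, params: ModelParams) -> SimState:
    """Execute one update step in place (see module docstring for the rule)."""
    state.advance(params, 1)
    return state


def snapshot(state: SimState, interior_only: bool | None = None) -> dict:
    """Per-cell observables of the current configuration.

    For ``cayley-ball`` lattices (or ``interior_only=True``) the census is
    restricted to *boundary-free clusters*: empty-cell type counts are
    taken over the cells of empty clusters that lie entirely in the
    interior, and occupied-cluster counts over clusters entirely in the
    interior — so that the exact tree identities (e.g.
    ``n0 = (x2 + 2 x3 - x0)/2``) hold per snapshot.  Counts are
    normalized per interior cell.
    """
    lat = state.lattice
    if interior_only is None:
        interior_only = lat.mode == "cayley-ball"
    occupied, adj = state.occupied, lat.adj
    interior = lat.interior
    nref = lat.n_interior if interior_only else lat.n_cells

    x = [0, 0, 0, 0]
    n_occ = 0
    if not interior_only:
        for v in range(lat.n_cells):
            if occupied[v]:
                n_occ += 1
            else:
                x[sum(occupied[nb] for nb in adj[v])] += 1
    else:
        for v in range(lat.n_cells):
            if interior[v] and occupied[v]:
                n_occ += 1

    # empty clusters (whole-graph components; in interior mode only those
    # entirely inside the interior contribute, both to n0 and to x)
    seen = bytearray(lat.n_cells)
    n0 = n1_0 = 0
    for v in range(lat.n_cells):
        if occupied[v] or seen[v]:
            continue
        comp = [v]
        seen[v] = 1
        stack = [v]
        while stack:
            w = stack.pop()
            for nb in adj[w]:
                if not occupied[nb] and not seen[nb]:
                    seen[nb] = 1
                    comp.append(nb)
                    stack.append(nb)
        if interior_only:
            if not all(interior[w] for w in comp):
                continue
            for w in comp:
                x[sum(occupied[nb] for nb in adj[w])] += 1
        n0 += 1
        if len(comp) == 1:
            n1_0 += 1

    # occupied clusters from union-find roots
    hist: Counter = Counter()
    n_cl = 0
    for v in range(lat.n_cells):
        if occupied[v] and state.parent[v] == v:
            if interior_only:
                continue  # counted below with the boundary filter
            hist[state.csize[v]] += 1
            n_cl += 1
    if interior_only:
        for size, count in _interior_cluster_hist(state).items():
            hist[size] += count
            n_cl += count

    return {
        "rho": n_occ / nref,
        "n": n_cl / nref,
        "n0": n0 / nref,
        "n1_0": n1_0 / nref,
        "x0": x[0] / nref, "x1": x[1] / nref,
        "x2": x[2] / nref, "x3": x[3] / nref,
        "histogram": dict(hist),
    }


def _iter_occupied_clusters(state: SimState):
    """Yield occupied clusters as vertex lists (BFS, whole graph)."""
    lat = state.lattice
    occupied, adj = state.occupied, lat.adj
    seen = bytearray(lat.n_cells)
    for v in range(lat.n_cells):
        if occupied[v] and not seen[v]:
            comp = [v]
            seen[v] = 1
            stack = [v]
            while stack:
                w = stack.pop()
                for nb in adj[w]:
                    if occupied[nb] and not seen[nb]:
                        seen[nb] = 1
                        comp.append(nb)
                        stack.append(nb)
            yield comp


def _interior_cluster_hist(state: SimState) -> dict[int, int]:
    interior = state.lattice.interior
    hist: Counter = Counter()
    for comp in _iter_occupied_clusters(state):
        if all(interior[w] for w in comp):
            hist[len(comp)] += 1
    return dict(hist)


def snapshot_composition(state: SimState) -> dict:
    """Cell-type census of every boundary-free empty cluster, checked
    against the exact composition formula.

    Returns ``{"tallies": {(i, j): count}, "violations": [...]}`` where a
    violation records any cluster whose measured (creating, enlarging, C2,
    C3) counts differ from ``empty_cluster_composition(i, j)``.
    """
    lat = state.lattice
    if lat.mode != "cayley-ball":
        raise DomainError("composition checks need a cycle-free lattice "
                          "(cayley-ball mode)")
    occupied, adj, interior = state.occupied, lat.adj, lat.interior
    seen = bytearray(lat.n_cells)
    tallies: Counter = Counter()
    violations = []
    for v in range(lat.n_cells):
        if occupied[v] or seen[v]:
            continue
        comp = [v]
        seen[v] = 1
        stack = [v]
        while stack:
            w = stack.pop()
            for nb in adj[w]:
                if not occupied[nb] and not seen[nb]:
                    seen[nb] = 1
                    comp.append(nb)
                    stack.append(nb)
        if not all(interior[w] for w in comp):
            continue
        counts = [0, 0, 0, 0]
        for w in comp:
            counts[sum(occupied[nb] for nb in adj[w])] += 1
        i, j = len(comp), counts[0]
        expected = empty_cluster_composition(i, j)
        measured = dict(n_creating=counts[0], n_enlarging=counts[1],
                        n_C2=counts[2], n_C3=counts[3])
        tallies[(i, j)] += 1
        if (measured["n_creating"] != expected.n_creating
                or measured["n_enlarging"] != expected.n_enlarging
                or measured["n_C2"] != expected.n_C2
                or measured["n_C3"] != expected.n_C3):
            violations.append({"i": i, "j": j, "measured": measured})
    return {"tallies": dict(tallies), "violations": violations}


def run(config: SimConfig) -> SimResult:
    """Burn in, then sample the stationary state.

    Means and standard errors use batch means (``config.n_batches``
    batches).  If the first- and second-half means of any observable
    differ by more than 5 standard errors a non-stationarity warning is
    issued and ``result.stationary`` is False.
    """
    rng = np.random.default_rng(config.seed)
    lattice = build_lattice(config.lattice_mode, config.n_cells,
                            seed=config.seed)
    state = SimState(lattice, rng)
    state.advance(config.params, config.burn_in)

    series = {k: np.empty(config.n_samples) for k in _OBSERVABLES}
    hist_acc: Counter = Counter()
    for s in range(config.n_samples):
        state.advance(config.params, config.sample_interval)
        snap = snapshot(state)
        for k in _OBSERVABLES:
            series[k][s] = snap[k]
        hist_acc.update(snap["histogram"])

    nb = min(config.n_batches, config.n_samples)
    means, se = {}, {}
    stationary = True
    for k, v in series.items():
        means[k] = float(v.mean())
        batches = np.array_split(v, nb)
        bm = np.array([b.mean() for b in batches])
        se[k] = float(bm.std(ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
        half = len(v) // 2
        drift = abs(v[:half].mean() - v[half:].mean())
        if se[k] > 0 and drift > 5.0 * se[k]:
            stationary = False
            warnings.warn(
                f"observable {k!r} drifts by {drift:.3g} "
                f"(> 5 SE = {5 * se[k]:.3g}); no stationary plateau",
                NonStationaryWarning, stacklevel=2)
    nref = lattice.n_interior if lattice.mode == "cayley-ball" \
        else lattice.n_cells
    histogram = {size: count / (config.n_samples * nref)
                 for size, count in sorted(hist_acc.items())}
    return SimResult(means=means, se=se, samples=series,
                     histogram=histogram, n_samples=config.n_samples,
                     stationary=stationary)
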