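"""Stationary-state balance equations and the solver for the law mu_i = delta/i.

The stationary state of the automaton is fixed by seven balance laws: three
exact ones (density ``rho``, cluster count ``n``, empty-cluster count ``n0``)
and four mean-field ones for the per-type empty-cell counts ``x0..x3``.  For
the solvable avalanche law ``mu_i = delta / i`` the system reduces to four
linear equations for ``x(n, rho)`` plus two quadratic (conic) equations in
``(n, rho)``; the admissible intersection of the two conics is the unique
stationary state.

Everything internal works per cell (``N = 1``); reference-scale counts are
produced when the :class:`~bethe_rda.core.SteadyState` is assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import numpy.polynomial.polynomial as npoly

from .core import ModelParams, SteadyState, aggregates_from_x
from .errors import DomainError, NoAdmissibleState, RDAError

__all__ = [
    "ConicPair",
    "DeltaRange",
    "neighbor_occupation_T",
    "balance_residuals",
    "conic_pair",
    "solve_special",
    "delta_range",
]

def neighbor_occupation_T(params: ModelParams, x0: float, x1: float,
                          x2: float) -> float:
    """Mean probability that an empty neighbour of an empty cell gets occupied.

    ``T = (c0 x0 + c1 x1 + c2 x2) / (x0 + x1 + x2)`` — only C0..C2 cells can
    neighbour an empty cell.  A value outside ``[0, 1]`` signals inadmissible
    counts (it is returned unclipped; callers decide).
    """
    den = x0 + x1 + x2
    if den <= 0:
        raise DomainError("x0 + x1 + x2 must be positive")
    return (params.c0 * x0 + params.c1 * x1 + params.c2 * x2) / den


def balance_residuals(params: ModelParams, state: SteadyState, dist) -> dict:
    """Signed residuals of the seven stationary balance laws, per ``N`` cells.

    ``dist`` must provide ``moment_sum(order)`` returning
    ``sum_i mu_i n_i i**order`` at the same reference scale as ``state``
    (see :class:`~bethe_rda.distribution.ClusterDistribution`).

    Orientation: the ``rho``/``n``/``n0`` residuals are (gains - losses) of
    the respective quantity; the ``x0..x3`` residuals are oriented so that
    the two dependency identities hold exactly for *any* state and any T:

    * ``res[rho] == res[n0] - res[n]``
    * ``res[rho] == res[x0] + res[x1] + res[x2] + res[x3]``
    """
    if state.n <= 0:
        raise DomainError("balance residuals undefined for n <= 0")
    c0, c1, c2, c3 = params.cs
    x0, x1, x2, x3 = state.xs
    n = state.n
    S1 = dist.moment_sum(1)   # sum mu_i n_i i
    S2 = dist.moment_sum(2)   # sum mu_i n_i i^2
    T = neighbor_occupation_T(params, x0, x1, x2)
    occ = c0 * x0 + c1 * x1 + c2 * x2 + c3 * x3
    return {
        "rho": occ - S2,
        "n": c0 * x0 - c2 * x2 - 2.0 * c3 * x3 - S1,
        "n0": 2.0 * c0 * x0 + c1 * x1 - c3 * x3 - (S2 + S1),
        "x0": (c0 + 3.0 * T) * x0 - S2 - x1 * S1 / n,
        "x1": (2.0 * T + c1) * x1 + (x1 - 2.0 * x2) * S1 / n - 3.0 * T * x0,
        "x2": (T + c2) * x2 + (2.0 * x2 - 3.0 * x3) * S1 / n - 2.0 * T * x1,
        "x3": c3 * x3 + 3.0 * x3 * S1 / n - T * x2,
    }


# ---------------------------------------------------------------------------
# elimination for mu_i = delta / i: linear x(n, rho) and the conic pair
# ---------------------------------------------------------------------------

def x_coefficients(params: ModelParams) -> np.ndarray:
    """Coefficients of the linear solution ``x_i = a_i0 + a_i1 n + a_i2 rho``.

    Per cell (``N = 1``).  Rows are the four linear equations obtained by
    (i) empty-cell conservation, (ii) the density balance, (iii) the cluster
    balance, and (iv) the T-elimination row: substituting the three
    ``T x_i`` expressions into the definition of T and removing the
    ``delta rho`` term via the density balance.  Returns the 4x3 matrix
    ``a`` with column order (const, n, rho).
    """
    if not params.is_special:
        raise DomainError("x elimination requires the law mu_i = delta / i")
    c0, c1, c2, c3 = params.cs
    d = params.delta
    A = np.array([
        [1.0, 1.0, 1.0, 1.0],
        [c0, c1, c2, c3],
        [c0, 0.0, -c2, -2.0 * c3],
        [-c0, (d - 2.0 * c1) / 3.0, d - c2 / 6.0, 3.0 * d + 11.0 * c3 / 6.0],
    ])
    # rhs as linear forms in (1, n, rho)
    B = np.array([
        [1.0, 0.0, -1.0],
        [0.0, 0.0, d],
        [0.0, d, 0.0],
        [0.0, 0.0, 0.0],
    ])
    return np.linalg.solve(A, B)


def x_of(params: ModelParams, n: float, rho: float) -> np.ndarray:
    """Per-cell empty-cell counts ``x0..x3`` for given per-cell ``(n, rho)``."""
    a = x_coefficients(params)
    return a @ np.array([1.0, n, rho])


def _quad_of_linforms(a, b) -> np.ndarray:
    """Conic coefficients (nn, nr, rr, n, r, 1) of the product of two
    linear forms given in (const, n, rho) order."""
    return np.array([
        a[1] * b[1],
        a[1] * b[2] + a[2] * b[1],
        a[2] * b[2],
        a[0] * b[1] + a[1] * b[0],
        a[0] * b[2] + a[2] * b[0],
        a[0] * b[0],
    ])


_CONIC_KEYS = ("nn", "nr", "rr", "n", "r", "1")


@dataclass(frozen=True)
class ConicPair:
    """The two conics in ``(n, rho)`` whose intersection is the steady state,
    plus the admissibility half-plane ``s_n n + s_rho rho + s_1 > 0``
    (the ``x2 > x0`` condition).  Coefficient order: nn, nr, rr, n, r, 1."""

    p: tuple
    q: tuple
    s: tuple  # (s_n, s_rho, s_1)

    def eval_p(self, n: float, rho: float) -> float:
        return _eval_conic(self.p, n, rho)

    def eval_q(self, n: float, rho: float) -> float:
        return _eval_conic(self.q, n, rho)

    def eval_s(self, n: float, rho: float) -> float:
        return self.s[0] * n + self.s[1] * rho + self.s[2]

    def as_dict(self) -> dict:
        return {
            **{f"p_{k}": v for k, v in zip(_CONIC_KEYS, self.p)},
            **{f"q_{k}": v for k, v in zip(_CONIC_KEYS, self.q)},
            "s_n": self.s[0], "s_rho": self.s[1], "s_1": self.s[2],
        }


def _eval_conic(c, n, rho):
    return (c[0] * n * n + c[1] * n * rho + c[2] * rho * rho
            + c[3] * n + c[4] * rho + c[5])


def conic_pair(params: ModelParams) -> ConicPair:
    """Build the conic pair by eliminating ``x`` through the linear solve.

    The two residual equations are the C0 and C1 balance rows with ``T``
    taken from the C3 row (``T = (3 delta + c3) x3 / x2``), multiplied
    through by ``x2`` so that they are exactly quadratic in ``(n, rho)``:

    * ``P = 3 (3 delta + c3) x3 x0 - x2 (delta rho + delta x1 - c0 x0)``
    * ``Q = 2 (3 delta + c3) x3 x1 - x2 ((c2 + 2 delta) x2 + c3 x3)``
    """
    c0, c1, c2, c3 = params.cs
    d = params.delta
    a = x_coefficients(params)
    x0l, x1l, x2l, x3l = a  # linear forms in (1, n, rho)
    rho_l = np.array([0.0, 0.0, 1.0])
    w = d * rho_l + d * x1l - c0 * x0l
    p = 3.0 * (3.0 * d + c3) * _quad_of_linforms(x3l, x0l) \
        - _quad_of_linforms(x2l, w)
    q = 2.0 * (3.0 * d + c3) * _quad_of_linforms(x3l, x1l) \
        - _quad_of_linforms(x2l, (c2 + 2.0 * d) * x2l + c3 * x3l)
    sline = x2l - x0l
    return ConicPair(p=tuple(p), q=tuple(q),
                     s=(sline[1], sline[2], sline[0]))


def conic_pair_symbolic(params: ModelParams) -> ConicPair:
    """Same conic pair obtained by symbolic elimination (cross-check path)."""
    import sympy as sp

    c0, c1, c2, c3 = [sp.Rational(str(c)) for c in params.cs]
    d = sp.Rational(str(params.delta))
    n, rho = sp.symbols("n rho")
    x = sp.symbols("x0 x1 x2 x3")
    rowD = (-c0 * x[0] + (d - 2 * c1) / 3 * x[1] + (d - c2 / 6) * x[2]
            + (3 * d + sp.Rational(11, 6) * c3) * x[3])
    sol = sp.solve(
        [x[0] + x[1] + x[2] + x[3] - (1 - rho),
         c0 * x[0] + c1 * x[1] + c2 * x[2] + c3 * x[3] - d * rho,
         c0 * x[0] - c2 * x[2] - 2 * c3 * x[3] - d * n,
         rowD], list(x), dict=True)[0]
    X = [sp.expand(sol[v]) for v in x]
    P = sp.expand(3 * (3 * d + c3) * X[3] * X[0]
                  - X[2] * (d * rho + d * X[1] - c0 * X[0]))
    Q = sp.expand(2 * (3 * d + c3) * X[3] * X[1]
                  - X[2] * ((c2 + 2 * d) * X[2] + c3 * X[3]))
    S = sp.expand(X[2] - X[0])

    def coeffs(expr):
        pol = sp.Poly(expr, n, rho)
        get = lambda i, j: float(pol.coeff_monomial(n ** i * rho ** j))
        return (get(2, 0), get(1, 1), get(0, 2), get(1, 0), get(0, 1), get(0, 0))

    spol = sp.Poly(S, n, rho)
    s = (float(spol.coeff_monomial(n)), float(spol.coeff_monomial(rho)),
         float(spol.coeff_monomial(1)))
    return ConicPair(p=coeffs(P), q=coeffs(Q), s=s)


# ---------------------------------------------------------------------------
# conic intersection
# ---------------------------------------------------------------------------

def _newton_polish(cp: ConicPair, n: float, rho: float,
                   tol: float = 1e-15, maxiter: int = 80):
    p, q = cp.p, cp.q
    z0, z1 = n, rho
    for _ in range(maxiter):
        F0 = _eval_conic(p, z0, z1)
        F1 = _eval_conic(q, z0, z1)
        J = np.array([
            [2 * p[0] * z0 + p[1] * z1 + p[3], p[1] * z0 + 2 * p[2] * z1 + p[4]],
            [2 * q[0] * z0 + q[1] * z1 + q[3], q[1] * z0 + 2 * q[2] * z1 + q[4]],
        ])
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        if abs(det) < 1e-300:
            return None
        d0 = (J[1, 1] * F0 - J[0, 1] * F1) / det
        d1 = (-J[1, 0] * F0 + J[0, 0] * F1) / det
        z0 -= d0
        z1 -= d1
        if abs(d0) < tol and abs(d1) < tol:
            return (z0, z1)
    return (z0, z1)


def conic_intersections(cp: ConicPair) -> list[tuple[float, float]]:
    """All real intersection points of the conic pair.

    The resultant of the two quadratics (viewed as polynomials in ``n`` with
    rho-dependent coefficients) is a quartic in ``rho``; each real root
    yields ``n`` from the pencil combination that cancels the ``n^2`` term.
    Points are polished by Newton iteration and deduplicated.
    """
    p, q = np.asarray(cp.p), np.asarray(cp.q)
    # quadratics in n: a + b(rho) n + c(rho) n^2, coefficient lists ascending in rho
    a1, b1, c1 = [p[0]], [p[3], p[1]], [p[5], p[4], p[2]]
    a2, b2, c2 = [q[0]], [q[3], q[1]], [q[5], q[4], q[2]]
    pm, ps = npoly.polymul, npoly.polysub
    t1 = ps(pm(a1, c2), pm(a2, c1))
    t2 = ps(pm(a1, b2), pm(a2, b1))
    t3 = ps(pm(b1, c2), pm(b2, c1))
    res = ps(pm(t1, t1), pm(t2, t3))
    res = np.trim_zeros(np.asarray(res), "b")
    if res.size == 0:
        return []
    roots = npoly.polyroots(res)
    # pencil combination with zero n^2 coefficient: q_nn * P - p_nn * Q
    A = q[0] * p - p[0] * q
    out: list[tuple[float, float]] = []
    for r in roots:
        if abs(r.imag) > 1e-7 * max(1.0, abs(r.real)):
            continue
        rho = float(r.real)
        den = A[1] * rho + A[3]
        if abs(den) < 1e-12:
            cands = _roots_in_n(p, rho) + _roots_in_n(q, rho)
        else:
            cands = [-(A[2] * rho * rho + A[4] * rho + A[5]) / den]
        for n in cands:
            z = _newton_polish(cp, n, rho)
            if z is None:
                continue
            scale = max(1.0, abs(z[0]), abs(z[1]))
            if (abs(cp.eval_p(*z)) > 1e-8 * scale
                    or abs(cp.eval_q(*z)) > 1e-8 * scale):
                continue
            if not any(math.isclose(z[0], w[0], abs_tol=1e-9)
                       and math.isclose(z[1], w[1], abs_tol=1e-9)
                       for w in out):
                out.append(z)
    return out


def _roots_in_n(c, rho):
    aa = c[0]
    bb = c[3] + c[1] * rho
    cc = c[5] + c[4] * rho + c[2] * rho * rho
    if aa == 0:
        return [-cc / bb] if bb != 0 else []
    disc = bb * bb - 4 * aa * cc
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    return [(-bb + sq) / (2 * aa), (-bb - sq) / (2 * aa)]


# ---------------------------------------------------------------------------
# admissibility and the special-case solver
# ---------------------------------------------------------------------------

def admissibility_failures(params: ModelParams, n: float, rho: float,
                           x=None) -> list[str]:
    """Names of all failed admissibility tests (empty list if admissible)."""
    if x is None:
        x = x_of(params, n, rho)
    out = []
    if n <= 0:
        out.append("n <= 0 branch")
    if not 0.0 < rho < 1.0:
        out.append("rho outside (0, 1)")
    if np.any(np.asarray(x) <= 0):
        out.append("x_i <= 0")
    if x[2] <= x[0]:
        out.append("x2 <= x0")
    den = x[0] + x[1] + x[2]
    T = neighbor_occupation_T(params, x[0], x[1], x[2]) if den > 0 else -1.0
    if not 0.0 < T < 1.0:
        out.append("T outside (0, 1)")
    return out


def admissibility_failure(params: ModelParams, n: float, rho: float,
                          x=None) -> str | None:
    """Name of the first failed admissibility test, or None if admissible."""
    fails = admissibility_failures(params, n, rho, x)
    return fails[0] if fails else None


def _assemble_state(params: ModelParams, n: float, rho: float,
                    N: float | None = None) -> SteadyState:
    N = params.N if N is None else N
    x = x_of(params, n, rho)
    agg = aggregates_from_x(*x, N=1.0)
    T = neighbor_occupation_T(params, x[0], x[1], x[2])
    Y = (params.c1 * x[1] + 2.0 * params.c2 * x[2]
         + 3.0 * params.c3 * x[3]) / n
    return SteadyState(rho=rho, n=n * N, n0=agg["n0"] * N,
                       n1_0=agg["n1_0"] * N, x0=x[0] * N, x1=x[1] * N,
                       x2=x[2] * N, x3=x[3] * N, T=T, Y=Y, N=N)


def _residual_check(params: ModelParams, n: float, rho: float,
                    tol: float) -> float:
    """Max residual of the six defining equations (per cell)."""
    c0, c1, c2, c3 = params.cs
    d = params.delta
    x0, x1, x2, x3 = x_of(params, n, rho)
    T = neighbor_occupation_T(params, x0, x1, x2)
    res = [
        x0 + x1 + x2 + x3 - (1.0 - rho),
        c0 * x0 + c1 * x1 + c2 * x2 + c3 * x3 - d * rho,
        c0 * x0 - c2 * x2 - 2.0 * c3 * x3 - d * n,
        (c0 + 3.0 * T) * x0 - d * rho - d * x1,
        3.0 * T * x0 - (2.0 * T + c1) * x1 - d * (x1 - 2.0 * x2),
        T * x2 - c3 * x3 - 3.0 * d * x3,
    ]
    worst = max(abs(r) for r in res)
    if worst > tol:
        raise RDAError(f"stationarity residual {worst:.3e} exceeds tol {tol:.1e}")
    return worst


def solve_special(params: ModelParams, N: float | None = None,
                  tol: float = 1e-10) -> SteadyState:
    """Unique admissible stationary state for the avalanche law mu_i = delta/i.

    Eliminates ``x`` through the linear solve, intersects the resulting two
    conics in ``(n, rho)``, filters by admissibility (``n > 0``,
    ``0 < rho < 1``, ``x_i > 0``, ``x2 > x0``, ``0 < T < 1``) and verifies
    the six defining equations to ``tol``.

    Raises
    ------
    NoAdmissibleState
        If no conic intersection passes admissibility; the error names the
        test failed by the nearest-to-admissible branch.
    """
    if not params.is_special:
        raise DomainError("solve_special requires the law mu_i = delta / i")
    cp = conic_pair(params)
    points = conic_intersections(cp)
    admissible = []
    failures = []
    for (n, rho) in points:
        fails = admissibility_failures(params, n, rho)
        if not fails:
            admissible.append((n, rho))
        else:
            failures.append(((n, rho), fails))
    if len(admissible) > 1:
        raise RDAError(f"multiple admissible intersections found: {admissible}")
    if not admissible:
        if not failures:
            raise NoAdmissibleState("no real conic intersection")
        # report the nearest-to-admissible branch: fewest failed tests wins
        (n, rho), fails = min(failures, key=lambda it: len(it[1]))
        raise NoAdmissibleState(fails[0],
                                f"nearest branch at n={n:.6g}, rho={rho:.6g}")
    n, rho = admissible[0]
    _residual_check(params, n, rho, tol)
    return _assemble_state(params, n, rho, N=N)


# ---------------------------------------------------------------------------
# the stationary window in delta
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaRange:
    """Stability window ``(delta_min, delta_max)`` and the ``n = n0``
    crossover ``delta_eq``, with the branch states at the two boundaries
    (per-``N`` counts) and per-root convergence diagnostics."""

    delta_min: float | None
    delta_max: float | None
    delta_eq: float | None
    at_min: dict | None = None      # {"n": ..., "rho": ...} at delta_min
    at_max: dict | None = None
    diagnostics: dict = field(default_factory=dict)


class _Branch:
    """Continuation tracker: follows the solution branch of the conic pair
    through delta by always taking the intersection nearest the previous
    point, regardless of admissibility."""

    def __init__(self, params: ModelParams, delta0: float,
                 point0: tuple[float, float]):
        self.params = params
        self.delta = delta0
        self.point = point0

    def at(self, delta: float) -> tuple[float, float]:
        pts = conic_intersections(conic_pair(self.params.with_delta(delta)))
        if not pts:
            raise NoAdmissibleState("branch lost",
                                    f"no real intersection at delta={delta}")
        n0, r0 = self.point
        pt = min(pts, key=lambda z: (z[0] - n0) ** 2 + (z[1] - r0) ** 2)
        self.delta, self.point = delta, pt
        return pt


def _walk_to_zero(params, anchor_delta, anchor_point, value, direction,
                  step=0.005, xtol=1e-12):
    """Walk the branch in delta until ``value(delta, (n, rho))`` changes sign,
    then bisect.  Returns (delta*, point*, diagnostics) or (None, None, diag)."""
    br = _Branch(params, anchor_delta, anchor_point)
    d, pt = anchor_delta, anchor_point
    v = value(d, pt)
    steps = 0
    while 1e-4 < d < 1.0 - 1e-4:
        d2 = min(max(d + direction * step, 1e-4), 1.0 - 1e-4)
        if d2 == d:
            break
        try:
            pt2 = br.at(d2)
        except NoAdmissibleState:
            return None, None, {"converged": False, "reason": "branch lost",
                                "last_delta": d}
        v2 = value(d2, pt2)
        steps += 1
        if v == 0.0 or (v > 0) != (v2 > 0):
            lo, hi, vlo = d, d2, v
            it = 0
            while abs(hi - lo) > xtol:
                mid = 0.5 * (lo + hi)
                ptm = br.at(mid)
                vm = value(mid, ptm)
                if vm == 0.0:
                    lo = hi = mid
                    break
                if (vm > 0) == (vlo > 0):
                    lo, vlo = mid, vm
                else:
                    hi = mid
                it += 1
            dstar = 0.5 * (lo + hi)
            ptstar = br.at(dstar)
            return dstar, ptstar, {"converged": True, "bisect_iters": it,
                                   "walk_steps": steps, "xtol": xtol}
        d, pt, v = d2, pt2, v2
    return None, None, {"converged": False, "reason": "open boundary",
                        "last_delta": d}


def _find_anchor(params: ModelParams) -> tuple[float, tuple[float, float]]:
    deltas = [i / 40.0 for i in range(1, 40)]
    # try mid-range values first
    for d in sorted(deltas, key=lambda v: abs(v - 0.5)):
        try:
            st = solve_special(params.with_delta(d))
        except (NoAdmissibleState, RDAError):
            continue
        return d, (st.n / st.N, st.rho)
    raise NoAdmissibleState("no admissible delta found in (0, 1)")


def delta_range(params: ModelParams, xtol: float = 1e-12) -> DeltaRange:
    """Stability window of the avalanche parameter for fixed ``c0..c3``.

    ``delta_min`` is where the branch cluster count reaches ``n = 0``
    (below it merging dominates and no stationary state exists);
    ``delta_max`` is where ``x2 = x0`` (the admissibility half-plane
    boundary); ``delta_eq`` is the ``n = n0`` crossover.  Each boundary is
    located by continuation along the solution branch plus bisection.
    """
    d0, pt0 = _find_anchor(params)

    def n_value(_d, pt):
        return pt[0]

    def x_gap(d, pt):
        x = x_of(params.with_delta(d), *pt)
        return x[2] - x[0]

    def n_minus_n0(d, pt):
        x = x_of(params.with_delta(d), *pt)
        return pt[0] - 0.5 * (x[2] + 2.0 * x[3] - x[0])

    dmin, pmin, diag_min = _walk_to_zero(params, d0, pt0, n_value, -1,
                                         xtol=xtol)
    dmax, pmax, diag_max = _walk_to_zero(params, d0, pt0, x_gap, +1,
                                         xtol=xtol)
    deq, _, diag_eq = _walk_to_zero(params, d0, pt0, n_minus_n0, +1,
                                    xtol=xtol)
    if deq is None:
        deq, _, diag_eq = _walk_to_zero(params, d0, pt0, n_minus_n0, -1,
                                        xtol=xtol)
    N = params.N
    mk = lambda pt: None if pt is None else {"n": pt[0] * N, "rho": pt[1]}
    return DeltaRange(
        delta_min=dmin, delta_max=dmax, delta_eq=deq,
        at_min=mk(pmin), at_max=mk(pmax),
        diagnostics={"delta_min": diag_min, "delta_max": diag_max,
                     "delta_eq": diag_eq, "anchor_delta": d0},
    )
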