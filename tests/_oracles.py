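"""Independent oracle implementations used only by the test suite.

Each oracle deliberately avoids the code path it checks: the unreduced
six-equation Newton solve (vs the conic-elimination solver), naive
convolution loops (vs the incremental cascade), closed-form / generating
function sequence evaluation (vs the recurrence generators).
"""

from __future__ import annotations

import math

import numpy as np
import scipy.optimize as so


def six_equation_residuals(cs, delta, v):
    """Residuals of the raw stationary system in (x0, x1, x2, x3, rho, n),
    per cell, with the neighbour-occupation probability evaluated directly
    from its definition."""
    c0, c1, c2, c3 = cs
    x0, x1, x2, x3, rho, n = v
    T = (c0 * x0 + c1 * x1 + c2 * x2) / (x0 + x1 + x2)
    return [
        x0 + x1 + x2 + x3 - (1.0 - rho),
        c0 * x0 + c1 * x1 + c2 * x2 + c3 * x3 - delta * rho,
        c0 * x0 - c2 * x2 - 2.0 * c3 * x3 - delta * n,
        (c0 + 3.0 * T) * x0 - delta * rho - delta * x1,
        3.0 * T * x0 - (2.0 * T + c1) * x1 - delta * (x1 - 2.0 * x2),
        T * x2 - c3 * x3 - 3.0 * delta * x3,
    ]


def solve_six_multistart(cs, delta, n_starts=120, seed=0):
    """Admissible (n, rho) roots of the unreduced system, deduplicated."""
    rng = np.random.default_rng(seed)
    fun = lambda v: six_equation_residuals(cs, delta, v)
    found = []
    for _ in range(n_starts):
        rho0 = rng.uniform(0.05, 0.95)
        n0 = rng.uniform(0.001, 0.4)
        w = rng.dirichlet(np.ones(4)) * (1.0 - rho0)
        sol = so.root(fun, np.concatenate([w, [rho0, n0]]), method="hybr",
                      tol=1e-13)
        if not sol.success or max(abs(r) for r in fun(sol.x)) > 1e-10:
            continue
        x0, x1, x2, x3, rho, n = sol.x
        if n <= 0 or not 0 < rho < 1:
            continue
        if min(x0, x1, x2, x3) <= 0 or x2 <= x0:
            continue
        T = (cs[0] * x0 + cs[1] * x1 + cs[2] * x2) / (x0 + x1 + x2)
        if not 0 < T < 1:
            continue
        if not any(math.isclose(n, a, rel_tol=1e-6)
                   and math.isclose(rho, b, rel_tol=1e-6)
                   for a, b in found):
            found.append((n, rho))
    return found


def naive_cascade(g_prev, i, a1, a2, a3, den):
    """Direct three-index evaluation of the cascade equation for g_i
    (g_prev holds g_1..g_{i-1} at indices 1..i-1)."""
    if i == 1:
        raise ValueError("naive_cascade starts at i = 2")
    s2 = 0.0
    for k in range(1, i - 1):
        s2 += g_prev[k] * g_prev[i - 1 - k]
    s3 = 0.0
    for k in range(1, i - 2):
        for l in range(1, i - k - 1):
            m = i - 1 - k - l
            if m >= 1:
                s3 += g_prev[k] * g_prev[l] * g_prev[m]
    return (a1 * g_prev[i - 1] + a2 * s2 + a3 * s3) / den


def motzkin_closed_form(n_terms):
    """Motzkin numbers via the binomial/Catalan closed form
    M(m) = sum_k C(m, 2k) Catalan(k); the sequence here is 1-indexed with
    first two terms 1, 1, i.e. term i equals M(i - 1)."""
    def motz(m):
        return sum(math.comb(m, 2 * k) * math.comb(2 * k, k) // (k + 1)
                   for k in range(m // 2 + 1))
    return [motz(i - 1) for i in range(1, n_terms + 1)]


def a036765_series(n_terms):
    """A036765 via its generating-function fixed point A = 1 + xA + x^2 A^2
    + x^3 A^3, iterated on truncated integer power series; term i of the
    1-indexed sequence equals the coefficient of x^(i-1)."""
    order = n_terms  # need coefficients up to x^(n_terms - 1)

    def mul(a, b):
        out = [0] * order
        for i, ai in enumerate(a):
            if ai == 0:
                continue
            for j, bj in enumerate(b):
                if i + j >= order:
                    break
                out[i + j] += ai * bj
        return out

    A = [1] + [0] * (order - 1)
    for _ in range(order + 1):
        A2 = mul(A, A)
        A3 = mul(A2, A)
        new = [0] * order
        new[0] = 1
        for i in range(1, order):
            new[i] = A[i - 1] + (A2[i - 2] if i >= 2 else 0) \
                + (A3[i - 3] if i >= 3 else 0)
        if new == A:
            break
        A = new
    return A[:n_terms]


def catalan_like_naive(n_terms, a3=0):
    """O(n^3) direct-summation evaluation of the Motzkin-type recurrence
    (independent of the incremental-convolution generator)."""
    M = [1, 1]
    for i in range(3, n_terms + 1):
        s2 = sum(M[k - 1] * M[i - 1 - k - 1] for k in range(1, i - 1))
        s3 = 0
        for k in range(1, i - 2):
            for l in range(1, i - k - 1):
                m = i - 1 - k - l
                if m >= 1:
                    s3 += M[k - 1] * M[l - 1] * M[m - 1]
        M.append(M[-1] + s2 + a3 * s3)
    return M[:n_terms]


def enumerate_subtrees_of_3regular_tree(size):
    """Enumerate all distinct (up to root position) connected subgraphs of
    the 3-regular infinite tree with ``size`` vertices, rooted at a fixed
    cell, and return the set of leaf/perimeter counts observed.

    Grows connected sets vertex by vertex inside a large finite ball.
    Returns a set of perimeter sizes (number of adjacent outside cells).
    """
    # build a ball of radius `size` (ample) around vertex 0
    nbrs = {0: []}
    nxt = 1
    frontier = [0]
    for _ in range(size):
        newf = []
        for v in frontier:
            want = 3 - len(nbrs[v])
            for _ in range(want):
                nbrs[v].append(nxt)
                nbrs[nxt] = [v]
                newf.append(nxt)
                nxt += 1
        frontier = newf
    perimeters = set()
    seen_sets = set()

    def grow(current: frozenset):
        if len(current) == size:
            boundary = set()
            for v in current:
                for nb in nbrs[v]:
                    if nb not in current:
                        boundary.add(nb)
            perimeters.add(len(boundary))
            return
        for v in current:
            for nb in nbrs[v]:
                if nb not in current:
                    nxt_set = current | {nb}
                    if nxt_set not in seen_sets:
                        seen_sets.add(nxt_set)
                        grow(nxt_set)

    grow(frozenset({0}))
    return perimeters


def enumerate_empty_cluster_compositions(size):
    """All (j -> type counts) censuses of connected empty sets of a given
    size on the 3-regular tree, each cell's type given by its number of
    occupied (outside) neighbours, with every outside neighbour occupied.

    Returns a dict j -> set of (creating, enlarging, C2, C3) tuples.
    """
    nbrs = {0: []}
    nxt = 1
    frontier = [0]
    for _ in range(size):
        newf = []
        for v in frontier:
            want = 3 - len(nbrs[v])
            for _ in range(want):
                nbrs[v].append(nxt)
                nbrs[nxt] = [v]
                newf.append(nxt)
                nxt += 1
        frontier = newf
    out: dict[int, set] = {}
    seen_sets = set()

    def census(current: frozenset):
        counts = [0, 0, 0, 0]
        for v in current:
            occ = sum(1 for nb in nbrs[v] if nb not in current)
            counts[occ] += 1
        # counts indexed by occupied neighbours: 0 creating, 1 enlarging,
        # 2 C2, 3 C3 — note index = occupied neighbours directly
        j = counts[0]
        out.setdefault(j, set()).add(tuple(counts))

    def grow(current: frozenset):
        if len(current) == size:
            census(current)
            return
        for v in current:
            for nb in nbrs[v]:
                if nb not in current:
                    nxt_set = current | {nb}
                    if nxt_set not in seen_sets:
                        seen_sets.add(nxt_set)
                        grow(nxt_set)

    grow(frozenset({0}))
    return out
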