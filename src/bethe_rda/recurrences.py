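"""Catalan-like integer recurrences hidden in the cascade equations.

When the three-cluster merging channel is off (``c3 = 0``) the cascade for
``n_i`` can be rescaled to

    M_1 = M_2 = a2,   M_i = M_{i-1} + sum_{k=1}^{i-2} M_k M_{i-1-k}

with ``a2 = (c0 x0)(c2 x2)/(c1 x1)^2`` — the Motzkin-number recurrence up
to initial values.  With all three channels the rescaled recurrence gains a
triple-convolution term with coefficient ``a3 = (c1 x1)(c3 x3)/(c2 x2)^2``;
setting both initial values and the cubic coefficient to 1 produces OEIS
A036765 (ordered rooted trees with all outdegrees <= 3).

Sequence generators work in exact integer / rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import ModelParams, SteadyState
from .errors import DomainError, NoAdmissibleState

__all__ = [
    "ScaledSequence",
    "motzkin",
    "generalized_k3",
    "catalan_like",
    "rescale_cascade",
    "motzkin_limit_aggregates",
    "a036765_limit_aggregates",
]


def catalan_like(n_terms: int, a2=1, a3=0, m1=1, m2=1) -> list:
    """Generic quadratic/cubic convolution recurrence, exact arithmetic.

    ``M_1 = m1``, ``M_2 = m2``; for ``i >= 3``

        M_i = M_{i-1} + a2' * sum_{k=1}^{i-2} M_k M_{i-1-k}
                      + a3  * sum_{k+l<=i-2}  M_k M_l M_{i-1-k-l}

    where the pairwise coefficient ``a2'`` is 1 in the rescaled form (the
    ``a2`` dependence enters through the initial values); here it is kept
    explicit for generality — ``motzkin`` and ``generalized_k3`` use 1.
    The triple sum term is empty until ``i >= 4``.
    """
    if n_terms < 1:
        raise DomainError("n_terms must be >= 1")
    M = [m1, m2]
    conv2 = [None, None, m1 * m1]  # conv2[m] = sum_{k=1}^{m-1} M_k M_{m-k}
    conv3 = [None, None, None]     # conv3[m] = sum_j conv2[j] M_{m-j}
    for i in range(3, n_terms + 1):
        s2 = conv2[i - 1]
        s3 = conv3[i - 1] if i >= 4 else 0
        M.append(M[-1] + a2 * s2 + (a3 * s3 if i >= 4 else 0))
        # extend convolutions to index i (uses M_1..M_{i-1})
        m = i
        conv2.append(sum(M[k - 1] * M[m - k - 1] for k in range(1, m)))
        conv3.append(sum(conv2[j] * M[m - j - 1] for j in range(2, m)))
    return M[:n_terms]


def motzkin(n_terms: int) -> list[int]:
    """Motzkin numbers 1, 1, 2, 4, 9, 21, 51, ... (exact integers).

    ``M_i = M_{i-1} + sum_{k=1}^{i-2} M_k M_{i-1-k}`` with ``M_1 = M_2 = 1``.
    """
    return catalan_like(n_terms, a2=1, a3=0)


def generalized_k3(n_terms: int) -> list[int]:
    """OEIS A036765: 1, 1, 2, 5, 13, 36, 104, ... (exact integers).

    The coordination-number-3 generalization of the Motzkin recurrence:
    the pairwise *and* triple convolution terms both carry coefficient 1,
    with ``M_1 = M_2 = 1`` (the triple term first contributes at the
    fourth term).
    """
    return catalan_like(n_terms, a2=1, a3=1)


@dataclass(frozen=True)
class ScaledSequence:
    """Rescaled cascade terms and their recurrence coefficients.

    ``M[i-1]`` is the i-th rescaled term.  ``a2`` and ``a3`` are the
    coefficients derived from the state; ``base`` is the geometric factor
    ``c1 x1 / ((delta + Y) n)`` absorbed by the rescaling; ``residual`` is
    the largest relative violation of the recurrence by the cascade output.
    """

    M: tuple
    a2: float
    a3: float
    base: float
    residual: float


def rescale_cascade(state: SteadyState, params: ModelParams,
                    n_terms: int = 200) -> ScaledSequence:
    """Map cascade output onto the Motzkin-form recurrence and verify it.

    The rescaling ``n_i / n = (c1 x1 / c2 x2) * base**i * M_i`` with
    ``base = c1 x1 / ((delta + Y) n)`` turns the ``c3 = 0`` cascade into
    ``M_i = M_{i-1} + sum M_k M_{i-1-k}``, ``M_1 = M_2 = a2``; for
    ``c3 != 0`` the triple-convolution term with coefficient ``a3`` is
    included.  The recurrence is *verified* against the cascade terms and
    the worst relative residual reported.
    """
    from .distribution import cascade

    if not params.is_special:
        raise DomainError("rescaling is defined for the law mu_i = delta / i")
    u1 = params.c1 * state.x1
    u2 = params.c2 * state.x2
    if u1 <= 0 or u2 <= 0:
        raise DomainError("rescaling requires c1 x1 > 0 and c2 x2 > 0")
    d = params.delta
    base = u1 / ((d + state.Y) * state.n)
    a2 = (params.c0 * state.x0) * u2 / u1 ** 2
    a3 = u1 * (params.c3 * state.x3) / u2 ** 2
    dist = cascade(state, params, imax=max(n_terms, 4), early_stop=False)
    n_terms = min(n_terms, dist.imax)
    g = dist.counts[:n_terms] / state.n
    pref = u1 / u2
    M = g / (pref * np.power(base, np.arange(1, n_terms + 1)))
    # verify the recurrence term by term
    worst = 0.0
    conv2 = np.zeros(n_terms + 1)
    conv3 = np.zeros(n_terms + 1)
    for i in range(2, n_terms + 1):
        conv2[i] = np.dot(M[0:i - 1], M[i - 2::-1])
        if i >= 3:
            conv3[i] = np.dot(conv2[2:i], M[i - 3::-1])
    for i in range(3, n_terms + 1):
        pred = M[i - 2] + conv2[i - 1] + (a3 * conv3[i - 1] if i >= 4 else 0.0)
        worst = max(worst, abs(M[i - 1] - pred) / abs(M[i - 1]))
    return ScaledSequence(M=tuple(M), a2=a2, a3=a3, base=base,
                          residual=worst)


def motzkin_limit_aggregates(delta_rhoN=Fraction(1)) -> dict:
    """Aggregate rates forced by the exact-Motzkin limit (``c3 = 0``).

    Imposing unit initial values (``a2 = 1``) and the geometric
    compensation ``c1 x1 = (delta + Y) n / 3`` that cancels the 3^i growth
    of Motzkin numbers forces, through the cluster and density balances,

        c0 x0 = c1 x1 = c2 x2 = delta rho N / 3    and    delta n = 0

    i.e. the strictly inverse-power state is reached only as the cluster
    count vanishes.  Returns the forced values (exact fractions scaled by
    ``delta_rhoN``) including ``delta_n``.
    """
    s = Fraction(delta_rhoN)
    # (delta + Y) n = delta n + (c1 x1 + 2 c2 x2) and, via the cluster
    # balance delta n = c0 x0 - c2 x2, this telescopes to the density
    # balance sum: (delta + Y) n = c0 x0 + c1 x1 + c2 x2 = delta rho N.
    u1 = s / 3
    # a2 = 1 with u0 u2 = u1^2 and u0 + u2 = s - u1 = 2s/3 forces u0 = u2
    u0 = u2 = s / 3
    delta_n = u0 - u2
    assert delta_n == 0
    return {"c0x0": u0, "c1x1": u1, "c2x2": u2, "delta_rhoN": s,
            "delta_n": delta_n}


def a036765_limit_aggregates(delta_rhoN=Fraction(1)) -> dict:
    """The corresponding limit for the full three-channel recurrence —
    provably unreachable.

    Unit initial values and a unit triple-convolution coefficient force
    ``c0 x0 = c1 x1 = c2 x2 = c3 x3 = delta rho N / 4``; the cluster
    balance then gives ``delta n = c0 x0 - c2 x2 - 2 c3 x3 =
    -delta rho N / 2 < 0``, contradicting ``n > 0``.

    Raises
    ------
    NoAdmissibleState
        Always — such initial conditions cannot be set.
    """
    s = Fraction(delta_rhoN)
    u = s / 4  # symmetric solution of u0 u2 = u1^2, u1 u3 = u2^2, sum = s
    delta_n = u - u - 2 * u
    assert delta_n == -s / 2
    raise NoAdmissibleState(
        "unreachable initial condition",
        f"unit-coefficient limit forces delta*n = {delta_n} < 0")
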