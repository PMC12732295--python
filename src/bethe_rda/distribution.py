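"""Cluster-size distribution from the cascade balance equations.

Given a solved stationary state, the number ``n_i`` of clusters of size
``i`` follows from a triangular ("cascade") system: each ``n_i`` depends
only on ``n_1 .. n_{i-1}`` through single, double and triple convolutions
weighted by the enlarging/merging channels:

    n_1 = c0 x0 / (mu_1 + Y)
    n_i = [ c1 x1 n_{i-1}/n
            + c2 x2 sum_{k} (n_k/n)(n_{i-1-k}/n)
            + c3 x3 sum_{k,l} (n_k/n)(n_l/n)(n_{i-1-k-l}/n) ] / (i mu_i + Y)

with ``Y = (c1 x1 + 2 c2 x2 + 3 c3 x3)/n``.  Internally the per-cluster
ratios ``g_i = n_i / n`` are propagated (they stay O(1)); the double and
triple sums are maintained as incremental self-convolutions so the total
cost is O(imax^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ModelParams, SteadyState
from .errors import DomainError

__all__ = [
    "ClusterDistribution",
    "cascade",
    "mean_cluster_size",
    "invert_for_mu",
    "tail_slope",
]


@dataclass(frozen=True)
class ClusterDistribution:
    """Cluster counts by size, at the reference scale of the source state.

    ``counts[i-1]`` is ``n_i`` per ``N`` cells for ``i = 1..imax``.
    ``captured_mass = sum(i n_i) / (rho N)`` and
    ``captured_count = sum(n_i) / n`` are truncation diagnostics: both
    approach 1 as ``imax`` grows.
    """

    counts: np.ndarray
    imax: int
    N: float
    n: float
    rho: float
    Y: float
    mu: tuple = field(repr=False, default=())  # mu_i for i = 1..imax

    def __getitem__(self, i: int) -> float:
        if not 1 <= i <= self.imax:
            raise DomainError(f"size {i} outside [1, {self.imax}]")
        return float(self.counts[i - 1])

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.imax + 1)

    @property
    def captured_mass(self) -> float:
        return float(np.dot(self.sizes, self.counts) / (self.rho * self.N))

    @property
    def captured_count(self) -> float:
        return float(self.counts.sum() / self.n)

    def moment_sum(self, order: int) -> float:
        """``sum_i mu_i n_i i**order`` — the moment sums feeding the
        balance residuals."""
        i = self.sizes.astype(float)
        return float(np.dot(np.asarray(self.mu) * i ** order, self.counts))

    def as_dict(self) -> dict[int, float]:
        return {int(i): float(v) for i, v in zip(self.sizes, self.counts)}


def _channel_weights(state: SteadyState, params: ModelParams):
    """Per-cluster channel rates a1, a2, a3 (and the creation rate a0)."""
    n = state.n
    if n <= 0:
        raise DomainError("cascade requires n > 0")
    return (params.c0 * state.x0 / n, params.c1 * state.x1 / n,
            params.c2 * state.x2 / n, params.c3 * state.x3 / n)


def cascade(state: SteadyState, params: ModelParams, imax: int = 10_000,
            early_stop: bool = True) -> ClusterDistribution:
    """Evaluate the cascade equations up to size ``imax``.

    ``mu_i`` comes from ``params`` (general law or ``delta/i``).  With
    ``early_stop`` the cascade stops once ``i * n_i < 1e-12 rho N`` (the
    remaining tail is numerically irrelevant); the returned ``imax``
    reflects the truncation actually used.
    """
    if imax < 4:
        raise DomainError("imax must be >= 4")
    a0, a1, a2, a3 = _channel_weights(state, params)
    Y = state.Y
    n, N, rho = state.n, state.N, state.rho
    mu = np.array([params.mu_of(i) for i in range(1, imax + 1)])
    g = np.zeros(imax + 1)        # g[i] = n_i / n
    conv2 = np.zeros(imax + 2)    # conv2[m] = sum_{k=1}^{m-1} g_k g_{m-k}
    conv3 = np.zeros(imax + 2)    # conv3[m] = sum_{j=2}^{m-1} conv2[j] g_{m-j}
    used = imax
    for i in range(1, imax + 1):
        den = i * mu[i - 1] + Y
        if den <= 0:
            raise DomainError(f"i*mu_i + Y = {den} not positive at i={i}")
        if i == 1:
            g[1] = a0 / den
        else:
            g[i] = (a1 * g[i - 1] + a2 * conv2[i - 1] + a3 * conv3[i - 1]) / den
        if g[i] <= 0:
            raise DomainError(f"cascade lost positivity at i={i}")
        if early_stop and i * g[i] * n < 1e-12 * rho * N:
            used = i
            break
        # extend the self-convolutions to index i+1 (uses g_1..g_i only)
        m = i + 1
        if m <= imax:
            conv2[m] = np.dot(g[1:m], g[m - 1:0:-1])
            if m >= 3:
                conv3[m] = np.dot(conv2[2:m], g[m - 2:0:-1])
    counts = g[1:used + 1] * n
    return ClusterDistribution(counts=counts, imax=used, N=N, n=n, rho=rho,
                               Y=Y, mu=tuple(mu[:used]))


def convolution_terms(dist: ClusterDistribution, i: int) -> tuple[float, float]:
    """The double and triple convolution sums entering the equation for
    ``n_i``, in per-cluster units (for cross-checking against direct loops):

    ``S2 = sum_{k=1}^{i-2} g_k g_{i-1-k}``,
    ``S3 = sum_{k,l >= 1, k+l <= i-2} g_k g_l g_{i-1-k-l}``.
    """
    g = np.concatenate(([0.0], dist.counts / dist.n))
    s2 = float(np.dot(g[1:i - 1], g[i - 2:0:-1])) if i >= 3 else 0.0
    s3 = 0.0
    if i >= 4:
        conv2 = [0.0, 0.0] + [float(np.dot(g[1:m], g[m - 1:0:-1]))
                              for m in range(2, i)]
        s3 = float(np.dot(conv2[2:i - 1], g[i - 3:0:-1]))
    return s2, s3


def mean_cluster_size(state: SteadyState,
                      dist: ClusterDistribution | None = None) -> dict:
    """Average cluster size, by the exact identity and by truncated sums.

    ``exact = rho N / n`` (equivalently ``Y/delta + 1`` for the solvable
    law).  If a distribution is given, the truncated-cascade mean
    ``sum(i n_i) / sum(n_i)`` is reported alongside — for heavy-tailed
    states it can differ substantially from the exact value at any finite
    truncation.
    """
    if state.n <= 0:
        raise DomainError("mean size undefined for n <= 0")
    out = {"exact": state.rho * state.N / state.n}
    if dist is not None:
        tot = dist.counts.sum()
        out["truncated"] = float(np.dot(dist.sizes, dist.counts) / tot)
    return out


def invert_for_mu(target: np.ndarray, state: SteadyState,
                  params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Avalanche probabilities ``mu_i`` that reproduce a target distribution.

    Solves each cascade equation for ``i mu_i`` with the state quantities
    (``x``, ``n``, ``Y``) held fixed:

        i mu_i = (cascade numerator for n_i) / n_i - Y

    Returns ``(mu, realizable)`` where ``realizable[i-1]`` is False when
    the implied ``mu_i`` falls outside [0, 1] (the target cannot be
    produced by any avalanche law at this state).
    """
    target = np.asarray(target, dtype=float)
    if np.any(target <= 0):
        raise DomainError("target n_i must be strictly positive")
    a0, a1, a2, a3 = _channel_weights(state, params)
    Y = state.Y
    imax = len(target)
    g = np.concatenate(([0.0], target / state.n))
    mu = np.empty(imax)
    for i in range(1, imax + 1):
        if i == 1:
            num = a0
        else:
            s2 = float(np.dot(g[1:i - 1], g[i - 2:0:-1])) if i >= 3 else 0.0
            s3 = 0.0
            if i >= 4:
                conv2 = [0.0, 0.0] + [float(np.dot(g[1:m], g[m - 1:0:-1]))
                                      for m in range(2, i)]
                s3 = float(np.dot(conv2[2:i - 1], g[i - 3:0:-1]))
            num = a1 * g[i - 1] + a2 * s2 + a3 * s3
        mu[i - 1] = (num / g[i] - Y) / i
    realizable = (mu >= 0.0) & (mu <= 1.0)
    return mu, realizable


def tail_slope(dist: ClusterDistribution, i_lo: int, i_hi: int) -> float:
    """Least-squares slope of ``log n_i`` against ``log i`` on ``[i_lo, i_hi]``."""
    if not (i_hi > i_lo >= 2):
        raise DomainError("need i_hi > i_lo >= 2")
    i_hi = min(i_hi, dist.imax)
    if i_hi - i_lo + 1 < 3:
        raise DomainError("need at least 3 points for a slope estimate")
    i = np.arange(i_lo, i_hi + 1)
    y = dist.counts[i_lo - 1:i_hi]
    if np.any(y <= 0):
        raise DomainError("distribution not positive on the requested range")
    return float(np.polyfit(np.log(i), np.log(y), 1)[0])
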