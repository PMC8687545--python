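"""Closed-form MSD theory for the centroid jump process.

The attachment count of the n-FA cell is a birth--death chain whose
stationary law ``pi`` has an explicit form in the propensity ratio ``r``.
Conditioning on the count and on the kind of the next event, the centroid
displacement is a simple function of the outreach vectors: an attach event
taking the count from k-1 to k moves the centroid by ``eta/k``, while a
detach displacement is computable in closed form whenever the attached FAs
form a *sequential configuration* -- one reachable by attaching FAs one at a
time at outreaches from successively updated centroids.

Assigning the full stationary probabilities to the sequential-configuration
detach displacements yields the approximate MSD at one event lag (AMSD).
Restricting instead to histories that literally follow a sequential creation
story yields a lower bound; the companion upper bound lives in
``centroidmsd.worst_case``.  All combinatorics use exact integer binomials,
and every formula degrades gracefully to ``fractions.Fraction`` inputs for
exact rational verification.

All analytic results assume equal spring weights (plain averages); passing
unequal weights raises ``UnequalWeightsError``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np

from .geometry import (
    CellState,
    OutreachDistribution,
    UnequalWeightsError,
    outreach_mean_square,
    outreach_mean_vector,
)

__all__ = [
    "SequentialConfiguration",
    "switch_probability",
    "stationary_distribution",
    "mean_jump",
    "attach_displacement",
    "detach_possibilities",
    "build_sequential_state",
    "attach_expectation",
    "detach_sum_expectation",
    "amsd",
    "amsd_attach_part",
    "exact_msd_small_n",
    "sequential_path_probability",
    "lower_bound",
    "msd_of_tau",
]


def _check_weights(weights) -> None:
    if weights is None:
        return
    w = np.asarray(weights, dtype=float)
    if w.size and not np.all(w == w.flat[0]):
        raise UnequalWeightsError(
            "the analytic MSD formulas assume equal spring weights"
        )


# ---------------------------------------------------------------------------
# Birth--death chain on the attachment count


def switch_probability(n: int, r, k: int):
    """Per-FA switch probability ``p_k = 1/(k + (n-k) r)``.

    ``r p_k`` is the probability that a given detached FA attaches next and
    ``p_k`` that a given attached FA detaches next, so
    ``k p_k + (n-k) r p_k = 1``.  Exact under ``Fraction`` arithmetic.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    return 1 / (k + (n - k) * r)


def stationary_distribution(n: int, r):
    """Stationary law ``(pi_0, ..., pi_n)`` of the attachment count.

    ``pi_0 = 1/(2 (1+r)^(n-1))`` and, for ``1 <= k <= n``,
    ``pi_k = r^(k-1) C(n-1, k-1) [k + (n-k) r] / (2 (1+r)^(n-1) k)``.

    Returns a float array, or a list of ``Fraction`` when ``r`` is one
    (useful for exact normalization and stationarity checks).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    norm = 2 * (1 + r) ** (n - 1)
    vals = [1 / norm]
    for k in range(1, n + 1):
        vals.append(r ** (k - 1) * comb(n - 1, k - 1) * (k + (n - k) * r) / (norm * k))
    if isinstance(vals[0], float):
        return np.array(vals)
    return vals


def mean_jump(n: int, r: float, dist: OutreachDistribution, weights=None) -> np.ndarray:
    """First moment of the per-event centroid displacement in stationarity.

    ``E[c^{j+1} - c^j]`` is proportional to ``E[eta]``:

    ``(1 + sum_{k=1}^{n} (r^{k-1}(1-r) C(n-1,k-1) + r^k C(n,k))
       * r (n-k) / ((k + r(n-k)) (k+1))) * E[eta] / (2 (1+r)^{n-1})``.
    """
    _check_weights(weights)
    if n < 1:
        raise ValueError("n must be >= 1")
    s = 0.0
    for k in range(1, n + 1):
        coeff = r ** (k - 1) * (1 - r) * comb(n - 1, k - 1) + r**k * comb(n, k)
        s += coeff * r * (n - k) / ((k + r * (n - k)) * (k + 1))
    factor = (1 + s) / (2 * (1 + r) ** (n - 1))
    return factor * outreach_mean_vector(dist)


# ---------------------------------------------------------------------------
# Sequential configurations and displacement algebra


@dataclass(frozen=True)
class SequentialConfiguration:
    """A k-FA configuration described by its sequential creation story.

    ``outreaches[m-2]`` is the outreach ``eta_m`` taken when the m-th FA
    attached (m = 2..k); the first FA sits at the first centroid, so eta_1
    never enters the detach algebra.
    """

    outreaches: np.ndarray  # shape (k-1, 2)

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.outreaches, dtype=float))
        if arr.size == 0:
            arr = np.empty((0, 2))
        if arr.shape[1] != 2:
            raise ValueError("outreaches must be planar vectors")
        object.__setattr__(self, "outreaches", arr)

    @property
    def k(self) -> int:
        return self.outreaches.shape[0] + 1


def attach_displacement(k: int, eta) -> np.ndarray:
    """Centroid displacement ``eta/k`` for an attach event reaching k FAs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return np.asarray(eta, dtype=float) / k


def build_sequential_state(
    config: SequentialConfiguration, origin=(0.0, 0.0)
) -> CellState:
    """Realize a sequential configuration geometrically.

    FA 1 sits at the first centroid (``origin``); FA m attaches at
    ``c_{m-1} + eta_m`` and the centroid updates to ``c_{m-1} + eta_m/m``.
    The returned state has all k FAs attached and satisfies force balance.
    """
    k = config.k
    c = np.asarray(origin, dtype=float).copy()
    v = np.empty((k, 2))
    v[0] = c
    for m in range(2, k + 1):
        eta = config.outreaches[m - 2]
        v[m - 1] = c + eta
        c = c + eta / m
    return CellState(psi=np.ones(k, dtype=bool), v=v, c=c)


def detach_possibilities(config: SequentialConfiguration) -> list[np.ndarray]:
    """The k centroid displacements when one FA of a sequential k-state detaches.

    Entry ``l`` (l = 0..k-2) is the displacement when creation-story FA
    ``l+1`` detaches:

    ``(1/(k-1)) [ sum_{m=l+2}^{k} eta_m/m  -  l * eta_{l+1}/(l+1) ]``,

    and the last entry, for FA k detaching, is ``-eta_k/k``.
    """
    k = config.k
    if k < 2:
        raise ValueError("detach displacements require k >= 2")
    etas = config.outreaches  # etas[m-2] = eta_m
    scaled = etas / np.arange(2, k + 1)[:, None]  # eta_m / m
    tail = np.vstack([np.cumsum(scaled[::-1], axis=0)[::-1], np.zeros((1, 2))])
    out = []
    for ell in range(k - 1):
        vec = tail[ell]  # sum_{m=ell+2}^{k} eta_m/m
        if ell > 0:
            vec = vec - ell * etas[ell - 1] / (ell + 1)
        out.append(vec / (k - 1))
    out.append(-etas[k - 2] / k)
    return out


def attach_expectation(k: int, dist: OutreachDistribution) -> float:
    """``E |c^{j+1} - c^j|^2 = E[|eta|^2] / k^2`` for an attach reaching k FAs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return outreach_mean_square(dist) / k**2


def detach_sum_expectation(k: int, dist: OutreachDistribution) -> float:
    """Sum over the k detach possibilities of ``E |c^{j+1} - c^j|^2``.

    ``(1/(k-1)^2) sum_{i=1}^{k-1} i E[|eta|^2]/(i+1)``.  Note this is the
    total over the possibilities, not their average: in the MSD assembly it
    is multiplied by the per-FA detach probability ``p_k``.  The closed form
    drops the cross terms ``E[eta_i] . E[eta_j]``, exact for a mean-zero
    (e.g. isotropic) outreach law.
    """
    if k < 2:
        raise ValueError("detach expectations require k >= 2")
    e2 = outreach_mean_square(dist)
    return sum(i * e2 / (i + 1) for i in range(1, k)) / (k - 1) ** 2


# ---------------------------------------------------------------------------
# MSD at one event lag


def amsd_attach_part(n: int, r: float, dist: OutreachDistribution) -> float:
    """Contribution of attach events to the one-lag MSD (exact, any state).

    ``E[|eta|^2]/(2(1+r)^{n-1}) * (1 + sum_{k=1}^{n-1} C(n-1,k) r^k/(k+1)^2)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    e2 = outreach_mean_square(dist)
    s = 1.0 + sum(comb(n - 1, k) * r**k / (k + 1) ** 2 for k in range(1, n))
    return e2 * s / (2 * (1 + r) ** (n - 1))


def amsd(n: int, r: float, dist: OutreachDistribution, weights=None) -> float:
    """Approximate MSD at one event lag.

    Attach displacements are exact for the whole state space; detach
    displacements use the sequential-configuration algebra but carry the
    *full* stationary probabilities ``pi_k p_k``:

    ``AMSD(1) = E[|eta|^2]/(2(1+r)^{n-1}) * [ 1 +
        sum_{k=1}^{n-1} C(n-1,k) r^k ( 1/(k+1)^2
          + (1/((k+1) k^2)) sum_{i=1}^{k} i/(i+1) ) ]``.

    For n = 1 the sum is empty and ``AMSD = E[|eta|^2]/2``; for n = 2 the
    formula is the exact MSD.
    """
    _check_weights(weights)
    if n < 1:
        raise ValueError("n must be >= 1")
    e2 = outreach_mean_square(dist)
    s = 1.0
    for k in range(1, n):
        inner = sum(i / (i + 1) for i in range(1, k + 1))
        s += comb(n - 1, k) * r**k * (1 / (k + 1) ** 2 + inner / ((k + 1) * k**2))
    return e2 * s / (2 * (1 + r) ** (n - 1))


def exact_msd_small_n(n: int, r: float, dist: OutreachDistribution) -> float:
    """Exact one-lag MSD for n = 1 or n = 2 (full enumeration of states).

    ``n=1: E[|eta|^2]/2``;  ``n=2: E[|eta|^2] (1 + r/2) / (2 (1+r))``.
    """
    e2 = outreach_mean_square(dist)
    if n == 1:
        return e2 / 2
    if n == 2:
        return e2 * (1 + r / 2) / (2 * (1 + r))
    raise ValueError("exact enumeration implemented for n in {1, 2} only")


# ---------------------------------------------------------------------------
# Sequential histories and the lower bound


def sequential_path_probability(n: int, r: float, k: int) -> float:
    """Probability ``P_k^d`` of a literal sequential history ending in a detach.

    Start with no attachments (probability ``pi_0``), attach k FAs one at a
    time (factors ``r p_0 n, r p_1 (n-1), ..., r p_{k-1} (n-k+1)``) and then
    detach one of the k (factor ``p_k k``):

    ``P_k^d(r) = pi_0 * k * r^k * p_0 p_1 ... p_k * n!/(n-k)!``.

    As ``r -> 0``, ``P_1^d -> 1/2`` and ``P_k^d -> 0`` for k >= 2; as
    ``r -> infinity`` every ``P_k^d -> 0``.
    """
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    pi0 = 1 / (2 * (1 + r) ** (n - 1))
    prod = 1.0
    for i in range(k + 1):
        prod *= switch_probability(n, r, i)
    return pi0 * k * r**k * prod * (factorial(n) / factorial(n - k))


def lower_bound(n: int, r: float, dist: OutreachDistribution, weights=None) -> float:
    """Lower bound on the one-lag MSD.

    Attach contributions are kept in full; detach contributions are only
    credited when the history literally follows a sequential creation story
    (probability ``P_k^d``), every other detach displacement being replaced
    by zero:

    ``LB = attach part + sum_{k=2}^{n} (P_k^d / k) * S_k``

    with ``S_k`` the detach-possibility sum ``detach_sum_expectation``.
    ``LB <= AMSD`` holds term by term.
    """
    _check_weights(weights)
    total = amsd_attach_part(n, r, dist)
    for k in range(2, n + 1):
        total += sequential_path_probability(n, r, k) / k * detach_sum_expectation(k, dist)
    return total


# ---------------------------------------------------------------------------
# MSD as a function of the event lag


def msd_of_tau(n: int, r: float, dist: OutreachDistribution, tau: int) -> float:
    """Quadratic-in-lag MSD estimate ``tau (AMSD - |m|^2) + tau^2 |m|^2``.

    ``m = mean_jump(n, r, dist)`` is the drift per event.  The form is the
    variance/drift decomposition of a space- and time-homogeneous walk; the
    centroid jumps are not independent, so for ``tau > 1`` this is an
    approximation.  At ``tau = 1`` it reduces to the AMSD exactly, and for
    an isotropic outreach law it is linear in ``tau``.
    """
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    m = mean_jump(n, r, dist)
    m2 = float(m @ m)
    a = amsd(n, r, dist)
    return tau * (a - m2) + tau**2 * m2
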