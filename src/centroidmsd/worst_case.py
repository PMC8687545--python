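"""Worst-case centroid displacements and the MSD upper bound.

The largest one-event displacement arises when one FA stays attached near
the origin while the others repeatedly reattach at maximal outreach
``eta_max`` in a common direction.  The positions of the far FAs then obey a
linear recurrence whose unique steady state is ``eta_max (n-1)``; all roots
of its characteristic polynomial lie strictly inside the unit circle, so the
steady state attracts and the limiting detach displacement
``eta_max (n-1)/n`` is approached (but it is a rare event).

Weighting these worst-case displacements by the non-sequential detach
probability mass, and keeping the exact attach and sequential-detach terms,
gives an upper bound on the one-lag MSD.
"""

from __future__ import annotations

import numpy as np

from .geometry import OutreachDistribution
from .theory import (
    amsd_attach_part,
    detach_sum_expectation,
    sequential_path_probability,
    stationary_distribution,
    switch_probability,
    _check_weights,
)

__all__ = [
    "max_detach_displacement",
    "recurrence_trajectory",
    "recurrence_fixed_point",
    "characteristic_roots",
    "limiting_displacement",
    "upper_bound_msd",
]


def max_detach_displacement(n: int, k: int, eta_max: float) -> float:
    """Upper bound ``eta_max (n-1)/k`` on a detach displacement with k attached.

    Derived from the worst-case configuration in which every attached FA but
    the detaching one sits ``eta_max (n-1)`` away from it.  Decreasing in k;
    at ``k = n`` it is the overall worst case ``eta_max (n-1)/n``.
    """
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    return eta_max * (n - 1) / k


def recurrence_fixed_point(n: int, eta_max: float) -> float:
    """Steady state ``x* = eta_max (n-1)`` of the worst-case FA recurrence."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return eta_max * (n - 1)


def recurrence_trajectory(n: int, eta_max: float, x_init=0.0, steps: int = 1000) -> np.ndarray:
    """Iterate ``x_t = (x_{t-1} + ... + x_{t-n+2})/(n-1) + eta_max``.

    The window holds the previous ``n-2`` FA positions (the pinned first FA
    at 0 is absorbed into the ``n-1`` divisor).  ``x_init`` may be a scalar
    (the window is filled with it) or a length ``n-2`` sequence, newest
    entry last.  Converges geometrically to ``eta_max (n-1)``.
    """
    if n < 3:
        raise ValueError("the recurrence needs n >= 3 (nonempty window)")
    w = n - 2
    init = np.asarray(x_init, dtype=float)
    if init.ndim == 0:
        window = [float(init)] * w
    else:
        if init.shape != (w,):
            raise ValueError(f"x_init must be scalar or length {w}")
        window = list(init)
    out = np.empty(steps)
    for t in range(steps):
        x = sum(window) / (n - 1) + eta_max
        out[t] = x
        window.pop(0)
        window.append(x)
    return out


def characteristic_roots(n: int) -> tuple[np.ndarray, float]:
    """Roots of ``(n-1) lam^{n-2} = lam^{n-3} + ... + lam + 1``.

    Returns ``(roots, zeta)`` where ``zeta`` is the unique positive real
    root; every root has modulus < 1, which is what makes the worst-case
    steady state attracting.
    """
    if n < 3:
        raise ValueError("characteristic polynomial defined for n >= 3")
    coeffs = np.array([n - 1.0] + [-1.0] * (n - 2))
    roots = np.roots(coeffs)
    real_pos = [z.real for z in roots if abs(z.imag) < 1e-9 and z.real > 0]
    if len(real_pos) != 1:
        raise RuntimeError("expected exactly one positive real root")
    return roots, float(real_pos[0])


def limiting_displacement(n: int, eta_max: float) -> float:
    """Displacement ``eta_max (n-1)/n`` attained in the worst-case limit."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return eta_max * (n - 1) / n


def upper_bound_msd(n: int, r: float, dist: OutreachDistribution, weights=None) -> float:
    """Upper bound on the one-lag MSD via a three-part state partition.

    Attach events keep their exact values and full probabilities; detach
    events from literal sequential histories (probability ``P_k^d``) keep
    the sequential algebra; every remaining detach event is charged the
    worst-case displacement ``eta_max (n-1)/k`` with the leftover
    probability ``k pi_k p_k - P_k^d`` (clamped at zero against rounding):

    ``UB = attach part + sum_{k>=2} (P_k^d/k) S_k
          + sum_{k>=2} max(0, k pi_k p_k - P_k^d) (eta_max (n-1)/k)^2``.

    Detaching the last FA (k = 1) leaves the centroid in place and
    contributes nothing.
    """
    _check_weights(weights)
    if n < 1:
        raise ValueError("n must be >= 1")
    eta_max = dist.max_length
    pi = stationary_distribution(n, r)
    total = amsd_attach_part(n, r, dist)
    for k in range(2, n + 1):
        pkd = sequential_path_probability(n, r, k)
        total += pkd / k * detach_sum_expectation(k, dist)
        leftover = max(0.0, k * pi[k] * switch_probability(n, r, k) - pkd)
        total += leftover * max_detach_displacement(n, k, eta_max) ** 2
    return total
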